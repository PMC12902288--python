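import numpy as np
import pytest

from introflow import coalsim, genotypes


def make_gm(calls, positions=None, contig_length=100_000, qual=60.0,
            pops=None, contig=None):
    """Build a GenotypeMatrix from a (n_samples, n_sites) dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    if positions is None:
        positions = np.arange(s) * 10
    if contig is None:
        contig = np.repeat("chr1", s)
    samples = [f"s{i}" for i in range(n)]
    if pops is None:
        pops = ["pop1"] * (n // 2) + ["pop2"] * (n - n // 2)
    contigs = {c: contig_length for c in dict.fromkeys(contig)}
    return genotypes.GenotypeMatrix(
        samples=samples,
        sample_pops=list(pops),
        contigs=contigs,
        site_contig=np.asarray(contig, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        qual=np.full(s, qual, dtype=float),
        ref=np.full(s, "A", dtype=object),
        alt=np.full(s, "T", dtype=object),
        calls=calls,
    )


def make_freq_table(freqs, pops=("P1", "P2", "P3", "O"), roles=None,
                    positions=None, contig=None, counts=8, polarized=True):
    """AlleleFreqTable from a (n_pops, n_sites) frequency array."""
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    n_pops, s = freqs.shape
    pops = list(pops)[:n_pops]
    if roles is None and set(pops) >= {"P1", "P2", "P3", "O"}:
        roles = {r: r for r in ("P1", "P2", "P3", "O")}
    if positions is None:
        positions = np.arange(s) * 10
    if contig is None:
        contig = np.repeat("chr1", s)
    return genotypes.AlleleFreqTable(
        pops=pops,
        roles=roles,
        polarized=polarized,
        site_contig=np.asarray(contig, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        freqs=freqs,
        counts=np.full((n_pops, s), counts, dtype=np.int64),
    )


@pytest.fixture(scope="session")
def study_pulse_dataset():
    model = coalsim.scenario_preset("study_pulse", phi=0.1)
    return coalsim.simulate(
        model, {"HS": 4, "TP_E": 4, "TP_M": 4, "TP_W": 4, "J": 2},
        n_loci=190, locus_length=1000, seed=11, n_contigs=19,
    )


@pytest.fixture(scope="session")
def study_pulse_freqs(study_pulse_dataset):
    gm = genotypes.from_simulated(study_pulse_dataset)
    roles = {"P1": "TP_W", "P2": "TP_E", "P3": "HS", "O": "J"}
    return gm, genotypes.allele_freqs(gm, roles=roles, polarize_by_outgroup=True)
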