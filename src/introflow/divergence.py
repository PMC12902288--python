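"""Pairwise codon-level Ka/Ks (Nei & Gojobori 1986) and the molecular
clock T = Ks / (2 r).

The NG86 method counts, per codon of the universal genetic code, the
fraction of possible single-nucleotide changes that are synonymous
(changes to stop codons count as nonsynonymous for site counting), and
averages observed differences over all minimal mutational pathways
between a codon pair, weighting pathways equally and discarding pathways
that pass through a stop codon.  Proportions are corrected for multiple
hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).  A
two-sided Fisher exact test on the rounded count table
{(Nd, N - Nd), (Sd, S - Sd)} gives the significance of omega != 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KaKsResult", "DivergenceEstimate", "kaks_ng86", "clock_convert"]

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STANDARD_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TO_AA = dict(zip(_CODONS, _STANDARD_TABLE))
STOP_CODONS = {c for c, aa in CODON_TO_AA.items() if aa == "*"}


@dataclass
class KaKsResult:
    ka: float
    ks: float
    omega: float  # NaN when Ks == 0 or undefined
    n_sites: float  # nonsynonymous sites N
    s_sites: float  # synonymous sites S
    n_diffs: float  # pathway-averaged nonsynonymous differences Nd
    s_diffs: float  # Sd
    p_fisher: float
    n_codons: int


@dataclass
class DivergenceEstimate:
    ks: float
    rate_per_year: float
    time_years: float
    generation_time: float | None = None

    @property
    def rate_per_generation(self) -> float | None:
        if self.generation_time is None:
            return None
        return self.rate_per_year * self.generation_time


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon (sums to 3)."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        s_pos = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TO_AA[alt] == aa:  # stop codons never match a sense aa
                s_pos += 1
        syn += s_pos / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts between two codons.

    All orders of introducing the differing positions are enumerated;
    pathways passing through a stop codon are discarded (if every
    pathway hits a stop, all are kept as a fallback so counts remain
    defined).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(1.0 for a, b in steps if CODON_TO_AA[a] == CODON_TO_AA[b])
        paths.append((through_stop, syn, len(steps) - syn))
    usable = [p for p in paths if not p[0]] or paths
    syn = sum(p[1] for p in usable) / len(usable)
    nonsyn = sum(p[2] for p in usable) / len(usable)
    return syn, nonsyn


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return np.nan
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _check_cds(seq: str, label: str) -> str:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: length {len(seq)} not divisible by 3")
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if any(b not in _BASES for b in codon):
            raise ValueError(f"{label}: non-ACGT base in codon {i // 3}")
        if codon in STOP_CODONS and i + 3 < len(seq):
            raise ValueError(f"{label}: internal stop codon at codon {i // 3}")
    return seq


def kaks_ng86(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka/Ks for a gap-free codon-aligned pair of CDS sequences.

    A trailing stop codon (present in both) is dropped before counting.
    omega is NaN when Ks = 0 (including identical sequences) or when the
    Jukes-Cantor correction is undefined (p >= 3/4).
    """
    s1 = _check_cds(seq1, "sequence 1")
    s2 = _check_cds(seq2, "sequence 2")
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    if s1[-3:] in STOP_CODONS and s2[-3:] in STOP_CODONS:
        s1, s2 = s1[:-3], s2[:-3]
    n_codons = len(s1) // 3
    if n_codons == 0:
        raise ValueError("no codons to compare")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        syn1, non1 = _syn_fraction(c1)
        syn2, non2 = _syn_fraction(c2)
        S += 0.5 * (syn1 + syn2)
        N += 0.5 * (non1 + non2)
        sd, nd = _pathway_diffs(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    omega = ka / ks if (ks and not np.isnan(ks) and not np.isnan(ka) and ks > 0) else np.nan
    # Fisher exact on rounded (half-up) integer counts
    rnd = lambda x: int(np.floor(x + 0.5))
    table = [[rnd(Nd), max(rnd(N) - rnd(Nd), 0)], [rnd(Sd), max(rnd(S) - rnd(Sd), 0)]]
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    return KaKsResult(ka=float(ka), ks=float(ks), omega=float(omega),
                      n_sites=N, s_sites=S, n_diffs=Nd, s_diffs=Sd,
                      p_fisher=float(p_fisher), n_codons=n_codons)


def clock_convert(
    ks: float | None = None,
    rate_per_year: float | None = None,
    time_years: float | None = None,
    generation_time: float | None = None,
) -> DivergenceEstimate:
    """Solve the molecular clock T = Ks / (2 r) for the missing quantity.

    Exactly two of (ks, rate_per_year, time_years) must be given; Ks = 0
    with a given rate is allowed and yields T = 0.  With
    ``generation_time`` the per-generation rate r * g is also reported.
    """
    given = [x is not None for x in (ks, rate_per_year, time_years)]
    if sum(given) != 2:
        raise ValueError("give exactly two of ks, rate_per_year, time_years")
    for name, val in (("ks", ks), ("rate_per_year", rate_per_year),
                      ("time_years", time_years)):
        if val is not None and val < 0:
            raise ValueError(f"{name} must be non-negative")
        if name == "rate_per_year" and val is not None and val == 0:
            raise ValueError("rate_per_year must be positive")
    if ks is None:
        ks = 2.0 * rate_per_year * time_years
    elif rate_per_year is None:
        if time_years == 0:
            raise ValueError("time_years must be positive to solve for the rate")
        rate_per_year = ks / (2.0 * time_years)
    else:
        time_years = ks / (2.0 * rate_per_year)
    return DivergenceEstimate(ks=float(ks), rate_per_year=float(rate_per_year),
                              time_years=float(time_years),
                              generation_time=generation_time)


def read_fasta_pair(path, path2=None) -> tuple[str, str]:
    """Read a codon-aligned pair: two records in one FASTA, or one each."""
    def records(p):
        out, name, seq = [], None, []
        with open(p) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        out.append("".join(seq))
                    name, seq = line[1:], []
                elif line:
                    seq.append(line)
        if name is not None:
            out.append("".join(seq))
        return out
    if path2 is None:
        recs = records(path)
        if len(recs) != 2:
            raise ValueError(f"{path}: expected exactly 2 records, got {len(recs)}")
        return recs[0], recs[1]
    r1, r2 = records(path), records(path2)
    if len(r1) != 1 or len(r2) != 1:
        raise ValueError("each file must contain exactly one record")
    return r1[0], r2[0]
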