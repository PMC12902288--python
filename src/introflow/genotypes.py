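"""VCF ingestion, variant filtering, polarized allele frequencies, windows.

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted at the I/O boundary.  Filter thresholds use strict inequalities
with the standard RAD hard-filter defaults (missing fraction < 0.20, QUAL > 30,
minor allele frequency > 0.05) — boundary sites are *excluded*, which
changes retained-site counts relative to ">="-style filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

try:
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover
    _CyVCF = None

__all__ = [
    "GenotypeMatrix",
    "AlleleFreqTable",
    "WindowSpec",
    "read_vcf",
    "read_popmap",
    "filter_variants",
    "allele_freqs",
    "make_windows",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage calls for biallelic SNPs.

    ``calls`` is (n_samples, n_sites) int8 with values {0, 1, 2} and
    ``MISSING`` (-1).  Sites are sorted by (contig, position); positions
    are 0-based.
    """

    samples: list[str]
    sample_pops: list[str]
    contigs: dict[str, int]
    site_contig: np.ndarray
    positions: np.ndarray
    qual: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def pop_index(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.sample_pops) if p == pop])
        if idx.size == 0:
            raise KeyError(f"population {pop!r} has no samples")
        return idx

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_pops:
            seen.setdefault(p)
        return list(seen)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        return replace(
            self,
            site_contig=self.site_contig[mask_or_index],
            positions=self.positions[mask_or_index],
            qual=self.qual[mask_or_index],
            ref=self.ref[mask_or_index],
            alt=self.alt[mask_or_index],
            calls=self.calls[:, mask_or_index],
        )


@dataclass(frozen=True)
class WindowSpec:
    """Half-open genomic window [start, end) on ``contig``."""

    contig: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class AlleleFreqTable:
    """Per-site derived (or alt) allele frequencies per population.

    Rows of ``freqs``/``counts`` follow ``pops``; ``counts`` holds
    non-missing allele counts.  When built with quartet/triple ``roles``
    (e.g. {"P1": ..., "P2": ..., "P3": ..., "O": ...}), ``p(role)``
    returns that population's frequency vector.
    """

    pops: list[str]
    roles: dict[str, str] | None
    polarized: bool
    site_contig: np.ndarray
    positions: np.ndarray
    freqs: np.ndarray  # (n_pops, n_sites)
    counts: np.ndarray  # (n_pops, n_sites) int
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]

    def p(self, role_or_pop: str) -> np.ndarray:
        name = role_or_pop
        if self.roles and role_or_pop in self.roles:
            name = self.roles[role_or_pop]
        return self.freqs[self.pops.index(name)]

    def take_sites(self, mask_or_index) -> "AlleleFreqTable":
        return replace(
            self,
            site_contig=self.site_contig[mask_or_index],
            positions=self.positions[mask_or_index],
            freqs=self.freqs[:, mask_or_index],
            counts=self.counts[:, mask_or_index],
        )


def read_popmap(path) -> dict[str, str]:
    """Two-column sample<TAB>population map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            out[parts[0]] = parts[1]
    return out


def read_vcf(vcf_path, popmap_path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF plus a population map.

    Non-biallelic or non-SNP records are skipped and counted in
    ``.excluded`` (keys ``multiallelic`` and ``non_snp``).  Genotypes are
    stored as alt-allele dosage; missing calls are preserved.
    """
    if _CyVCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    popmap = read_popmap(popmap_path)
    vcf = _CyVCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"samples missing from population map: {absent}")
    contigs: dict[str, int] = {}
    for c, ln in zip(vcf.seqnames, vcf.seqlens or []):
        contigs[c] = ln
    site_contig, positions, qual, ref, alt, cols = [], [], [], [], [], []
    excluded = {"multiallelic": 0, "non_snp": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            excluded["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            excluded["non_snp"] += 1
            continue
        site_contig.append(v.CHROM)
        positions.append(v.POS - 1)  # to 0-based
        qual.append(np.nan if v.QUAL is None else v.QUAL)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gts012=True: 0/1/2 dosage, 3 = unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
    calls = (np.stack(cols, axis=1) if cols
             else np.zeros((len(samples), 0), dtype=np.int8))
    gm = GenotypeMatrix(
        samples=samples,
        sample_pops=[popmap[s] for s in samples],
        contigs=contigs,
        site_contig=np.array(site_contig, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        qual=np.array(qual, dtype=float),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=calls,
        excluded=excluded,
    )
    # enforce (contig, position) sort without reordering contig groups seen in file
    order = np.lexsort((gm.positions, _contig_rank(gm)))
    out = gm.take_sites(order)
    out.excluded = excluded
    return out


def _contig_rank(gm: GenotypeMatrix) -> np.ndarray:
    names = list(dict.fromkeys(gm.site_contig))
    rank = {c: i for i, c in enumerate(names)}
    return np.array([rank[c] for c in gm.site_contig])


def filter_variants(
    gm: GenotypeMatrix,
    max_missing: float = 0.20,
    min_qual: float = 30.0,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Apply the default hard site filters with strict boundaries.

    Retains sites with missing-call fraction strictly below
    ``max_missing``, QUAL strictly above ``min_qual`` and overall minor
    allele frequency strictly above ``min_maf`` (computed jointly from
    all non-missing calls).  Per-rule exclusion counts land in
    ``.excluded`` (a site failing several rules is counted under each).
    """
    if not (0 < max_missing <= 1 and 0 <= min_maf < 0.5):
        raise ValueError("thresholds out of range")
    miss_frac = (gm.calls == MISSING).mean(axis=0) if gm.n_sites else np.empty(0)
    ok_miss = miss_frac < max_missing
    with np.errstate(invalid="ignore"):
        ok_qual = gm.qual > min_qual
    nonmiss = gm.calls != MISSING
    n_alleles = 2 * nonmiss.sum(axis=0)
    alt_dose = np.where(nonmiss, gm.calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt_dose / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    ok_maf = maf > min_maf
    keep = ok_miss & ok_qual & ok_maf
    out = gm.take_sites(keep)
    out.excluded = {
        "missing": int((~ok_miss).sum()),
        "qual": int((~ok_qual).sum()),
        "maf": int((~ok_maf).sum()),
    }
    if out.n_sites == 0 and gm.n_sites > 0:
        warnings.warn("all sites removed by filters", stacklevel=2)
    return out


def allele_freqs(
    gm: GenotypeMatrix,
    roles: dict[str, str] | None = None,
    polarize_by_outgroup: bool = False,
    min_alleles_per_pop: int = 2,
) -> AlleleFreqTable:
    """Per-population alt (or outgroup-polarized derived) allele frequencies.

    With ``polarize_by_outgroup`` the outgroup's (role ``"O"``) major
    allele is declared ancestral and all frequencies are flipped where
    needed, so each frequency is a derived-allele frequency and the
    retained outgroup frequency is always <= 0.5.  Sites where the
    outgroup is at exactly 0.5 (ancestral state ambiguous) or where any
    involved population has fewer than ``min_alleles_per_pop`` non-missing
    alleles are dropped and counted in ``.dropped``.
    """
    if polarize_by_outgroup and (roles is None or "O" not in roles):
        raise ValueError("polarization requires a roles map containing 'O'")
    pops = list(dict.fromkeys(roles.values())) if roles else gm.populations
    for p in pops:
        gm.pop_index(p)  # raises on unknown population
    n_pops, n_sites = len(pops), gm.n_sites
    freqs = np.zeros((n_pops, n_sites))
    counts = np.zeros((n_pops, n_sites), dtype=np.int64)
    for i, pop in enumerate(pops):
        sub = gm.calls[gm.pop_index(pop)]
        nonmiss = sub != MISSING
        counts[i] = 2 * nonmiss.sum(axis=0)
        dose = np.where(nonmiss, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[i] = np.where(counts[i] > 0, dose / np.maximum(counts[i], 1), np.nan)
    dropped = {"low_count": 0, "outgroup_tie": 0}
    keep = (counts >= min_alleles_per_pop).all(axis=0)
    dropped["low_count"] = int((~keep).sum())
    if polarize_by_outgroup:
        o = pops.index(roles["O"])
        tie = keep & (freqs[o] == 0.5)
        dropped["outgroup_tie"] = int(tie.sum())
        keep &= ~tie
        flip = freqs[o] > 0.5
        freqs = np.where(flip[None, :], 1.0 - freqs, freqs)
    table = AlleleFreqTable(
        pops=pops,
        roles=dict(roles) if roles else None,
        polarized=polarize_by_outgroup,
        site_contig=gm.site_contig,
        positions=gm.positions,
        freqs=freqs,
        counts=counts,
        dropped=dropped,
    )
    return table.take_sites(keep)


def from_simulated(ds, default_qual: float = 60.0) -> GenotypeMatrix:
    """Build a GenotypeMatrix directly from a coalsim SimulatedDataset
    (skipping the VCF round trip); unset QUAL becomes ``default_qual``."""
    qual = np.where(np.isnan(ds.qual), default_qual, ds.qual)
    n = ds.n_sites
    return GenotypeMatrix(
        samples=list(ds.samples),
        sample_pops=list(ds.sample_pops),
        contigs=dict(ds.contigs),
        site_contig=np.asarray(ds.site_contig, dtype=object),
        positions=ds.positions.copy(),
        qual=qual.astype(float),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "T", dtype=object),
        calls=ds.genotypes(),
    )


def make_windows(
    contigs: dict[str, int], width: int = 10_000, step: int | None = None
) -> list[WindowSpec]:
    """Tile each contig with half-open windows; trailing partial windows
    (smaller than ``width``) are discarded."""
    if width <= 0:
        raise ValueError("width must be positive")
    step = width if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    out = []
    for contig, length in contigs.items():
        start = 0
        while start + width <= length:
            out.append(WindowSpec(contig, start, start + width))
            start += step
    return out


def windows_to_bed(windows: list[WindowSpec], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\n")
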