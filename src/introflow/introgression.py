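"""ABBA-BABA D statistics, windowed f_dM scans and the f3 admixture test.

All statistics are frequency-based: with outgroup-polarized derived-allele
frequencies (p1, p2, p3, p4) for the quartet (((P1, P2), P3), O),

    ABBA_i = (1 - p1) * p2 * p3 * (1 - p4)
    BABA_i = p1 * (1 - p2) * p3 * (1 - p4)
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

Positive D(P1, P2; P3, O) means excess allele sharing between P2 and P3.
Significance comes from a weighted delete-one block jackknife over
contiguous SNP blocks (block weight = informative-site count); |Z| > 3 is
the conventional significance line, and Z < -3 for f3 marks the target
population as admixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import AlleleFreqTable, WindowSpec

__all__ = [
    "DStatResult",
    "FdMResult",
    "F3Result",
    "site_patterns",
    "block_jackknife",
    "patterson_d",
    "fdm_windows",
    "fdm_outliers",
    "f3",
    "chrom_scan_d",
]


@dataclass
class DStatResult:
    roles: dict[str, str] | None
    abba: float
    baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_informative_sites: int
    contig: str | None = None
    status: str = "ok"

    @property
    def significant(self) -> bool:
        return abs(self.z) > 3


@dataclass
class FdMResult:
    window: WindowSpec
    n_sites_used: int
    fdm: float
    numerator: float
    denominator: float


@dataclass
class F3Result:
    roles: dict[str, str]
    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    @property
    def call(self) -> str:
        return "admixed" if self.z < -3 else "not significant"


def _quartet_freqs(freqs: AlleleFreqTable, quartet=None):
    if not freqs.polarized:
        raise ValueError("quartet statistics require outgroup-polarized frequencies")
    roles = quartet or {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}
    if isinstance(roles, (list, tuple)):
        roles = dict(zip(("P1", "P2", "P3", "O"), roles))
    return roles, freqs.p(roles["P1"]), freqs.p(roles["P2"]), freqs.p(roles["P3"]), freqs.p(roles["O"])


def site_patterns(freqs: AlleleFreqTable, quartet=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (abba, baba) pattern weights from polarized frequencies.

    Sites where P3 carries no derived allele contribute (0, 0).
    """
    _, p1, p2, p3, p4 = _quartet_freqs(freqs, quartet)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _busing_se(theta: float, theta_del: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one jackknife SE (Busing et al. 1999 delete-m_j)."""
    m = np.asarray(weights, dtype=float)
    g = len(m)
    total = m.sum()
    h = total / m
    pseudo = h * theta - (h - 1.0) * theta_del
    theta_j = g * theta - ((1.0 - m / total) * theta_del).sum()
    dev = pseudo - theta_j
    # identical leave-one-out estimates: zero variance, not rounding noise
    if np.max(np.abs(dev)) <= 1e-12 * max(1.0, abs(theta)) * np.max(h):
        return 0.0
    var = (dev**2 / (h - 1.0)).sum() / g
    return float(np.sqrt(max(var, 0.0)))


def block_jackknife(
    per_block_values, per_block_weights=None
) -> tuple[float, float, float]:
    """Weighted-mean statistic with delete-one-block jackknife (estimate, SE, Z).

    The statistic is the weighted mean sum(w*v)/sum(w); with equal weights
    this is the sample mean and the SE reduces to the classical s/sqrt(n).
    """
    v = np.asarray(per_block_values, dtype=float)
    if per_block_weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(per_block_weights, dtype=float)
    if len(v) < 2:
        raise ValueError("block jackknife needs at least 2 blocks")
    if np.any(w <= 0):
        raise ValueError("block weights must be positive")
    sw, swv = w.sum(), (w * v).sum()
    theta = swv / sw
    theta_del = (swv - w * v) / (sw - w)
    se = _busing_se(theta, theta_del, w)
    z = theta / se if se > 0 else (np.inf if theta > 0 else -np.inf if theta < 0 else 0.0)
    return float(theta), se, float(z)


def _blocks(n_sites: int, block_size: int) -> list[slice]:
    return [slice(i, min(i + block_size, n_sites)) for i in range(0, n_sites, block_size)]


def patterson_d(
    freqs: AlleleFreqTable,
    quartet=None,
    block_size_snps: int = 1000,
    weighted: bool = True,
) -> DStatResult:
    """Genome-wide Patterson's D with block-jackknife Z.

    D is the ratio of genome-wide sums; the jackknife deletes contiguous
    blocks of ``block_size_snps`` SNPs and recomputes the ratio, with
    Busing-weighted variance (block weight = informative sites, i.e.
    sites with abba + baba > 0).  Set ``weighted=False`` for the
    classical unweighted delete-one scheme.
    """
    roles, *_ = _quartet_freqs(freqs, quartet)
    abba, baba = site_patterns(freqs, quartet)
    blocks = _blocks(len(abba), block_size_snps)
    if len(blocks) < 2:
        raise ValueError("need at least 2 non-empty blocks for the jackknife")
    a_b = np.array([abba[s].sum() for s in blocks])
    b_b = np.array([baba[s].sum() for s in blocks])
    n_inf = np.array([(abba[s] + baba[s] > 0).sum() for s in blocks])
    a_tot, b_tot = a_b.sum(), b_b.sum()
    denom = a_tot + b_tot
    if denom == 0:
        raise ValueError("D undefined: no informative sites (ABBA + BABA = 0)")
    d = (a_tot - b_tot) / denom
    keep = n_inf > 0
    a_b, b_b, n_inf = a_b[keep], b_b[keep], n_inf[keep]
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-empty blocks for the jackknife")
    theta_del = (a_tot - a_b - (b_tot - b_b)) / (a_tot - a_b + b_tot - b_b)
    weights = n_inf.astype(float) if weighted else np.ones(len(n_inf))
    se = _busing_se(d, theta_del, weights)
    status = "ok"
    if se == 0 and d != 0:
        warnings.warn("jackknife SE is zero with nonzero D; Z reported as infinite",
                      stacklevel=2)
        status = "degenerate"
    z = d / se if se > 0 else (np.inf if d > 0 else -np.inf if d < 0 else 0.0)
    return DStatResult(
        roles=roles, abba=float(a_tot), baba=float(b_tot), d=float(d), se=se,
        z=float(z), n_blocks=int(keep.sum()), n_informative_sites=int(n_inf.sum()),
        status=status,
    )


def _fdm_sites(p1, p2, p3, p4):
    """Per-site f_dM numerator and donor-substituted denominator.

    The dynamic donor p_D = max(p2, p3) (when p2 >= p1) is substituted
    into both the P2 and P3 slots of the numerator expression; in the
    mirrored case p_D = max(p1, p3) fills the P1 and P3 slots and the
    term is negated, making the statistic symmetric for donor sharing
    with P1 versus P2.
    """
    num = (1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)
    case2 = p2 >= p1
    pd2 = np.maximum(p2, p3)
    den2 = (1 - p1) * pd2 * pd2 * (1 - p4) - p1 * (1 - pd2) * pd2 * (1 - p4)
    pd1 = np.maximum(p1, p3)
    den1 = -((1 - pd1) * p2 * pd1 * (1 - p4) - pd1 * (1 - p2) * pd1 * (1 - p4))
    den = np.where(case2, den2, den1)
    return num, den


def fdm_windows(
    freqs: AlleleFreqTable,
    quartet=None,
    windows: list[WindowSpec] | None = None,
    min_sites: int = 5,
) -> tuple[list[FdMResult], dict[str, int]]:
    """Windowed f_dM scan; windows with fewer than ``min_sites`` usable
    sites, or a zero denominator, are omitted (and counted)."""
    _, p1, p2, p3, p4 = _quartet_freqs(freqs, quartet)
    if windows is None:
        raise ValueError("windows are required (see genotypes.make_windows)")
    num, den = _fdm_sites(p1, p2, p3, p4)
    by_contig: dict[str, np.ndarray] = {}
    for c in dict.fromkeys(freqs.site_contig):
        by_contig[c] = np.nonzero(freqs.site_contig == c)[0]
    out: list[FdMResult] = []
    skipped = {"too_few_sites": 0, "zero_denominator": 0}
    for w in windows:
        idx = by_contig.get(w.contig)
        if idx is None:
            skipped["too_few_sites"] += 1
            continue
        pos = freqs.positions[idx]
        sel = idx[(pos >= w.start) & (pos < w.end)]
        if len(sel) < min_sites:
            skipped["too_few_sites"] += 1
            continue
        nsum, dsum = num[sel].sum(), den[sel].sum()
        if dsum == 0:
            skipped["zero_denominator"] += 1
            continue
        out.append(FdMResult(window=w, n_sites_used=len(sel), fdm=float(nsum / dsum),
                             numerator=float(nsum), denominator=float(dsum)))
    return out, skipped


def fdm_outliers(
    results: list[FdMResult], quantile: float = 0.95
) -> tuple[float, list[FdMResult]]:
    """Top-quantile f_dM windows; the threshold is the type-7 empirical
    quantile and ties at the threshold are excluded (strict >)."""
    if not results:
        raise ValueError("no f_dM results to rank")
    vals = np.array([r.fdm for r in results])
    threshold = float(np.quantile(vals, quantile))  # numpy default = type 7
    return threshold, [r for r in results if r.fdm > threshold]


def f3(
    freqs: AlleleFreqTable,
    triple: dict[str, str] | tuple[str, str, str],
    block_size_snps: int = 500,
) -> F3Result:
    """Outgroup-free f3(C; A, B) = mean over sites of (c - a)(c - b).

    Significantly negative values (Z < -3 by block jackknife over
    ``block_size_snps``-SNP blocks) indicate that C is admixed between
    sources related to A and B.
    """
    if isinstance(triple, (tuple, list)):
        triple = dict(zip(("C", "A", "B"), triple))
    c, a, b = freqs.p(triple["C"]), freqs.p(triple["A"]), freqs.p(triple["B"])
    terms = (c - a) * (c - b)
    blocks = _blocks(len(terms), block_size_snps)
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks for the jackknife")
    vals = np.array([terms[s].mean() for s in blocks])
    weights = np.array([s.stop - s.start for s in blocks], dtype=float)
    est, se, z = block_jackknife(vals, weights)
    return F3Result(roles=triple, f3=est, se=se, z=z,
                    n_blocks=len(blocks), n_sites=len(terms))


def chrom_scan_d(
    freqs: AlleleFreqTable,
    quartet=None,
    contigs: list[str] | None = None,
    block_size_snps: int = 1000,
) -> list[DStatResult]:
    """Per-contig Patterson's D with contig-local jackknife blocks.

    Contigs with fewer than 2 blocks (or no informative sites) are
    reported with ``status='untested'`` rather than dropped.
    """
    roles, *_ = _quartet_freqs(freqs, quartet)
    if contigs is None:
        contigs = list(dict.fromkeys(freqs.site_contig))
    out = []
    for contig in contigs:
        sub = freqs.take_sites(freqs.site_contig == contig)
        try:
            res = patterson_d(sub, quartet, block_size_snps)
            res.contig = contig
        except ValueError:
            res = DStatResult(roles=roles, abba=0.0, baba=0.0, d=np.nan, se=np.nan,
                              z=np.nan, n_blocks=0, n_informative_sites=0,
                              contig=contig, status="untested")
        out.append(res)
    return out
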