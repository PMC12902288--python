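"""Windowed diversity/differentiation statistics, neutrality tests,
LD decay and the Z(FST) / log10(theta-pi ratio) selection scan.

Conventions that matter for absolute levels:

* pi uses accessible-site denominators — the mean per-site unbiased
  heterozygosity ``2 p (1-p) n/(n-1)`` is averaged over the genotyped
  variant sites in the window, not the window width.  With
  reduced-representation (RAD-like) data the set of accessible invariant
  sites is unknown, so these are per-variant-site values; SNP density
  (segregating sites / window width) carries the per-bp scale.
* FST is Hudson's (1992) ratio of averages per window,
  ``1 - mean(Hw) / mean(Hb)``; Weir & Cockerham (1984) is available via
  ``estimator="wc"`` for AMOVA-style comparisons.
* Tajima's D and Fu & Li's tests use sites with complete data in the
  focal population, so the sample size entering the normalizing
  constants is fixed within a window.
* r^2 is composite (genotype-dosage correlation), appropriate for
  unphased genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, WindowSpec

__all__ = [
    "SiteCounts",
    "WindowStats",
    "LDDecayCurve",
    "window_diversity",
    "site_counts",
    "tajimas_d",
    "fu_li",
    "ld_decay",
    "selection_scan",
]


# ---------------------------------------------------------------------------
# per-site building blocks


def _pop_freq(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and non-missing allele count per site."""
    nonmiss = calls != MISSING
    n = 2 * nonmiss.sum(axis=0)
    dose = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, dose / np.maximum(n, 1), np.nan)
    return p, n


def _unbiased_het(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site 2p(1-p) * n/(n-1); NaN where n < 2."""
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return np.where(n >= 2, h, np.nan)


@dataclass
class WindowStats:
    """Per-window summary statistics; dict fields are keyed by population
    or by 'pop1|pop2' pairs."""

    window: WindowSpec
    n_sites: int
    pi: dict[str, float] = field(default_factory=dict)
    dxy: dict[str, float] = field(default_factory=dict)
    fst: dict[str, float] = field(default_factory=dict)
    tajima_d: dict[str, float] = field(default_factory=dict)
    ho: dict[str, float] = field(default_factory=dict)
    he: dict[str, float] = field(default_factory=dict)
    snp_density: float = np.nan
    fdm: float = np.nan


def hudson_fst_sums(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson within/between heterozygosity components."""
    hw = 0.5 * (_unbiased_het(p1, n1) + _unbiased_het(p2, n2))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    return hw, hb


def _wc_fst(calls1: np.ndarray, calls2: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta for two populations over a window."""
    a_sum = b_sum = c_sum = 0.0
    for j in range(calls1.shape[1]):
        groups = []
        for calls in (calls1, calls2):
            col = calls[:, j]
            col = col[col != MISSING]
            if len(col) >= 1:
                groups.append(col)
        if len(groups) < 2:
            continue
        r = 2
        n_i = np.array([len(g) for g in groups], dtype=float)  # diploids
        p_i = np.array([g.mean() / 2.0 for g in groups])
        h_i = np.array([(g == 1).mean() for g in groups])
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    tot = a_sum + b_sum + c_sum
    return a_sum / tot if tot != 0 else np.nan


def window_diversity(
    gm: GenotypeMatrix,
    populations: list[str] | None = None,
    windows: list[WindowSpec] | None = None,
    fst_estimator: str = "hudson",
    with_tajima: bool = True,
) -> list[WindowStats]:
    """Windowed pi, Dxy, FST, Tajima's D, Ho, He and SNP density.

    A window with zero genotyped sites is retained with ``n_sites=0`` and
    all statistics absent (NaN/empty).
    """
    populations = populations or gm.populations
    if windows is None:
        raise ValueError("windows are required (see genotypes.make_windows)")
    if fst_estimator not in ("hudson", "wc"):
        raise ValueError("fst_estimator must be 'hudson' or 'wc'")
    pf = {pop: _pop_freq(gm.calls[gm.pop_index(pop)]) for pop in populations}
    pcalls = {pop: gm.calls[gm.pop_index(pop)] for pop in populations}
    contig_idx = {c: np.nonzero(gm.site_contig == c)[0]
                  for c in dict.fromkeys(gm.site_contig)}
    out = []
    for w in windows:
        idx = contig_idx.get(w.contig, np.empty(0, dtype=int))
        pos = gm.positions[idx]
        sel = idx[(pos >= w.start) & (pos < w.end)]
        any_called = (gm.calls[:, sel] != MISSING).any(axis=0)
        ws = WindowStats(window=w, n_sites=int(any_called.sum()))
        if ws.n_sites == 0:
            out.append(ws)
            continue
        # overall segregating sites for SNP density
        p_all, n_all = _pop_freq(gm.calls[:, sel])
        seg = (p_all > 0) & (p_all < 1)
        ws.snp_density = float(seg.sum()) / w.width
        for pop in populations:
            p, n = pf[pop][0][sel], pf[pop][1][sel]
            het = _unbiased_het(p, n)
            ws.pi[pop] = float(np.nanmean(het)) if np.any(~np.isnan(het)) else np.nan
            calls = pcalls[pop][:, sel]
            nonmiss = calls != MISSING
            with np.errstate(invalid="ignore"):
                ho = np.where(nonmiss.sum(axis=0) > 0,
                              (calls == 1).sum(axis=0) / np.maximum(nonmiss.sum(axis=0), 1),
                              np.nan)
            ws.ho[pop] = float(np.nanmean(ho)) if np.any(~np.isnan(ho)) else np.nan
            he = 2.0 * p * (1.0 - p)
            ws.he[pop] = float(np.nanmean(he)) if np.any(~np.isnan(he)) else np.nan
            if with_tajima:
                sc = site_counts(pcalls[pop][:, sel])
                ws.tajima_d[pop] = tajimas_d(sc) if sc is not None else np.nan
        for i, x in enumerate(populations):
            for y in populations[i + 1:]:
                px, nx = pf[x][0][sel], pf[x][1][sel]
                py, ny = pf[y][0][sel], pf[y][1][sel]
                both = (nx >= 1) & (ny >= 1)
                key = f"{x}|{y}"
                if not both.any():
                    ws.dxy[key] = np.nan
                    ws.fst[key] = np.nan
                    continue
                dxy = px * (1 - py) + py * (1 - px)
                ws.dxy[key] = float(np.nanmean(dxy[both]))
                if fst_estimator == "hudson":
                    hw, hb = hudson_fst_sums(px, nx, py, ny)
                    ok = both & ~np.isnan(hw) & ~np.isnan(hb)
                    mhb = hb[ok].mean() if ok.any() else np.nan
                    ws.fst[key] = float(1.0 - hw[ok].mean() / mhb) if mhb and mhb > 0 else np.nan
                else:
                    ws.fst[key] = float(_wc_fst(pcalls[x][:, sel], pcalls[y][:, sel]))
        out.append(ws)
    return out


def window_stats_frame(stats: list[WindowStats]) -> pd.DataFrame:
    """Flatten WindowStats into a BED-compatible DataFrame."""
    rows = []
    for ws in stats:
        row = {"contig": ws.window.contig, "start": ws.window.start,
               "end": ws.window.end, "n_sites": ws.n_sites,
               "snp_density": ws.snp_density, "fdm": ws.fdm}
        for d, prefix in ((ws.pi, "pi"), (ws.dxy, "dxy"), (ws.fst, "fst"),
                          (ws.tajima_d, "tajima_d"), (ws.ho, "ho"), (ws.he, "he")):
            for k, v in d.items():
                row[f"{prefix}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neutrality tests


@dataclass
class SiteCounts:
    """Sufficient statistics for Tajima's D and Fu & Li's tests.

    ``eta`` is the total number of mutations (equal to S under infinite
    sites), ``eta_e`` the external (derived-singleton) mutations, and
    ``pi_abs`` the mean number of pairwise differences (absolute, not
    per site).
    """

    n: int
    s: int
    eta: int
    eta_e: int | None
    pi_abs: float
    eta_s: int = 0  # total singletons (minor-allele count 1), for D*/F*


def site_counts(calls: np.ndarray, derived_is_alt: bool = True) -> SiteCounts | None:
    """Build SiteCounts from a population's dosage matrix using sites with
    complete data; returns None when no complete site exists.

    ``eta_e`` (needed by Fu & Li's D/F) counts derived singletons and is
    only meaningful when the alt allele is the derived allele
    (outgroup-polarized input); set ``derived_is_alt=False`` to leave it
    undefined.  ``eta_s`` counts all singletons regardless of polarity.
    """
    complete = (calls != MISSING).all(axis=0)
    sub = calls[:, complete]
    if sub.shape[1] == 0 or sub.shape[0] == 0:
        return None
    n = 2 * sub.shape[0]
    d = sub.sum(axis=0)
    seg = (d > 0) & (d < n)
    s = int(seg.sum())
    pi_abs = float((d * (n - d)).sum() / (n * (n - 1) / 2.0))
    eta_e = int((d == 1).sum()) if derived_is_alt else None
    eta_s = int(((d == 1) | (d == n - 1)).sum())
    return SiteCounts(n=n, s=s, eta=s, eta_e=eta_e, pi_abs=pi_abs, eta_s=eta_s)


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float((1.0 / i).sum()), float((1.0 / i**2).sum())


def tajimas_d(counts: SiteCounts) -> float:
    """Tajima (1989) D from (n, S, pi_abs); NaN when S = 0."""
    n, s = counts.n, counts.s
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    if s == 0:
        return np.nan
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((counts.pi_abs - s / a1) / np.sqrt(var))


def fu_li(counts: SiteCounts, variant: str = "D") -> float:
    """Fu & Li (1993) D, F, D* or F* tests; NaN when eta = 0.

    D and F contrast total mutations with external (derived-singleton)
    mutations and require outgroup polarization; the starred variants
    use total singletons and need no outgroup.
    """
    n, eta = counts.n, counts.eta
    if n < 4:
        raise ValueError("Fu & Li tests require at least 4 haplotypes")
    if eta == 0:
        return np.nan
    if variant in ("D", "F") and counts.eta_e is None:
        raise ValueError("variants 'D' and 'F' need polarized eta_e")
    a_n, b_n = _harmonics(n)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    eta_e = counts.eta_e if counts.eta_e is not None else 0
    if variant == "D":
        v = 1.0 + a_n**2 / (b_n + a_n**2) * (c_n - (n + 1.0) / (n - 1.0))
        u = a_n - 1.0 - v
        return float((eta - a_n * eta_e) / np.sqrt(u * eta + v * eta**2))
    if variant == "F":
        v = (c_n + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a_n**2 + b_n)
        u = (1.0 + (n + 1.0) / (3.0 * (n - 1))
             - 4.0 * (n + 1.0) / (n - 1.0) ** 2 * (a_n1 - 2.0 * n / (n + 1.0))) / a_n - v
        return float((counts.pi_abs - eta_e) / np.sqrt(u * eta + v * eta**2))
    eta_s = counts.eta_s
    d_n = c_n + (n - 2.0) / ((n - 1.0) ** 2) + 2.0 / (n - 1.0) * (1.5 - (2 * a_n1 - 3) / (n - 2.0) - 1.0 / n)
    if variant == "D*":
        v = ((n / (n - 1.0)) ** 2 * b_n + a_n**2 * d_n
             - 2.0 * n * a_n * (a_n + 1) / ((n - 1.0) ** 2)) / (a_n**2 + b_n)
        u = n / (n - 1.0) * (a_n - n / (n - 1.0)) - v
        return float((n / (n - 1.0) * eta - a_n * eta_s) / np.sqrt(u * eta + v * eta**2))
    if variant == "F*":
        v = (d_n + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
             - 2.0 / (n - 1.0) * (4.0 * b_n - 6.0 + 8.0 / n)) / (a_n**2 + b_n)
        u = (n / (n - 1.0) + (n + 1.0) / (3.0 * (n - 1))
             - 4.0 / (n * (n - 1.0)) + 2.0 * (n + 1.0) / ((n - 1.0) ** 2)
             * (a_n1 - 2.0 * n / (n + 1.0))) / a_n - v
        return float((counts.pi_abs - (n - 1.0) / n * eta_s) / np.sqrt(u * eta + v * eta**2))
    raise ValueError(f"unknown Fu & Li variant {variant!r}")


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray  # bp, len = n_bins + 1
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_bp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1].astype(int),
            "bin_end": self.bin_edges[1:].astype(int),
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })


def ld_decay(
    gm: GenotypeMatrix,
    population: str,
    max_dist_bp: int = 5000,
    bin_width: int = 500,
) -> LDDecayCurve:
    """Composite-LD decay: dosage-correlation r^2 for all intra-contig SNP
    pairs within ``max_dist_bp``, binned by distance.

    The half-decay distance is the midpoint of the first bin whose mean
    r^2 drops to half of the maximum bin mean (NaN if never reached).
    Monomorphic members of a pair are skipped.
    """
    calls = gm.calls[gm.pop_index(population)].astype(float)
    calls[calls == MISSING] = np.nan
    mask = ~np.isnan(calls)
    filled = np.where(mask, calls, 0.0)
    edges = np.arange(0, max_dist_bp + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    cnts = np.zeros(len(edges) - 1, dtype=np.int64)
    n_pairs = 0
    for contig in dict.fromkeys(gm.site_contig):
        idx = np.nonzero(gm.site_contig == contig)[0]
        pos = gm.positions[idx]
        hi = np.searchsorted(pos, pos + max_dist_bp, side="right")
        for ai in range(len(idx)):
            if hi[ai] <= ai + 1:
                continue
            js = idx[ai + 1:hi[ai]]
            # pairwise-complete correlation via masked sums, vectorized
            # over all partner sites of this anchor
            x = filled[:, idx[ai]][:, None]
            mx = mask[:, idx[ai]][:, None]
            y = filled[:, js]
            my = mask[:, js]
            both = mx & my
            n = both.sum(axis=0).astype(float)
            xs = (x * both).sum(axis=0)
            ys = (y * both).sum(axis=0)
            xx = (x * x * both).sum(axis=0)
            yy = (y * y * both).sum(axis=0)
            xy = (x * y * both).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = xy - xs * ys / n
                vx = xx - xs * xs / n
                vy = yy - ys * ys / n
                r2 = cov * cov / (vx * vy)
            ok = (n >= 2) & (vx > 0) & (vy > 0)
            if not ok.any():
                continue
            d = gm.positions[js] - pos[ai]
            b = np.minimum(d // bin_width, len(sums) - 1).astype(int)
            np.add.at(sums, b[ok], r2[ok])
            np.add.at(cnts, b[ok], 1)
            n_pairs += int(ok.sum())
    if n_pairs == 0:
        raise ValueError(f"no SNP pairs within {max_dist_bp} bp for {population!r}")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    half = np.nan
    valid = ~np.isnan(mean_r2)
    if valid.any():
        peak = np.nanmax(mean_r2)
        mids = 0.5 * (edges[:-1] + edges[1:])
        below = valid & (mean_r2 <= peak / 2.0)
        if below.any():
            half = float(mids[np.nonzero(below)[0][0]])
    return LDDecayCurve(bin_edges=edges, mean_r2=mean_r2, n_pairs=cnts,
                        half_decay_bp=half)


# ---------------------------------------------------------------------------
# selection scan


def selection_scan(
    fst: np.ndarray,
    pi_group1: np.ndarray,
    pi_group2: np.ndarray,
    quantile: float = 0.95,
    mode: str = "both",
) -> dict:
    """Z(FST) / log10(pi1/pi2) outlier scan over aligned windows.

    Windows in the top ``1 - quantile`` tail of *both* scores (default)
    or of *either* score (``mode="either"``) are flagged.  Windows with
    zero or missing pi in the denominator are excluded from the ratio
    ranking and counted.
    """
    fst = np.asarray(fst, dtype=float)
    pi1 = np.asarray(pi_group1, dtype=float)
    pi2 = np.asarray(pi_group2, dtype=float)
    if not (len(fst) == len(pi1) == len(pi2)):
        raise ValueError("window vectors must be aligned")
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    ok_fst = ~np.isnan(fst)
    z = np.full_like(fst, np.nan)
    if ok_fst.sum() >= 2 and np.nanstd(fst) > 0:
        z[ok_fst] = (fst[ok_fst] - np.nanmean(fst)) / np.nanstd(fst)
    bad_ratio = np.isnan(pi1) | np.isnan(pi2) | (pi2 == 0)
    log_ratio = np.full_like(fst, np.nan)
    with np.errstate(divide="ignore"):
        log_ratio[~bad_ratio] = np.log10(pi1[~bad_ratio] / pi2[~bad_ratio])
    log_ratio[~bad_ratio & np.isinf(log_ratio)] = np.nan  # pi1 == 0
    z_thr = float(np.nanquantile(z, quantile)) if np.any(~np.isnan(z)) else np.nan
    r_thr = (float(np.nanquantile(log_ratio, quantile))
             if np.any(~np.isnan(log_ratio)) else np.nan)
    top_z = z > z_thr
    top_r = log_ratio > r_thr
    outliers = (top_z & top_r) if mode == "both" else (top_z | top_r)
    return {
        "z_fst": z,
        "log10_pi_ratio": log_ratio,
        "z_threshold": z_thr,
        "ratio_threshold": r_thr,
        "outliers": np.nonzero(outliers)[0],
        "n_ratio_excluded": int(bad_ratio.sum()),
    }
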