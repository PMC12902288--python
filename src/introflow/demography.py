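"""Joint-SFS demographic inference for two-population gene-flow models.

The observed unfolded joint site frequency spectrum (SFS) is compared to
a Monte-Carlo expected SFS generated with the built-in structured
coalescent, through the multinomial composite log-likelihood

    CL = sum over unmasked entries of  obs[i, j] * ln(prob[i, j]).

The expected SFS is accumulated from branch lengths rather than sampled
mutations: each genealogy branch contributes its length to the entry
indexed by its derived-leaf counts in the two populations.  This is the
exact expectation of the infinite-sites mutation process given the
genealogies, so far fewer simulated loci are needed per evaluation.
Common random numbers (a fixed simulation seed shared by every
evaluation within an optimizer start) keep the likelihood surface
deterministic for derivative-free maximization.

Parameters are optimized on a log scale with multi-start Nelder-Mead,
bounded by the default sampling ranges (effective sizes log-uniform on
1000-60000 haploid individuals, i.e. 500-30000 diploids; migration
rates log-uniform on 1e-5 to 1e-2 per generation).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import coalsim
from .genotypes import GenotypeMatrix, MISSING

__all__ = [
    "JointSFS",
    "FitResult",
    "ScalingConstants",
    "joint_sfs",
    "expected_sfs",
    "composite_loglik",
    "fit_model",
    "model_select",
    "direction_test",
    "scale_params",
    "PAIR_TEMPLATES",
]

# default parameter bounds, diploid Ne and per-generation rates
DEFAULT_BOUNDS = {
    "ne": (500.0, 30_000.0),
    "t_split": (100.0, 200_000.0),
    "m": (1e-5, 1e-2),
    "m_old": (1e-5, 1e-2),
    "phi": (1e-3, 0.9),
}


@dataclass
class JointSFS:
    """Unfolded (or folded) joint SFS on a (n1+1) x (n2+1) haplotype grid.

    The fixed-fixed corners (0, 0) and (n1, n2) are masked and excluded
    from totals and likelihoods.  When ``sequence_length`` (total
    surveyed bp) is known, ``n_monomorphic`` anchors the absolute scale
    of demographic fits through the expected SNP density; without it the
    composite likelihood sees only the SFS shape, which is close to
    invariant under joint rescaling of sizes and times.
    """

    pops: tuple[str, str]
    grid: np.ndarray
    polarized: bool
    mask: np.ndarray  # True = excluded
    sequence_length: float | None = None
    n_monomorphic: float | None = None

    @property
    def total(self) -> float:
        return float(self.grid[~self.mask].sum())

    def key(self) -> str:
        h = hashlib.sha1(np.ascontiguousarray(self.grid).tobytes()).hexdigest()[:12]
        return f"{self.pops[0]}|{self.pops[1]}|{self.grid.shape}|{h}"


def _corner_mask(shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, 0] = True
    mask[-1, -1] = True
    return mask


def _project_counts(d: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection of derived count d (of n alleles) down to
    m alleles: expected weight on each projected count j."""
    j = np.arange(m + 1)
    return stats.hypergeom.pmf(j, n, d, m)


def joint_sfs(
    gm: GenotypeMatrix,
    pop_pair: tuple[str, str],
    polarized: bool = True,
    projection: tuple[int, int] | None = None,
    sequence_length: float | None = None,
) -> JointSFS:
    """Accumulate the joint SFS of two populations from a genotype matrix.

    With ``polarized=True`` the alt allele is taken as derived (use
    outgroup-polarized input, or simulator output where alt is the
    derived allele by construction).  ``projection`` gives smaller
    haplotype sample sizes; each site's counts are projected down
    hypergeometrically, and sites with fewer non-missing alleles than
    the projection are dropped.

    ``sequence_length`` is the total surveyed bp (e.g. the summed contig
    lengths of a simulated dataset); when given, the monomorphic-site
    count (length minus accumulated SNPs) is recorded so fits can use
    absolute SNP density.  Only meaningful when the input retains all
    SNPs from a known amount of sequence (no MAF-style ascertainment).
    """
    i1, i2 = (gm.pop_index(p) for p in pop_pair)
    full = (2 * len(i1), 2 * len(i2))
    proj = projection or full
    if proj[0] > full[0] or proj[1] > full[1]:
        raise ValueError(f"projection {proj} exceeds sample sizes {full}")
    grid = np.zeros((proj[0] + 1, proj[1] + 1))
    for j in range(gm.n_sites):
        col1, col2 = gm.calls[i1, j], gm.calls[i2, j]
        ok1, ok2 = col1 != MISSING, col2 != MISSING
        n1, n2 = 2 * ok1.sum(), 2 * ok2.sum()
        if n1 < proj[0] or n2 < proj[1]:
            continue
        d1, d2 = int(col1[ok1].sum()), int(col2[ok2].sum())
        w1 = _project_counts(d1, n1, proj[0]) if n1 > proj[0] else _one_hot(d1, proj[0])
        w2 = _project_counts(d2, n2, proj[1]) if n2 > proj[1] else _one_hot(d2, proj[1])
        grid += np.outer(w1, w2)
    mask = _corner_mask(grid.shape)
    grid = grid.copy()
    grid[mask] = 0.0
    if not polarized:
        grid = _fold(grid)
    n_mono = None
    if sequence_length is not None:
        n_mono = float(sequence_length) - float(grid.sum())
        if n_mono < 0:
            raise ValueError("sequence_length smaller than the SNP count")
    return JointSFS(pops=tuple(pop_pair), grid=grid, polarized=polarized,
                    mask=mask, sequence_length=sequence_length,
                    n_monomorphic=n_mono)


def _one_hot(d: int, m: int) -> np.ndarray:
    v = np.zeros(m + 1)
    v[d] = 1.0
    return v


def _fold(grid: np.ndarray) -> np.ndarray:
    """Fold onto minor-allele entries; ties (i+j = (n1+n2)/2) keep half."""
    flipped = grid[::-1, ::-1]
    folded = grid + flipped
    n1, n2 = np.array(grid.shape) - 1
    i, j = np.meshgrid(np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij")
    tot = 2 * (i + j)
    out = np.where(tot < n1 + n2, folded, np.where(tot == n1 + n2, folded / 2.0, 0.0))
    return out


def _branch_grid(
    model: coalsim.DemographicModel,
    sampling: dict[str, int],
    n_sims: int,
    seed: int,
) -> np.ndarray:
    """Summed branch-length weights (generations) per joint-SFS entry over
    ``n_sims`` simulated genealogies."""
    if len(sampling) != 2:
        raise ValueError("joint-SFS simulation requires exactly two sampled demes")
    (pa, na), (pb, nb) = sampling.items()
    grid = np.zeros((2 * na + 1, 2 * nb + 1))
    pop_of_leaf = None
    for parent, node_time, leaf_demes in coalsim.simulate_trees(model, sampling, n_sims, seed):
        n_leaves = len(leaf_demes)
        n_nodes = len(parent)
        if pop_of_leaf is None:
            first = leaf_demes[0]
            pop_of_leaf = (leaf_demes != first).astype(int)  # 0 = first deme
        counts = np.zeros((n_nodes, 2), dtype=np.int64)
        counts[np.arange(n_leaves), pop_of_leaf] = 1
        blen = np.zeros(n_nodes)
        for v in range(n_nodes - 1):
            p = parent[v]
            if p >= 0:
                counts[p] += counts[v]
                blen[v] = node_time[p] - node_time[v]
        np.add.at(grid, (counts[:-1, 0], counts[:-1, 1]), blen[:-1])
    return grid


def expected_sfs(
    model: coalsim.DemographicModel,
    sampling: dict[str, int],
    n_sims: int = 200,
    seed: int = 0,
    eps: float | None = None,
) -> np.ndarray:
    """Monte-Carlo expected joint-SFS probability grid for a two-deme model.

    ``n_sims`` counts simulated genealogies (loci).  Entries are branch-
    length weights (the exact per-genealogy expectation of infinite-sites
    mutations), corner-masked, floored at a pseudocount ``eps`` (default
    0.5 / total weight) on unobserved entries, and renormalized.
    """
    grid = _branch_grid(model, sampling, n_sims, seed)
    mask = _corner_mask(grid.shape)
    grid[mask] = 0.0
    total = grid.sum()
    if total <= 0:
        raise RuntimeError("no usable simulated branch weight; increase n_sims")
    if eps is None:
        eps = 0.5 / total
    probs = grid / total
    unmasked = ~mask
    zero = unmasked & (probs <= 0)
    probs[zero] = eps
    probs[unmasked] /= probs[unmasked].sum()
    probs[mask] = 0.0
    return probs


def expected_site_probs(
    model: coalsim.DemographicModel,
    sampling: dict[str, int],
    n_sims: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-site probabilities (q_poly grid, q_monomorphic).

    ``q_poly[i, j]`` is the probability that a random base is a SNP with
    derived counts (i, j): the model's mutation rate times the mean
    branch weight per genealogy.  ``q_mono = 1 - sum(q_poly)``.  Using
    these in the composite likelihood anchors the absolute parameter
    scale through the expected SNP density.
    """
    grid = _branch_grid(model, sampling, n_sims, seed)
    mask = _corner_mask(grid.shape)
    grid[mask] = 0.0
    mu = model.mutation_rate
    q = mu * grid / n_sims
    # pseudocount: half a generation of branch weight per simulated locus
    eps = 0.5 * mu / n_sims
    q[~mask & (q <= 0)] = eps
    q_mono = 1.0 - q.sum()
    if q_mono <= 0:
        raise RuntimeError("expected polymorphism probability >= 1; "
                           "model implies more than one mutation per base")
    return q, float(q_mono)


def composite_loglik_sites(obs: JointSFS, q_poly: np.ndarray, q_mono: float) -> float:
    """Per-site composite log-likelihood including the monomorphic class.

    Requires ``obs.n_monomorphic`` (built with ``sequence_length``).
    """
    if obs.n_monomorphic is None:
        raise ValueError("observed SFS lacks a monomorphic count; "
                         "build it with sequence_length")
    return composite_loglik(obs, q_poly / q_poly.sum()) \
        + float(obs.grid[~obs.mask].sum()) * float(np.log(q_poly.sum())) \
        + obs.n_monomorphic * float(np.log(q_mono))


def composite_loglik(obs: JointSFS, probs: np.ndarray) -> float:
    """Multinomial composite log-likelihood sum(obs * ln(prob)) over
    unmasked entries (up to a data-only constant)."""
    if probs.shape != obs.grid.shape:
        raise ValueError(f"shape mismatch: obs {obs.grid.shape}, probs {probs.shape}")
    sel = ~obs.mask & (obs.grid > 0)
    if np.any(sel & (probs <= 0)):
        raise ValueError("observed entries with zero probability; use a pseudocount")
    return float((obs.grid[sel] * np.log(probs[sel])).sum())


# ---------------------------------------------------------------------------
# model templates


def _pair_factory(epoch: str):
    def build(params: dict) -> coalsim.DemographicModel:
        pulse = None
        if "phi" in params:
            direction = params.get("pulse_direction", ("A", "B"))
            pulse = (direction[0], direction[1],
                     params.get("pulse_time", 0.05 * params["t_split"]), params["phi"])
        return coalsim._pair_model(
            ne=params["ne"],
            t_split=params["t_split"],
            m=params.get("m", 0.0) or 0.0,
            m_old=params.get("m_old"),
            epoch=epoch,
            epoch_fraction=params.get("epoch_fraction", coalsim.PAIR_EPOCH_FRACTION),
            pulse=pulse,
        )
    return build


PAIR_TEMPLATES = {
    "pair_IM_constant": {"factory": _pair_factory("constant"),
                         "free": ("ne", "t_split", "m")},
    "pair_IM_recent": {"factory": _pair_factory("recent"),
                       "free": ("ne", "t_split", "m")},
    "pair_IM_early": {"factory": _pair_factory("early"),
                      "free": ("ne", "t_split", "m")},
    "pair_IM_different": {"factory": _pair_factory("different"),
                          "free": ("ne", "t_split", "m", "m_old")},
}


@dataclass
class FitResult:
    model_label: str
    params: dict
    loglik: float
    trace: list = field(default_factory=list)
    seed: int = 0
    n_params: int = 0
    obs_key: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


@dataclass
class ScalingConstants:
    mutation_rate: float = 6.675e-8
    generation_time: float = 10.0
    calibration: tuple[str, float] | None = None  # (time-parameter name, years)

    def __post_init__(self):
        if self.mutation_rate <= 0 or self.generation_time <= 0:
            raise ValueError("scaling constants must be positive")


def fit_model(
    obs: JointSFS,
    model_template: str,
    bounds: dict | None = None,
    fixed: dict | None = None,
    n_starts: int = 3,
    max_iters: int = 40,
    sims_per_eval: int = 150,
    seed: int = 0,
    sampling: dict[str, int] | None = None,
    free_params: tuple[str, ...] | None = None,
) -> FitResult:
    """Multi-start Nelder-Mead composite-likelihood fit of a pair template.

    Free parameters are optimized in log space within ``bounds``
    (defaults from the package's standard sampling ranges); ``fixed`` pins
    parameters at given values.  Each start uses common random numbers:
    one simulation seed per start shared across all of its likelihood
    evaluations, so the surface each Nelder-Mead run sees is
    deterministic.  ``sims_per_eval`` genealogies feed each expected-SFS
    evaluation.
    """
    if model_template not in PAIR_TEMPLATES:
        raise ValueError(f"unknown template {model_template!r}; "
                         f"choose from {sorted(PAIR_TEMPLATES)}")
    tpl = PAIR_TEMPLATES[model_template]
    fixed = dict(fixed or {})
    default_free = list(tpl["free"])
    if "pulse_time" in fixed and "phi" not in default_free:
        default_free.append("phi")
    candidates = free_params if free_params is not None else default_free
    free = [p for p in candidates if p not in fixed]
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.log([bnds[p][0] for p in free])
    hi = np.log([bnds[p][1] for p in free])
    samp = _sampling_for(obs, sampling)
    rng = np.random.default_rng(seed)
    best = None
    trace_all = []

    anchored = obs.n_monomorphic is not None

    def evaluate(params, sim_seed):
        model = tpl["factory"](params)
        if anchored:
            q, q_mono = expected_site_probs(model, samp,
                                            n_sims=sims_per_eval, seed=sim_seed)
            return composite_loglik_sites(obs, q, q_mono)
        probs = expected_sfs(model, samp, n_sims=sims_per_eval, seed=sim_seed)
        return composite_loglik(obs, probs)

    def objective(x, sim_seed):
        xc = np.clip(x, lo, hi)
        penalty = 1e4 * float(np.abs(x - xc).sum())
        params = dict(fixed)
        params.update({p: float(np.exp(v)) for p, v in zip(free, xc)})
        try:
            cl = evaluate(params, sim_seed)
        except (coalsim.ModelError, RuntimeError, ValueError):
            return 1e12
        trace_all.append((params, cl))
        return -cl + penalty

    if not free:
        params = dict(fixed)
        cl = evaluate(params, seed)
        return FitResult(model_label=model_template, params=params, loglik=cl,
                         trace=[(params, cl)], seed=seed, n_params=0,
                         obs_key=obs.key())

    failures = []
    for start in range(n_starts):
        # first start at the log-midpoint of the bounds, rest random
        x0 = 0.5 * (lo + hi) if start == 0 else rng.uniform(lo, hi)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        try:
            # Nelder-Mead with a wide initial simplex (log-units; the
            # default 5% simplex crawls on decade-spanning bounds), plus
            # one restart from the incumbent to escape premature
            # contraction on curved likelihood ridges.
            for step in (0.7, 0.35):
                simplex = np.vstack([x0] + [x0 + step * np.eye(len(free))[d]
                                            for d in range(len(free))])
                res = optimize.minimize(
                    objective, x0, args=(sim_seed,), method="Nelder-Mead",
                    options={"maxiter": max_iters, "xatol": 1e-3,
                             "fatol": 1e-2, "initial_simplex": simplex},
                )
                x0 = np.clip(res.x, lo, hi)
        except Exception as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, sim_seed)
    if best is None:
        raise RuntimeError(f"all optimizer starts failed: {failures}")
    _, x_best, sim_seed = best
    xc = np.clip(x_best, lo, hi)
    params = dict(fixed)
    params.update({p: float(np.exp(v)) for p, v in zip(free, xc)})
    cl = evaluate(params, sim_seed)
    return FitResult(model_label=model_template, params=params, loglik=cl,
                     trace=trace_all, seed=seed, n_params=len(free), obs_key=obs.key())


def _sampling_for(obs: JointSFS, sampling: dict[str, int] | None) -> dict[str, int]:
    if sampling is not None:
        return sampling
    n1 = (obs.grid.shape[0] - 1) // 2
    n2 = (obs.grid.shape[1] - 1) // 2
    return {"A": n1, "B": n2}


def model_select(fits: list[FitResult], criterion: str = "maxCL") -> list[dict]:
    """Rank fits of the same observed SFS by max composite likelihood or AIC.

    Returns a list of dicts (best first) with delta columns; ties keep
    input order (stable sort).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    keys = {f.obs_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were made on different observed spectra")
    if criterion == "maxCL":
        scored = [(-f.loglik, i) for i, f in enumerate(fits)]
    elif criterion == "AIC":
        scored = [(f.aic, i) for i, f in enumerate(fits)]
    else:
        raise ValueError("criterion must be 'maxCL' or 'AIC'")
    order = [i for _, i in sorted(scored, key=lambda t: t[0])]
    best_cl = fits[order[0]].loglik
    best_aic = fits[order[0]].aic
    return [
        {"model": fits[i].model_label, "loglik": fits[i].loglik,
         "aic": fits[i].aic, "delta_cl": best_cl - fits[i].loglik,
         "delta_aic": fits[i].aic - best_aic, "params": fits[i].params}
        for i in order
    ]


def direction_test(
    obs: JointSFS,
    base_params: dict,
    pulse_time: float,
    template: str = "pair_IM_constant",
    phi_bounds: tuple[float, float] = (1e-3, 0.9),
    n_starts: int = 2,
    max_iters: int = 25,
    sims_per_eval: int = 150,
    seed: int = 0,
) -> dict:
    """Compare admixture-pulse direction A->B vs B->A on the SFS surface.

    Both models share ``base_params`` (ne, t_split, m, ...) and differ
    only in the pulse direction at ``pulse_time``; the pulse proportion
    phi is fitted for each direction.  Returns both fits, delta CL, and
    the supported direction ('A->B', 'B->A', or 'undetermined' when the
    composite likelihoods tie).
    """
    if not 0 < pulse_time < base_params["t_split"]:
        raise ValueError("pulse_time must lie in (0, t_split)")
    fits = {}
    for label, direction in (("A->B", ("A", "B")), ("B->A", ("B", "A"))):
        fixed = dict(base_params)
        fixed["pulse_time"] = pulse_time
        fixed["pulse_direction"] = direction
        fits[label] = fit_model(
            obs, template, bounds={"phi": phi_bounds}, fixed=fixed,
            n_starts=n_starts, max_iters=max_iters,
            sims_per_eval=sims_per_eval, seed=seed, free_params=("phi",),
        )
    delta = fits["A->B"].loglik - fits["B->A"].loglik
    if delta > 0:
        supported = "A->B"
    elif delta < 0:
        supported = "B->A"
    else:
        supported = "undetermined"
    return {"fits": fits, "delta_cl": float(delta), "supported": supported}


def scale_params(fit: FitResult, scaling: ScalingConstants) -> dict:
    """Convert a fit's generation-scaled times to absolute units.

    Times in years = generations x generation_time; with a
    ``calibration`` (time-parameter name, absolute age in years) all
    times are further rescaled linearly so the named parameter matches
    its calibrated age (e.g. anchoring the species split at 6.4 My).
    """
    time_keys = [k for k in fit.params if k in ("t_split", "pulse_time")
                 or k.startswith("t_")]
    years = {k: fit.params[k] * scaling.generation_time for k in time_keys}
    factor = 1.0
    if scaling.calibration is not None:
        node, age = scaling.calibration
        if node not in years:
            raise ValueError(f"calibration node {node!r} not among {sorted(years)}")
        if years[node] <= 0:
            raise ValueError("cannot calibrate a zero-time node")
        factor = age / years[node]
        years = {k: v * factor for k, v in years.items()}
    out = {f"{k}_years": v for k, v in years.items()}
    out["calibration_factor"] = factor
    out.update({k: v for k, v in fit.params.items()
                if k not in time_keys and not isinstance(v, tuple)})
    return out
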