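"""Single-threshold GMYC model on ultrametric trees.

The model places a time threshold ``T`` on the tree: branching events older
than ``T`` belong to a diversification (Yule-like) rate class acting on
species-tree lineages, events at or below ``T`` to a within-species
coalescent class.  For interval ``i`` (delimited by consecutive branching
events, root to tips) the total rate is

    b_i = lambda_div * k_i**p_div
        + lambda_coal * sum_j (n_ij * (n_ij - 1))**p_coal

with ``k_i`` species-tree lineages and ``n_ij`` within-species lineages of
species ``j`` crossing the interval.  Each interval contributes
``log(rho_i) - b_i * x_i`` to the log-likelihood, where ``rho_i`` is the
component rate of the class of the event ending the interval and ``x_i``
the waiting time.  Rate multipliers are profiled analytically; the two
exponents are optimized numerically per candidate threshold; candidate
thresholds are midpoints between consecutive distinct node heights plus
the two boundary partitions.  The null model is a single coalescent-form
class over all events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_io import BranchingSchedule, TreeNode, UltrametricTree, branching_events

__all__ = [
    "GmycParams",
    "GmycConfig",
    "GmycFit",
    "SpeciesPartition",
    "LikelihoodError",
    "threshold_partition",
    "single_class_rate",
    "gmyc_log_likelihood",
    "profile_lambdas",
    "fit_null",
    "fit_single_threshold",
    "likelihood_ratio_test",
    "entity_counts",
    "node_support",
]


class LikelihoodError(ValueError):
    """Raised when a likelihood is requested for an inconsistent state."""


@dataclass(frozen=True)
class GmycParams:
    """Rate/exponent/threshold parameters of the two-class model.

    ``lambda_div``/``lambda_coal`` may be exactly 0 when the corresponding
    class has no events (boundary thresholds), otherwise they are
    strictly positive.
    """

    lambda_div: float
    lambda_coal: float
    p_div: float
    p_coal: float
    threshold: float

    def __post_init__(self) -> None:
        if self.lambda_div < 0 or self.lambda_coal < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class GmycConfig:
    """Options controlling the single-threshold fit."""

    p_bounds: tuple[float, float] = (0.0, 10.0)
    df: int = 3
    n_starts: int = 3
    grid_points: int = 21  # coarse grid for the null exponent


@dataclass(frozen=True)
class SpeciesPartition:
    """Disjoint, exhaustive tip-name sets; one set per delimited species.

    Species are in canonical order (by smallest tip label); ``ids`` are
    1-based indices into that order.
    """

    species: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.species:
            if not members:
                raise ValueError("empty species set")
            if seen & members:
                raise ValueError("species sets are not disjoint")
            seen |= members
        canon = tuple(sorted(self.species, key=min))
        if canon != self.species:
            object.__setattr__(self, "species", canon)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.species) + 1))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def tips(self) -> frozenset[str]:
        return frozenset().union(*self.species)

    def species_of(self, name: str) -> int:
        for i, members in enumerate(self.species, start=1):
            if name in members:
                return i
        raise KeyError(name)

    @classmethod
    def from_labels(cls, labels: dict[str, str]) -> "SpeciesPartition":
        """Build a partition from a name -> label mapping."""
        by_label: dict[str, set[str]] = {}
        for name, lab in labels.items():
            by_label.setdefault(lab, set()).add(name)
        return cls(tuple(frozenset(v) for v in by_label.values()))


@dataclass(frozen=True)
class GmycFit:
    """Result of a single-threshold fit."""

    params: GmycParams
    logL: float
    null_logL: float
    LR: float
    p_value: float
    partition: SpeciesPartition
    threshold_profile: tuple[tuple[float, float], ...]
    n_entities: int
    n_clusters: int
    n_singletons: int
    df: int
    null_params: tuple[float, float] = (0.0, 0.0)  # (lambda0, p0)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def threshold_partition(tree: UltrametricTree, threshold: float) -> SpeciesPartition:
    """Partition tips into species induced by a time threshold.

    Each maximal subtree whose root node height is <= ``threshold`` is one
    species; a tip whose parent is older than the threshold forms a
    singleton species.
    """
    if not (0.0 <= threshold <= tree.depth * (1 + 1e-12)):
        raise ValueError(f"threshold {threshold} outside [0, {tree.depth}]")
    species: list[frozenset[str]] = []

    def walk(node: TreeNode) -> None:
        if node.is_tip or node.height <= threshold:
            species.append(node.tip_set())
            return
        for child in node.children:
            walk(child)

    walk(tree.root)
    return SpeciesPartition(tuple(species))


def entity_counts(partition: SpeciesPartition) -> tuple[int, int, int]:
    """Return ``(entities, clusters, singletons)`` of a partition."""
    entities = partition.n_species
    singletons = sum(1 for s in partition.species if len(s) == 1)
    return entities, entities - singletons, singletons


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------


def single_class_rate(
    n: int, lam: float, p: float, *, kind: str = "coalescent"
) -> float:
    """Rate of one class given its lineage count.

    ``lambda * (n*(n-1))**p`` for a coalescent-class state with ``n``
    within-species lineages (0 when ``n < 2``: no pair to coalesce) and
    ``lambda * k**p`` for a diversification-class state with ``k``
    species-tree lineages.
    """
    if kind == "coalescent":
        pairs = n * (n - 1)
        return 0.0 if pairs <= 0 else lam * pairs**p
    if kind == "diversification":
        return lam * n**p
    raise ValueError(f"unknown rate class {kind!r}")


class _ScheduleArrays:
    """Vectorized view of a classified schedule for repeated evaluation."""

    __slots__ = (
        "x",
        "k",
        "is_div",
        "coal_interval",
        "coal_n",
        "n_div",
        "n_coal",
        "n_events",
    )

    def __init__(self, schedule: BranchingSchedule) -> None:
        if not schedule.classified:
            raise LikelihoodError("schedule is not classified by a threshold")
        ev = schedule.events
        self.n_events = len(ev)
        self.x = np.array([e.waiting_time for e in ev])
        self.k = np.array([e.k for e in ev], dtype=float)
        self.is_div = np.array([bool(e.is_diversification) for e in ev])
        idx: list[int] = []
        nj: list[int] = []
        for i, e in enumerate(ev):
            for n in e.coal_counts:
                idx.append(i)
                nj.append(n)
        self.coal_interval = np.array(idx, dtype=np.intp)
        self.coal_n = np.array(nj, dtype=float)
        self.n_div = int(self.is_div.sum())
        self.n_coal = self.n_events - self.n_div

    def div_rates(self, p_div: float) -> np.ndarray:
        """Per-interval diversification factor ``k_i**p_div``."""
        return self.k**p_div

    def coal_rates(self, p_coal: float) -> np.ndarray:
        """Per-interval coalescent factor ``sum_j (n_ij(n_ij-1))**p_coal``."""
        out = np.zeros(self.n_events)
        if self.coal_n.size:
            pairs = (self.coal_n * (self.coal_n - 1.0)) ** p_coal
            np.add.at(out, self.coal_interval, pairs)
        return out


def gmyc_log_likelihood(schedule: BranchingSchedule, params: GmycParams) -> float:
    """Log-likelihood of a classified schedule under ``params``.

    Returns ``-inf`` if any event's own class rate is zero.
    """
    arr = _ScheduleArrays(schedule)
    fdiv = arr.div_rates(params.p_div)
    fcoal = arr.coal_rates(params.p_coal)
    b = params.lambda_div * fdiv + params.lambda_coal * fcoal
    rho = np.where(
        arr.is_div, params.lambda_div * fdiv, params.lambda_coal * fcoal
    )
    if np.any(rho <= 0):
        return float("-inf")
    return float(np.sum(np.log(rho)) - np.sum(b * arr.x))


def _profile_from_arrays(
    arr: _ScheduleArrays, p_div: float, p_coal: float
) -> tuple[float, float, float]:
    fdiv = arr.div_rates(p_div)
    fcoal = arr.coal_rates(p_coal)
    exp_div = float(np.sum(fdiv * arr.x))
    exp_coal = float(np.sum(fcoal * arr.x))
    logL = 0.0
    if arr.n_div:
        if exp_div <= 0:
            raise LikelihoodError(
                "diversification class has events but zero exposure"
            )
        lam_div = arr.n_div / exp_div
        ev_f = fdiv[arr.is_div]
        if np.any(ev_f <= 0):
            return lam_div, 0.0, float("-inf")
        logL += float(np.sum(np.log(lam_div * ev_f))) - arr.n_div
    else:
        lam_div = 0.0
    if arr.n_coal:
        if exp_coal <= 0:
            raise LikelihoodError("coalescent class has events but zero exposure")
        lam_coal = arr.n_coal / exp_coal
        ev_f = fcoal[~arr.is_div]
        if np.any(ev_f <= 0):
            return lam_div, lam_coal, float("-inf")
        logL += float(np.sum(np.log(lam_coal * ev_f))) - arr.n_coal
    else:
        lam_coal = 0.0
    return lam_div, lam_coal, logL


def profile_lambdas(
    schedule: BranchingSchedule, p_div: float, p_coal: float
) -> tuple[float, float, float]:
    """Analytically profile the class rates at fixed exponents.

    For each class with ``m`` events and exposure ``E = sum_i f_i x_i``
    (``f_i`` the class state factor in interval ``i``) the maximizing rate
    is ``m / E``; a class with no events gets rate 0 and contributes only
    exposure.  Returns ``(lambda_div, lambda_coal, logL)`` with ``logL``
    the profile maximum.
    """
    return _profile_from_arrays(_ScheduleArrays(schedule), p_div, p_coal)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------


def _null_arrays(schedule: BranchingSchedule) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([e.waiting_time for e in schedule.events])
    n = np.array([e.n_lineages for e in schedule.events], dtype=float)
    return x, n * (n - 1.0)


def _null_profile_logL(pairs: np.ndarray, x: np.ndarray, p0: float) -> tuple[float, float]:
    f = pairs**p0
    exposure = float(np.sum(f * x))
    m = len(x)
    lam0 = m / exposure
    logL = float(np.sum(np.log(lam0 * f))) - m
    return lam0, logL


def fit_null(
    schedule: BranchingSchedule,
    config: GmycConfig = GmycConfig(),
    *,
    p0: float | None = None,
) -> tuple[float, float, float]:
    """Fit the single-class null ``lambda0 * (n(n-1))**p0`` to a schedule.

    ``lambda0`` is profiled analytically, ``p0`` maximized within the
    configured bounds (coarse grid then local polish) unless fixed by the
    caller.  Returns ``(lambda0, p0, logL)``.
    """
    x, pairs = _null_arrays(schedule)
    lo, hi = config.p_bounds
    if p0 is not None:
        lam0, logL = _null_profile_logL(pairs, x, p0)
        return lam0, p0, logL
    if len(x) < 2:
        warnings.warn("degenerate 1-event schedule: fixing p0 at lower bound")
        lam0, logL = _null_profile_logL(pairs, x, lo)
        return lam0, lo, logL

    def neg(p0: float) -> float:
        return -_null_profile_logL(pairs, x, float(p0))[1]

    grid = np.linspace(lo, hi, config.grid_points)
    best_p = float(min(grid, key=neg))
    span = (hi - lo) / (config.grid_points - 1)
    res = optimize.minimize_scalar(
        neg,
        bounds=(max(lo, best_p - span), min(hi, best_p + span)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    p0 = float(res.x) if res.fun <= neg(best_p) else best_p
    lam0, logL = _null_profile_logL(pairs, x, p0)
    return lam0, p0, logL


# ---------------------------------------------------------------------------
# Threshold scan
# ---------------------------------------------------------------------------


def candidate_thresholds(tree: UltrametricTree) -> list[float]:
    """Candidate thresholds, oldest first.

    Midpoints between consecutive distinct internal-node heights, plus the
    two boundary partitions: the root height (one species) and a point
    below every internal node (all tips singletons).
    """
    heights = sorted({n.height for n in tree.internal_nodes()}, reverse=True)
    cands = [tree.depth]
    for upper, lower in zip(heights, heights[1:]):
        cands.append(0.5 * (upper + lower))
    cands.append(0.5 * heights[-1])
    return cands


def _optimize_exponents(
    arr: _ScheduleArrays, config: GmycConfig
) -> tuple[float, float, float, float, float]:
    """Maximize the profile likelihood over (p_div, p_coal).

    Returns ``(lambda_div, lambda_coal, p_div, p_coal, logL)``.
    """
    lo, hi = config.p_bounds

    if arr.n_div == 0 and arr.n_coal == 0:  # pragma: no cover - n_tips >= 2
        raise LikelihoodError("schedule has no events")

    if arr.n_div == 0 or arr.n_coal == 0:
        # One active class: scalar optimization of its exponent.
        active_div = arr.n_coal == 0

        def neg1(p: float) -> float:
            p = float(np.clip(p, lo, hi))
            pd, pc = (p, lo) if active_div else (lo, p)
            return -_profile_from_arrays(arr, pd, pc)[2]

        grid = np.linspace(lo, hi, config.grid_points)
        best_p = float(min(grid, key=neg1))
        span = (hi - lo) / (config.grid_points - 1)
        res = optimize.minimize_scalar(
            neg1,
            bounds=(max(lo, best_p - span), min(hi, best_p + span)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        p = float(res.x) if res.fun <= neg1(best_p) else best_p
        pd, pc = (p, lo) if active_div else (lo, p)
        lam_d, lam_c, logL = _profile_from_arrays(arr, pd, pc)
        return lam_d, lam_c, pd, pc, logL

    def neg2(p: np.ndarray) -> float:
        pd = float(np.clip(p[0], lo, hi))
        pc = float(np.clip(p[1], lo, hi))
        return -_profile_from_arrays(arr, pd, pc)[2]

    # Deterministic multi-start: the best points of a coarse grid scan.
    grid = np.linspace(lo, hi, 9)
    scored = sorted(
        ((neg2(np.array([pd, pc])), pd, pc) for pd in grid for pc in grid),
        key=lambda t: t[0],
    )
    starts = [(pd, pc) for _, pd, pc in scored[: config.n_starts]]
    best: tuple[float, float, float] = (scored[0][0], scored[0][1], scored[0][2])
    for s in starts:
        res = optimize.minimize(
            neg2,
            x0=np.array(s),
            method="Nelder-Mead",
            bounds=[(lo, hi), (lo, hi)],
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 600},
        )
        cand = (float(res.fun), float(np.clip(res.x[0], lo, hi)), float(np.clip(res.x[1], lo, hi)))
        if cand[0] < best[0]:
            best = cand
    _, pd, pc = best
    lam_d, lam_c, logL = _profile_from_arrays(arr, pd, pc)
    return lam_d, lam_c, pd, pc, logL


def fit_single_threshold(
    tree: UltrametricTree, config: GmycConfig = GmycConfig()
) -> GmycFit:
    """Maximum-likelihood single-threshold GMYC fit.

    Scans every candidate threshold, profiles the class rates and
    optimizes both exponents at each, and returns the argmax together
    with the likelihood-ratio test against the single-class null, the
    induced species partition and the entity/cluster/singleton counts.
    Ties between equally likely thresholds resolve toward fewer species
    (the older threshold).  Deterministic given tree and config.
    """
    if tree.n_tips < 3:
        raise ValueError("single-threshold fit needs at least 3 tips")
    null_schedule = branching_events(tree, None)
    lam0, p0, null_logL = fit_null(null_schedule, config)

    heights = {n.height for n in tree.internal_nodes()}
    if len(heights) < 2:
        warnings.warn(
            "all internal node heights tied: only boundary partitions scanned"
        )

    profile: list[tuple[float, float]] = []
    best: tuple[float, float, GmycParams] | None = None  # (logL, T, params)
    for T in candidate_thresholds(tree):
        schedule = branching_events(tree, T)
        arr = _ScheduleArrays(schedule)
        lam_d, lam_c, pd, pc, logL = _optimize_exponents(arr, config)
        profile.append((T, logL))
        if best is None or logL > best[0] + 1e-12:
            best = (
                logL,
                T,
                GmycParams(
                    lambda_div=lam_d,
                    lambda_coal=lam_c,
                    p_div=pd,
                    p_coal=pc,
                    threshold=T,
                ),
            )
    assert best is not None
    logL, T_hat, params = best
    partition = threshold_partition(tree, T_hat)
    entities, clusters, singletons = entity_counts(partition)
    LR, p_value = likelihood_ratio_test(logL, null_logL, config.df)
    return GmycFit(
        params=params,
        logL=logL,
        null_logL=null_logL,
        LR=LR,
        p_value=p_value,
        partition=partition,
        threshold_profile=tuple(profile),
        n_entities=entities,
        n_clusters=clusters,
        n_singletons=singletons,
        df=config.df,
        null_params=(lam0, p0),
    )


def likelihood_ratio_test(
    logL: float, null_logL: float, df: int = 3
) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-square upper-tail p-value."""
    if logL < null_logL - 1e-6:
        raise ValueError(
            f"alternative logL {logL} below null {null_logL}: models not nested?"
        )
    LR = max(0.0, 2.0 * (logL - null_logL))
    p_value = float(stats.chi2.sf(LR, df))
    return LR, p_value


# ---------------------------------------------------------------------------
# Node support
# ---------------------------------------------------------------------------


def node_support(
    tree: UltrametricTree,
    threshold_profile: list[tuple[float, float]] | tuple[tuple[float, float], ...],
) -> dict[frozenset[str], float]:
    """Akaike-weight support for species-defining nodes.

    Each candidate threshold model gets weight proportional to
    ``exp(logL - max logL)`` (equal parameter counts).  A node's support
    is the summed weight of models in which it is the crown node of a
    multi-tip species.  Nodes are keyed by their tip sets.
    """
    if not threshold_profile:
        raise ValueError("empty threshold profile")
    logLs = np.array([lL for _, lL in threshold_profile])
    w = np.exp(logLs - logLs.max())
    w /= w.sum()
    support: dict[frozenset[str], float] = {}
    for (T, _), weight in zip(threshold_profile, w):
        partition = threshold_partition(tree, T)
        for members in partition.species:
            if len(members) < 2:
                continue
            support[members] = support.get(members, 0.0) + float(weight)
    return support
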