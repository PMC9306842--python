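"""Independent straight-line oracles used by the test suite.

These deliberately avoid the package's vectorized likelihood code path:
plain Python loops over the schedule events, plus exhaustive grid/polish
search over thresholds and exponents for small trees.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

from gmycsampler.data_io import BranchingSchedule, UltrametricTree, branching_events


def naive_log_likelihood(
    schedule: BranchingSchedule,
    lam_div: float,
    lam_coal: float,
    p_div: float,
    p_coal: float,
) -> float:
    """Per-interval summation of the two-class likelihood, loop form."""
    total = 0.0
    for event in schedule.events:
        G = event.k**p_div
        F = sum((n * (n - 1)) ** p_coal for n in event.coal_counts)
        b = lam_div * G + lam_coal * F
        rho = lam_div * G if event.is_diversification else lam_coal * F
        if rho <= 0:
            return -math.inf
        total += math.log(rho) - b * event.waiting_time
    return total


def naive_profile_logL(
    schedule: BranchingSchedule, p_div: float, p_coal: float
) -> float:
    """Profile the two rates analytically, then evaluate the loop form."""
    m_div = sum(1 for e in schedule.events if e.is_diversification)
    m_coal = len(schedule.events) - m_div
    exp_div = sum(e.k**p_div * e.waiting_time for e in schedule.events)
    exp_coal = sum(
        sum((n * (n - 1)) ** p_coal for n in e.coal_counts) * e.waiting_time
        for e in schedule.events
    )
    lam_div = m_div / exp_div if m_div else 0.0
    lam_coal = m_coal / exp_coal if m_coal else 0.0
    return naive_log_likelihood(schedule, lam_div, lam_coal, p_div, p_coal)


def naive_candidate_thresholds(tree: UltrametricTree) -> list[float]:
    heights = sorted({n.height for n in tree.internal_nodes()}, reverse=True)
    cands = [tree.depth]
    cands += [(a + b) / 2 for a, b in zip(heights, heights[1:])]
    cands.append(heights[-1] / 2)
    return cands


def brute_force_best_logL(
    tree: UltrametricTree,
    p_bounds: tuple[float, float] = (0.0, 10.0),
    grid_points: int = 41,
) -> tuple[float, float]:
    """Exhaustive threshold scan x dense exponent grid, with local polish.

    Returns ``(best_logL, best_threshold)``.
    """
    lo, hi = p_bounds
    grid = np.linspace(lo, hi, grid_points)
    best = (-math.inf, math.nan)
    for T in naive_candidate_thresholds(tree):
        schedule = branching_events(tree, T)

        def neg(p: np.ndarray) -> float:
            pd = float(np.clip(p[0], lo, hi))
            pc = float(np.clip(p[1], lo, hi))
            return -naive_profile_logL(schedule, pd, pc)

        grid_best = max(
            ((naive_profile_logL(schedule, pd, pc), pd, pc)
             for pd in grid for pc in grid),
            key=lambda t: t[0],
        )
        res = optimize.minimize(
            neg,
            x0=np.array([grid_best[1], grid_best[2]]),
            method="Nelder-Mead",
            bounds=[(lo, hi), (lo, hi)],
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 600},
        )
        logL = max(grid_best[0], -float(res.fun))
        if logL > best[0]:
            best = (logL, T)
    return best


def naive_null_grid(
    schedule: BranchingSchedule,
    lam_grid: np.ndarray,
    p_grid: np.ndarray,
) -> float:
    """Best single-class null log-likelihood over an explicit (lambda, p) grid."""
    best = -math.inf
    xs = [e.waiting_time for e in schedule.events]
    ns = [e.n_lineages for e in schedule.events]
    for lam in lam_grid:
        for p in p_grid:
            logL = 0.0
            for x, n in zip(xs, ns):
                rate = lam * (n * (n - 1)) ** p
                if rate <= 0:
                    logL = -math.inf
                    break
                logL += math.log(rate) - rate * x
            best = max(best, logL)
    return best
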