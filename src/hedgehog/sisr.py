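"""Distance-matching prediction of self-induced stochastic resonance.

On each stable branch of the slow manifold, the frozen-y fast subsystem is
an overdamped particle in a potential well of depth dU(y) with barrier
distance S(y).  With white noise of intensity sigma on the fast variable,
Kramers' formula gives the mean first passage time over the barrier (in
fast time tau = t/eps)

    T_e(y) = 2*pi / sqrt(|U''_barrier| * U''_branch) * exp(2*dU(y)/sigma)

and the mean first passage velocity V_e(y) = S(y)/T_e(y) is the effective
rate of displacement off the branch.  While the slow drift carries the
state along the branch (dy/dtau = eps*(x_branch(y) + a)), the accumulated
mean displacement is

    lhs(y0, y) = int V_e(u) / |dy/dtau| du
               = int S(u) * sqrt(|U''_m| U''_b) / (2*pi*eps*|x_b(u)+a|)
                     * exp(-2*dU(u)/sigma) du .

The critical transition position y* is the first downstream point where
this accumulated displacement equals the barrier distance itself,
lhs = S(y*): the distance matching condition.  On the wavy right branch
the condition is applied region by region (one wave lobe at a time,
restarting the integral at each lobe's bottom), which yields the
staircase dependence of y* on sigma, the noise-tuned spike counts, and —
where the left- and right-branch positions meet — the end of coherent
bursting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .geometry import BranchGeometry, Region
from .model import ModelParams

#: Default starting position on the left branch: the maximum y reached on
#: the left-branch portion of the deterministic limit cycle.
Y0_LEFT_DEFAULT = 0.221

#: Default log-spaced noise grid for staircase scans.
SIGMA_GRID_DEFAULT = np.logspace(-3.0, -0.5, 26)


@dataclass(frozen=True)
class TransitionSolution:
    """Critical transition position on one branch at one noise strength.

    ``region_index`` is the 1-based wave-lobe region containing ``y_star``
    on the right branch and 0 on the left; ``residual`` is
    ``|lhs - S|`` at ``y_star``; ``converged`` is False when no matching
    point exists inside the branch window (noise too small for the window,
    or beyond the orbit-collapse crossing).
    """

    sigma: float
    branch: str
    y_star: float
    region_index: int
    y0: float
    converged: bool
    residual: float


@dataclass
class StaircaseCurve:
    """Transition positions on both branches over a noise grid.

    ``ystar_left`` is non-decreasing in sigma; ``ystar_right`` decreases
    stepwise, dropping a wave lobe at a time (``region_of`` records the
    escape lobe).  ``crossing`` is the (sigma_c, y_c) point where the two
    curves meet; entries with sigma > sigma_c cannot form a complete orbit
    and are flagged invalid.
    """

    sigma_grid: np.ndarray
    ystar_left: np.ndarray
    ystar_right: np.ndarray
    region_of: np.ndarray
    valid: np.ndarray
    crossing: tuple | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sigma": self.sigma_grid,
                "ystar_left": self.ystar_left,
                "ystar_right": self.ystar_right,
                "region": self.region_of,
                "valid": self.valid,
            }
        )


@dataclass(frozen=True)
class PredictedOrbit:
    """Glued slow-manifold orbit predicted for one noise strength.

    ``period`` is the bursting period in fast-time units (slow drift along
    both branches between the transition positions; the near-instantaneous
    jumps are neglected).  ``spike_count`` counts the wave-lobe tips
    traversed per burst, including the escape lobe's tip.  ``polyline`` is
    the (x, y) orbit skeleton: left branch top-down, jump at y_cl, right
    branch bottom-up, jump at y_cr.
    """

    sigma: float
    y_cl: float
    y_cr: float
    period: float
    spike_count: int
    polyline: np.ndarray


def _grid_slice(geom: BranchGeometry, lo: float, hi: float) -> np.ndarray:
    """Tabulation grid restricted to [lo, hi] with exact interpolated ends."""
    y = geom.y_grid
    if lo < y[0] - 1e-12 or hi > y[-1] + 1e-12:
        raise ValueError(
            f"[{lo}, {hi}] leaves the tabulated {geom.branch}-branch "
            f"window [{y[0]}, {y[-1]}]"
        )
    lo, hi = max(lo, y[0]), min(hi, y[-1])
    inner = y[(y > lo) & (y < hi)]
    return np.concatenate(([lo], inner, [hi]))


def _integrand(yy: np.ndarray, sigma: float, geom: BranchGeometry, p: ModelParams) -> np.ndarray:
    """Accumulated-displacement integrand V_e / |dy/dtau| on grid yy."""
    S = geom.interp(yy, "S")
    dU = geom.interp(yy, "dU")
    cb = geom.interp(yy, "curv_branch")
    cm = geom.interp(yy, "curv_barrier")
    xb = geom.interp(yy, "x_of_y")
    drift = np.abs(xb + p.a)
    if np.any(drift < 1e-12):
        raise ValueError("slow drift vanishes inside the integration window")
    return (
        S
        * np.sqrt(np.abs(cm) * np.abs(cb))
        / (2.0 * math.pi * p.eps * drift)
        * np.exp(-2.0 * dU / sigma)
    )


def mfpt(y: float, branch: str, sigma: float, geom: BranchGeometry) -> float:
    """Kramers mean first passage time over the barrier at frozen y (fast time).

    ``T_e = 2*pi / sqrt(|U''_barrier| * U''_branch) * exp(2*dU/sigma)``.
    Raises near folds, where the vanishing curvatures make the Kramers
    prefactor singular (escape is effectively instantaneous there).
    """
    if sigma <= 0:
        raise ValueError("mfpt requires sigma > 0")
    if geom.branch != branch:
        raise ValueError(f"geometry is for branch {geom.branch!r}, not {branch!r}")
    cb = float(geom.interp(y, "curv_branch"))
    cm = float(geom.interp(y, "curv_barrier"))
    if cb < 0.05 or cm < 0.05:
        raise ValueError(
            f"curvature vanishes at y={y} (fold): Kramers prefactor singular; "
            "treat S -> 0 before the formula breaks"
        )
    dU = float(geom.interp(y, "dU"))
    arg = 2.0 * dU / sigma
    if arg > 700.0:
        return float("inf")  # escape time beyond any double, physically infinite
    return 2.0 * math.pi / math.sqrt(cm * cb) * math.exp(arg)


def mfpv(y: float, branch: str, sigma: float, geom: BranchGeometry) -> float:
    """Mean first passage velocity ``V_e(y) = S(y) / T_e(y)`` (x per fast time)."""
    return float(geom.interp(y, "S")) / mfpt(y, branch, sigma, geom)


def matching_lhs(
    y0: float,
    y: float,
    sigma: float,
    branch: str,
    geom: BranchGeometry,
    p: ModelParams | None = None,
) -> float:
    """Accumulated mean x-displacement off the branch from y0 to y.

    Integration runs in the direction of the slow drift: decreasing y on
    the left branch (x_l + a < 0), increasing y on the right branch.
    ``y`` must lie downstream of ``y0``; the integral over an empty
    interval is 0.
    """
    if p is None:
        p = geom.params
    if sigma <= 0:
        raise ValueError("matching_lhs requires sigma > 0")
    if branch == "left":
        lo, hi = y, y0
    else:
        lo, hi = y0, y
    if hi < lo:
        raise ValueError(f"y={y} is upstream of y0={y0} on the {branch} branch")
    if hi == lo:
        return 0.0
    yy = _grid_slice(geom, lo, hi)
    w = _integrand(yy, sigma, geom, p)
    return float(np.trapezoid(w, yy))


def _first_crossing(
    yy: np.ndarray,
    W: np.ndarray,
    S: np.ndarray,
    refine,
) -> float | None:
    """First y (in traversal order) where the cumulative lhs W reaches S.

    ``yy``/``W``/``S`` are ordered in traversal direction (for the left
    branch pass the arrays reversed).  The bracketed crossing is polished
    by ``refine(y_lo, y_hi)`` — a bracketed root solve of the exact
    lhs - S function — so the returned position satisfies the matching
    condition to the solver tolerance, not merely to grid resolution.
    """
    h = W - S
    if h[0] >= 0:
        return float(yy[0])
    idx = np.nonzero((h[:-1] < 0) & (h[1:] >= 0))[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    a, b = sorted((float(yy[i]), float(yy[i + 1])))
    return refine(a, b)


def solve_transition(
    branch: str,
    sigma: float,
    y0: float | None,
    geom: BranchGeometry,
    p: ModelParams | None = None,
    y_min: float | None = None,
) -> TransitionSolution:
    """Solve the distance matching condition lhs(y0, y) = S(y) on one branch.

    Left branch: scan downstream (decreasing y) from ``y0`` (default
    0.221) and return the first matching point; ``y_min`` optionally
    truncates the scan (used in the excitable regime to stop above the
    rest state).  Right branch: apply the condition wave lobe by wave
    lobe in increasing-y order starting from the lobe containing ``y0``
    (default: the window bottom); within each lobe the displacement
    integral restarts at the lobe's bottom (``y_start``) and the first
    matching point is sought; if none exists before the lobe ends the
    state survives to the next lobe and the procedure starts over.

    Returns a flagged (``converged=False``) solution when no matching
    point exists in the window.
    """
    if p is None:
        p = geom.params
    if sigma <= 0:
        raise ValueError("solve_transition requires sigma > 0")
    ylo, yhi = geom.y_grid[0], geom.y_grid[-1]
    if branch == "left":
        if y0 is None:
            y0 = Y0_LEFT_DEFAULT
        lo = ylo if y_min is None else max(ylo, y_min)
        if not (lo < y0 <= yhi + 1e-12):
            raise ValueError(f"y0={y0} outside left-branch window [{lo}, {yhi}]")
        yy = _grid_slice(geom, lo, min(y0, yhi))
        w = _integrand(yy, sigma, geom, p)
        # traverse top-down: reverse so index order = traversal order
        yyr = yy[::-1]
        # cumulative integral from y0 downward (traversal order)
        W = cumulative_trapezoid(w[::-1], -yyr, initial=0.0)
        Sr = geom.interp(yyr, "S")

        def g_left(y: float) -> float:
            return matching_lhs(y0, y, sigma, "left", geom, p) - float(
                geom.interp(y, "S")
            )

        ystar = _first_crossing(
            yyr, W, Sr, lambda a, b: float(brentq(g_left, a, b, xtol=1e-13))
        )
        if ystar is None:
            return TransitionSolution(sigma, "left", float(yyr[-1]), 0, y0, False, float("nan"))
        res = abs(g_left(ystar))
        return TransitionSolution(sigma, "left", ystar, 0, y0, True, float(res))
    elif branch == "right":
        if y0 is None:
            y0 = float(ylo)
        if not (ylo - 1e-12 <= y0 < yhi):
            raise ValueError(f"y0={y0} outside right-branch window [{ylo}, {yhi}]")
        regions: list[Region] = geom.regions
        if not regions:
            regions = [Region(index=1, y_start=float(ylo), y_end=float(yhi), y_tip=float(yhi))]
        for reg in regions:
            if reg.y_end <= y0:
                continue
            start = max(reg.y_start, y0)
            if reg.y_end - start < 1e-9:
                continue
            yy = _grid_slice(geom, start, reg.y_end)
            w = _integrand(yy, sigma, geom, p)
            W = cumulative_trapezoid(w, yy, initial=0.0)
            Ss = geom.interp(yy, "S")

            def g_right(y: float, _start=start) -> float:
                return matching_lhs(_start, y, sigma, "right", geom, p) - float(
                    geom.interp(y, "S")
                )

            ystar = _first_crossing(
                yy, W, Ss, lambda a, b: float(brentq(g_right, a, b, xtol=1e-13))
            )
            if ystar is not None:
                res = abs(g_right(ystar))
                return TransitionSolution(
                    sigma, "right", float(ystar), reg.index, y0, True, float(res)
                )
        return TransitionSolution(sigma, "right", float(yhi), 0, y0, False, float("nan"))
    raise ValueError("branch must be 'left' or 'right'")


def refine_pair(
    sigma: float,
    geom_l: BranchGeometry,
    geom_r: BranchGeometry,
    p: ModelParams | None = None,
    y0_left: float = Y0_LEFT_DEFAULT,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> tuple[TransitionSolution, TransitionSolution]:
    """Self-consistent transition pair via alternating starting-position refinement.

    Each branch's transition position is recomputed with the OTHER
    branch's transition as its starting position (the state enters the
    left branch at y_cr and the right branch at y_cl), iterating to a
    fixed point.  For well-separated transitions the refined positions
    coincide with the unrefined ones; the refinement matters only when
    the two positions approach each other near the orbit-collapse
    crossing.
    """
    if p is None:
        p = geom_l.params
    left = solve_transition("left", sigma, y0_left, geom_l, p)
    right = solve_transition("right", sigma, None, geom_r, p)
    if not (left.converged and right.converged):
        return left, right
    for _ in range(max_iter):
        new_left = solve_transition("left", sigma, min(right.y_star, geom_l.y_grid[-1]), geom_l, p)
        new_right = solve_transition("right", sigma, max(left.y_star, geom_r.y_grid[0]), geom_r, p)
        if not (new_left.converged and new_right.converged):
            return new_left, new_right
        dy = max(abs(new_left.y_star - left.y_star), abs(new_right.y_star - right.y_star))
        left, right = new_left, new_right
        if dy < tol:
            return left, right
    # did not settle within max_iter: flag both
    return (
        TransitionSolution(sigma, "left", left.y_star, 0, left.y0, False, left.residual),
        TransitionSolution(sigma, "right", right.y_star, right.region_index, right.y0, False, right.residual),
    )


def staircase(
    sigma_grid: np.ndarray | None,
    geom_l: BranchGeometry,
    geom_r: BranchGeometry,
    p: ModelParams | None = None,
    locate_crossing: bool = True,
) -> StaircaseCurve:
    """Transition positions on both branches over a log-spaced noise grid.

    The stored curves are the refined (self-consistent-start) positions.
    The crossing (sigma_c, y_c) that bounds the coherent-bursting regime
    is located by bisection on the gap y*_right - y*_left of the
    DEFAULT-start solutions (left from y0 = 0.221, right from the window
    bottom): with refined starting positions the two curves only approach
    each other asymptotically and never cross, so the finite crossing —
    which marks where predicted transition positions stop forming a
    complete orbit — is a property of the fixed-start procedure.  All
    grid entries beyond sigma_c are flagged invalid.
    """
    if p is None:
        p = geom_l.params
    if sigma_grid is None:
        sigma_grid = SIGMA_GRID_DEFAULT
    sigma_grid = np.asarray(sigma_grid, dtype=float)

    def default_gap(s: float) -> tuple[float, tuple]:
        left = solve_transition("left", s, None, geom_l, p)
        right = solve_transition("right", s, None, geom_r, p)
        g = right.y_star - left.y_star if (left.converged and right.converged) else float("nan")
        return g, (left, right)

    yl = np.full(len(sigma_grid), np.nan)
    yr = np.full(len(sigma_grid), np.nan)
    reg = np.zeros(len(sigma_grid), dtype=int)
    valid = np.zeros(len(sigma_grid), dtype=bool)
    for i, s in enumerate(sigma_grid):
        left, right = refine_pair(s, geom_l, geom_r, p)
        yl[i], yr[i] = left.y_star, right.y_star
        reg[i] = right.region_index
        valid[i] = left.converged and right.converged and yr[i] > yl[i]
    crossing = None
    if locate_crossing:
        gaps = np.array([default_gap(s)[0] for s in sigma_grid])
        ok = np.isfinite(gaps)
        pos = np.nonzero(ok & (gaps > 0))[0]
        neg = np.nonzero(ok & (gaps <= 0))[0]
        if len(pos) and len(neg) and pos[0] < neg[0]:
            s_lo = float(sigma_grid[pos[pos < neg[0]][-1]])
            s_hi = float(sigma_grid[neg[0]])
            # bisection on log(sigma), relative tolerance 1e-3
            while s_hi / s_lo > 1.0 + 1e-3:
                s_mid = math.sqrt(s_lo * s_hi)
                g_mid, _ = default_gap(s_mid)
                if not math.isfinite(g_mid) or g_mid <= 0:
                    s_hi = s_mid
                else:
                    s_lo = s_mid
            sigma_c = math.sqrt(s_lo * s_hi)
            _, (left_c, right_c) = default_gap(sigma_c)
            y_c = 0.5 * (left_c.y_star + right_c.y_star)
            crossing = (float(sigma_c), float(y_c))
            valid &= sigma_grid <= sigma_c
    return StaircaseCurve(sigma_grid, yl, yr, reg, valid, crossing)


def predict_orbit(
    sigma: float,
    pair: tuple[TransitionSolution, TransitionSolution],
    geom_l: BranchGeometry,
    geom_r: BranchGeometry,
    p: ModelParams | None = None,
) -> PredictedOrbit:
    """Glue the slow-manifold motions into the stochastic periodic orbit.

    The bursting period (fast-time units) is the slow transit time along
    both branches between the transition positions,

        T = int_{y_cl}^{y_cr} dy / (eps*|x_l(y)+a|)
          + int_{y_cl}^{y_cr} dy / (eps*(x_r(y)+a)) ,

    and the predicted spikes per burst are the wave-lobe tips traversed
    on the right branch, counting the escape lobe's tip (the escape jump
    itself produces the final spike).
    """
    if p is None:
        p = geom_l.params
    left, right = pair
    if not (left.converged and right.converged):
        raise ValueError("predict_orbit requires a converged transition pair")
    y_cl, y_cr = left.y_star, right.y_star
    if not y_cl < y_cr:
        raise ValueError(f"invalid orbit: y_cl={y_cl} >= y_cr={y_cr}")

    def transit(geom: BranchGeometry) -> float:
        yy = _grid_slice(geom, y_cl, y_cr)
        xb = geom.interp(yy, "x_of_y")
        return float(np.trapezoid(1.0 / (p.eps * np.abs(xb + p.a)), yy))

    period = transit(geom_l) + transit(geom_r)
    tips = [r for r in geom_r.regions if y_cl < r.y_tip <= y_cr]
    count = len(tips)
    esc = next((r for r in geom_r.regions if r.index == right.region_index), None)
    if esc is not None and not (y_cl < esc.y_tip <= y_cr):
        count += 1
    count = max(count, 1)
    yy_l = _grid_slice(geom_l, y_cl, y_cr)[::-1]
    yy_r = _grid_slice(geom_r, y_cl, y_cr)
    poly = np.concatenate(
        [
            np.column_stack([geom_l.interp(yy_l, "x_of_y"), yy_l]),
            np.column_stack([geom_r.interp(yy_r, "x_of_y"), yy_r]),
            np.column_stack([geom_l.interp([y_cr], "x_of_y"), [y_cr]]),
        ]
    )
    return PredictedOrbit(
        sigma=float(sigma),
        y_cl=float(y_cl),
        y_cr=float(y_cr),
        period=period,
        spike_count=int(count),
        polyline=poly,
    )


def rest_state_y(geom_l: BranchGeometry, a: float) -> float:
    """y of the left-branch rest state x_l(y) = -a (excitable regime)."""
    x = geom_l.x_of_y
    y = geom_l.y_grid
    h = x + a
    idx = np.nonzero(h[:-1] * h[1:] < 0)[0]
    if len(idx) == 0:
        raise ValueError(f"no rest state on the tabulated left branch for a={a}")
    i = idx[0]
    t = h[i] / (h[i] - h[i + 1])
    return float(y[i] + t * (y[i + 1] - y[i]))


def excitable_threshold(
    a: float,
    geom_l: BranchGeometry,
    p: ModelParams | None = None,
    y0: float = Y0_LEFT_DEFAULT,
    clearance: float = 0.02,
    sigma_bracket: tuple = (1e-4, 2.0),
    rel_tol: float = 1e-3,
) -> float:
    """Minimal noise strength for coherent escape in the excitable regime.

    For ``a`` in the excitable range the left branch carries a stable rest
    state at x = -a; the slow drift funnels the state toward it and the
    drift factor |x_l + a| in the matching integral vanishes there.  The
    threshold is the smallest sigma for which the distance matching
    condition produces a transition at y* at least ``clearance`` above the
    rest-state y — i.e. escape occurs before the state is absorbed into
    the slowing-down neighborhood of the rest state.  Located by bisection
    on log(sigma).

    The nullcline geometry does not depend on ``a``, so the default-window
    left-branch table can be reused; only the drift factor and the rest
    state move.
    """
    if p is None:
        p = geom_l.params
    p = p.replace(a=a)
    y_fp = rest_state_y(geom_l, a)
    floor = y_fp + clearance
    if floor >= y0:
        raise ValueError(f"rest state y={y_fp:.3f} too close to y0={y0}")

    def escapes(s: float) -> bool:
        sol = solve_transition("left", s, y0, geom_l, p, y_min=floor)
        return sol.converged and sol.y_star > floor + 1e-12

    s_lo, s_hi = sigma_bracket
    if escapes(s_lo):
        return float(s_lo)
    if not escapes(s_hi):
        raise RuntimeError(f"no escape even at sigma={s_hi}: bracket failed")
    while s_hi / s_lo > 1.0 + rel_tol:
        s_mid = math.sqrt(s_lo * s_hi)
        if escapes(s_mid):
            s_hi = s_mid
        else:
            s_lo = s_mid
    return float(math.sqrt(s_lo * s_hi))
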