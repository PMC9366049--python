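"""Numerical geometry of the fast (x) nullcline.

Per-y root finding with stability labels, branch tabulation by
continuation (so the wavy right branch is followed through its near-fold
wiggles), barrier distances S(y), potential differences dU between barrier
and branch, curvatures at branch minimum and barrier maximum, the
wave-lobe region partition of the right branch, and the intersections of
the two potential-difference curves.

Conventions
-----------
* "left" branch: the leftmost stable root x_l(y); its barrier x_m is the
  unstable root immediately to its right.  S = x_m - x_l, dU = U_m - U_l.
* "right" branch: the stable root tracked by continuation starting from
  the rightmost stable root at the bottom of the window; its barrier is
  the unstable root immediately to its left.  S = x_r - x_m,
  dU = U_m - U_r.
* When a slice has more than three roots the barrier used is always the
  unstable root ADJACENT to the branch on the side toward the other
  branch: Kramers escape is governed by the nearest saddle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import DEFAULT_PARAMS, ModelParams, fast_drift, fast_drift_dx, potential

#: Default y windows containing the deterministic limit cycle and all
#: stochastic orbits of interest.
LEFT_WINDOW = (-0.66, 0.30)
RIGHT_WINDOW = (-0.70, 0.25)

#: Default tabulation resolution per branch (>= 60 points per cosine lobe).
DEFAULT_GRID_N = 4000


@dataclass(frozen=True)
class NullclineSlice:
    """All roots of f(., y) = 0 at one y, with stability labels.

    ``roots`` is sorted ascending in x and stabilities alternate
    (stable/unstable).  ``x_l`` is the leftmost stable root, ``x_r`` the
    rightmost stable root, ``x_m`` the unstable root immediately right of
    ``x_l`` (the barrier governing left-branch escape); each is None when
    absent.
    """

    y: float
    roots: tuple  # of (x, "stable"|"unstable")
    x_l: float | None
    x_m: float | None
    x_r: float | None


@dataclass(frozen=True)
class Region:
    """One wave lobe of the right branch.

    ``y_start`` is the lobe's bottom-rightmost point (local potential
    minimum along the traversal, locally maximal barrier distance S);
    ``y_tip`` its leftmost tip (local minimum of S, where escape is
    easiest); ``y_end`` the start of the next lobe (or the window top).
    """

    index: int
    y_start: float
    y_end: float
    y_tip: float


@dataclass
class BranchGeometry:
    """Tabulated geometry of one stable branch on a monotone y grid.

    Arrays are aligned with ``y_grid``: branch position ``x_of_y``, barrier
    position ``x_barrier``, barrier distance ``S`` (>= 0), potential
    difference ``dU = U_barrier - U_branch`` (>= 0), curvature
    ``curv_branch = U'' > 0`` at the branch minimum and
    ``curv_barrier = |U''|`` at the barrier maximum.  For the right branch
    ``regions`` holds the wave-lobe partition.
    """

    branch: str  # "left" | "right"
    y_grid: np.ndarray
    x_of_y: np.ndarray
    x_barrier: np.ndarray
    S: np.ndarray
    dU: np.ndarray
    curv_branch: np.ndarray
    curv_barrier: np.ndarray
    params: ModelParams
    regions: list = field(default_factory=list)
    truncated: bool = False

    def interp(self, y, name: str):
        """Linear interpolation of a tabulated column at y."""
        return np.interp(y, self.y_grid, getattr(self, name))

    def to_frame(self):
        """Columnar export (y, x, x_barrier, S, dU, curvatures)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "y": self.y_grid,
                "x": self.x_of_y,
                "x_barrier": self.x_barrier,
                "S": self.S,
                "dU": self.dU,
                "curv_branch": self.curv_branch,
                "curv_barrier": self.curv_barrier,
            }
        )


class FoldError(RuntimeError):
    """Raised when branch continuation loses its root (a fold was crossed)."""


def nullcline_roots(
    y: float,
    p: ModelParams = DEFAULT_PARAMS,
    x_window: tuple = (-3.0, 3.0),
    grid_n: int = 800,
) -> NullclineSlice:
    """Find all roots of ``f(., y) = 0`` in ``x_window`` with stability labels.

    Sign changes of f on a uniform grid are bracketed and polished with a
    bracketed scalar solver to ~1e-12; stability is the sign of df/dx
    (negative = stable).  Raises if adjacent roots have conflicting
    (non-alternating) stability labels, which signals a degenerate fold
    sitting exactly on the grid — perturb y slightly in that case.
    """
    if grid_n < 400:
        raise ValueError("grid_n must be >= 400 to bracket the wavy roots")
    xs = np.linspace(x_window[0], x_window[1], grid_n)
    fs = fast_drift(xs, y, p)
    roots: list[tuple[float, str]] = []
    for i in range(len(xs) - 1):
        f0, f1 = fs[i], fs[i + 1]
        if f0 == 0.0:
            r = xs[i]
        elif f0 * f1 < 0:
            r = brentq(lambda x: fast_drift(x, y, p), xs[i], xs[i + 1], xtol=1e-13)
        else:
            continue
        stab = "stable" if fast_drift_dx(r, y, p) < 0 else "unstable"
        if roots and abs(r - roots[-1][0]) < 1e-10:
            if roots[-1][1] != stab:
                raise RuntimeError(
                    f"degenerate fold at y={y}: colliding roots with "
                    "conflicting stability — perturb y"
                )
            continue
        roots.append((float(r), stab))
    for (x0, s0), (x1, s1) in zip(roots, roots[1:]):
        if s0 == s1:
            raise RuntimeError(
                f"non-alternating stability at y={y} between x={x0} and "
                f"x={x1}; refine grid_n or perturb y"
            )
    stable = [x for x, s in roots if s == "stable"]
    x_l = stable[0] if stable else None
    x_r = stable[-1] if stable else None
    x_m = None
    if x_l is not None:
        above = [x for x, s in roots if s == "unstable" and x > x_l]
        x_m = above[0] if above else None
    return NullclineSlice(y=float(y), roots=tuple(roots), x_l=x_l, x_m=x_m, x_r=x_r)


def _branch_point(
    y: float,
    p: ModelParams,
    branch: str,
    x_prev: float | None,
    max_jump: float,
) -> tuple[float, float]:
    """Branch root and adjacent barrier root at one y (continuation step)."""
    sl = nullcline_roots(y, p)
    stable = [x for x, s in sl.roots if s == "stable"]
    unstable = [x for x, s in sl.roots if s == "unstable"]
    if not stable or not unstable:
        raise FoldError(f"no stable/unstable root pair at y={y}")
    if x_prev is None:
        xb = stable[0] if branch == "left" else stable[-1]
    else:
        xb = min(stable, key=lambda x: abs(x - x_prev))
        if abs(xb - x_prev) > max_jump:
            raise FoldError(
                f"continuation jump {abs(xb - x_prev):.3g} > {max_jump} at y={y}"
            )
    if branch == "left":
        cand = [x for x in unstable if x > xb]
        if not cand:
            raise FoldError(f"no barrier right of left branch at y={y}")
        xm = cand[0]
    else:
        cand = [x for x in unstable if x < xb]
        if not cand:
            raise FoldError(f"no barrier left of right branch at y={y}")
        xm = cand[-1]
    return xb, xm


def branch_table(
    branch: str,
    y_range: tuple | None = None,
    n: int = DEFAULT_GRID_N,
    p: ModelParams = DEFAULT_PARAMS,
    max_jump: float = 0.15,
) -> BranchGeometry:
    """Tabulate one stable branch of the x nullcline on a uniform y grid.

    The branch is tracked by continuation: each grid point's root is the
    stable root nearest the previous one, so the wavy right branch is
    followed through its near-fold wiggles instead of hopping between
    disconnected nullcline components.  If continuation loses the root
    (fold crossed), the table is truncated at the last valid y and flagged.
    """
    if branch not in ("left", "right"):
        raise ValueError("branch must be 'left' or 'right'")
    if y_range is None:
        y_range = LEFT_WINDOW if branch == "left" else RIGHT_WINDOW
    if n < 1000:
        raise ValueError("n must be >= 1000 to resolve the cosine lobes")
    y_grid = np.linspace(y_range[0], y_range[1], n)
    xb = np.empty(n)
    xm = np.empty(n)
    x_prev = None
    truncated = False
    first, last = 0, n
    started = False
    for i, y in enumerate(y_grid):
        try:
            xb[i], xm[i] = _branch_point(y, p, branch, x_prev, max_jump)
        except FoldError:
            if not started:
                # branch (or its barrier) does not yet exist: the window
                # bottom lies in the monostable range below the fold
                first = i + 1
                truncated = True
                continue
            truncated = True
            last = i
            break
        started = True
        x_prev = xb[i]
    if last - first < 2:
        raise FoldError(
            f"{branch} branch with a barrier does not exist inside {y_range}"
        )
    y_grid, xb, xm = y_grid[first:last], xb[first:last], xm[first:last]
    pb = potential(xb, y_grid, p)
    pm = potential(xm, y_grid, p)
    S = np.abs(xb - xm)
    dU = pm.U - pb.U
    geom = BranchGeometry(
        branch=branch,
        y_grid=y_grid,
        x_of_y=xb,
        x_barrier=xm,
        S=S,
        dU=dU,
        curv_branch=pb.d2U,
        curv_barrier=np.abs(pm.d2U),
        params=p,
        truncated=truncated,
    )
    if branch == "right":
        try:
            geom.regions = partition_right_branch(geom)
        except ValueError:
            geom.regions = []
    return geom


def _local_extrema(v: np.ndarray, kind: str) -> np.ndarray:
    """Indices of strict interior local minima/maxima of a 1-D array."""
    if kind == "min":
        mask = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])
    else:
        mask = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    return np.nonzero(mask)[0] + 1


def partition_right_branch(geom: BranchGeometry) -> list[Region]:
    """Partition the wavy right branch into its wave-lobe regions.

    Region starting positions are the local maxima of the barrier distance
    S(y) along the branch (the bottom-rightmost point of each lobe, where
    the potential along the traversal is locally minimal and escape is
    hardest); region tips are the local minima of S(y) (the lobe's
    leftmost point, where escape is easiest).  Regions tile the window
    from each start to the next; the segment above the last start forms
    the final region, ending at the window top.
    """
    if geom.branch != "right":
        raise ValueError("partition applies to the right branch only")
    S = geom.S
    y = geom.y_grid
    starts = _local_extrema(S, "max")
    if len(starts) == 0:
        # monotone branch (FitzHugh-Nagumo limit): one region, tip at the
        # point of smallest barrier distance (the upper fold)
        return [
            Region(
                index=1,
                y_start=float(y[0]),
                y_end=float(y[-1]),
                y_tip=float(y[int(np.argmin(S))]),
            )
        ]
    if len(starts) < 2:
        raise ValueError(
            "wavy branch with fewer than 2 wave lobes — wrong window or parameters"
        )
    regions: list[Region] = []
    bounds = list(starts) + [len(y) - 1]
    for k in range(len(starts)):
        i0, i1 = bounds[k], bounds[k + 1]
        seg = S[i0 : i1 + 1]
        tip_rel = _local_extrema(seg, "min")
        if len(tip_rel) == 0:
            tip_idx = i0 + int(np.argmin(seg))
        else:
            tip_idx = i0 + int(tip_rel[np.argmin(seg[tip_rel])])
        regions.append(
            Region(
                index=k + 1,
                y_start=float(y[i0]),
                y_end=float(y[i1]),
                y_tip=float(y[tip_idx]),
            )
        )
    return regions


def potential_difference_intersections(
    left_geom: BranchGeometry, right_geom: BranchGeometry
) -> np.ndarray:
    """All y where the two barrier heights coincide, dU_ml(y) = dU_mr(y).

    Found by sign-change bracketing of the difference on the common y
    window followed by bisection refinement on the interpolated tables;
    returns a sorted (possibly empty) array.
    """
    lo = max(left_geom.y_grid[0], right_geom.y_grid[0])
    hi = min(left_geom.y_grid[-1], right_geom.y_grid[-1])
    if hi <= lo:
        return np.array([])
    n = max(len(left_geom.y_grid), len(right_geom.y_grid))
    yy = np.linspace(lo, hi, n)

    def gap(y):
        return left_geom.interp(y, "dU") - right_geom.interp(y, "dU")

    g = gap(yy)
    out = []
    for i in np.nonzero(g[:-1] * g[1:] < 0)[0]:
        out.append(brentq(gap, yy[i], yy[i + 1], xtol=1e-12))
    for i in np.nonzero(g == 0.0)[0]:
        out.append(float(yy[i]))
    return np.array(sorted(out))
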