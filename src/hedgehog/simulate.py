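"""Direct simulation of the noise-perturbed Hedgehog burster and event analysis.

Integration is Euler-Maruyama in fast time tau = t/eps,

    x <- x + f(x, y) dt + sqrt(sigma dt) N(0, 1)
    y <- y + eps (x + a) dt ,

which reduces to deterministic forward Euler at sigma = 0.  Event-level
analysis covers hysteretic burst segmentation and spike counting,
empirical transition positions, cycle-period statistics, mixed-mode
(double-escape) detection, and large-noise slow-variable trap detection.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .model import DEFAULT_PARAMS, ModelParams


@njit(cache=True)
def _em_kernel(x0, y0, n_steps, dt, eps, a, cos_amp, cos_freq, gain, center,
               noise_scale, noise, rec_every, xs, ys):
    """Euler-Maruyama inner loop; records every ``rec_every`` steps."""
    x = x0
    y = y0
    xs[0] = x
    ys[0] = y
    k = 1
    for i in range(n_steps):
        z = gain * (center - x)
        if z > 40.0:
            L = math.exp(-z)  # saturated tail, avoids exp overflow
        else:
            L = 1.0 / (1.0 + math.exp(z))
        f = x - x * x * x / 3.0 - y + cos_amp * L * math.cos(cos_freq * y)
        xn = x + f * dt + noise_scale * noise[i]
        yn = y + eps * (x + a) * dt
        x = xn
        y = yn
        if (i + 1) % rec_every == 0:
            xs[k] = x
            ys[k] = y
            k += 1
    return k


@dataclass
class Trajectory:
    """One simulated path on a uniform fast-time grid.

    ``dt`` is the integration step; samples are stored every
    ``record_every`` steps, so the sampling interval is
    ``dt * record_every``.
    """

    tau: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sigma: float
    seed: int
    params: ModelParams
    dt: float
    record_every: int = 1

    @property
    def dt_sample(self) -> float:
        return self.dt * self.record_every

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"tau": self.tau, "x": self.x, "y": self.y})

    def save(self, path: str | Path) -> None:
        """Write columnar text (tau,x,y) plus a JSON sidecar of metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "sigma": self.sigma,
            "seed": self.seed,
            "dt": self.dt,
            "record_every": self.record_every,
            "params": self.params.to_dict(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            tau=df["tau"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            sigma=meta["sigma"],
            seed=meta["seed"],
            params=ModelParams.from_dict(meta["params"]),
            dt=meta["dt"],
            record_every=meta["record_every"],
        )


@dataclass
class BurstStatistics:
    """Event-level summary of a trajectory's bursting cycles.

    One burst = one maximal right-branch sojourn; ``bursts`` rows are
    (start tau, end tau, spike count, y at right entry, y at right exit).
    Periods are fast-time intervals between successive right-branch
    entries.
    """

    bursts: list
    modal_spikes: int
    spike_count_set: tuple
    period_mean: float
    period_std: float
    n_cycles: int
    complete: bool = True

    @property
    def spike_counts(self) -> list:
        return [b[2] for b in self.bursts]

    @property
    def y_entries(self) -> list:
        return [b[3] for b in self.bursts]

    @property
    def y_exits(self) -> list:
        return [b[4] for b in self.bursts]

    def to_dict(self) -> dict:
        return {
            "bursts": [list(b) for b in self.bursts],
            "modal_spikes": self.modal_spikes,
            "spike_count_set": list(self.spike_count_set),
            "period_mean": self.period_mean,
            "period_std": self.period_std,
            "n_cycles": self.n_cycles,
            "complete": self.complete,
        }


@dataclass
class TrapReport:
    """Coexisting slow-variable traps detected at one (large) noise strength."""

    sigma: float
    trap_centers: list
    trap_widths: list
    n_traps: int
    assignments: list  # per initial condition: trap index or "escaped"/"transient"

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "trap_centers": list(self.trap_centers),
            "trap_widths": list(self.trap_widths),
            "n_traps": self.n_traps,
            "assignments": list(self.assignments),
        }


def integrate(
    p: ModelParams,
    x0: float,
    y0: float,
    tau_end: float,
    dt: float = 5e-3,
    seed: int = 0,
    record_every: int = 1,
    sigma: float | None = None,
) -> Trajectory:
    """Euler-Maruyama integration in fast time from (x0, y0) up to tau_end.

    ``sigma`` overrides ``p.sigma`` when given.  Reproducible: a fixed
    seed yields a bit-identical trajectory.  Raises on non-finite states
    (blow-up means dt is too large).
    """
    if dt <= 0 or dt > 0.01:
        raise ValueError("dt must be in (0, 0.01] to resolve the fast relaxation")
    if tau_end <= 0:
        raise ValueError("tau_end must be > 0")
    s = p.sigma if sigma is None else float(sigma)
    if s < 0:
        raise ValueError("sigma must be >= 0")
    n_steps = int(round(tau_end / dt))
    rng = np.random.default_rng(seed)
    if s > 0:
        noise = rng.standard_normal(n_steps)
    else:
        noise = np.zeros(n_steps)
    n_rec = n_steps // record_every + 1
    xs = np.empty(n_rec)
    ys = np.empty(n_rec)
    k = _em_kernel(
        float(x0), float(y0), n_steps, dt, p.eps, p.a, p.cos_amp, p.cos_freq,
        p.logistic_gain, p.logistic_center, math.sqrt(s * dt), noise,
        record_every, xs, ys,
    )
    xs, ys = xs[:k], ys[:k]
    if not (np.isfinite(xs[-1]) and np.isfinite(ys[-1])):
        raise FloatingPointError("trajectory blew up: reduce dt")
    tau = np.arange(k) * (dt * record_every)
    return Trajectory(
        tau=tau, x=xs, y=ys, sigma=s, seed=seed, params=p.replace(sigma=s),
        dt=dt, record_every=record_every,
    )


def _hysteretic_state(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """-1 below lo, +1 above hi, previous state in between (0 before first)."""
    s = np.zeros(len(x), dtype=np.int8)
    s[x > hi] = 1
    s[x < lo] = -1
    # forward-fill zeros with the last nonzero state
    idx = np.nonzero(s != 0)[0]
    if len(idx) == 0:
        return s
    pos = np.zeros(len(x), dtype=np.int64)
    pos[idx] = idx
    np.maximum.accumulate(pos, out=pos)
    filled = s[pos]
    filled[: idx[0]] = 0
    return filled


def _runs(state: np.ndarray) -> list:
    """Maximal constant runs as (value, start_index, end_index_exclusive)."""
    if len(state) == 0:
        return []
    change = np.nonzero(np.diff(state))[0] + 1
    bounds = np.concatenate(([0], change, [len(state)]))
    return [
        (int(state[bounds[i]]), int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
    ]


def segment_bursts(
    traj: Trajectory,
    x_left_thr: float = -1.0,
    x_right_thr: float = 1.0,
    min_dwell: float = 1.0,
    spike_prominence: float = 0.3,
    smooth_window: float = 20.0,
) -> BurstStatistics:
    """Segment a trajectory into bursts and count spikes per burst.

    A hysteretic state machine labels the path ON-LEFT when x has crossed
    below ``x_left_thr`` and ON-RIGHT after crossing above ``x_right_thr``
    (the wavy right branch dips between the thresholds without leaving the
    ON-RIGHT state); sojourns shorter than ``min_dwell`` fast-time units
    are merged into their predecessor.  Spikes within a burst are the
    local maxima of x with prominence >= ``spike_prominence`` — one per
    wave-lobe traversal.  Before peak detection x is smoothed with a
    moving average of ``smooth_window`` fast-time units, which is two
    orders of magnitude shorter than a lobe traversal but long enough to
    suppress spurious noise peaks at large sigma.

    Returns flagged-empty statistics when the path contains no complete
    cycle.
    """
    dt_s = traj.dt_sample
    x = traj.x
    width = max(1, int(round(smooth_window / dt_s)))
    xs = uniform_filter1d(x, size=width, mode="nearest") if width > 1 else x
    state = _hysteretic_state(xs, x_left_thr, x_right_thr)
    runs = _runs(state)
    min_len = max(1, int(round(min_dwell / dt_s)))
    merged: list = []
    for val, i0, i1 in runs:
        if merged and (i1 - i0 < min_len or val == merged[-1][0]):
            merged[-1] = (merged[-1][0], merged[-1][1], i1)
        else:
            merged.append((val, i0, i1))
    bursts = []
    entries = []
    for k, (val, i0, i1) in enumerate(merged):
        if val != 1:
            continue
        if k == 0 or merged[k - 1][0] != -1:
            continue  # need a left sojourn before: complete entry
        closed = k + 1 < len(merged) and merged[k + 1][0] == -1
        entries.append(traj.tau[i0])
        if not closed:
            continue
        seg = xs[i0:i1]
        peaks, _ = find_peaks(seg, prominence=spike_prominence)
        n_spikes = len(peaks)
        if n_spikes == 0:
            n_spikes = 1  # the escape jump itself is a spike
        bursts.append(
            (
                float(traj.tau[i0]),
                float(traj.tau[i1 - 1]),
                int(n_spikes),
                float(traj.y[i0]),
                float(traj.y[i1 - 1]),
            )
        )
    periods = np.diff(entries)
    n_cycles = len(periods)
    if not bursts:
        return BurstStatistics([], 0, (), float("nan"), float("nan"), 0, complete=False)
    counts = Counter(b[2] for b in bursts)
    modal = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return BurstStatistics(
        bursts=bursts,
        modal_spikes=int(modal),
        spike_count_set=tuple(sorted(counts)),
        period_mean=float(np.mean(periods)) if n_cycles else float("nan"),
        period_std=float(np.std(periods)) if n_cycles >= 2 else float("nan"),
        n_cycles=int(n_cycles),
    )


def detect_mixed_mode(
    stats: BurstStatistics,
    min_frac: float = 0.1,
    p: ModelParams = DEFAULT_PARAMS,
) -> tuple:
    """Mixed-mode (double-escape) flag and spike-count histogram.

    Double-escape bursting means the right-branch escape occurs at two
    different wave-lobe tips across realizations.  The burst exit
    positions (y at right-branch exit) are clustered with a merge radius
    of a quarter wave-lobe spacing; the flag is True when at least two
    clusters each hold >= ``min_frac`` of the bursts.  Exit positions
    rather than raw spike counts are used because spike counts also vary
    with the left-branch entry position, which does not constitute a
    double escape.
    """
    counts = dict(sorted(Counter(stats.spike_counts).items()))
    exits = sorted(stats.y_exits)
    if not exits:
        return False, counts
    radius = math.pi / (2.0 * p.cos_freq)
    clusters = [[exits[0]]]
    for v in exits[1:]:
        if v - clusters[-1][-1] <= radius:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    frequent = [c for c in clusters if len(c) / len(exits) >= min_frac]
    return len(frequent) >= 2, counts


def left_branch_x(y: float, p: ModelParams = DEFAULT_PARAMS) -> float:
    """x position of the left nullcline branch at y (for initial conditions)."""
    from .geometry import nullcline_roots

    sl = nullcline_roots(y, p)
    if sl.x_l is None:
        raise ValueError(f"no left-branch root at y={y}")
    return sl.x_l


def detect_traps(
    p: ModelParams,
    sigma: float,
    initial_conditions: list | None = None,
    tau_end: float = 5e3,
    dt: float = 5e-3,
    seed: int = 0,
    burn_in: float | None = None,
    n_init: int = 25,
    y_init_range: tuple = (-0.6, 0.2),
    clamp_tol: float = 0.05,
    merge_radius: float = 0.03,
    record_every: int = 10,
    n_restart_per: int = 20,
    escape_radius: float = 0.1,
    confirm_frac: float = 0.75,
) -> TrapReport:
    """Detect coexisting slow-variable traps at large noise.

    Two stages.  First, an ensemble of trajectories started on the left
    branch at y values spread over ``y_init_range`` (default:
    ``n_init = 20`` uniformly spaced starts; an explicit list of
    (x0, y0) pairs overrides) is integrated; after discarding ``burn_in``
    (default: the first half of the run) a trajectory is *clamped* when
    its y range over the remaining window is below ``clamp_tol``, and
    clamped steady-state y means are clustered by 1-D merge with radius
    ``merge_radius`` (below half the wave-lobe spacing, which sets the
    natural trap separation).  Second, each candidate trap is confirmed
    by a supplementary ensemble of ``n_restart_per`` restarts from the
    candidate center with fresh noise.  A restart re-clamps when its
    median y stays within ``escape_radius`` of the center and its
    central-95% y range over the last half stays below ``clamp_tol``;
    the candidate is a stable trap only if at least ``confirm_frac`` of
    its restarts re-clamp.  This persistence-and-width vote separates the
    genuinely clamped regions from wide or short-lived metastable
    transients, whose single-run statistics straddle the clamping
    tolerance.  Trajectories not clamped at a confirmed trap are recorded
    as "transient".  A report with zero traps signals that sigma is too
    small for trapping.
    """
    if burn_in is None:
        burn_in = tau_end / 2.0
    if initial_conditions is None:
        ys0 = np.linspace(y_init_range[0], y_init_range[1], n_init)
        initial_conditions = [(left_branch_x(yy, p), float(yy)) for yy in ys0]
    means = []
    widths = []
    flags: list = []
    for i, (x0, y0) in enumerate(initial_conditions):
        traj = integrate(
            p, x0, y0, tau_end, dt=dt, seed=seed + i, record_every=record_every,
            sigma=sigma,
        )
        tail = traj.y[traj.tau >= burn_in]
        q_lo, q_hi = np.percentile(tail, [2.5, 97.5])
        rng_y = float(q_hi - q_lo)
        if rng_y < clamp_tol:
            means.append(float(tail.mean()))
            widths.append(rng_y / 2.0)
            flags.append(len(means) - 1)  # placeholder: cluster later
        else:
            means.append(None)
            widths.append(None)
            flags.append("transient")
    clamped = sorted(
        (m, w, i) for i, (m, w) in enumerate(zip(means, widths)) if m is not None
    )
    centers: list = []
    cwidths: list = []
    members: list = []
    for m, w, i in clamped:
        if members and m - members[-1][-1][0] <= merge_radius:
            members[-1].append((m, w, i))
        else:
            members.append([(m, w, i)])
    assignments: list = list(flags)
    keep: list = []
    restart_seed = seed + 100_000
    for k, grp in enumerate(members):
        ms = [m for m, _, _ in grp]
        ws = [w for _, w, _ in grp]
        center = float(np.mean(ms))
        x0 = left_branch_x(center, p)
        n_clamped = 0
        for j in range(n_restart_per):
            rt = integrate(
                p, x0, center, tau_end, dt=dt, seed=restart_seed, sigma=sigma,
                record_every=record_every,
            )
            restart_seed += 1
            tail = rt.y[rt.tau >= burn_in]
            q_lo, q_hi = np.percentile(tail, [2.5, 97.5])
            if (
                abs(float(np.median(tail)) - center) <= escape_radius
                and q_hi - q_lo < clamp_tol
            ):
                n_clamped += 1
        if n_clamped >= confirm_frac * n_restart_per:
            keep.append(k)
            centers.append(center)
            cwidths.append(float(max(ws)))
            for _, _, i in grp:
                assignments[i] = len(centers) - 1
        else:
            for _, _, i in grp:
                assignments[i] = "transient"
    return TrapReport(
        sigma=float(sigma),
        trap_centers=centers,
        trap_widths=cwidths,
        n_traps=len(centers),
        assignments=assignments,
    )
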