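"""Water diffusion (MSD + Einstein relation) and first-shell residence times.

The MSD is averaged over all sliding time origins and over the selected
waters; the FFT-based correlation algorithm gives exactly the all-origins
average at O(F log F) per water.  D = slope/6 over a fit window (default
10-50 % of the maximum lag, avoiding both the short-time regime and the
noisy tail), converted Å²/ps → cm²/s.

Residence episodes are maximal runs of consecutive in-contact frames.
Episodes touching either trajectory end are censored (their true length is
unknown) and excluded from the mean by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .classify import DEFAULT_CONTACT_CUTOFF, _as_coords
from .errors import EmptyInputError, SelectionError
from .models import ComplexStructure
from .units import A2_PER_PS_TO_CM2_PER_S


@dataclass
class Trajectory:
    """Time-ordered water-oxygen coordinates.

    coords: (n_frames, n_waters, 3) in Å; dt in ps between stored frames;
    box: orthorhombic box lengths (3,) in Å or None; ids stable across frames.
    """

    coords: np.ndarray
    dt: float
    ids: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, waters, 3), got {self.coords.shape}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.ids is None:
            self.ids = np.arange(self.coords.shape[1])
        self.ids = np.asarray(self.ids)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_waters(self) -> int:
        return self.coords.shape[1]


def trajectory_from_structure(structure: ComplexStructure, dt: float, box=None) -> Trajectory:
    """Build a water trajectory from a multi-model structure.

    Waters are matched across models by serial; every model must contain the
    same water serials.
    """
    if structure.n_models < 2:
        raise ValueError("need at least two models for a trajectory")
    serials0 = [w.serial for w in structure.models[0].waters]
    order = {s: i for i, s in enumerate(serials0)}
    coords = np.empty((structure.n_models, len(serials0), 3))
    for fi, m in enumerate(structure.models):
        if sorted(w.serial for w in m.waters) != sorted(serials0):
            raise SelectionError(f"model {fi} water serials differ from model 0")
        for w in m.waters:
            coords[fi, order[w.serial]] = (w.x, w.y, w.z)
    return Trajectory(coords=coords, dt=dt, ids=np.array(serials0), box=box)


def unwrap(traj: Trajectory) -> np.ndarray:
    """Continuous coordinates: accumulate minimum-image frame displacements."""
    if traj.box is None:
        return traj.coords
    disp = np.diff(traj.coords, axis=0)
    disp -= traj.box * np.round(disp / traj.box)
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    out[1:] = traj.coords[0] + np.cumsum(disp, axis=0)
    return out


def _msd_fft_single(r: np.ndarray) -> np.ndarray:
    """All-origins MSD of one particle path (F,3) via FFT autocorrelation."""
    F = r.shape[0]
    sq = np.sum(r**2, axis=1)
    # autocorrelation of each coordinate, summed
    n = 1 << (2 * F - 1).bit_length()
    fr = np.fft.rfft(r, n=n, axis=0)
    acf = np.fft.irfft(fr * np.conj(fr), n=n, axis=0)[:F].sum(axis=1)
    counts = np.arange(F, 0, -1, dtype=float)
    # S1(m) = sum over valid origins t of sq(t) + sq(t+m)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    total = csum[-1]
    m = np.arange(F)
    s1 = (total - csum[m]) + csum[F - m]
    return s1 / counts - 2.0 * acf / counts


def msd(traj: Trajectory, selection=None, max_lag: float | None = None):
    """Mean square displacement curve.

    Returns (lags_ps, msd_A2), averaged over sliding time origins and over
    the selected waters (ids; default all).  Coordinates are unwrapped first
    when a periodic box is attached.
    """
    if selection is None:
        cols = np.arange(traj.n_waters)
    else:
        sel = list(selection)
        if not sel:
            raise EmptyInputError("empty water selection")
        id_index = {int(i): k for k, i in enumerate(traj.ids)}
        missing = [s for s in sel if int(s) not in id_index]
        if missing:
            raise SelectionError(f"water id(s) {missing} not in trajectory")
        cols = np.array([id_index[int(s)] for s in sel])
    r = unwrap(traj)[:, cols, :]
    F = traj.n_frames
    if max_lag is None:
        n_lag = F - 1
    else:
        n_lag = int(round(max_lag / traj.dt))
        if n_lag >= F:
            raise ValueError(f"max_lag {max_lag} ps exceeds trajectory length")
    curves = np.stack([_msd_fft_single(r[:, k, :]) for k in range(r.shape[1])])
    curve = curves.mean(axis=0)[: n_lag + 1]
    curve[0] = 0.0  # exact by definition; guards FFT round-off
    lags = np.arange(n_lag + 1) * traj.dt
    return lags, curve


def fit_diffusion(lags, msd_curve, fit_window: tuple[float, float] | None = None):
    """Einstein-relation fit: D = slope/6 on the MSD over a lag window.

    ``fit_window`` is (lo, hi) in ps; default [10 %, 50 %] of the maximum
    lag.  Returns (D, D_stderr) in cm²/s.
    """
    lags = np.asarray(lags, dtype=float)
    msd_curve = np.asarray(msd_curve, dtype=float)
    if fit_window is None:
        fit_window = (0.1 * lags[-1], 0.5 * lags[-1])
    lo, hi = fit_window
    mask = (lags >= lo) & (lags <= hi)
    if np.sum(mask) < 2:
        raise ValueError(f"fit window [{lo}, {hi}] ps contains fewer than 2 points")
    res = stats.linregress(lags[mask], msd_curve[mask])
    return (
        res.slope / 6.0 * A2_PER_PS_TO_CM2_PER_S,
        res.stderr / 6.0 * A2_PER_PS_TO_CM2_PER_S,
    )


def contact_timeline(
    traj: Trajectory, protein_heavy_per_frame, d_c: float = DEFAULT_CONTACT_CUTOFF
) -> np.ndarray:
    """Boolean (n_frames, n_waters) first-shell contact state.

    ``protein_heavy_per_frame``: one (M,3) heavy-atom coordinate array per
    frame (a single array is broadcast to all frames for a rigid protein).
    """
    if isinstance(protein_heavy_per_frame, np.ndarray) and protein_heavy_per_frame.ndim == 2:
        protein_heavy_per_frame = [protein_heavy_per_frame] * traj.n_frames
    protein_heavy_per_frame = list(protein_heavy_per_frame)
    if len(protein_heavy_per_frame) != traj.n_frames:
        raise ValueError(
            f"{len(protein_heavy_per_frame)} protein frames vs {traj.n_frames} water frames"
        )
    out = np.zeros((traj.n_frames, traj.n_waters), dtype=bool)
    for fi in range(traj.n_frames):
        p = _as_coords(protein_heavy_per_frame[fi])
        if p.shape[0] == 0:
            raise EmptyInputError(f"no protein atoms in frame {fi}")
        d, _ = cKDTree(p).query(traj.coords[fi])
        out[fi] = d <= d_c
    return out


@dataclass
class ResidenceSummary:
    """Residence episodes of first-shell waters."""

    episodes_ps: list = field(default_factory=list)  # uncensored
    n_censored: int = 0
    dt: float = 0.0
    selection_label: str = "associated"

    @property
    def mean_ps(self) -> float | None:
        """Mean uncensored episode length; None when every episode is censored."""
        if not self.episodes_ps:
            return None
        return float(np.mean(self.episodes_ps))


def residence_times(
    timeline: np.ndarray,
    dt: float,
    gap_frames: int = 0,
    selection_label: str = "associated",
) -> ResidenceSummary:
    """Episode statistics from a boolean contact timeline.

    A run of k consecutive in-contact frames is an episode of k·dt ps.  Runs
    separated by ≤ ``gap_frames`` out-of-contact frames are merged (default
    0: no tolerance).  Runs touching either end of the trajectory are
    censored and excluded from the mean.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    timeline = np.asarray(timeline, dtype=bool)
    if timeline.ndim == 1:
        timeline = timeline[:, None]
    if timeline.size == 0:
        raise EmptyInputError("empty contact timeline")
    F = timeline.shape[0]
    summary = ResidenceSummary(dt=dt, selection_label=selection_label)
    for w in range(timeline.shape[1]):
        col = timeline[:, w]
        runs = _runs(col)
        if gap_frames > 0:
            runs = _merge_runs(runs, gap_frames)
        for start, stop in runs:  # stop exclusive
            if start == 0 or stop == F:
                summary.n_censored += 1
            else:
                summary.episodes_ps.append((stop - start) * dt)
    return summary


def _runs(col: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop-exclusive) pairs."""
    padded = np.concatenate([[False], col, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    stops = np.where(d == -1)[0]
    return list(zip(starts, stops))


def _merge_runs(runs, gap_frames: int):
    if not runs:
        return runs
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= gap_frames:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [tuple(r) for r in merged]
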