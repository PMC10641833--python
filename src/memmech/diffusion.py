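"""Lateral mean-squared displacement, diffusion-coefficient fitting, and a
Kolmogorov–Smirnov check for anomalous (non-Gaussian) diffusion.

For 2D lateral motion MSD(τ) = 4 D τ; D is the slope/4 of an ordinary
least-squares fit over a configurable lag window, reported in 1e-9 cm²/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import LeafletAssignment, Trajectory
from .units import A2_PER_PS_TO_1E9_CM2_PER_S

__all__ = [
    "MSDCurve",
    "DiffusionResult",
    "unwrap_tracks",
    "unwrap_xy",
    "msd",
    "fit_diffusion",
    "anomaly_test",
]

log = logging.getLogger(__name__)


@dataclass
class MSDCurve:
    lags: np.ndarray        # ps, starting at 0
    msd: np.ndarray         # Å²
    counts: np.ndarray      # (origin, particle) pairs contributing per lag
    dt: float               # ps between consecutive frames
    selection: str = ""


@dataclass
class DiffusionResult:
    d: float                # 1e-9 cm²/s
    se: float
    window: tuple[float, float]     # ps
    intercept: float        # Å²
    negative_slope: bool = False
    ks_statistic: float | None = None
    ks_p: float | None = None


def unwrap_tracks(wrapped: np.ndarray, box_xy: np.ndarray,
                  warn_threshold: float = 0.45) -> np.ndarray:
    """Accumulate minimum-image x–y increments into continuous tracks.

    ``wrapped`` is (n_frames, n_particles, 2); ``box_xy`` is (2,) or
    (n_frames, 2) in Å.  Warns when an imaged increment exceeds
    ``warn_threshold`` of the box (undersampling makes unwrapping ambiguous).
    """
    wrapped = np.asarray(wrapped, dtype=float)
    box = np.asarray(box_xy, dtype=float)
    if box.ndim == 1:
        box = np.broadcast_to(box, (wrapped.shape[0], 2))
    inc = np.diff(wrapped, axis=0)
    inc -= box[1:, None, :] * np.round(inc / box[1:, None, :])
    big = np.abs(inc) > warn_threshold * box[1:, None, :]
    if np.any(big):
        frames = np.unique(np.nonzero(big)[0] + 1)
        log.warning(
            "near half-box jumps at frame(s) %s: trajectory may be undersampled",
            frames[:10].tolist(),
        )
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    np.cumsum(inc, axis=0, out=out[1:])
    out[1:] += wrapped[0]
    return out


def unwrap_xy(
    traj: Trajectory,
    species: str | None = None,
    role: str = "HEAD_P",
    remove_drift: bool = True,
    assignment: LeafletAssignment | None = None,
    per_leaflet_drift: bool = False,
) -> np.ndarray:
    """Continuous drift-free x–y tracks for the selected reference atoms.

    Selects one atom per lipid by ``role`` ("HEAD_P" or "FIRST_TAIL_BEAD"),
    unwraps periodic crossings by minimum image, and subtracts the per-frame
    selection centroid (or per-leaflet centroids when ``per_leaflet_drift``).
    Returns (n_frames, n_selected, 2).
    """
    top = traj.topology
    if role == "HEAD_P":
        ix = top.head_p_indices(species)
    elif role == "FIRST_TAIL_BEAD":
        ix = top.first_tail_bead_indices(species)
    else:
        raise ValueError(f"unsupported role {role!r}")
    coords = traj.coordinate_array()
    tracks = unwrap_tracks(coords[:, ix, :2], traj.box_array()[:, :2])
    if remove_drift:
        if per_leaflet_drift:
            if assignment is None:
                raise ValueError("per-leaflet drift removal needs an assignment")
            sel_mask = top.lipid_mask(species)
            leaf = assignment.labels[sel_mask]
            for side in ("upper", "lower"):
                m = leaf == side
                if m.any():
                    tracks[:, m, :] -= tracks[:, m, :].mean(axis=1, keepdims=True)
        else:
            tracks -= tracks.mean(axis=1, keepdims=True)
    return tracks


def _msd_direct(tracks: np.ndarray, n_lags: int) -> np.ndarray:
    n = tracks.shape[0]
    out = np.zeros(n_lags)
    for k in range(1, n_lags):
        d = tracks[k:] - tracks[:-k] if k else 0.0
        out[k] = np.mean(np.sum(d * d, axis=-1))
    return out

def _msd_fft(tracks: np.ndarray, n_lags: int) -> np.ndarray:
    # standard O(N log N) decomposition MSD(k) = S1(k) - 2 S2(k)
    n, p, d = tracks.shape
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(tracks, nfft, axis=0)
    s2 = np.fft.irfft(f * np.conj(f), nfft, axis=0)[:n]       # (n, p, d)
    sq = np.sum(tracks**2, axis=-1)                           # (n, p)
    pre = np.concatenate([np.zeros((1, p)), np.cumsum(sq, axis=0)])
    total = pre[-1]
    k = np.arange(n)
    # sum over origins t of |r(t)|² + |r(t+k)|²
    sd = 2 * total[None, :] - (pre[-1] - pre[n - k]) - pre[k]
    msd_all = sd / (n - k)[:, None] - 2 * s2.sum(axis=-1) / (n - k)[:, None]
    return msd_all[:n_lags].mean(axis=1)


def msd(
    tracks: np.ndarray,
    dt: float,
    max_lag: float | None = None,
    method: str = "fft",
    selection: str = "",
) -> MSDCurve:
    """MSD over all particles and overlapping time origins (stride 1).

    ``tracks`` is (n_frames, n_particles, 2) of unwrapped Å positions;
    ``max_lag`` is in ps (default: half the span).  ``method="direct"`` is
    the O(N²) reference implementation, bit-compatible with a brute-force
    double loop; ``"fft"`` is the fast equivalent.
    """
    tracks = np.asarray(tracks, dtype=float)
    n = tracks.shape[0]
    if n < 2:
        raise ValueError("MSD needs at least 2 frames")
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = (n - 1) * dt
    if max_lag is None:
        max_lag = span / 2
    if max_lag >= span + dt:
        log.warning("max_lag %.6g ps exceeds trajectory span %.6g ps; truncating",
                    max_lag, span)
    n_lags = min(int(np.floor(max_lag / dt)) + 1, n)
    if method == "direct":
        vals = _msd_direct(tracks, n_lags)
    elif method == "fft":
        vals = _msd_fft(tracks, n_lags)
        vals[0] = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    lags = np.arange(n_lags) * dt
    counts = (n - np.arange(n_lags)) * tracks.shape[1]
    return MSDCurve(lags=lags, msd=vals, counts=counts, dt=dt,
                    selection=selection)


def fit_diffusion(curve: MSDCurve,
                  window: tuple[float, float] | None = None) -> DiffusionResult:
    """D (1e-9 cm²/s) from an OLS fit of MSD(τ) = 4 D τ + b over a lag window.

    Default window: 10–50 % of the largest available lag.
    """
    lag_max = curve.lags[-1]
    if window is None:
        window = (0.1 * lag_max, 0.5 * lag_max)
    lo, hi = window
    if lo < 0 or hi > lag_max or lo >= hi:
        raise ValueError(f"window {window} not inside curve lags [0, {lag_max}]")
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if sel.sum() < 5:
        raise ValueError(f"need >= 5 lags in the fit window, got {int(sel.sum())}")
    x, y = curve.lags[sel], curve.msd[sel]
    res = stats.linregress(x, y)
    d_a2ps = res.slope / 4.0
    d = d_a2ps * A2_PER_PS_TO_1E9_CM2_PER_S
    se = res.stderr / 4.0 * A2_PER_PS_TO_1E9_CM2_PER_S
    negative = d < 0
    return DiffusionResult(d=float(max(d, 0.0)), se=float(se),
                           window=(float(lo), float(hi)),
                           intercept=float(res.intercept),
                           negative_slope=bool(negative))


def anomaly_test(tracks: np.ndarray, dt: float,
                 lag: float) -> tuple[float, float]:
    """Two-sided KS test of displacement Gaussianity at one lag.

    Pools the x and y increments over disjoint time origins, and tests them
    against a zero-mean normal whose variance is estimated from the same
    increments.  Returns (KS statistic, p value).
    """
    tracks = np.asarray(tracks, dtype=float)
    n = tracks.shape[0]
    k = int(round(lag / dt))
    if k < 1 or k >= n:
        raise ValueError(f"lag {lag} ps out of range for dt={dt}, n={n}")
    starts = np.arange(0, n - k, k)
    inc = tracks[starts + k] - tracks[starts]           # (m, P, 2)
    pooled = inc.reshape(-1)
    if pooled.size < 100:
        raise ValueError(
            f"need >= 100 increments at this lag, got {pooled.size}"
        )
    sd = float(pooled.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate (constant) increments; KS test undefined")
    result = stats.kstest(pooled, "norm", args=(0.0, sd))
    return float(result.statistic), float(result.pvalue)
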