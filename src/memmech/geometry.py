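"""Area per lipid, bilayer thickness, and the surface-unevenness statistic."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import LeafletAssignment, Trajectory
from .elasticity import stationary_se

__all__ = [
    "AreaSeries",
    "ThicknessSeries",
    "UnevennessResult",
    "area_per_lipid",
    "bilayer_thickness",
    "surface_unevenness",
]

log = logging.getLogger(__name__)


@dataclass
class AreaSeries:
    per_frame: np.ndarray   # Å² per frame
    mean: float             # Å²
    se: float               # Å², autocorrelation-corrected
    n_frames: int
    n_per_leaflet: int
    n_eff: float = 1.0


@dataclass
class ThicknessSeries:
    per_frame: np.ndarray   # Å per frame
    mean: float
    se: float
    n_frames: int
    n_eff: float = 1.0


@dataclass
class UnevennessResult:
    u: float                # Å, sd_upper + sd_lower
    sd_upper: float
    sd_lower: float
    n_frames_sampled: int
    rng_seed: int | None
    mode: str = "pooled"


def _robust_se(series: np.ndarray) -> tuple[float, float]:
    """stationary_se with graceful fallback for very short series."""
    n = series.size
    if np.ptp(series) == 0.0:
        return 0.0, float(n)
    if n < 10:
        return float(np.std(series, ddof=1) / np.sqrt(n)), float(n)
    return stationary_se(series)


def area_per_lipid(traj: Trajectory, n_per_leaflet: int) -> AreaSeries:
    """Per-frame and mean area per lipid: lateral box area / lipids per leaflet."""
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    boxes = traj.box_array()
    apl = boxes[:, 0] * boxes[:, 1] / n_per_leaflet
    se, n_eff = _robust_se(apl)
    return AreaSeries(per_frame=apl, mean=float(apl.mean()), se=se,
                      n_frames=traj.n_frames, n_per_leaflet=n_per_leaflet,
                      n_eff=n_eff)


def bilayer_thickness(traj: Trajectory,
                      assignment: LeafletAssignment) -> ThicknessSeries:
    """Per-frame P–P thickness: mean HEAD_P z (upper) − mean HEAD_P z (lower)."""
    head_ix = traj.topology.head_p_indices()
    upper = assignment.mask("upper")
    lower = assignment.mask("lower")
    coords = traj.coordinate_array()
    z = coords[:, head_ix, 2]                       # (F, n_lipids)
    thick = z[:, upper].mean(axis=1) - z[:, lower].mean(axis=1)
    se, n_eff = _robust_se(thick)
    return ThicknessSeries(per_frame=thick, mean=float(thick.mean()), se=se,
                           n_frames=traj.n_frames, n_eff=n_eff)


def surface_unevenness(
    traj: Trajectory,
    assignment: LeafletAssignment,
    n_frames: int = 500,
    seed: int | None = None,
    mode: str = "pooled",
) -> UnevennessResult:
    """Headgroup-surface roughness from randomly sampled frames.

    For each sampled frame and leaflet the mean HEAD_P z is computed; the
    default ``"pooled"`` mode pools the per-lipid deviations z − mean over all
    sampled frames and reports one standard deviation per leaflet, summed into
    U.  The ``"frame_means"`` mode instead takes the SD of the per-frame
    leaflet means themselves (a frame-to-frame drift measure, kept for
    comparison).  Frames are sampled without replacement under ``seed``.
    """
    if n_frames <= 1:
        raise ValueError("n_frames must be > 1")
    if mode not in ("pooled", "frame_means"):
        raise ValueError(f"unknown mode {mode!r}")
    total = traj.n_frames
    if n_frames > total:
        log.warning("requested %d frames but trajectory has %d; using all",
                    n_frames, total)
        n_frames = total
    rng = np.random.default_rng(seed)
    sel = np.sort(rng.choice(total, size=n_frames, replace=False))

    head_ix = traj.topology.head_p_indices()
    coords = traj.coordinate_array()
    z = coords[np.ix_(sel, head_ix)][:, :, 2]       # (n_frames, n_lipids)
    sds = {}
    for side in ("upper", "lower"):
        zl = z[:, assignment.mask(side)]
        frame_means = zl.mean(axis=1, keepdims=True)
        if mode == "pooled":
            sds[side] = float(np.std(zl - frame_means, ddof=0))
        else:
            sds[side] = float(np.std(frame_means.ravel(), ddof=0))
    u = sds["upper"] + sds["lower"]
    return UnevennessResult(u=u, sd_upper=sds["upper"], sd_lower=sds["lower"],
                            n_frames_sampled=n_frames, rng_seed=seed, mode=mode)
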