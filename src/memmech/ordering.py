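"""Acyl-tail order parameters, relative-order profiles, and terminal-methyl
z-distributions.

The per-carbon order parameter is S_C = <(3 cos²θ_i − 1)/2>, with θ_i the
angle between the membrane normal (z) and the vector joining the heavy tail
atoms i−1 and i+1; it is defined for interior carbons 2..n−1 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import LeafletAssignment, Trajectory
from .geometry import _robust_se

__all__ = [
    "OrderProfile",
    "RelativeOrderProfile",
    "ZHistogram",
    "order_parameter_profile",
    "relative_order_profile",
    "tmg_distribution",
]

log = logging.getLogger(__name__)


@dataclass
class OrderProfile:
    species: str
    tail: str                       # "sn1" or "sn2"
    carbons: np.ndarray             # interior carbon indices 2..n-1
    s_c: np.ndarray                 # per-carbon order parameter
    se: np.ndarray
    n_frames: int

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.carbons.tolist(), self.s_c.tolist()))


@dataclass
class RelativeOrderProfile:
    species: str
    tail: str
    carbons: np.ndarray
    values: np.ndarray              # (S_mix / S_pure) * carbon index


@dataclass
class ZHistogram:
    bin_edges: np.ndarray           # Å, relative to the bilayer midplane
    density_upper: np.ndarray
    density_lower: np.ndarray
    density_both: np.ndarray
    bin_width: float
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def order_parameter_profile(traj: Trajectory, species: str,
                            tail: str = "sn1") -> OrderProfile:
    """Per-carbon S_C averaged over lipids and frames for one species/tail.

    Standard errors come from the autocorrelation-corrected SE of the
    per-frame means.
    """
    tail = tail.lower()
    if tail not in ("sn1", "sn2"):
        raise ValueError(f"tail must be 'sn1' or 'sn2', got {tail!r}")
    tix = traj.topology.tail_indices(species, tail)     # (L, n)
    n = tix.shape[1]
    coords = traj.coordinate_array()                    # (F, A, 3)
    pos = coords[:, tix, :]                             # (F, L, n, 3)
    vec = pos[:, :, 2:, :] - pos[:, :, :-2, :]          # i-1 -> i+1, (F, L, n-2, 3)
    norm = np.linalg.norm(vec, axis=-1)
    if np.any(norm == 0):
        raise ValueError("zero-length i-1 -> i+1 vector encountered")
    cos2 = (vec[..., 2] / norm) ** 2
    p2 = 1.5 * cos2 - 0.5                               # (F, L, n-2)
    per_frame = p2.mean(axis=1)                         # (F, n-2)
    s_c = per_frame.mean(axis=0)
    se = np.array([_robust_se(per_frame[:, j])[0] for j in range(n - 2)])
    return OrderProfile(species=species, tail=tail,
                        carbons=np.arange(2, n), s_c=s_c, se=se,
                        n_frames=traj.n_frames)


def relative_order_profile(mixed: OrderProfile,
                           pure: OrderProfile) -> RelativeOrderProfile:
    """(S_mix,i / S_pure,i) · i on the common carbon grid.

    Carbons where the pure profile is exactly zero are excluded with a
    warning; identical profiles reproduce the carbon-index diagonal.
    """
    if mixed.tail != pure.tail:
        raise ValueError("profiles are for different tails")
    common = np.intersect1d(mixed.carbons, pure.carbons)
    if common.size == 0:
        raise ValueError("no common carbons between profiles")
    m = {c: v for c, v in zip(mixed.carbons, mixed.s_c)}
    p = {c: v for c, v in zip(pure.carbons, pure.s_c)}
    carbons, values = [], []
    for c in common:
        if p[c] == 0.0:
            log.warning("pure S_C = 0 at carbon %d; relative order undefined", c)
            continue
        carbons.append(c)
        values.append(m[c] / p[c] * c)
    return RelativeOrderProfile(species=mixed.species, tail=mixed.tail,
                                carbons=np.array(carbons),
                                values=np.array(values))


def tmg_distribution(
    traj: Trajectory,
    assignment: LeafletAssignment,
    species: str,
    bin_width: float = 1.0,
) -> ZHistogram:
    """Density-normalized histograms of terminal-methyl z relative to the
    per-frame bilayer midplane, per leaflet and combined."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = traj.topology
    head_ix = top.head_p_indices()
    coords = traj.coordinate_array()
    midplane = coords[:, head_ix, 2].mean(axis=1)       # (F,)

    # TMG atoms of the species, each tagged with its lipid's leaflet
    tmg_ix, tmg_leaf = [], []
    for lip_pos, lip in enumerate(top.lipids):
        if lip.species != species:
            continue
        for a in lip.atoms:
            if a.is_tmg:
                tmg_ix.append(a.index)
                tmg_leaf.append(assignment.labels[lip_pos])
    if not tmg_ix:
        raise ValueError(f"species {species!r} has no TMG-tagged atoms")
    tmg_ix = np.array(tmg_ix, dtype=np.intp)
    tmg_leaf = np.array(tmg_leaf)

    z_rel = coords[:, tmg_ix, 2] - midplane[:, None]    # (F, n_tmg)
    lo = np.floor(z_rel.min() / bin_width) * bin_width
    hi = np.ceil(z_rel.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)

    dens = {}
    for side in ("upper", "lower"):
        vals = z_rel[:, tmg_leaf == side].ravel()
        dens[side], _ = (np.histogram(vals, bins=edges, density=True)
                         if vals.size else (np.zeros(edges.size - 1), edges))
    both, _ = np.histogram(z_rel.ravel(), bins=edges, density=True)
    return ZHistogram(bin_edges=edges, density_upper=dens["upper"],
                      density_lower=dens["lower"], density_both=both,
                      bin_width=bin_width, n_samples=int(z_rel.size))
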