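"""Synthetic bilayer trajectories, pressure streams, and tension series with
fully known ground truth.

Every statistical target is built in analytically:

* headgroup z-scatter is Gaussian about ±h/2, so thickness → h and the
  unevenness statistic → 2·sigma_z;
* tail geometry is generated through *skip vectors* — the vector joining
  tail atoms i−1 and i+1 is drawn directly from a two-component mixture
  (probability w: exactly z-aligned; 1−w: isotropic), whose second Legendre
  moment is exactly w, so the measured S_C equals w per interior carbon;
* lateral motion is 2D Brownian with per-axis step variance 2·D·dt, wrapped
  periodically, with the true unwrapped tracks kept in the ground truth;
* area-per-lipid streams are AR(1) around A0·(1 + gamma/K_A), giving a
  closed-form effective-sample-size target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter

from .core_io import (AtomRecord, Frame, LipidRecord, Topology, Trajectory)
from .elasticity import PressureRecord, TensionPoint, stationary_se
from .units import A2_PER_PS_TO_1E9_CM2_PER_S, BAR_ANGSTROM_TO_MN_PER_M

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_bilayer",
    "make_tension_series",
    "make_pressure_stream",
    "make_brownian_tracks",
]

_SEGMENT_LENGTH = 2.5   # Å between skip-vector endpoints


@dataclass
class SyntheticSpec:
    """Ground-truth parameterization of a generated bilayer."""

    n_per_leaflet: int = 100
    box: tuple[float, float, float] = (80.0, 80.0, 70.0)    # Å
    h: float = 38.0                 # target P–P thickness, Å
    sigma_z: float = 2.0            # headgroup z-scatter, Å
    tail_length: int = 8            # atoms per tail
    order_weight: float | tuple = 0.6   # ground-truth S_C (scalar or per carbon)
    tmg_offset: float = 16.0        # TMG mean z = -/+ (h/2 - tmg_offset)
    tmg_sd: float = 2.0
    d_true: float = 100.0           # 1e-9 cm²/s
    dt: float = 10.0                # ps
    n_frames: int = 100
    k_a_true: float = 245.0         # mN/m
    a0: float = 68.0                # Å²
    tension_list: tuple = (-7.0, 0.0, 7.0, 15.0)
    ar1_tau: float = 20.0           # frames
    species_fraction: float = 1.0   # fraction of primary species "LIPA"
    layout: str = "random"          # or "clustered"
    n_clusters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_leaflet < 2:
            raise ValueError("need at least 2 lipids per leaflet")
        if not (0.0 <= self.species_fraction <= 1.0):
            raise ValueError("species_fraction must be in [0, 1]")
        w = np.atleast_1d(np.asarray(self.order_weight, dtype=float))
        if np.any((w < 0) | (w > 1)):
            raise ValueError("order_weight must be in [0, 1]")
        if self.layout not in ("random", "clustered"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.tail_length < 3:
            raise ValueError("tail_length must be >= 3")


@dataclass
class GroundTruth:
    """Everything needed to score the analyses without re-reading the spec."""

    spec: SyntheticSpec
    leaflets: np.ndarray            # per-lipid "upper"/"lower"
    species: np.ndarray             # per-lipid species label
    true_tracks: np.ndarray         # (n_frames, n_lipids, 2) unwrapped Å
    s_c: np.ndarray                 # per-interior-carbon ground-truth S_C
    thickness: float
    sigma_z: float
    d_true: float
    tmg_mean: dict                  # leaflet -> mean TMG z (midplane frame)
    tmg_sd: float


def _lattice(n: int, box_xy, rng: np.random.Generator,
             jitter: float = 0.15) -> np.ndarray:
    lx, ly = box_xy
    if lx * ly / n < 1.0:
        raise ValueError(
            f"lattice too dense: {n} lipids in {lx:.1f}x{ly:.1f} Å box")
    m = int(np.ceil(np.sqrt(n)))
    gx, gy = lx / m, ly / m
    ix, iy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    sites = np.column_stack([(ix.ravel() + 0.5) * gx, (iy.ravel() + 0.5) * gy])
    sites = sites[:n]
    sites += rng.uniform(-jitter, jitter, size=sites.shape) * np.array([gx, gy])
    return np.mod(sites, [lx, ly])


def _species_labels(n: int, fraction_a: float, layout: str, n_clusters: int,
                    sites: np.ndarray, box_xy, rng: np.random.Generator,
                    names=("LIPA", "LIPB")) -> np.ndarray:
    n_a = int(round(fraction_a * n))
    labels = np.array([names[0]] * n, dtype=object)
    n_b = n - n_a
    if n_b == 0:
        return labels.astype(str)
    if layout == "random":
        b_idx = rng.choice(n, size=n_b, replace=False)
    else:
        # seed-and-grow: minority species occupies the sites closest (on the
        # torus) to a few randomly chosen cluster centers
        centers = sites[rng.choice(n, size=min(n_clusters, n), replace=False)]
        d = sites[:, None, :] - centers[None, :, :]
        d -= np.asarray(box_xy) * np.round(d / np.asarray(box_xy))
        dist = np.sqrt((d**2).sum(-1)).min(axis=1)
        b_idx = np.argsort(dist)[:n_b]
    labels[b_idx] = names[1]
    return labels.astype(str)


def make_brownian_tracks(
    n_particles: int,
    n_steps: int,
    dt: float,
    d_true: float,
    box_xy,
    seed=None,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """2D Brownian tracks: returns ``(wrapped, true)`` of shape (n_steps, n, 2).

    ``d_true`` is in 1e-9 cm²/s; per-axis step variance is 2·D·dt.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box_xy, dtype=float)
    d_a2ps = d_true / A2_PER_PS_TO_1E9_CM2_PER_S
    step_sd = np.sqrt(2.0 * d_a2ps * dt)
    if start is None:
        start = rng.uniform(0, 1, size=(n_particles, 2)) * box
    steps = rng.normal(0.0, step_sd, size=(n_steps - 1, n_particles, 2))
    true = np.empty((n_steps, n_particles, 2))
    true[0] = start
    np.cumsum(steps, axis=0, out=true[1:])
    true[1:] += start
    return np.mod(true, box), true


def make_bilayer(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a two-leaflet bilayer trajectory with known ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_leaflet
    lx, ly, lz = spec.box
    n_t = spec.tail_length
    n_int = n_t - 2
    w = np.broadcast_to(np.atleast_1d(
        np.asarray(spec.order_weight, dtype=float)), (n_int,)).copy()

    # per-leaflet lattices, species layouts, and Brownian lateral motion
    sites, labels, signs = [], [], []
    for sgn in (+1.0, -1.0):
        s = _lattice(n, (lx, ly), rng)
        sites.append(s)
        labels.append(_species_labels(n, spec.species_fraction, spec.layout,
                                      spec.n_clusters, s, (lx, ly), rng))
        signs.append(np.full(n, sgn))
    start = np.concatenate(sites)
    species = np.concatenate(labels)
    sign = np.concatenate(signs)               # +1 upper, -1 lower
    leaflets = np.where(sign > 0, "upper", "lower")
    n_lip = 2 * n
    F = spec.n_frames

    wrapped, true = make_brownian_tracks(
        n_lip, F, spec.dt, spec.d_true, (lx, ly),
        seed=rng.integers(2**63), start=start)

    head_z = rng.normal(sign * spec.h / 2.0, spec.sigma_z, size=(F, n_lip))

    # tails via skip vectors (see module docstring); shape (F, n_lip, 2, n_t, 3)
    aligned = rng.random((F, n_lip, 2, n_int)) < w
    iso = rng.normal(size=(F, n_lip, 2, n_int, 3))
    iso /= np.linalg.norm(iso, axis=-1, keepdims=True)
    aligned_dir = np.zeros((n_lip, 3))
    aligned_dir[:, 2] = -sign
    u = np.where(aligned[..., None], aligned_dir[None, :, None, None, :], iso)
    rel = np.empty((F, n_lip, 2, n_t, 3))
    rel[..., 0, :] = np.array([0.3, 0.3, 0.0])
    rel[..., 0, 2] = -sign[None, :, None] * 1.0
    rel[..., 1, :] = rel[..., 0, :]
    rel[..., 1, 2] -= sign[None, :, None] * 1.25
    for j in range(2, n_t):
        rel[..., j, :] = rel[..., j - 2, :] + _SEGMENT_LENGTH * u[..., j - 2, :]

    # rigid per-tail z-shift pins the terminal methyl to its target
    # distribution without touching any skip vector (S_C is preserved)
    tmg_mu = -sign * (spec.h / 2.0 - spec.tmg_offset)      # (n_lip,)
    tmg_z = rng.normal(tmg_mu[None, :, None], spec.tmg_sd,
                       size=(F, n_lip, 2))
    current = head_z[..., None] + rel[..., -1, 2]
    rel[..., 2] += (tmg_z - current)[..., None]

    # assemble atom coordinates: per lipid [P, sn1 x n_t, sn2 x n_t]
    apl_atoms = 1 + 2 * n_t
    head_pos = np.concatenate([wrapped, head_z[..., None]], axis=-1)
    tails_abs = rel.copy()            # rel is relative to the head position
    tails_abs += head_pos[:, :, None, None, :]
    coords = np.empty((F, n_lip * apl_atoms, 3))
    cv = coords.reshape(F, n_lip, apl_atoms, 3)
    cv[:, :, 0] = head_pos
    cv[:, :, 1:1 + n_t] = tails_abs[:, :, 0]
    cv[:, :, 1 + n_t:] = tails_abs[:, :, 1]

    # topology
    lipids = []
    for li in range(n_lip):
        base = li * apl_atoms
        atoms = [AtomRecord(index=base, name="P", role="HEAD_P")]
        for t, role in enumerate(("TAIL_SN1", "TAIL_SN2")):
            for j in range(n_t):
                atoms.append(AtomRecord(
                    index=base + 1 + t * n_t + j,
                    name=f"T{t + 1}{j + 1}",
                    role=role, tail_pos=j + 1,
                    is_tmg=(j == n_t - 1),
                    is_first_tail_bead=(t == 0 and j == 0),
                ))
        lipids.append(LipidRecord(lipid_id=li + 1, species=str(species[li]),
                                  atoms=atoms))
    top = Topology(lipids=lipids, n_atoms=n_lip * apl_atoms)

    box = np.array([lx, ly, lz])
    frames = [Frame(coords=coords[f], box=box.copy(), time=f * spec.dt)
              for f in range(F)]
    traj = Trajectory(topology=top, frames=frames)

    gt = GroundTruth(
        spec=spec, leaflets=leaflets, species=species, true_tracks=true,
        s_c=w, thickness=spec.h, sigma_z=spec.sigma_z, d_true=spec.d_true,
        tmg_mean={"upper": float(-(spec.h / 2 - spec.tmg_offset)),
                  "lower": float(+(spec.h / 2 - spec.tmg_offset))},
        tmg_sd=spec.tmg_sd,
    )
    return traj, gt


def make_tension_series(
    k_a_true: float,
    a0: float,
    tensions=(-7.0, 0.0, 7.0, 15.0),
    n_samples: int = 3500,
    ar1_tau: float = 20.0,
    noise_sd: float = 0.5,
    seed=None,
) -> tuple[dict[float, np.ndarray], list[TensionPoint]]:
    """AR(1) area-per-lipid streams around A0·(1 + gamma/K_A) per tension.

    Returns ``(streams, points)`` where ``streams[gamma]`` is the APL sample
    stream and ``points`` are the summarized :class:`TensionPoint` inputs for
    the K_A fit.  ``ar1_tau`` is in frames; stationary SD is ``noise_sd``.
    """
    if k_a_true <= 0:
        raise ValueError("K_A_true must be positive")
    if a0 <= 0:
        raise ValueError("A0 must be positive")
    tensions = list(tensions)
    if not any(np.isclose(g, 0.0) for g in tensions):
        raise ValueError("the tension list must include gamma = 0")
    rng = np.random.default_rng(seed)
    phi = np.exp(-1.0 / ar1_tau) if ar1_tau > 0 else 0.0
    streams: dict[float, np.ndarray] = {}
    points: list[TensionPoint] = []
    for g in tensions:
        mu = a0 * (1.0 + g / k_a_true)
        if noise_sd == 0.0:
            x = np.full(n_samples, mu)
        else:
            innov = rng.normal(0.0, noise_sd * np.sqrt(1.0 - phi**2),
                               size=n_samples)
            innov[0] = rng.normal(0.0, noise_sd)   # stationary start
            x = lfilter([1.0], [1.0, -phi], innov) + mu
        streams[g] = x
        if np.ptp(x) == 0.0:
            se, n_eff = 0.0, float(n_samples)
        else:
            se, n_eff = stationary_se(x)
        points.append(TensionPoint(gamma=float(g), apl_mean=float(x.mean()),
                                   apl_se=se, n_eff=n_eff))
    return streams, points


def make_pressure_stream(
    gamma_true: float,
    lz: float = 100.0,
    n: int = 1000,
    noise_sd_bar: float = 50.0,
    seed=None,
) -> list[PressureRecord]:
    """Pressure records whose per-record tension has mean ``gamma_true``.

    P_zz is fixed at 1 bar; the lateral components fluctuate around the value
    implied by the target tension.
    """
    if lz <= 0:
        raise ValueError("Lz must be positive")
    rng = np.random.default_rng(seed)
    p_zz = 1.0
    lateral_mean = p_zz - gamma_true / (BAR_ANGSTROM_TO_MN_PER_M * lz)
    noise = rng.normal(0.0, noise_sd_bar, size=(n, 2)) if noise_sd_bar else \
        np.zeros((n, 2))
    return [
        PressureRecord(p_xx=lateral_mean + noise[i, 0],
                       p_yy=lateral_mean + noise[i, 1],
                       p_zz=p_zz, l_z=lz, time=float(i))
        for i in range(n)
    ]
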