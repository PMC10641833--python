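"""Lateral organization: periodic Voronoi areas, mixed-contact fraction, and
neighbor-composition tables.

Voronoi tessellation of the headgroup x–y positions uses 3×3 periodic image
tiling, exact whenever each cell's diameter is below the box length.  A pair
of lipids is a contact when the minimum-image distance between their
reference beads is within the cutoff (same leaflet); f_mix is the fraction
of unlike-species contacts over all contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .core_io import Frame, LeafletAssignment, Topology, Trajectory
from .geometry import _robust_se

__all__ = [
    "VoronoiMap",
    "ContactStats",
    "NeighborComposition",
    "voronoi_areas",
    "mixed_contacts",
    "neighbor_composition",
    "voronoi_area_distribution",
    "percentage_shares",
]


@dataclass
class VoronoiMap:
    areas: np.ndarray           # Å² per lipid in the leaflet
    lipid_ids: np.ndarray
    species: np.ndarray
    seeds: np.ndarray           # (n, 2) wrapped seed positions
    leaflet: str
    frame_index: int
    box_area: float             # Å², Lx·Ly


@dataclass
class ContactStats:
    c_aa: float                 # mean per-frame same-species contacts (species A)
    c_ab: float                 # mean mixed contacts
    c_bb: float
    f_mix: float
    f_mix_se: float
    cutoff: float
    n_frames: int
    per_frame_f_mix: np.ndarray = field(repr=False, default=None)
    species: tuple[str, ...] = ()


@dataclass
class NeighborComposition:
    center_species: list[str]
    neighbor_species: list[str]
    mean_counts: np.ndarray     # (n_center, n_neighbor)
    se: np.ndarray
    percentages: np.ndarray     # rows sum to 100
    cutoff: float
    n_frames: int


def percentage_shares(counts) -> np.ndarray:
    """Percentage shares of a vector of mean neighbor counts (sums to 100)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total neighbor count must be positive")
    return 100.0 * counts / total


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_areas(
    frame: Frame,
    topology: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    frame_index: int = 0,
) -> VoronoiMap:
    """Per-lipid Voronoi cell areas from a periodic 2D tessellation of the
    HEAD_P x–y positions of one leaflet."""
    mask = assignment.mask(leaflet)
    head_ix = topology.head_p_indices()[mask]
    if head_ix.size < 3:
        raise ValueError("Voronoi tessellation needs at least 3 seeds")
    box = frame.box[:2]
    seeds = np.mod(frame.coords[head_ix, :2], box)

    tree = cKDTree(seeds, boxsize=box)
    close = tree.query_pairs(1e-6)
    if close:
        ids = topology.species_labels()  # for error context
        lipid_ids = np.array([lip.lipid_id for lip in topology.lipids])[mask]
        pairs = sorted((int(lipid_ids[i]), int(lipid_ids[j])) for i, j in close)
        raise ValueError(f"coincident Voronoi seeds for lipid pairs {pairs[:5]}")

    # 3x3 image tiling; central copy first so cell -> seed mapping is direct
    shifts = np.array([(i, j) for i in (0, -1, 1) for j in (0, -1, 1)
                       if not (i == 0 and j == 0)])
    tiled = np.concatenate(
        [seeds] + [seeds + s * box for s in shifts], axis=0)
    vor = Voronoi(tiled)
    n = seeds.shape[0]
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError(
                f"unbounded Voronoi cell for seed {i}: cell diameter exceeds "
                f"the box; 3x3 tiling insufficient"
            )
        areas[i] = _shoelace(vor.vertices[region])

    box_area = float(box[0] * box[1])
    lipid_ids = np.array([lip.lipid_id for lip in topology.lipids])[mask]
    species = topology.species_labels()[mask]
    return VoronoiMap(areas=areas, lipid_ids=lipid_ids, species=species,
                      seeds=seeds, leaflet=leaflet, frame_index=frame_index,
                      box_area=box_area)


def _min_image_sq_dists(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(n, n) squared minimum-image distances (3D orthorhombic)."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    return np.einsum("ijk,ijk->ij", d, d)


def mixed_contacts(
    traj: Trajectory,
    assignment: LeafletAssignment,
    cutoff: float = 11.0,
    bead_role: str = "HEAD_P",
    same_leaflet_only: bool = True,
    denominator: str = "all",
) -> ContactStats:
    """Contact counts and mixed-contact fraction averaged over frames.

    ``denominator="all"`` (default) divides mixed contacts by all contacts
    (like + unlike); ``"like_a"`` divides by contacts involving the majority
    species only — an alternative normalization kept for comparison.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    species = top.species_labels()
    uniq = sorted(set(species))
    if len(uniq) > 2:
        raise ValueError("mixed_contacts supports at most 2 species")
    if bead_role == "HEAD_P":
        bead_ix = top.head_p_indices()
    elif bead_role == "FIRST_TAIL_BEAD":
        bead_ix = top.first_tail_bead_indices()
    else:
        raise ValueError(f"unsupported bead_role {bead_role!r}")

    sp_a = uniq[0]
    is_a = species == sp_a
    cut2 = cutoff * cutoff
    caa = np.zeros(traj.n_frames)
    cab = np.zeros(traj.n_frames)
    cbb = np.zeros(traj.n_frames)
    leaflets = (("upper", "lower") if same_leaflet_only else (None,))
    for fi, fr in enumerate(traj.frames):
        for side in leaflets:
            lm = assignment.mask(side) if side else np.ones(len(species), bool)
            pos = fr.coords[bead_ix[lm]]
            a_mask = is_a[lm]
            sq = _min_image_sq_dists(pos, fr.box)
            iu, ju = np.triu_indices(pos.shape[0], k=1)
            contact = sq[iu, ju] <= cut2
            both_a = a_mask[iu] & a_mask[ju]
            both_b = ~a_mask[iu] & ~a_mask[ju]
            caa[fi] += np.sum(contact & both_a)
            cbb[fi] += np.sum(contact & both_b)
            cab[fi] += np.sum(contact & ~both_a & ~both_b)

    total = caa + cab + cbb
    if denominator == "all":
        denom = total
    elif denominator == "like_a":
        denom = caa + cab
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        fmix = np.where(denom > 0, cab / denom, 0.0)
    se, _ = _robust_se(fmix)
    return ContactStats(
        c_aa=float(caa.mean()), c_ab=float(cab.mean()), c_bb=float(cbb.mean()),
        f_mix=float(fmix.mean()), f_mix_se=se, cutoff=cutoff,
        n_frames=traj.n_frames, per_frame_f_mix=fmix, species=tuple(uniq),
    )


def neighbor_composition(
    traj: Trajectory,
    assignment: LeafletAssignment,
    cutoff: float = 15.0,
    bead_role: str = "FIRST_TAIL_BEAD",
) -> NeighborComposition:
    """Mean neighbor counts of each species around each center species.

    Two lipids are neighbors when their reference beads (same leaflet) are
    within the cutoff by minimum image; percentages are shares of the mean
    counts per center species.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    species = top.species_labels()
    uniq = sorted(set(species))
    if bead_role == "HEAD_P":
        bead_ix = top.head_p_indices()
    elif bead_role == "FIRST_TAIL_BEAD":
        bead_ix = top.first_tail_bead_indices()
    else:
        raise ValueError(f"unsupported bead_role {bead_role!r}")

    cut2 = cutoff * cutoff
    nF = traj.n_frames
    # per-frame mean count matrix (center species x neighbor species)
    per_frame = np.zeros((nF, len(uniq), len(uniq)))
    for fi, fr in enumerate(traj.frames):
        counts = np.zeros((len(species), len(uniq)))
        for side in ("upper", "lower"):
            lm = assignment.mask(side)
            pos = fr.coords[bead_ix[lm]]
            sq = _min_image_sq_dists(pos, fr.box)
            np.fill_diagonal(sq, np.inf)
            nb = sq <= cut2
            local_sp = species[lm]
            for sj, sp in enumerate(uniq):
                counts[lm, sj] = nb[:, local_sp == sp].sum(axis=1)
        for si, sp in enumerate(uniq):
            per_frame[fi, si] = counts[species == sp].mean(axis=0)

    mean_counts = per_frame.mean(axis=0)
    se = np.zeros_like(mean_counts)
    for si in range(len(uniq)):
        for sj in range(len(uniq)):
            se[si, sj], _ = _robust_se(per_frame[:, si, sj])
    pct = np.vstack([percentage_shares(row) for row in mean_counts])
    return NeighborComposition(
        center_species=list(uniq), neighbor_species=list(uniq),
        mean_counts=mean_counts, se=se, percentages=pct,
        cutoff=cutoff, n_frames=nF,
    )


def voronoi_area_distribution(
    maps,
    n_bins: int = 30,
) -> dict[str, dict]:
    """Per-species Voronoi-area histograms and quartiles pooled over maps.

    Returns ``{species: {"areas", "hist", "bin_edges", "quartiles", "median"}}``
    with quartiles = (Q1, Q2, Q3).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one VoronoiMap")
    pooled: dict[str, list[np.ndarray]] = {}
    for m in maps:
        for sp in np.unique(m.species):
            pooled.setdefault(str(sp), []).append(m.areas[m.species == sp])
    out: dict[str, dict] = {}
    for sp, chunks in pooled.items():
        areas = np.concatenate(chunks)
        q1, q2, q3 = np.percentile(areas, [25, 50, 75])
        hist, edges = np.histogram(areas, bins=n_bins)
        out[sp] = {"areas": areas, "hist": hist, "bin_edges": edges,
                   "quartiles": (float(q1), float(q2), float(q3)),
                   "median": float(q2)}
    return out
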