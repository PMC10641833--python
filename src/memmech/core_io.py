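"""Domain types and I/O for bilayer topologies and trajectories.

Atomistic/CG structures are read through MDAnalysis (GRO/PDB topologies,
XTC/DCD coordinates); a self-contained plain-text *fixture* format is
provided for portable, diffable test data.  Internally coordinates are Å,
times ps, and ``z`` is the bilayer normal (see :mod:`memmech.units`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "LipidRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "LeafletAssignment",
    "RoleMap",
    "DEFAULT_ROLE_MAPS",
    "TopologyError",
    "TrajectoryError",
    "load_topology",
    "load_trajectory",
    "assign_leaflets",
    "write_fixture",
]

ROLE_HEAD_P = "HEAD_P"
ROLE_TAIL_SN1 = "TAIL_SN1"
ROLE_TAIL_SN2 = "TAIL_SN2"

#: Residue names silently skipped when reading GRO/PDB files.
SOLVENT_RESNAMES = frozenset(
    {"SOL", "TIP3", "TIP3P", "WAT", "HOH", "W", "WF", "NA", "CL", "NA+", "CL-",
     "SOD", "CLA", "POT", "K", "ION"}
)


class TopologyError(ValueError):
    """Raised when a topology cannot be built or violates its invariants."""


class TrajectoryError(ValueError):
    """Raised when a trajectory cannot be read or is inconsistent."""


@dataclass
class AtomRecord:
    """One atom (or CG bead) with its structural role tags."""

    index: int                      # 0-based global atom index
    name: str
    role: str | None = None         # HEAD_P / TAIL_SN1 / TAIL_SN2 / None
    tail_pos: int | None = None     # 1-based position along its tail
    is_tmg: bool = False            # terminal methyl of its tail
    is_first_tail_bead: bool = False


@dataclass
class LipidRecord:
    lipid_id: int
    species: str
    atoms: list[AtomRecord]

    @property
    def head_p(self) -> AtomRecord:
        heads = [a for a in self.atoms if a.role == ROLE_HEAD_P]
        if len(heads) != 1:
            raise TopologyError(
                f"lipid {self.lipid_id} ({self.species}) has {len(heads)} "
                f"HEAD_P atoms; exactly one is required"
            )
        return heads[0]

    def tail(self, which: str) -> list[AtomRecord]:
        role = ROLE_TAIL_SN1 if which.lower() == "sn1" else ROLE_TAIL_SN2
        members = sorted(
            (a for a in self.atoms if a.role == role),
            key=lambda a: a.tail_pos,
        )
        return members


@dataclass
class Topology:
    """Ordered lipid records plus fast index lookups for analyses."""

    lipids: list[LipidRecord]
    n_atoms: int
    source: str | None = None       # file the topology was parsed from
    dialect: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [lip.lipid_id for lip in self.lipids]
        if len(set(ids)) != len(ids):
            raise TopologyError("lipid_ids are not unique")
        for lip in self.lipids:
            lip.head_p  # raises if not exactly one
            for which in ("sn1", "sn2"):
                tail = lip.tail(which)
                if not tail:
                    continue
                if len(tail) < 3:
                    raise TopologyError(
                        f"lipid {lip.lipid_id} ({lip.species}): tail {which} has "
                        f"{len(tail)} members; at least 3 are required"
                    )
                if not tail[-1].is_tmg:
                    raise TopologyError(
                        f"lipid {lip.lipid_id} ({lip.species}): last {which} "
                        f"member is not tagged TMG"
                    )

    # ---- index helpers -------------------------------------------------

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    def species_labels(self) -> np.ndarray:
        return np.array([lip.species for lip in self.lipids])

    def species_present(self) -> list[str]:
        seen: dict[str, None] = {}
        for lip in self.lipids:
            seen.setdefault(lip.species, None)
        return list(seen)

    def lipid_mask(self, species: str | None) -> np.ndarray:
        if species is None:
            return np.ones(self.n_lipids, dtype=bool)
        return self.species_labels() == species

    def head_p_indices(self, species: str | None = None) -> np.ndarray:
        """Global atom index of HEAD_P for each (selected) lipid, in lipid order."""
        return np.array(
            [lip.head_p.index for lip in self.lipids
             if species is None or lip.species == species],
            dtype=np.intp,
        )

    def tail_indices(self, species: str, which: str) -> np.ndarray:
        """(n_lipids_of_species, tail_length) array of global atom indices."""
        rows = []
        for lip in self.lipids:
            if lip.species != species:
                continue
            tail = lip.tail(which)
            if not tail:
                raise TopologyError(f"species {species!r} has no {which} tail atoms")
            rows.append([a.index for a in tail])
        if not rows:
            raise TopologyError(f"no lipids of species {species!r}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise TopologyError(
                f"inconsistent {which} tail lengths for species {species!r}: {lengths}"
            )
        return np.array(rows, dtype=np.intp)

    def tmg_indices(self, species: str | None = None) -> np.ndarray:
        out = [a.index
               for lip in self.lipids
               if species is None or lip.species == species
               for a in lip.atoms if a.is_tmg]
        if not out:
            raise TopologyError(f"no TMG atoms for species {species!r}")
        return np.array(out, dtype=np.intp)

    def first_tail_bead_indices(self, species: str | None = None) -> np.ndarray:
        out = []
        for lip in self.lipids:
            if species is not None and lip.species != species:
                continue
            beads = [a for a in lip.atoms if a.is_first_tail_bead]
            if not beads:
                raise TopologyError(
                    f"lipid {lip.lipid_id} ({lip.species}) has no FIRST_TAIL_BEAD"
                )
            out.append(beads[0].index)
        return np.array(out, dtype=np.intp)


@dataclass
class Frame:
    """Coordinates (Å) for one time point with an orthorhombic box."""

    coords: np.ndarray              # (n_atoms, 3) float
    box: np.ndarray                 # (Lx, Ly, Lz) Å
    time: float = 0.0               # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryError("coords must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TrajectoryError("box must be 3 positive lengths (orthorhombic)")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory must contain at least one frame")
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != self.topology.n_atoms:
                raise TrajectoryError(
                    f"frame {i}: {fr.coords.shape[0]} atoms but topology has "
                    f"{self.topology.n_atoms}"
                )
        times = self.times
        if np.any(np.diff(times) < 0):
            raise TrajectoryError("frame times must be monotonic non-decreasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def dt(self) -> float:
        """Median frame spacing in ps (0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def coordinate_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([fr.coords for fr in self.frames])

    def box_array(self) -> np.ndarray:
        return np.stack([fr.box for fr in self.frames])


@dataclass
class LeafletAssignment:
    labels: np.ndarray              # per-lipid, "upper" or "lower"
    z_center: float                 # Å, bilayer midplane

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        for side in ("upper", "lower"):
            if not np.any(self.labels == side):
                raise TopologyError(f"degenerate leaflet assignment: no {side} leaflet")

    def mask(self, leaflet: str) -> np.ndarray:
        if leaflet not in ("upper", "lower"):
            raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
        return self.labels == leaflet


# ----------------------------------------------------------------------
# Role mapping: species → atom-name patterns
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RoleMap:
    """Atom-name patterns assigning structural roles within one species.

    ``sn1``/``sn2`` regexes must capture the 1-based tail position as the
    first group; the largest position found is tagged TMG.
    """

    head: str
    sn1: str
    sn2: str
    first_tail_bead: str | None = None   # exact atom name (e.g. Martini GL1)

    def tag(self, names: Sequence[str]) -> list[AtomRecord] | None:
        """Tag atoms of one lipid; indices are local (0..n-1). None if no head."""
        head_re = re.compile(self.head)
        sn1_re = re.compile(self.sn1)
        sn2_re = re.compile(self.sn2)
        atoms = [AtomRecord(index=i, name=nm) for i, nm in enumerate(names)]
        n_head = 0
        per_tail: dict[str, list[AtomRecord]] = {ROLE_TAIL_SN1: [], ROLE_TAIL_SN2: []}
        for atom in atoms:
            if head_re.fullmatch(atom.name):
                atom.role = ROLE_HEAD_P
                n_head += 1
                continue
            for role, rx in ((ROLE_TAIL_SN1, sn1_re), (ROLE_TAIL_SN2, sn2_re)):
                m = rx.fullmatch(atom.name)
                if m:
                    atom.role = role
                    atom.tail_pos = int(m.group(1))
                    per_tail[role].append(atom)
                    break
            if self.first_tail_bead and atom.name == self.first_tail_bead:
                atom.is_first_tail_bead = True
        if n_head != 1:
            return None
        for members in per_tail.values():
            if members:
                members.sort(key=lambda a: a.tail_pos)
                # re-index 1..n so gaps in naming (double-bond beads) close up
                for pos, a in enumerate(members, start=1):
                    a.tail_pos = pos
                members[-1].is_tmg = True
        if self.first_tail_bead is None and per_tail[ROLE_TAIL_SN1]:
            per_tail[ROLE_TAIL_SN1][0].is_first_tail_bead = True
        return atoms


# CHARMM-style atomistic PC lipids: phosphorus "P", sn-1 carbons C3x,
# sn-2 carbons C2x.  Martini CG lipids: PO4 head bead, GL1 first tail
# bead, A/B-chain beads C1A..C4A / C1B..C4B (D for unsaturated).
_AA_MAP = RoleMap(head=r"P", sn1=r"C3(\d+)", sn2=r"C2(\d+)")
_CG_MAP = RoleMap(head=r"PO4", sn1=r"[CD](\d+)A", sn2=r"[CD](\d+)B",
                  first_tail_bead="GL1")

DEFAULT_ROLE_MAPS: dict[str, tuple[RoleMap, ...]] = {
    # six atomistic species; DOPC/DLPC also exist as Martini models, so both
    # candidate maps are tried in order
    "DOPC": (_AA_MAP, _CG_MAP),
    "DPMPC": (_AA_MAP,),
    "DHPC": (_AA_MAP,),
    "DDPC": (_AA_MAP,),
    "DLPC": (_AA_MAP, _CG_MAP),
    "DMPC": (_AA_MAP,),
    # Martini-only species
    "DPPC": (_CG_MAP, _AA_MAP),
    "DTPC": (_CG_MAP,),
}


# ----------------------------------------------------------------------
# Fixture format
# ----------------------------------------------------------------------
#
# Plain text, self contained:
#
#   #MEMMECH_FIXTURE 1
#   { ... JSON header: units, n_atoms, n_frames, lipid/atom records ... }
#   #END_HEADER
#   #FRAME <time_ps> <Lx> <Ly> <Lz>
#   x y z                (n_atoms lines, Å)
#   ...

_FIXTURE_MAGIC = "#MEMMECH_FIXTURE 1"


def _topology_to_header(top: Topology, n_frames: int) -> dict:
    return {
        "version": 1,
        "units": {"length": "A", "time": "ps"},
        "n_atoms": top.n_atoms,
        "n_frames": n_frames,
        "lipids": [
            {
                "lipid_id": lip.lipid_id,
                "species": lip.species,
                "atoms": [
                    {
                        "index": a.index,
                        "name": a.name,
                        "role": a.role,
                        "tail_pos": a.tail_pos,
                        "is_tmg": a.is_tmg,
                        "is_first_tail_bead": a.is_first_tail_bead,
                    }
                    for a in lip.atoms
                ],
            }
            for lip in top.lipids
        ],
    }


def _topology_from_header(header: dict, source: str | None) -> Topology:
    lipids = []
    for lrec in header["lipids"]:
        atoms = [
            AtomRecord(
                index=a["index"],
                name=a["name"],
                role=a.get("role"),
                tail_pos=a.get("tail_pos"),
                is_tmg=a.get("is_tmg", False),
                is_first_tail_bead=a.get("is_first_tail_bead", False),
            )
            for a in lrec["atoms"]
        ]
        lipids.append(LipidRecord(lipid_id=lrec["lipid_id"],
                                  species=lrec["species"], atoms=atoms))
    return Topology(lipids=lipids, n_atoms=header["n_atoms"],
                    source=source, dialect="fixture")


def write_fixture(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory (topology + frames) as a portable text fixture."""
    path = Path(path)
    header = _topology_to_header(traj.topology, traj.n_frames)
    with path.open("w") as fh:
        fh.write(_FIXTURE_MAGIC + "\n")
        json.dump(header, fh)
        fh.write("\n#END_HEADER\n")
        for fr in traj.frames:
            fh.write(f"#FRAME {fr.time:.6f} "
                     f"{fr.box[0]:.10g} {fr.box[1]:.10g} {fr.box[2]:.10g}\n")
            np.savetxt(fh, fr.coords, fmt="%.8f")


def _read_fixture_header(path: Path) -> tuple[dict, int]:
    """Return (header dict, file offset of the first frame line)."""
    with path.open() as fh:
        magic = fh.readline().strip()
        if magic != _FIXTURE_MAGIC:
            raise TrajectoryError(f"{path}: not a memmech fixture file")
        header_lines = []
        while True:
            line = fh.readline()
            if not line:
                raise TrajectoryError(f"{path}: missing #END_HEADER")
            if line.strip() == "#END_HEADER":
                break
            header_lines.append(line)
        offset = fh.tell()
    return json.loads("".join(header_lines)), offset


def _read_fixture_frames(path: Path, offset: int, n_atoms: int,
                         n_frames: int) -> list[Frame]:
    frames: list[Frame] = []
    with path.open() as fh:
        fh.seek(offset)
        for _ in range(n_frames):
            head = fh.readline()
            if not head.startswith("#FRAME"):
                raise TrajectoryError(
                    f"{path}: truncated fixture — expected {n_frames} frames, "
                    f"found {len(frames)}"
                )
            parts = head.split()
            time, box = float(parts[1]), np.array([float(p) for p in parts[2:5]])
            rows = []
            for _ in range(n_atoms):
                line = fh.readline()
                if not line or line.startswith("#"):
                    raise TrajectoryError(
                        f"{path}: truncated frame {len(frames)} "
                        f"(expected {n_atoms} coordinate lines)"
                    )
                rows.append([float(v) for v in line.split()])
            frames.append(Frame(coords=np.array(rows), box=box, time=time))
    return frames


# ----------------------------------------------------------------------
# Loaders
# ----------------------------------------------------------------------

def load_topology(
    path: str | Path,
    dialect: str = "fixture",
    role_maps: dict[str, tuple[RoleMap, ...]] | None = None,
    solvent_resnames: Iterable[str] = SOLVENT_RESNAMES,
) -> Topology:
    """Read a topology from a GRO/PDB file or a memmech fixture.

    For GRO/PDB, residues are mapped to lipids via ``role_maps`` (species →
    candidate :class:`RoleMap` tuples; defaults cover common atomistic and
    Martini PC lipids).  Residues in ``solvent_resnames`` are skipped; any
    other unmapped residue name is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect.lower()
    if dialect == "fixture":
        header, _ = _read_fixture_header(path)
        return _topology_from_header(header, source=str(path))
    if dialect not in ("gro", "pdb"):
        raise ValueError(f"unknown topology dialect {dialect!r}")

    import MDAnalysis as mda

    maps = dict(DEFAULT_ROLE_MAPS)
    if role_maps:
        maps.update(role_maps)
    solvent = {s.upper() for s in solvent_resnames}

    uni = mda.Universe(str(path))
    lipids: list[LipidRecord] = []
    for res in uni.residues:
        resname = str(res.resname).strip().upper()
        if resname in solvent:
            continue
        if resname not in maps:
            raise TopologyError(
                f"unknown species {resname!r} (residue {res.resid}): "
                f"no role mapping supplied"
            )
        names = [str(n) for n in res.atoms.names]
        tagged = None
        for candidate in maps[resname]:
            tagged = candidate.tag(names)
            if tagged is not None:
                break
        if tagged is None:
            raise TopologyError(
                f"lipid {res.resid} ({resname}) has no HEAD_P atom under any "
                f"role mapping for this species"
            )
        global_ix = res.atoms.ix  # 0-based universe indices
        for a, gix in zip(tagged, global_ix):
            a.index = int(gix)
        lipids.append(LipidRecord(lipid_id=int(res.resid), species=resname,
                                  atoms=tagged))
    if not lipids:
        raise TopologyError(f"{path}: no lipids found")
    return Topology(lipids=lipids, n_atoms=len(uni.atoms),
                    source=str(path), dialect=dialect)


def load_trajectory(
    topology: Topology,
    path: str | Path,
    dialect: str = "fixture",
) -> Trajectory:
    """Read coordinates for ``topology`` from XTC/DCD or a memmech fixture.

    Coordinates are returned in Å regardless of the source's native unit
    (MDAnalysis converts nm-based formats; the fixture stores Å directly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect.lower()
    if dialect == "fixture":
        header, offset = _read_fixture_header(path)
        if header["n_atoms"] != topology.n_atoms:
            raise TrajectoryError(
                f"atom-count mismatch: fixture has {header['n_atoms']}, "
                f"topology has {topology.n_atoms}"
            )
        frames = _read_fixture_frames(path, offset, header["n_atoms"],
                                      header["n_frames"])
        return Trajectory(topology=topology, frames=frames)
    if dialect not in ("xtc", "dcd"):
        raise ValueError(f"unknown trajectory dialect {dialect!r}")

    import MDAnalysis as mda

    if topology.source is None or topology.dialect == "fixture":
        raise TrajectoryError(
            "XTC/DCD reading requires a topology loaded from a GRO/PDB file"
        )
    uni = mda.Universe(topology.source, str(path))
    if len(uni.atoms) != topology.n_atoms:
        raise TrajectoryError(
            f"atom-count mismatch: trajectory has {len(uni.atoms)}, "
            f"topology has {topology.n_atoms}"
        )
    frames = []
    for ts in uni.trajectory:
        frames.append(Frame(coords=np.array(ts.positions, dtype=float),
                            box=np.array(ts.dimensions[:3], dtype=float),
                            time=float(ts.time)))
    return Trajectory(topology=topology, frames=frames)


def assign_leaflets(frame: Frame, topology: Topology) -> LeafletAssignment:
    """Assign each lipid to the upper or lower leaflet from HEAD_P z positions.

    The midplane is the unweighted mean z over all HEAD_P atoms; a lipid is
    "upper" iff its HEAD_P lies above the midplane.  A configuration with all
    heads on one side (a monolayer) is rejected.
    """
    if topology.n_lipids < 2:
        raise TopologyError("leaflet assignment needs at least 2 lipids")
    z = frame.coords[topology.head_p_indices(), 2]
    z_center = float(np.mean(z))
    labels = np.where(z > z_center, "upper", "lower")
    if np.all(labels == "upper") or np.all(labels == "lower"):
        raise TopologyError(
            "degenerate configuration: all HEAD_P atoms on one side of the midplane"
        )
    return LeafletAssignment(labels=labels, z_center=z_center)
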