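import numpy as np
import pytest

from memmech.core_io import AtomRecord, Frame, LipidRecord, Topology, Trajectory


def build_topology(n_lipids: int, tail_len: int = 3,
                   species=None) -> Topology:
    """Minimal topology: per lipid [P, sn1 x tail_len, sn2 x tail_len]."""
    if species is None:
        species = ["LIPA"] * n_lipids
    per_lipid = 1 + 2 * tail_len
    lipids = []
    for li in range(n_lipids):
        base = li * per_lipid
        atoms = [AtomRecord(index=base, name="P", role="HEAD_P")]
        for t, role in enumerate(("TAIL_SN1", "TAIL_SN2")):
            for j in range(tail_len):
                atoms.append(AtomRecord(
                    index=base + 1 + t * tail_len + j, name=f"T{t+1}{j+1}",
                    role=role, tail_pos=j + 1, is_tmg=(j == tail_len - 1),
                    is_first_tail_bead=(t == 0 and j == 0)))
        lipids.append(LipidRecord(lipid_id=li + 1, species=species[li],
                                  atoms=atoms))
    return Topology(lipids=lipids, n_atoms=n_lipids * per_lipid)


def planar_frame(top: Topology, head_z, box=(80.0, 80.0, 70.0),
                 head_xy=None, time=0.0) -> Frame:
    """Frame with heads at given z (and optional xy); tails stacked below."""
    n = top.n_lipids
    head_z = np.asarray(head_z, dtype=float)
    if head_xy is None:
        rng = np.random.default_rng(0)
        head_xy = rng.uniform(0, 1, size=(n, 2)) * np.asarray(box[:2])
    coords = np.zeros((top.n_atoms, 3))
    for li, lip in enumerate(top.lipids):
        sgn = 1.0 if head_z[li] >= np.median(head_z) else -1.0
        coords[lip.head_p.index] = [*head_xy[li], head_z[li]]
        for which in ("sn1", "sn2"):
            for a in lip.tail(which):
                coords[a.index] = [*head_xy[li],
                                   head_z[li] - sgn * 1.5 * a.tail_pos]
    return Frame(coords=coords, box=np.asarray(box, float), time=time)


def single_frame_traj(top, frame) -> Trajectory:
    return Trajectory(topology=top, frames=[frame])


@pytest.fixture(scope="session")
def default_bilayer():
    """One moderately sized generated bilayer shared across tests."""
    from memmech.synthetic import SyntheticSpec, make_bilayer
    spec = SyntheticSpec(n_per_leaflet=50, n_frames=60, seed=42)
    traj, gt = make_bilayer(spec)
    return spec, traj, gt


@pytest.fixture(scope="session")
def mixed_bilayer():
    """75:25 two-species bilayer for lateral-organization tests."""
    from memmech.synthetic import SyntheticSpec, make_bilayer
    spec = SyntheticSpec(n_per_leaflet=60, n_frames=20,
                         species_fraction=0.75, seed=7)
    traj, gt = make_bilayer(spec)
    return spec, traj, gt
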