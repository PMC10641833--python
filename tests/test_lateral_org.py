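import numpy as np
import pytest
from scipy.spatial import cKDTree

from memmech.core_io import Frame, LeafletAssignment, Trajectory, assign_leaflets
from memmech.lateral_org import (mixed_contacts, neighbor_composition,
                                 percentage_shares, voronoi_area_distribution,
                                 voronoi_areas)
from memmech.synthetic import SyntheticSpec, make_bilayer

from conftest import build_topology, planar_frame, single_frame_traj


def _monolayer_pair(xy, species=None, box=(80.0, 80.0, 70.0), z=(15.0, -15.0)):
    """Two identical leaflets with heads at given xy; returns top, traj, asg."""
    xy = np.asarray(xy, float)
    n = xy.shape[0]
    if species is None:
        species = ["LIPA"] * n
    top = build_topology(2 * n, species=list(species) * 2)
    head_z = np.array([z[0]] * n + [z[1]] * n)
    fr = planar_frame(top, head_z=head_z, box=box,
                      head_xy=np.vstack([xy, xy]))
    asg = assign_leaflets(fr, top)
    return top, single_frame_traj(top, fr), asg


def raster_areas(seeds, box, n_pix=2000):
    """Pixel-rasterization oracle for periodic Voronoi cell areas."""
    lx, ly = box
    gx = (np.arange(n_pix) + 0.5) * lx / n_pix
    gy = (np.arange(n_pix) + 0.5) * ly / n_pix
    px, py = np.meshgrid(gx, gy, indexing="ij")
    pix = np.column_stack([px.ravel(), py.ravel()])
    tree = cKDTree(np.mod(seeds, box), boxsize=box)
    _, owner = tree.query(pix, workers=-1)
    pixel_area = (lx / n_pix) * (ly / n_pix)
    return np.bincount(owner, minlength=seeds.shape[0]) * pixel_area


def brute_force_contacts(pos, box, species, cutoff):
    """O(N²) same-leaflet contact oracle (3D minimum image)."""
    n = pos.shape[0]
    caa = cab = cbb = 0
    uniq = sorted(set(species))
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            if np.sqrt(d @ d) <= cutoff:
                if species[i] == species[j]:
                    if species[i] == uniq[0]:
                        caa += 1
                    else:
                        cbb += 1
                else:
                    cab += 1
    return caa, cab, cbb


class TestVoronoi:
    def test_square_lattice_equal_cells(self):
        g = (np.arange(6) + 0.5) * (60.0 / 6)
        xy = np.array([(x, y) for x in g for y in g])
        top, traj, asg = _monolayer_pair(xy, box=(60.0, 60.0, 70.0))
        vm = voronoi_areas(traj.frames[0], top, asg, "upper")
        np.testing.assert_allclose(vm.areas, 100.0, rtol=1e-9)

    def test_area_conservation_random(self):
        rng = np.random.default_rng(0)
        for seed_count in (10, 50, 120):
            xy = rng.uniform(0, 80, (seed_count, 2))
            top, traj, asg = _monolayer_pair(xy)
            vm = voronoi_areas(traj.frames[0], top, asg, "upper")
            assert abs(vm.areas.sum() - vm.box_area) / vm.box_area <= 1e-6
            assert np.all(vm.areas > 0)

    def test_matches_raster_oracle(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 80, (50, 2))
        top, traj, asg = _monolayer_pair(xy)
        vm = voronoi_areas(traj.frames[0], top, asg, "upper")
        oracle = raster_areas(xy, (80.0, 80.0), n_pix=2000)
        np.testing.assert_allclose(vm.areas, oracle, rtol=5e-3)

    def test_coincident_seeds_error(self):
        xy = np.array([[10.0, 10.0], [10.0, 10.0], [30.0, 30.0],
                       [50.0, 50.0]])
        top, traj, asg = _monolayer_pair(xy)
        with pytest.raises(ValueError, match="coincident"):
            voronoi_areas(traj.frames[0], top, asg, "upper")

    def test_too_few_seeds_error(self):
        xy = np.array([[10.0, 10.0], [40.0, 40.0]])
        top, traj, asg = _monolayer_pair(xy)
        with pytest.raises(ValueError, match="3 seeds"):
            voronoi_areas(traj.frames[0], top, asg, "upper")


class TestMixedContacts:
    def test_single_species_zero(self, default_bilayer):
        _, traj, _ = default_bilayer
        asg = assign_leaflets(traj.frames[0], traj.topology)
        st = mixed_contacts(traj, asg, cutoff=11.0)
        assert st.f_mix == 0.0

    def test_checkerboard_all_mixed(self):
        m, a = 8, 10.0
        xy, sp = [], []
        for i in range(m):
            for j in range(m):
                xy.append(((i + 0.5) * a, (j + 0.5) * a))
                sp.append("LIPA" if (i + j) % 2 == 0 else "LIPB")
        top, traj, asg = _monolayer_pair(np.array(xy), species=sp,
                                         box=(m * a, m * a, 70.0))
        # cutoff covers the 4 nearest neighbors (a) but not diagonals (a*sqrt2)
        st = mixed_contacts(traj, asg, cutoff=1.2 * a)
        assert st.f_mix == pytest.approx(1.0)
        assert st.c_aa == 0 and st.c_bb == 0

    def test_random_75_25_binomial_expectation(self):
        rng = np.random.default_rng(2)
        m, a = 20, 10.0
        fmixes = []
        for seed in range(10):
            sp = np.where(np.random.default_rng(seed).random(m * m) < 0.75,
                          "LIPA", "LIPB")
            xy = np.array([((i + 0.5) * a, (j + 0.5) * a)
                           for i in range(m) for j in range(m)])
            top, traj, asg = _monolayer_pair(xy, species=list(sp),
                                             box=(m * a, m * a, 70.0))
            st = mixed_contacts(traj, asg, cutoff=1.2 * a)
            fmixes.append(st.f_mix)
        se = np.std(fmixes, ddof=1) / np.sqrt(len(fmixes))
        assert np.mean(fmixes) == pytest.approx(2 * 0.75 * 0.25,
                                                abs=3 * se + 1e-3)

    def test_matches_brute_force(self, mixed_bilayer):
        _, traj, gt = mixed_bilayer
        asg = assign_leaflets(traj.frames[0], traj.topology)
        short = Trajectory(topology=traj.topology, frames=traj.frames[:3])
        st = mixed_contacts(short, asg, cutoff=25.0)
        head_ix = traj.topology.head_p_indices()
        species = traj.topology.species_labels()
        totals = np.zeros(3)
        for fr in short.frames:
            for side in ("upper", "lower"):
                lm = asg.mask(side)
                c = brute_force_contacts(fr.coords[head_ix[lm]], fr.box,
                                         species[lm], 25.0)
                totals += c
        totals /= short.n_frames
        assert (st.c_aa, st.c_ab, st.c_bb) == pytest.approx(tuple(totals))

    def test_species_relabel_invariance(self):
        m, a = 10, 10.0
        sp = np.where(np.random.default_rng(3).random(m * m) < 0.75,
                      "LIPA", "LIPB")
        comp = np.where(sp == "LIPA", "LIPB", "LIPA")
        xy = np.array([((i + 0.5) * a, (j + 0.5) * a)
                       for i in range(m) for j in range(m)])
        box = (m * a, m * a, 70.0)
        _, t1, a1 = _monolayer_pair(xy, species=list(sp), box=box)
        _, t2, a2 = _monolayer_pair(xy, species=list(comp), box=box)
        s1 = mixed_contacts(t1, a1, cutoff=1.2 * a)
        s2 = mixed_contacts(t2, a2, cutoff=1.2 * a)
        assert s1.f_mix == pytest.approx(s2.f_mix)
        assert s1.c_aa == s2.c_bb and s1.c_bb == s2.c_aa

    def test_invalid_cutoff(self, default_bilayer):
        _, traj, _ = default_bilayer
        asg = assign_leaflets(traj.frames[0], traj.topology)
        with pytest.raises(ValueError):
            mixed_contacts(traj, asg, cutoff=0.0)


class TestNeighborComposition:
    def test_pure_system_100_percent(self, default_bilayer):
        _, traj, _ = default_bilayer
        asg = assign_leaflets(traj.frames[0], traj.topology)
        short = Trajectory(topology=traj.topology, frames=traj.frames[:2])
        nc = neighbor_composition(short, asg, cutoff=15.0)
        assert nc.percentages[0, 0] == pytest.approx(100.0)

    def test_percentage_shares_printed_counts(self):
        shares = percentage_shares([6.73, 3.26])
        assert shares[0] == pytest.approx(67.4, abs=0.05)
        assert shares[1] == pytest.approx(32.6, abs=0.05)
        assert shares.sum() == pytest.approx(100.0)

    def test_toy_layout_hand_enumeration(self):
        # 5 lipids per leaflet on a line, spacing 10 Å, cutoff 15 Å:
        # each end lipid has 1 neighbor, inner ones 2 (no wrap at box 200)
        xy = np.column_stack([10.0 + 10.0 * np.arange(5), np.full(5, 50.0)])
        sp = ["LIPA", "LIPB", "LIPA", "LIPA", "LIPB"]
        top, traj, asg = _monolayer_pair(xy, species=sp,
                                         box=(200.0, 200.0, 70.0))
        nc = neighbor_composition(traj, asg, cutoff=15.0,
                                  bead_role="FIRST_TAIL_BEAD")
        ia = nc.center_species.index("LIPA")
        ib = nc.center_species.index("LIPB")
        # LIPA centers at x=10,30,40: neighbors A: (0,1,1) -> 2/3; B: (1,1,1) -> 1
        assert nc.mean_counts[ia, ia] == pytest.approx(2 / 3)
        assert nc.mean_counts[ia, ib] == pytest.approx(1.0)
        # LIPB centers at x=20,50: A neighbors (2,1) -> 1.5; B: (0,0) -> 0
        assert nc.mean_counts[ib, ia] == pytest.approx(1.5)
        assert nc.mean_counts[ib, ib] == pytest.approx(0.0)

    def test_row_percentages_sum_100(self, mixed_bilayer):
        _, traj, _ = mixed_bilayer
        asg = assign_leaflets(traj.frames[0], traj.topology)
        short = Trajectory(topology=traj.topology, frames=traj.frames[:2])
        nc = neighbor_composition(short, asg, cutoff=20.0)
        np.testing.assert_allclose(nc.percentages.sum(axis=1), 100.0)


class TestAreaDistribution:
    def test_lattice_degenerate(self):
        g = (np.arange(5) + 0.5) * (50.0 / 5)
        xy = np.array([(x, y) for x in g for y in g])
        top, traj, asg = _monolayer_pair(xy, box=(50.0, 50.0, 70.0))
        vm = voronoi_areas(traj.frames[0], top, asg, "upper")
        dist = voronoi_area_distribution([vm])
        q = dist["LIPA"]["quartiles"]
        np.testing.assert_allclose(q, 100.0, rtol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 80, (40, 2))
        top1, t1, a1 = _monolayer_pair(xy)
        top2, t2, a2 = _monolayer_pair(np.mod(xy + [13.0, -7.0], 80.0))
        d1 = voronoi_area_distribution(
            [voronoi_areas(t1.frames[0], top1, a1, "upper")])
        d2 = voronoi_area_distribution(
            [voronoi_areas(t2.frames[0], top2, a2, "upper")])
        np.testing.assert_allclose(sorted(d1["LIPA"]["areas"]),
                                   sorted(d2["LIPA"]["areas"]), atol=1e-6)

    def test_exchangeable_species_similar_quartiles(self, mixed_bilayer):
        _, traj, _ = mixed_bilayer
        asg = assign_leaflets(traj.frames[0], traj.topology)
        maps = [voronoi_areas(fr, traj.topology, asg, "upper", frame_index=i)
                for i, fr in enumerate(traj.frames[:10])]
        dist = voronoi_area_distribution(maps)
        qa = np.array(dist["LIPA"]["quartiles"])
        qb = np.array(dist["LIPB"]["quartiles"])
        np.testing.assert_allclose(qa, qb, rtol=0.15)

    def test_empty_maps_error(self):
        with pytest.raises(ValueError):
            voronoi_area_distribution([])
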