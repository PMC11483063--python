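"""P3 layers, F432 crystals, zone-axis projections, Bragg positions."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from symbond.building_blocks import make_toy_cyclic_oligomer
from symbond.geometry import rotation_about_axis
from symbond.lattice_builder import (
    CrystalModel,
    PlaneGroupLayer,
    bragg_positions,
    build_f432_crystal,
    build_p3_layer,
    local_tetrahedron_counts,
    zone_axis_projection,
)
from symbond.placement_engine import ArchitectureError, DOFVector, build_cage, parse_architecture


@pytest.fixture(scope="module")
def o3_cage():
    spec = parse_architecture("O3")
    return build_cage(spec, [make_toy_cyclic_oligomer(3, seed=0)], DOFVector.of((0.0, 30.0)))


@pytest.fixture(scope="module")
def linker():
    return make_toy_cyclic_oligomer(3, ring_radius=10.0, helix_length=16, seed=2)


class TestP3Layer:
    def test_patch_counts(self, toy_c3):
        other = make_toy_cyclic_oligomer(3, seed=8)
        _, model = build_p3_layer(toy_c3, other, a=120.0, z_off=4.0, phi=10.0, n_cells=2)
        # 2x2 cells x 2 occupied sites x 3 chains
        assert model.n_chains == 24
        per_site = {}
        for cid, (site, cell) in model.chain_map.items():
            per_site.setdefault(site, set()).add(cell)
        assert len(per_site[0]) == 4 and len(per_site[1]) == 4

    def test_translational_copies_are_exact_lattice_translates(self, toy_c3):
        other = make_toy_cyclic_oligomer(3, seed=8)
        layer, model = build_p3_layer(toy_c3, other, a=150.0, z_off=0.0, phi=0.0, n_cells=2)
        a1, a2 = layer.lattice_vectors()
        cells = {}
        for ch in model.chains:
            site, cell = model.chain_map[ch.chain_id]
            cells.setdefault((site, cell), []).append(ch.coords)
        ref = np.concatenate(cells[(0, 0)])
        # cell index 1 corresponds to (i, j) = (0, 1): translation a2
        assert np.allclose(np.concatenate(cells[(0, 1)]), ref + a2, atol=1e-9)

    def test_threefold_rotation_maps_layer_onto_lattice_translates(self, toy_c3):
        """Rotating the infinite P3 pattern by 120° about the origin site
        is a symmetry; on a finite patch each rotated chain must land on
        a lattice translate of a chain of the same site type."""
        other = make_toy_cyclic_oligomer(3, seed=8)
        layer, model = build_p3_layer(toy_c3, other, a=150.0, z_off=6.0, phi=25.0, n_cells=2)
        a1, a2 = layer.lattice_vectors()
        R = rotation_about_axis((0, 0, 1), 120.0)
        # reference chain clouds per site, reduced to the home cell
        per_site = {0: [], 1: []}
        for ch in model.chains:
            site, cell = model.chain_map[ch.chain_id]
            if cell == 0:
                per_site[site].append(ch.coords)
        for ch in model.chains[:6]:
            site, _ = model.chain_map[ch.chain_id]
            rotated = ch.coords @ R.T
            matched = False
            for ref in per_site[site]:
                # candidate lattice shift from centroids
                shift = rotated.mean(0) - ref.mean(0)
                ij = np.linalg.lstsq(np.stack([a1[:2], a2[:2]], axis=1), shift[:2], rcond=None)[0]
                ij_round = np.round(ij)
                if np.allclose(ij, ij_round, atol=1e-6):
                    cand = ref + ij_round[0] * a1 + ij_round[1] * a2
                    if np.allclose(np.sort(cand, axis=0), np.sort(rotated, axis=0), atol=1e-6):
                        matched = True
                        break
            assert matched

    def test_non_c3_block_rejected(self, toy_c2, toy_c3):
        with pytest.raises(ArchitectureError):
            build_p3_layer(toy_c2, toy_c3, a=100.0, z_off=0.0, phi=0.0)


class TestF432Crystal:
    def test_cell_counts_and_coordination(self, o3_cage, linker):
        crystal, model = build_f432_crystal(o3_cage, linker, a=150.0, n_cells=(2, 2, 2))
        assert len(crystal.cage_sites) == 4 * 8
        assert len(crystal.linker_sites) == 4 * 8
        assert local_tetrahedron_counts(crystal) == (4, 4)

    def test_linker_sites_equidistant_from_nearest_cages(self, o3_cage, linker):
        crystal, _ = build_f432_crystal(o3_cage, linker, a=100.0, n_cells=(1, 1, 1))
        cages = crystal.cage_cartesian()
        for site in crystal.linker_cartesian():
            d = np.sort(np.linalg.norm(cages - site, axis=1))
            near = d[d < d[0] + 1e-6]
            assert np.allclose(near, np.sqrt(3) / 4 * 100.0, atol=1e-9)

    def test_linker_axis_along_local_111(self, o3_cage, linker):
        _, model = build_f432_crystal(o3_cage, linker, a=120.0, n_cells=(1, 1, 1))
        d = model.component_axes[1][0]
        assert abs(abs(np.dot(d, np.ones(3) / np.sqrt(3))) - 1.0) < 1e-9

    def test_non_octahedral_cage_rejected(self, toy_c3, linker):
        from symbond.placement_engine import AssemblyModel

        bogus = AssemblyModel(chains=toy_c3.chains, provenance={}, chain_map={})
        with pytest.raises(ArchitectureError):
            build_f432_crystal(bogus, linker, a=100.0)


class TestZoneAxisProjection:
    def test_100_projection_of_fcc_is_square_net(self):
        crystal = CrystalModel(
            a=100.0, n_cells=(1, 1, 1),
            cage_sites=np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]], dtype=float),
            linker_sites=np.zeros((0, 3)),
        )
        xy = zone_axis_projection(crystal.cage_cartesian(), (1, 0, 0))
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        nn = np.sort(d[d > 1e-9])
        assert nn[0] == pytest.approx(100.0 / 2, abs=1e-9)  # a/2 square net

    def test_111_projection_is_hexagonal_net(self):
        # FCC points project along [111] onto a triangular (hexagonal) net:
        # all nearest-neighbour projected distances equal a/sqrt(2) * sqrt(3)/2 pattern
        pts = []
        for i in range(-1, 2):
            for j in range(-1, 2):
                for k in range(-1, 2):
                    for b in [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]:
                        pts.append((np.array([i, j, k]) + b) * 100.0)
        xy = zone_axis_projection(np.array(pts), (1, 1, 1))
        # project out duplicates
        uniq = np.unique(np.round(xy, 6), axis=0)
        d = np.linalg.norm(uniq[:, None] - uniq[None, :], axis=-1)
        nn = np.sort(d[d > 1e-6])[0]
        # each projected point's nearest neighbours all at the same distance
        counts = [np.sum(np.abs(d[i][(d[i] > 1e-6)] - nn) < 1e-6) for i in range(len(uniq))]
        assert max(counts) == 6  # hexagonal coordination for interior points

    def test_equivariance_under_rotation_about_axis(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 3)) * 30
        hkl = (1, 1, 0)
        v = np.array(hkl) / np.linalg.norm(hkl)
        R = rotation_about_axis(v, 35.0)
        p1 = zone_axis_projection(pts @ R.T, hkl)
        p0 = zone_axis_projection(pts, hkl)
        # rotated projection differs from original by an in-plane rotation
        c = np.cos(np.deg2rad(35.0)); s = np.sin(np.deg2rad(35.0))
        M = np.array([[c, -s], [s, c]])
        assert np.allclose(p1, p0 @ M.T, atol=1e-9) or np.allclose(p1, p0 @ M, atol=1e-9)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            zone_axis_projection(np.zeros((3, 3)), (0, 0, 0))


class TestBraggPositions:
    def test_p3_first_peak_formula(self):
        layer = PlaneGroupLayer(a=200.0, n_cells=1)
        peaks = bragg_positions(layer, 0.08)
        assert peaks[0][1] == pytest.approx(4 * np.pi / (np.sqrt(3) * 200.0), rel=1e-12)

    def test_fcc_selection_rules(self):
        crystal = CrystalModel(a=100.0, n_cells=(1, 1, 1), cage_sites=np.zeros((0, 3)), linker_sites=np.zeros((0, 3)))
        peaks = bragg_positions(crystal, 0.5)
        hkls = [h for h, _ in peaks]
        assert (1, 1, 1) in hkls
        assert (1, 0, 0) not in hkls and (0, 1, 1) not in hkls
        # first allowed reflections ordered (111) < (200) < (220)
        assert hkls[0] == (1, 1, 1) and hkls[1] == (0, 0, 2) and hkls[2] == (0, 2, 2)

    def test_fcc_rules_match_structure_factor_oracle(self):
        """4-point-basis structure factor: |F|² > 0 iff h,k,l same parity."""
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
        crystal = CrystalModel(a=80.0, n_cells=(1, 1, 1), cage_sites=np.zeros((0, 3)), linker_sites=np.zeros((0, 3)))
        peaks = {h for h, _ in bragg_positions(crystal, 0.6)}
        for h in range(3):
            for k in range(3):
                for l in range(3):
                    if h == k == l == 0:
                        continue
                    F = np.sum(np.exp(2j * np.pi * (basis @ np.array([h, k, l]))))
                    q = 2 * np.pi / 80.0 * np.sqrt(h * h + k * k + l * l)
                    if q > 0.6:
                        continue
                    present = any(
                        abs(q - qq) < 1e-9 for _, qq in bragg_positions(crystal, 0.6)
                    )
                    assert present == (abs(F) > 1e-9)

    def test_qmax_below_first_peak_empty(self):
        layer = PlaneGroupLayer(a=200.0, n_cells=1)
        assert bragg_positions(layer, 0.01) == []
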