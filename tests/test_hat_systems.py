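"""Radical-system construction, reaction configurations, paths and barriers."""

import numpy as np
import pytest
from scipy import stats

from hatforge.geometry import Geometry, GeometryError
from hatforge.calculators import ToyPotential, clash_check
from hatforge.hat_systems import (
    CHI2_DF,
    CHI2_FLOOR,
    CHI2_SCALE,
    RadicalSystem,
    SystemConstructionError,
    build_inter_system,
    build_intra_system,
    compute_barriers,
    displace_hydrogen,
    eligible_donors,
    end_position,
    interpolate_path,
    make_radical,
    path_energies,
    reduce_to_child,
    sample_da_distance,
)
from hatforge.molecules import embed_peptide, embed_with_topology


@pytest.fixture(scope="module")
def capped_alanine():
    geom, bonds, _ = embed_with_topology("CC(=O)N[C@@H](C)C(=O)NC", seed=2)
    return geom, bonds


@pytest.fixture(scope="module")
def mock_pair():
    """Tiny molecules for placement tests: a single-carbon radical and a
    C–H diatomic donor."""
    radical = Geometry(["C"], [[0.0, 0.0, 0.0]], multiplicity=2)
    donor = Geometry(["C", "H"], [[0.0, 0.0, 0.0], [1.09, 0.0, 0.0]])
    return radical, donor


class TestMakeRadical:
    def test_glycine_loses_one_hydrogen(self, glycine):
        geom, bonds = glycine
        h = eligible_donors(geom, bonds)[0]
        trimmed, acceptor, new_bonds = make_radical(geom, h, bonds)
        assert trimmed.n_atoms == geom.n_atoms - 1
        assert trimmed.elements[acceptor] != "H"
        assert trimmed.multiplicity == 2

    def test_non_hydrogen_rejected(self, glycine):
        geom, bonds = glycine
        carbon = next(i for i, e in enumerate(geom.elements) if e == "C")
        with pytest.raises(SystemConstructionError):
            make_radical(geom, carbon, bonds)

    def test_atom_count_restored_by_end_position(self, two_well):
        system, _ = two_well
        # conceptual round trip: removing then re-attaching at the end
        # position keeps the atom budget
        end = end_position(system)
        g = system.geometry.copy()
        g.coordinates[system.h_index] = end
        assert g.n_atoms == system.geometry.n_atoms


class TestEligibleDonors:
    def test_capped_alanine_ch_nh(self, capped_alanine):
        geom, bonds = capped_alanine
        from hatforge.geometry import neighbor_map

        hs = eligible_donors(geom, bonds)
        nb = neighbor_map(geom.n_atoms, bonds)
        # oracle: every H with a C or N heavy neighbor, and nothing else
        expected = [
            i
            for i, e in enumerate(geom.elements)
            if e == "H" and any(geom.elements[j] in "CN" for j in nb[i])
        ]
        assert hs == expected

    def test_no_hydrogens_empty(self):
        g = Geometry(["C", "O"], [[0, 0, 0], [1.2, 0, 0]])
        assert eligible_donors(g, [(0, 1)]) == []

    def test_rule_table_excluding_oxygen(self, glycine):
        geom, bonds = glycine
        from hatforge.geometry import neighbor_map

        hs = eligible_donors(geom, bonds, allowed_heavy=frozenset("CNS"))
        nb = neighbor_map(geom.n_atoms, bonds)
        assert all(
            "O" not in [geom.elements[j] for j in nb[h] if geom.elements[j] != "H"]
            for h in hs
        )


class TestDistanceSampler:
    def test_bounds_over_many_draws(self):
        d = sample_da_distance(0, size=10_000)
        assert d.max() <= 4.0
        assert d.min() >= CHI2_FLOOR

    def test_matches_rejection_oracle(self):
        """Empirical CDF vs an independently hand-rolled χ²₃ rejection
        sampler (sum of three squared normals, scaled)."""
        d = sample_da_distance(12, size=10_000)
        rng = np.random.default_rng(99)
        oracle = []
        while len(oracle) < 10_000:
            x = CHI2_SCALE * (rng.normal(size=3) ** 2).sum()
            if CHI2_FLOOR <= x <= 4.0:
                oracle.append(x)
        ks = stats.ks_2samp(d, np.array(oracle)).statistic
        assert ks < 0.02

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            sample_da_distance(0, max_distance=1.0)


class TestInterSystem:
    def test_placement_distance_exact_on_mocks(self, mock_pair):
        """With clash censoring switched off, the first pose succeeds and
        |r_H − r_0| equals the first sampled distance to 1e-9 Å."""
        radical, donor = mock_pair
        system = build_inter_system(
            radical, 0, donor, 1, seed=4, radical_bonds=[], donor_bonds=[(0, 1)],
            budget=1, clash_scale=0.01,
        )
        d = system.geometry.distance(system.h_index, system.acceptor_index)
        expected = sample_da_distance(np.random.default_rng(4))
        assert d == pytest.approx(expected, abs=1e-9)

    def test_distance_cap_and_nearest_h(self, glycine):
        geom, bonds = glycine
        h = eligible_donors(geom, bonds)[0]
        radical, acceptor, rbonds = make_radical(geom, h, bonds)
        built = 0
        for seed in range(12):
            try:
                system = build_inter_system(
                    radical, acceptor, geom, eligible_donors(geom, bonds)[1],
                    seed=seed, radical_bonds=rbonds, donor_bonds=bonds,
                    system_label="inter-aa+aa",
                )
            except SystemConstructionError:
                continue
            built += 1
            d = system.geometry.distance(system.h_index, system.acceptor_index)
            assert d <= 4.0
            system.validate()  # includes the nearest-hydrogen rule
            ok, _ = clash_check(system.geometry, system.bonded_pairs)
            assert ok
        assert built >= 5

    def test_distance_distribution_follows_sampler_law(self, mock_pair):
        """Realized donor–acceptor distances over many built systems
        reproduce the sampler's law (clash-free mocks, so no censoring)."""
        radical, donor = mock_pair
        realized = []
        for s in range(2000):
            system = build_inter_system(
                radical, 0, donor, 1, seed=s, radical_bonds=[], donor_bonds=[(0, 1)],
                clash_scale=0.01,
            )
            realized.append(
                system.geometry.distance(system.h_index, system.acceptor_index)
            )
        reference = sample_da_distance(123456, size=2000)
        assert stats.ks_2samp(realized, reference).pvalue > 0.01

    def test_budget_exhaustion(self, mock_pair):
        radical, donor = mock_pair
        with pytest.raises(SystemConstructionError, match="attempts"):
            build_inter_system(
                radical, 0, donor, 1, seed=0, radical_bonds=[], donor_bonds=[(0, 1)],
                budget=0,
            )


class TestIntraSystem:
    def test_capped_alanine_yields_valid_system(self, capped_alanine):
        geom, bonds = capped_alanine
        system = build_intra_system(geom, seed=7, bonds=bonds)
        assert system.transfer_type == "intra"
        assert system.donor_index != system.acceptor_index
        assert system.geometry.distance(system.h_index, system.acceptor_index) <= 4.0
        system.validate()

    def test_diatomic_rejected(self):
        hx = Geometry(["C", "H"], [[0, 0, 0], [1.09, 0, 0]])
        with pytest.raises(SystemConstructionError):
            build_intra_system(hx, seed=0, bonds=[(0, 1)])

    def test_serialization_round_trip_revalidates(self, capped_alanine, tmp_path):
        geom, bonds = capped_alanine
        system = build_intra_system(geom, seed=7, bonds=bonds)
        system.write(tmp_path / "s.extxyz", tmp_path / "s.json")
        back = RadicalSystem.read(tmp_path / "s.extxyz", tmp_path / "s.json")
        back.validate()
        assert back.transfer_type == system.transfer_type
        assert back.h_index == system.h_index
        np.testing.assert_allclose(
            back.geometry.coordinates, system.geometry.coordinates, atol=1e-8
        )


class TestEndPositionAndDisplacement:
    def test_end_point_at_reference_bond_length(self, two_well):
        system, _ = two_well
        end = end_position(system)
        acc = system.geometry.coordinates[system.acceptor_index]
        assert np.linalg.norm(end - acc) == pytest.approx(1.09, abs=1e-9)
        # collinear with the acceptor->start direction
        start = system.geometry.coordinates[system.h_index]
        cosang = np.dot(end - acc, start - acc) / (
            np.linalg.norm(end - acc) * np.linalg.norm(start - acc)
        )
        assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_start_at_end_is_fixed_point(self, two_well):
        system, _ = two_well
        moved = system.geometry.copy()
        moved.coordinates[system.h_index] = end_position(system)
        shifted = RadicalSystem(
            moved, system.molecule_boundaries, system.h_index,
            system.donor_index, system.acceptor_index, "inter",
            bonded_pairs=system.bonded_pairs,
        )
        np.testing.assert_allclose(
            end_position(shifted), moved.coordinates[system.h_index], atol=1e-12
        )

    def test_radius_zero_is_midpoint(self, two_well):
        system, calc = two_well
        rc = displace_hydrogen(system, calc, seed=1, radius=0.0)
        start = system.geometry.coordinates[system.h_index]
        mid = 0.5 * (start + end_position(system))
        np.testing.assert_allclose(rc.h_position, mid, atol=1e-12)

    def test_half_span_along_axis_reaches_endpoints(self, two_well):
        system, calc = two_well
        start = system.geometry.coordinates[system.h_index]
        end = end_position(system)
        axis = (end - start) / np.linalg.norm(end - start)
        half = 0.5 * np.linalg.norm(end - start)
        rc = displace_hydrogen(system, calc, seed=1, radius=half, direction=axis)
        np.testing.assert_allclose(rc.h_position, end, atol=1e-12)
        rc = displace_hydrogen(system, calc, seed=1, radius=half, direction=-axis)
        np.testing.assert_allclose(rc.h_position, start, atol=1e-12)

    def test_accepted_samples_pass_checks_post_hoc(self, two_well):
        system, calc = two_well
        e_ref = calc.energy_forces(system.geometry)[0]
        for seed in range(200):
            rc = displace_hydrogen(system, calc, max_rel_energy=5.0, seed=seed)
            g = rc.geometry
            ok, _ = clash_check(g, system.bonded_pairs)
            assert ok
            assert calc.energy_forces(g)[0] - e_ref <= 5.0

    def test_only_hydrogen_moves(self, two_well):
        system, calc = two_well
        rc = displace_hydrogen(system, calc, seed=5)
        g = rc.geometry
        mask = np.ones(g.n_atoms, dtype=bool)
        mask[system.h_index] = False
        np.testing.assert_array_equal(
            g.coordinates[mask], system.geometry.coordinates[mask]
        )


class TestInterpolation:
    def test_twelve_images_default(self, two_well):
        system, _ = two_well
        path = interpolate_path(system)
        assert len(path.images) == 12

    def test_image_zero_is_start_geometry(self, two_well):
        system, _ = two_well
        path = interpolate_path(system)
        np.testing.assert_array_equal(
            path.images[0].coordinates, system.geometry.coordinates
        )

    def test_even_spacing_and_static_environment(self, two_well):
        system, _ = two_well
        path = interpolate_path(system)
        h = system.h_index
        steps = [
            np.linalg.norm(b.coordinates[h] - a.coordinates[h])
            for a, b in zip(path.images, path.images[1:])
        ]
        span = np.linalg.norm(
            end_position(system) - system.geometry.coordinates[h]
        )
        np.testing.assert_allclose(steps, span / 11, atol=1e-12)
        mask = np.ones(system.geometry.n_atoms, dtype=bool)
        mask[h] = False
        for img in path.images:
            np.testing.assert_array_equal(
                img.coordinates[mask], system.geometry.coordinates[mask]
            )

    def test_negative_intermediate_count_rejected(self, two_well):
        system, _ = two_well
        with pytest.raises(ValueError):
            interpolate_path(system, n_intermediate=-1)


class TestBarriers:
    def test_simple_profile(self):
        res = compute_barriers([0.0, 1.0, 3.0, 2.0, 0.5])
        assert (res.delta_e_left, res.delta_e_right) == (3.0, 2.5)
        assert res.argmax_image == 2

    def test_flat_profile(self):
        res = compute_barriers([1.0, 1.0, 1.0])
        assert res.delta_e_left == res.delta_e_right == 0.0
        assert res.argmax_image == 0  # ties resolve to the lowest index

    def test_published_style_asymmetric_profile(self):
        """A path whose maximum sits 2.50 eV above the start and 2.85 eV
        above the end (the asymmetry of a typical semi-empirical HAT
        profile)."""
        energies = [0.0, 0.8, 1.9, 2.50, 2.1, 1.2, 0.6, 0.1, -0.2, -0.35]
        res = compute_barriers(energies)
        assert res.delta_e_left == pytest.approx(2.50)
        assert res.delta_e_right == pytest.approx(2.85)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            e = rng.normal(size=rng.integers(2, 15))
            res = compute_barriers(e)
            best, arg = -np.inf, None
            for i, x in enumerate(e):
                if x > best:
                    best, arg = x, i
            assert res.delta_e_left == pytest.approx(best - e[0])
            assert res.delta_e_right == pytest.approx(best - e[-1])
            assert res.argmax_image == arg

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_barriers([1.0])


@pytest.fixture(scope="module")
def tripeptide_system():
    """A capped G-A-G tripeptide intra system whose motif avoids the
    C-terminal residue."""
    from hatforge.geometry import neighbor_map
    from hatforge.hat_systems import _nearest_h_ok

    geom, bonds, rid = embed_peptide("GAG", True, seed=3)
    hs = eligible_donors(geom, bonds)
    for h_abs in hs:
        trimmed, acc, nb = make_radical(geom, h_abs, bonds)
        rid_t = np.delete(rid, h_abs)
        for h_tr in (h for h in hs if h != h_abs):
            h_new = h_tr - 1 if h_tr > h_abs else h_tr
            donors = [
                j
                for j in neighbor_map(trimmed.n_atoms, nb)[h_new]
                if trimmed.elements[j] != "H"
            ]
            if len(donors) != 1 or donors[0] == acc:
                continue
            if trimmed.distance(h_new, acc) > 4.0:
                continue
            if not _nearest_h_ok(trimmed, h_new, acc, nb):
                continue
            system = RadicalSystem(
                trimmed, [(0, trimmed.n_atoms)], h_new, donors[0], acc,
                "intra", "intra-tripeptide", nb,
            )
            motif_res = {rid_t[h_new], rid_t[donors[0]], rid_t[acc]}
            if 3 not in motif_res:
                system.validate()
                return system, rid_t, motif_res
    pytest.fail("no suitable tripeptide motif found")


class TestReduceToChild:
    def test_child_preserves_motif_coordinates(self, tripeptide_system):
        system, rid, _ = tripeptide_system
        child, child_ids = reduce_to_child(system, rid, 3)
        child.validate()
        assert child.geometry.n_atoms < system.geometry.n_atoms
        for parent_idx, child_idx in (
            (system.h_index, child.h_index),
            (system.donor_index, child.donor_index),
            (system.acceptor_index, child.acceptor_index),
        ):
            np.testing.assert_array_equal(
                child.geometry.coordinates[child_idx],
                system.geometry.coordinates[parent_idx],
            )

    def test_child_is_recapped(self, tripeptide_system):
        """Trimming the C-terminal glycine must leave an N-methylamide cap:
        the cut amide N keeps its H and its alpha carbon becomes a methyl."""
        from hatforge.geometry import neighbor_map

        system, rid, _ = tripeptide_system
        child, child_ids = reduce_to_child(system, rid, 3)
        cap_atoms = np.where(child_ids == 3)[0]
        elems = sorted(child.geometry.elements[i] for i in cap_atoms)
        assert elems == ["C", "H", "H", "H", "H", "N"]  # NH-CH3
        nb = neighbor_map(child.geometry.n_atoms, child.bonded_pairs)
        carbon = next(i for i in cap_atoms if child.geometry.elements[i] == "C")
        h_on_c = [j for j in nb[carbon] if child.geometry.elements[j] == "H"]
        assert len(h_on_c) == 3

    def test_removing_motif_residue_rejected(self, tripeptide_system):
        system, rid, motif_res = tripeptide_system
        if motif_res & {0, 1}:  # motif touches the N-terminal unit
            with pytest.raises(SystemConstructionError, match="D–H–A"):
                reduce_to_child(system, rid, 1)

    def test_interior_residue_not_removable(self, tripeptide_system):
        system, rid, _ = tripeptide_system
        with pytest.raises(SystemConstructionError, match="terminal"):
            reduce_to_child(system, rid, 2)
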