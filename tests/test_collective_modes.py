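"""Superposition, pooled PCA, mode recovery and distance–mode correlations."""

import dataclasses

import numpy as np
import pytest

from barrelens.collective_modes import (
    distance_mode_correlation,
    ensemble_rmsd,
    pca,
    square_fluctuations,
    superpose,
    top_correlated_pairs,
)
from barrelens.ensemble_io import Conformer, ConformerEnsemble
from barrelens.synthetic_data import (
    GeneratorSpec,
    generate_ensemble,
    make_topology,
    mode_fields,
    reporter_pair,
)
from conftest import random_rotation

ALL_ATOMS = ("N", "H", "CA", "C", "O")


def rigid_copies(topology, n, rng):
    members = []
    for m in range(n):
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        members.append(Conformer(topology.atoms, topology.coords @ R.T + t, m + 1))
    return ConformerEnsemble(members)


class TestSuperpose:
    def test_rigid_copies_collapse_to_zero_rmsd(self, topo20):
        rng = np.random.default_rng(0)
        ens = superpose(rigid_copies(topo20, 5, rng))
        coords = ens.coord_array()
        for m in range(1, 5):
            assert np.abs(coords[m] - coords[0]).max() < 1e-6

    def test_two_member_fit_matches_pairwise_oracle(self, topo20):
        from barrelens._geom import kabsch

        rng = np.random.default_rng(1)
        a = topo20.coords
        b = topo20.coords + rng.normal(0, 0.5, topo20.coords.shape)
        ens = ConformerEnsemble([Conformer(topo20.atoms, a, 1),
                                 Conformer(topo20.atoms, b, 2)])
        sup = superpose(ens, ALL_ATOMS)
        # after mutual fitting, the residual equals the direct pairwise fit rmsd
        _, _, direct = kabsch(b, a)
        residual = np.sqrt(np.mean(np.sum(
            (sup.coord_array()[0] - sup.coord_array()[1]) ** 2, axis=1)))
        assert residual == pytest.approx(direct, rel=1e-6)

    def test_mirror_image_is_not_reflected_onto_target(self, topo20):
        mirrored = topo20.coords * np.array([-1.0, 1.0, 1.0])
        ens = ConformerEnsemble([Conformer(topo20.atoms, topo20.coords, 1),
                                 Conformer(topo20.atoms, mirrored, 2)])
        sup = superpose(ens, ALL_ATOMS)
        residual = np.sqrt(np.mean(np.sum(
            (sup.coord_array()[0] - sup.coord_array()[1]) ** 2, axis=1)))
        assert residual > 0.5  # a reflection would give 0


class TestEnsembleRmsd:
    def test_identical_members(self, topo20):
        ens = ConformerEnsemble([Conformer(topo20.atoms, topo20.coords, m) for m in (1, 2, 3)])
        mean, sd = ensemble_rmsd(ens)
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_two_members_single_subensemble(self, topo20):
        rng = np.random.default_rng(2)
        other = topo20.coords + rng.normal(0, 0.7, topo20.coords.shape)
        ens = ConformerEnsemble([Conformer(topo20.atoms, topo20.coords, 1),
                                 Conformer(topo20.atoms, other, 2)])
        from barrelens._geom import kabsch

        sel = ens.select(("N", "CA", "C"))
        idx = [ens.members[0].index_of(a) for a in sel]
        _, _, expected = kabsch(other[idx], topo20.coords[idx])
        mean, sd = ensemble_rmsd(ens)
        assert mean == pytest.approx(expected, rel=1e-9)
        assert sd == 0.0

    def test_subensemble_grouping(self, topo20):
        rng = np.random.default_rng(3)
        members = [Conformer(topo20.atoms,
                             topo20.coords + rng.normal(0, 0.4, topo20.coords.shape), m)
                   for m in range(1, 5)]
        ens = ConformerEnsemble(members, sub_ensemble_ids=[0, 0, 1, 1])
        mean, sd = ensemble_rmsd(ens)
        # only intra-group pairs (1,2) and (3,4) contribute
        single = ConformerEnsemble(members[:2])
        m1, _ = ensemble_rmsd(single)
        single2 = ConformerEnsemble(members[2:])
        m2, _ = ensemble_rmsd(single2)
        assert mean == pytest.approx((m1 + m2) / 2, rel=1e-12)
        assert sd == pytest.approx(abs(m1 - m2) / 2, rel=1e-9)

    def test_single_member_rejected(self, topo20):
        with pytest.raises(ValueError):
            ensemble_rmsd(ConformerEnsemble([Conformer(topo20.atoms, topo20.coords, 1)]))


class TestPCA:
    def test_single_mode_limit(self, topo32):
        spec = GeneratorSpec(n_residues=32, n_members=100, seed=5,
                             mode_sds=(2.0, 0.0, 0.0), noise_sd=0.0)
        dec = pca(generate_ensemble(spec))
        assert dec.eigenvalues[0] / dec.eigenvalues.sum() >= 0.99

    def test_eigenvalue_ratio_recovery(self):
        spec = GeneratorSpec(n_residues=32, n_members=500, seed=6)
        dec = pca(generate_ensemble(spec))
        ratio = dec.eigenvalues[0] / dec.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_modes_orthonormal_and_variance_partitioned(self):
        spec = GeneratorSpec(n_residues=16, n_members=40, seed=7)
        dec = pca(generate_ensemble(spec))
        gram = dec.modes @ dec.modes.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-8
        assert np.all(dec.eigenvalues >= -1e-10)
        total = dec.projections.shape[0]
        # eigenvalue sum equals total variance of the superposed coordinates
        assert dec.eigenvalues.sum() == pytest.approx(
            dec.projections.var(axis=0, ddof=1).sum(), rel=1e-6
        )

    def test_projections_zero_mean_variance_eigenvalue(self):
        spec = GeneratorSpec(n_residues=16, n_members=50, seed=8)
        dec = pca(generate_ensemble(spec))
        assert np.abs(dec.projections.mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose(
            dec.projections.var(axis=0, ddof=1), dec.eigenvalues,
            rtol=1e-6, atol=1e-12,
        )

    def test_reconstruction(self):
        spec = GeneratorSpec(n_residues=10, n_members=8, seed=9)
        ens = generate_ensemble(spec)
        dec = pca(ens)
        sup = superpose(ConformerEnsemble(list(ens.members), label="p"), ("CA",))
        sel = sup.select(("CA",))
        coords = sup.coord_array(sel)
        for m in range(len(ens)):
            np.testing.assert_allclose(dec.reconstruct(m), coords[m], atol=1e-6)

    def test_bimodal_clusters_separated_by_planted_displacement(self):
        apo_spec = GeneratorSpec(n_residues=24, n_members=80, seed=10,
                                 state_displacement=10.0)
        holo_spec = dataclasses.replace(apo_spec, state="holo", seed=11)
        apo = generate_ensemble(apo_spec)
        holo = generate_ensemble(holo_spec)
        dec = pca([apo, holo], selection=ALL_ATOMS)
        labels = np.array(dec.member_labels)
        p_apo = dec.projections[labels == apo.label, 0]
        p_holo = dec.projections[labels == holo.label, 0]
        separation = abs(p_holo.mean() - p_apo.mean())
        assert separation == pytest.approx(10.0, rel=0.05)

    def test_cluster_labels_linearly_separable_along_pc1(self):
        apo_spec = GeneratorSpec(n_residues=24, n_members=80, seed=12)
        holo_spec = dataclasses.replace(apo_spec, state="holo", seed=13)
        apo = generate_ensemble(apo_spec)
        holo = generate_ensemble(holo_spec)
        dec = pca([apo, holo])
        labels = np.array(dec.member_labels)
        p_apo = dec.projections[labels == apo.label, 0]
        p_holo = dec.projections[labels == holo.label, 0]
        lo, hi = (p_apo, p_holo) if p_apo.mean() < p_holo.mean() else (p_holo, p_apo)
        assert lo.max() < hi.min()  # 0 misassignments by a single threshold

    def test_degenerate_pool_rejected(self, topo20):
        ens = ConformerEnsemble([Conformer(topo20.atoms, topo20.coords, m) for m in (1, 2, 3)])
        with pytest.raises(ValueError, match="degenerate"):
            pca(ens)


class TestSquareFluctuations:
    def test_sum_equals_eigenvalue(self):
        spec = GeneratorSpec(n_residues=16, n_members=30, seed=14)
        dec = pca(generate_ensemble(spec))
        for k in (0, 1):
            f = square_fluctuations(dec, k)
            assert sum(f.values()) == pytest.approx(dec.eigenvalues[k], rel=1e-9)

    def test_localized_mode(self, topo20):
        # hand-built decomposition: mode concentrated on one residue
        from barrelens.collective_modes import ModeDecomposition

        sel = [a for a in topo20.atoms if a.atom_name == "CA"]
        n = len(sel)
        mode = np.zeros(3 * n)
        mode[3 * 4] = 1.0  # x of 5th CA
        dec = ModeDecomposition(sel, topo20.coords[:n], mode[None, :],
                                np.array([2.5]), np.zeros((1, 1)), ["x"])
        f = square_fluctuations(dec, 0)
        assert f[sel[4].residue_number] == pytest.approx(2.5)
        assert sum(v for r, v in f.items() if r != sel[4].residue_number) == 0.0

    def test_planted_mode_shape_recovered(self):
        spec = GeneratorSpec(n_residues=32, n_members=500, seed=15,
                             mode_sds=(2.0, 0.0, 0.0), noise_sd=0.0)
        ens = generate_ensemble(spec)
        dec = pca(ens, selection=ALL_ATOMS)
        f = square_fluctuations(dec, 0)
        topo = make_topology(32)
        field = mode_fields(topo)[0]
        planted = {}
        for atom, comp in zip(topo.atoms, field):
            planted[atom.residue_number] = planted.get(atom.residue_number, 0.0) + \
                float(comp @ comp)
        scale = dec.eigenvalues[0]
        for res, expected in planted.items():
            if expected * scale > 0.01:  # avoid relative tests on ~zero entries
                assert f[res] == pytest.approx(expected * scale, rel=0.10)


class TestDistanceModeCorrelation:
    def test_affine_pair_correlates_perfectly(self):
        spec = GeneratorSpec(n_residues=24, n_members=60, seed=16,
                             mode_sds=(1.5, 0.0, 0.0), noise_sd=0.0)
        ens = generate_ensemble(spec)
        dec = pca(ens)
        matrix = distance_mode_correlation(ens, dec, 0)
        topo = make_topology(24)
        pair = reporter_pair(topo, mode_fields(topo), 0)
        # noiseless single-mode: distance is a smooth monotone function of the
        # projection over the sampled range
        assert abs(matrix.value(*pair)) > 0.999

    def test_planted_reporter_pair(self):
        spec = GeneratorSpec(n_residues=32, n_members=500, seed=17)
        ens = generate_ensemble(spec)
        dec = pca(ens)
        topo = make_topology(32)
        pair = reporter_pair(topo, mode_fields(topo), 0)
        c1 = distance_mode_correlation(ens, dec, 0).value(*pair)
        c2 = distance_mode_correlation(ens, dec, 1).value(*pair)
        assert abs(c1) >= 0.9
        assert abs(c2) <= 0.3

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(18)
        spec = GeneratorSpec(n_residues=12, n_members=20, seed=19)
        ens = generate_ensemble(spec)
        moved = ConformerEnsemble(
            [m.transformed(random_rotation(rng), rng.uniform(-10, 10, 3))
             for m in ens.members], label=ens.label)
        base = distance_mode_correlation(ens, pca(ens), 0)
        after = distance_mode_correlation(moved, pca(moved), 0)
        mask = ~np.isnan(base.matrix)
        np.testing.assert_allclose(np.abs(after.matrix[mask]),
                                   np.abs(base.matrix[mask]), atol=1e-6)

    def test_zero_variance_pair_flagged_nan(self, topo20):
        members = [Conformer(topo20.atoms, topo20.coords + np.array([0, 0, float(m)]), m)
                   for m in (1, 2, 3, 4)]
        # identical internal geometry: every distance has zero variance
        ens = ConformerEnsemble(members)
        with pytest.raises(ValueError, match="degenerate"):
            pca(ens)


class TestTopCorrelatedPairs:
    def _matrix(self, values):
        from barrelens.collective_modes import DistanceModeCorrelation

        n = len(values)
        mat = np.array(values, dtype=float)
        return DistanceModeCorrelation(list(range(1, n + 1)), mat, 0)

    def test_unique_extreme(self):
        m = self._matrix([[np.nan, 0.5, -0.9], [0.5, np.nan, 0.2], [-0.9, 0.2, np.nan]])
        assert top_correlated_pairs(m, 1) == [(1, 3, -0.9)]

    def test_sign_filter_and_ties(self):
        m = self._matrix([[np.nan, 0.7, 0.7], [0.7, np.nan, -0.7], [0.7, -0.7, np.nan]])
        top = top_correlated_pairs(m, 2, sign=+1)
        assert top == [(1, 2, 0.7), (1, 3, 0.7)]  # deterministic index order

    def test_k_zero_and_truncation(self):
        m = self._matrix([[np.nan, 0.5], [0.5, np.nan]])
        assert top_correlated_pairs(m, 0) == []
        with pytest.warns(UserWarning, match="only 1"):
            out = top_correlated_pairs(m, 5)
        assert len(out) == 1
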