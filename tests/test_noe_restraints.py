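"""Restraint preprocessing and r^-6 ensemble evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barrelens.ensemble_io import AtomKey, ConformerEnsemble
from barrelens.noe_restraints import (
    AtomGroup,
    DistanceRestraint,
    bin_upper_bound,
    destereo,
    effective_distance,
    filter_unviolated,
    preprocess,
    violation_report,
)
from conftest import make_conformer, make_hh_ensemble


def brute_force_effective_distance(ensemble, restraint):
    """Independent oracle: explicit loops over members and cross pairs."""
    sums = []
    for member in ensemble.members:
        s = 0.0
        for a in restraint.group_a:
            for b in restraint.group_b:
                r = np.linalg.norm(member[a] - member[b])
                s += r ** -6
        sums.append(s)
    return (sum(sums) / len(sums)) ** (-1 / 6)


@pytest.fixture(scope="module")
def leu_topology():
    """One Leu with a full isopropyl proton set, one Gly, one Ala."""
    spec = [(23, "LEU", name, (i * 1.5, 0.0, 0.0)) for i, name in enumerate(
        ["HD11", "HD12", "HD13", "HD21", "HD22", "HD23", "HB2", "HB3"])]
    spec += [(40, "GLY", "HA2", (0, 3, 0)), (40, "GLY", "HA3", (1, 3, 0))]
    spec += [(8, "ALA", "HA", (0, 6, 0))]
    return make_conformer(spec)


class TestDestereo:
    def test_methyl_proton_widens_to_full_isopropyl(self, leu_topology):
        r = DistanceRestraint(
            AtomGroup(frozenset({AtomKey(23, "LEU", "HD11")})),
            AtomGroup(frozenset({AtomKey(8, "ALA", "HA")})),
            5.0,
        )
        out = destereo(r, leu_topology)
        assert {a.atom_name for a in out.group_a} == {
            "HD11", "HD12", "HD13", "HD21", "HD22", "HD23"
        }

    def test_non_stereo_atom_unchanged(self, leu_topology):
        r = DistanceRestraint(
            AtomGroup(frozenset({AtomKey(8, "ALA", "HA")})),
            AtomGroup(frozenset({AtomKey(40, "GLY", "HA2")})),
            5.0,
        )
        out = destereo(r, leu_topology)
        assert {a.atom_name for a in out.group_a} == {"HA"}
        assert {a.atom_name for a in out.group_b} == {"HA2", "HA3"}

    def test_methylene_pair(self, leu_topology):
        r = DistanceRestraint(
            AtomGroup(frozenset({AtomKey(23, "LEU", "HB2")})),
            AtomGroup(frozenset({AtomKey(8, "ALA", "HA")})),
            4.0,
        )
        out = destereo(r, leu_topology)
        assert {a.atom_name for a in out.group_a} == {"HB2", "HB3"}

    def test_wildcard_expansion(self, leu_topology):
        r = DistanceRestraint(
            AtomGroup(frozenset({AtomKey(23, "LEU", "HD#")})),
            AtomGroup(frozenset({AtomKey(8, "ALA", "HA")})),
            5.0,
        )
        out = destereo(r, leu_topology)
        assert len(out.group_a) == 6

    def test_unknown_atom_raises(self, leu_topology):
        r = DistanceRestraint(
            AtomGroup(frozenset({AtomKey(23, "LEU", "HZ9")})),
            AtomGroup(frozenset({AtomKey(8, "ALA", "HA")})),
            5.0,
        )
        with pytest.raises(KeyError):
            destereo(r, leu_topology)


class TestBinning:
    @pytest.mark.parametrize(
        "bound,expected",
        [(4.3, 5), (3.2, 4), (9.0, 9), (4.0, 4), (10.0, 10), (5.01, 6)],
    )
    def test_examples(self, bound, expected):
        assert bin_upper_bound(bound) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_upper_bound(10.4)
        with pytest.raises(ValueError):
            bin_upper_bound(0.0)

    @given(st.floats(min_value=0.01, max_value=10.0))
    @settings(deadline=None)
    def test_bin_properties(self, d):
        b = bin_upper_bound(d)
        assert 4 <= b <= 10
        assert b >= d or b == 4  # only the 4 Å clamp may sit below the bound
        assert b - d < 1.0 or b == 4


class TestEffectiveDistance:
    def test_single_member_single_pair_is_plain_distance(self):
        ens = make_hh_ensemble([3.0])
        r = DistanceRestraint(
            AtomGroup(frozenset({ens.atoms[0]})), AtomGroup(frozenset({ens.atoms[1]})), 5.0
        )
        assert effective_distance(ens, r) == pytest.approx(3.0, abs=1e-12)

    def test_two_member_average(self):
        ens = make_hh_ensemble([3.0, 5.0])
        r = DistanceRestraint(
            AtomGroup(frozenset({ens.atoms[0]})), AtomGroup(frozenset({ens.atoms[1]})), 5.0
        )
        expected = ((3.0 ** -6 + 5.0 ** -6) / 2) ** (-1 / 6)  # ≈ 3.342
        assert effective_distance(ens, r) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(3.342, abs=2e-3)

    def test_two_identical_pairs_sum_convention(self):
        conf = make_conformer(
            [
                (1, "ALA", "H", (0, 0, 0)),
                (2, "ALA", "HB2", (3, 0, 0)),
                (2, "ALA", "HB3", (0, 3, 0)),
            ]
        )
        ens = ConformerEnsemble([conf])
        r = DistanceRestraint(
            AtomGroup(frozenset({conf.atoms[0]})),
            AtomGroup(frozenset({conf.atoms[1], conf.atoms[2]})),
            5.0,
        )
        expected = (2 * 3.0 ** -6) ** (-1 / 6)  # ≈ 2.673
        assert effective_distance(ens, r) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2.673, abs=1e-3)
        # mean-combination flag averages instead of summing
        assert effective_distance(ens, r, ambiguity="mean") == pytest.approx(3.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_ensembles(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n_atoms = rng.integers(4, 12)
            members = []
            for m in range(rng.integers(2, 6)):
                spec = [
                    (i + 1, "ALA", "H", tuple(rng.uniform(-5, 5, 3)))
                    for i in range(n_atoms)
                ]
                members.append(make_conformer(spec, m + 1))
            ens = ConformerEnsemble(members)
            atoms = ens.atoms
            ga = AtomGroup(frozenset(atoms[: rng.integers(1, 3)]))
            gb = AtomGroup(frozenset(atoms[-rng.integers(1, 3):]))
            r = DistanceRestraint(ga, gb, 6.0)
            assert effective_distance(ens, r) == pytest.approx(
                brute_force_effective_distance(ens, r), abs=1e-10
            )

    def test_ensemble_average_bracketed_by_member_extremes(self):
        ens = make_hh_ensemble([2.5, 3.5, 6.0])
        r = DistanceRestraint(
            AtomGroup(frozenset({ens.atoms[0]})), AtomGroup(frozenset({ens.atoms[1]})), 5.0
        )
        d = effective_distance(ens, r)
        assert 2.5 <= d <= 6.0

    def test_ambiguity_never_longer_than_closest_pair(self):
        conf = make_conformer(
            [
                (1, "ALA", "H", (0, 0, 0)),
                (2, "ALA", "HB2", (2.8, 0, 0)),
                (2, "ALA", "HB3", (0, 7.0, 0)),
            ]
        )
        ens = ConformerEnsemble([conf])
        r = DistanceRestraint(
            AtomGroup(frozenset({conf.atoms[0]})),
            AtomGroup(frozenset({conf.atoms[1], conf.atoms[2]})),
            5.0,
        )
        assert effective_distance(ens, r) <= 2.8

    def test_duplicating_every_member_changes_nothing(self):
        ens = make_hh_ensemble([2.5, 4.0])
        doubled = ConformerEnsemble(ens.members + ens.members)
        r = DistanceRestraint(
            AtomGroup(frozenset({ens.atoms[0]})), AtomGroup(frozenset({ens.atoms[1]})), 5.0
        )
        assert effective_distance(doubled, r) == pytest.approx(
            effective_distance(ens, r), abs=1e-12
        )


class TestViolationReport:
    def _restraints(self, ens, bins):
        a, b = ens.atoms
        return [
            DistanceRestraint(
                AtomGroup(frozenset({a})), AtomGroup(frozenset({b})), float(x), bin=x
            )
            for x in bins
        ]

    def test_no_violations(self):
        ens = make_hh_ensemble([3.0])
        report = violation_report(ens, self._restraints(ens, [4, 5]))
        assert report.percent_violated == 0.0

    def test_fraction(self):
        # distance 6.0: violates bin 4 (4.5 < 6) and bin 5 (5.5 < 6), not 6, 7
        ens = make_hh_ensemble([6.0])
        report = violation_report(ens, self._restraints(ens, [4, 5, 6, 7]))
        assert report.n_violated == 2
        assert report.percent_violated == pytest.approx(50.0)
        flags = [v for _, _, v in report.per_restraint]
        assert flags == [True, True, False, False]

    def test_tolerance_monotonicity(self):
        ens = make_hh_ensemble([4.2, 5.1, 6.3])
        restraints = self._restraints(ens, [4, 5])
        pv = [
            violation_report(ens, restraints, tolerance=t).percent_violated
            for t in (0.0, 0.25, 0.5, 1.0, 2.0)
        ]
        assert pv == sorted(pv, reverse=True)

    def test_strict_inequality_at_threshold(self):
        ens = make_hh_ensemble([4.5])
        report = violation_report(ens, self._restraints(ens, [4]), tolerance=0.5)
        assert report.n_violated == 0  # 4.5 is not > 4 + 0.5

    def test_empty_list_rejected(self):
        ens = make_hh_ensemble([3.0])
        with pytest.raises(ValueError):
            violation_report(ens, [])


class TestFilterUnviolated:
    def test_empty_and_all_violated(self):
        ens = make_hh_ensemble([8.0])
        a, b = ens.atoms
        r = DistanceRestraint(AtomGroup(frozenset({a})), AtomGroup(frozenset({b})), 4.0, bin=4)
        assert filter_unviolated([], ens) == []
        assert filter_unviolated([r], ens) == []

    def test_filtered_subset_is_self_consistent(self):
        ens = make_hh_ensemble([4.8])
        a, b = ens.atoms
        restraints = [
            DistanceRestraint(AtomGroup(frozenset({a})), AtomGroup(frozenset({b})), float(x), bin=x)
            for x in (4, 5, 6)
        ]
        kept = filter_unviolated(restraints, ens)
        assert [r.bin for r in kept] == [5, 6]
        assert violation_report(ens, kept).percent_violated == 0.0


def test_preprocess_pipeline(leu_topology):
    raw = [
        DistanceRestraint(
            AtomGroup(frozenset({AtomKey(23, "LEU", "HD11")})),
            AtomGroup(frozenset({AtomKey(8, "ALA", "HA")})),
            4.3,
        )
    ]
    out = preprocess(raw, leu_topology)
    assert out[0].bin == 5
    assert len(out[0].group_a) == 6
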