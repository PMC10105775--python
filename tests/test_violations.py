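"""Distance measurement, violation classification and assembly rescue."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from xlvalidate.crosslinks import CrossLink
from xlvalidate.errors import UndefinedValueError
from xlvalidate.synthetic import (
    SyntheticSpec,
    make_assembly,
    make_rescue_scenario,
    make_structure,
    sample_crosslinks,
)
from xlvalidate.violations import (
    SATISFIED,
    UNMAPPED,
    VIOLATED,
    Assessment,
    agreement_fraction,
    apply_assembly_rescue,
    assembly_min_distance,
    assess,
    ca_distance,
    summarize_protein,
)

from conftest import structure_from_coords


def _link(acc, i, j):
    return CrossLink.create(acc, i, acc, j)


class TestCaDistance:
    def test_three_four_five_triangle(self, make_structure_from_coords):
        s = make_structure_from_coords([[0, 0, 0], [3, 4, 0]])
        assert ca_distance(s, "A", 1, 2) == pytest.approx(5.0)
        assert ca_distance(s, "A", 2, 1) == pytest.approx(5.0)

    def test_identical_residue_zero(self, make_structure_from_coords):
        s = make_structure_from_coords([[1, 2, 3]])
        assert ca_distance(s, "A", 1, 1) == 0.0

    def test_absent_residue_is_unmapped_not_error(self, make_structure_from_coords):
        s = make_structure_from_coords([[0, 0, 0]])
        assert ca_distance(s, "A", 1, 99) is None

    def test_matches_coordinate_arithmetic_oracle(self, random_walk_structure):
        s = random_walk_structure
        coords = s.ca_array("A")
        rng = np.random.default_rng(13)
        for _ in range(100):
            i, j = (int(v) for v in rng.integers(1, 51, size=2))
            # brute-force oracle: explicit component arithmetic
            dx, dy, dz = (coords[i - 1][k] - coords[j - 1][k] for k in range(3))
            expected = (dx * dx + dy * dy + dz * dz) ** 0.5
            assert ca_distance(s, "A", i, j) == pytest.approx(expected, abs=1e-9)


class TestAssess:
    def test_boundary_inclusive_and_34A_violated(self, make_structure_from_coords):
        s = make_structure_from_coords([[0, 0, 0], [30.0, 0, 0], [34.0, 0, 0]], name="P")
        links = [_link("P", 1, 2), _link("P", 1, 3)]
        by_key = {a.link.residue_b: a for a in assess(s, links, threshold=30.0)}
        assert by_key[2].status == SATISFIED  # exactly 30.0 A is within reach
        assert by_key[3].status == VIOLATED  # 34 A, just above threshold
        assert by_key[3].distance == pytest.approx(34.0)

    def test_unmapped_link_excluded_from_agreement(self, make_structure_from_coords):
        s = make_structure_from_coords([[0, 0, 0], [10, 0, 0]], name="P")
        out = assess(s, [_link("P", 1, 2), _link("P", 1, 50)])
        statuses = {a.link.residue_b: a.status for a in out}
        assert statuses == {2: SATISFIED, 50: UNMAPPED}
        assert agreement_fraction(out) == 1.0

    def test_generator_ground_truth_counts(self):
        spec = SyntheticSpec(
            n_residues=300,
            domain_ranges=((1, 140), (161, 300)),
            lysine_fraction=0.2,
            seed=21,
            n_links=10,
            violated_fraction=0.2,
        )
        s = make_structure(spec)
        links, truth = sample_crosslinks(s, spec)
        out = assess(s, links, threshold=30.0)
        assert sum(a.status == SATISFIED for a in out) == 8
        assert sum(a.status == VIOLATED for a in out) == 2
        for a in out:
            assert (a.status == VIOLATED) == truth[a.link.key]


class TestAgreementFraction:
    def test_all_satisfied(self):
        out = [
            Assessment(_link("P", 1, i), 10.0, SATISFIED, 30.0) for i in range(2, 6)
        ]
        assert agreement_fraction(out) == 1.0

    def test_97_of_100(self):
        out = [
            Assessment(_link("P", 1, i + 2), 10.0, SATISFIED, 30.0) for i in range(97)
        ] + [
            Assessment(_link("P", 200, 300 + i), 50.0, VIOLATED, 30.0) for i in range(3)
        ]
        assert agreement_fraction(out) == pytest.approx(0.97)

    def test_zero_mapped_is_undefined(self):
        out = [Assessment(_link("P", 1, 2), None, UNMAPPED, 30.0)]
        with pytest.raises(UndefinedValueError):
            agreement_fraction(out)

    def test_monotone_in_threshold(self):
        spec = SyntheticSpec(
            n_residues=300,
            domain_ranges=((1, 140), (161, 300)),
            lysine_fraction=0.2,
            seed=5,
            n_links=30,
            violated_fraction=0.3,
        )
        s = make_structure(spec)
        links, _ = sample_crosslinks(s, spec)
        fractions = [
            agreement_fraction(assess(s, links, threshold=t)) for t in (30, 35, 40)
        ]
        assert fractions == sorted(fractions)


class TestRigidMotionInvariance:
    @given(st.integers(0, 10_000))
    def test_distances_invariant_under_global_rotation_translation(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=20, size=(10, 3))
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=50, size=3)
        s1 = structure_from_coords(coords, name="P")
        s2 = structure_from_coords(coords @ R.T + t, name="P")
        for i, j in [(1, 5), (2, 9), (3, 10)]:
            assert ca_distance(s1, "A", i, j) == pytest.approx(
                ca_distance(s2, "A", i, j), abs=1e-8
            )


class TestAssemblyMinDistance:
    def test_single_copy_equals_monomer_distance(self, make_structure_from_coords):
        s = make_structure_from_coords([[0, 0, 0], [3, 4, 0]], name="P")
        assert assembly_min_distance(s, _link("P", 1, 2)) == pytest.approx(5.0)

    def test_cross_copy_rescue_with_known_transform(self):
        # two residues 200 A apart within a copy; copy B shifted so that
        # residue 2 of B sits 20 A from residue 1 of A
        coords = np.array([[0.0, 0, 0], [200.0, 0, 0]])
        monomer = structure_from_coords(coords, name="P")
        assembly = make_assembly(monomer, translation=(-180.0, 0, 0))
        link = _link("P", 1, 2)
        # oracle: enumerate all four ordered chain pairings explicitly
        pos = {
            ("A", 1): coords[0],
            ("A", 2): coords[1],
            ("B", 1): coords[0] + [-180, 0, 0],
            ("B", 2): coords[1] + [-180, 0, 0],
        }
        oracle = min(
            math.dist(pos[(ca, 1)], pos[(cb, 2)])
            for ca in "AB"
            for cb in "AB"
        )
        got = assembly_min_distance(assembly, link)
        assert got == pytest.approx(oracle) == pytest.approx(20.0)

    def test_never_exceeds_intra_copy_distance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=30, size=(20, 3))
        monomer = structure_from_coords(coords, name="P")
        assembly = make_assembly(monomer, translation=rng.normal(scale=40, size=3))
        for _ in range(25):
            i, j = sorted(int(v) for v in rng.integers(1, 21, size=2))
            if i == j:
                continue
            link = _link("P", i, j)
            d_mono = ca_distance(monomer, "A", i, j)
            assert assembly_min_distance(assembly, link) <= d_mono + 1e-12

    def test_residual_violation_stays_violated(self, make_structure_from_coords):
        # every pairing of this link exceeds the threshold: rescue must not fire
        monomer = structure_from_coords([[0.0, 0, 0], [34.0, 0, 0]], name="P")
        assembly = make_assembly(monomer, translation=(500.0, 0, 0))
        out = apply_assembly_rescue(assess(monomer, [_link("P", 1, 2)]), assembly)
        (a,) = out
        assert a.status == VIOLATED
        assert a.min_assembly_distance == pytest.approx(34.0)
        assert not a.rescued

    def test_rescue_scenario_rescues_exactly_the_constructed_links(self):
        monomer, assembly, links, rescued_keys = make_rescue_scenario(seed=1, n_rescued=3)
        out = apply_assembly_rescue(assess(monomer, links), assembly)
        got = {a.link.key for a in out if a.rescued}
        assert got == rescued_keys


class TestSummaries:
    def test_counts_and_agreement(self, make_structure_from_coords):
        s = make_structure_from_coords(
            np.column_stack([np.arange(12) * 5.0, np.zeros(12), np.zeros(12)]),
            plddt=[80.0],
            name="P",
        )
        links = [_link("P", 1, 1 + k) for k in range(1, 11)]
        summary = summarize_protein(s, assess(s, links))
        assert (summary.n_links, summary.n_mapped) == (10, 10)
        assert summary.n_violations == sum(5.0 * k > 30 for k in range(1, 11))
        assert summary.agreement == pytest.approx(
            (summary.n_mapped - summary.n_violations) / summary.n_mapped
        )
        assert summary.mean_plddt == pytest.approx(80.0)

    def test_order_permutation_does_not_change_summary(self, random_walk_structure):
        s = random_walk_structure
        links = [_link("WALK", i, i + 7) for i in range(1, 40)]
        a1 = assess(s, links)
        a2 = list(reversed(a1))
        s1 = summarize_protein(s, a1, accession="WALK")
        s2 = summarize_protein(s, a2, accession="WALK")
        assert (s1.n_links, s1.n_mapped, s1.n_violations) == (
            s2.n_links,
            s2.n_mapped,
            s2.n_violations,
        )
        assert sorted(s1.distances) == sorted(s2.distances)
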