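"""CBC/HCBC classification, delimitation, p-distance, and K/theta."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from its2barcode import errors
from its2barcode.barcode import Barcode, PAIR_FROM_CODE
from its2barcode.cbc_delimit import (
    CbcMatrix,
    ChangeClass,
    classify_code_pair,
    cbc_hcbc_matrix,
    collapse_matrix,
    delimit_species,
    k_over_theta,
    p_distance,
    p_distance_matrix,
)
from its2barcode.io_formats import SequenceRecord

codes_st = st.integers(min_value=0, max_value=8)


def brute_force_class(a: int, b: int) -> ChangeClass:
    """Independent oracle: expand codes to ordered base pairs and count
    differing partners."""
    if a == b and a in (7, 8):
        return ChangeClass.IDENTICAL
    if a not in PAIR_FROM_CODE or b not in PAIR_FROM_CODE:
        return ChangeClass.NOT_COMPARABLE
    diffs = sum(x != y for x, y in zip(PAIR_FROM_CODE[a], PAIR_FROM_CODE[b]))
    return {0: ChangeClass.IDENTICAL, 1: ChangeClass.HCBC, 2: ChangeClass.CBC}[diffs]


class TestClassifyCodePair:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            (1, 2, ChangeClass.CBC),  # A-U vs U-A: both partners substituted
            (3, 5, ChangeClass.HCBC),  # G-C vs G.U: only the 3' base differs
            (4, 4, ChangeClass.IDENTICAL),
            (7, 1, ChangeClass.NOT_COMPARABLE),
            (8, 3, ChangeClass.NOT_COMPARABLE),
            (7, 7, ChangeClass.IDENTICAL),
            (8, 8, ChangeClass.IDENTICAL),
            (0, 0, ChangeClass.NOT_COMPARABLE),
        ],
    )
    def test_known_classifications(self, a, b, expected):
        assert classify_code_pair(a, b) is expected

    def test_agrees_with_brute_force_oracle_on_all_code_pairs(self):
        for a, b in itertools.product(range(9), repeat=2):
            assert classify_code_pair(a, b) is brute_force_class(a, b), (a, b)

    @given(codes_st, codes_st)
    def test_symmetric(self, a, b):
        assert classify_code_pair(a, b) is classify_code_pair(b, a)

    def test_out_of_alphabet_rejected(self):
        with pytest.raises(errors.UsageError):
            classify_code_pair(9, 1)


class TestCbcMatrix:
    def test_self_comparison_is_zero(self):
        bc = Barcode("a", (1, 2, 3, 7, 8))
        m = cbc_hcbc_matrix([bc, Barcode("b", bc.codes)])
        assert m.cbc_between("a", "b") == 0
        assert m.hcbc_between("a", "b") == 0

    def test_single_cbc_position_counted(self):
        m = cbc_hcbc_matrix([Barcode("a", (1, 3, 3)), Barcode("b", (2, 3, 3))])
        assert m.cbc_between("a", "b") == 1
        assert m.hcbc_between("a", "b") == 0

    def test_not_comparable_positions_count_nowhere(self):
        m = cbc_hcbc_matrix([Barcode("a", (1, 7, 8, 0)), Barcode("b", (2, 1, 1, 1))])
        assert m.cbc_between("a", "b") == 1  # only the first position

    def test_reordering_strains_permutes_matrix(self):
        bcs = [Barcode("a", (1, 2)), Barcode("b", (2, 2)), Barcode("c", (3, 5))]
        m1 = cbc_hcbc_matrix(bcs)
        m2 = cbc_hcbc_matrix(bcs[::-1])
        for x, y in itertools.combinations("abc", 2):
            assert m1.cbc_between(x, y) == m2.cbc_between(x, y)
            assert m1.hcbc_between(x, y) == m2.hcbc_between(x, y)

    def test_removing_a_position_never_increases_counts(self, default_barcodes):
        full = cbc_hcbc_matrix(default_barcodes)
        trimmed = cbc_hcbc_matrix(
            [Barcode(b.strain_id, b.codes[:-1]) for b in default_barcodes]
        )
        assert (trimmed.cbc <= full.cbc).all()
        assert (trimmed.hcbc <= full.hcbc).all()

    def test_mismatched_axes_rejected(self):
        with pytest.raises(errors.CrossReferenceError):
            cbc_hcbc_matrix([Barcode("a", (1, 2)), Barcode("b", (1,))])

    def test_combined_frame_layout(self):
        m = cbc_hcbc_matrix([Barcode("a", (1, 3)), Barcode("b", (2, 5))])
        frame = m.combined_frame()
        assert frame.loc["a", "b"] == m.cbc_between("a", "b")  # upper = CBC
        assert frame.loc["b", "a"] == m.hcbc_between("a", "b")  # lower = HCBC


class TestDelimitSpecies:
    def test_all_separated_strains_become_singletons(self):
        n = 4
        cbc = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        m = CbcMatrix(list("abcd"), cbc, np.zeros((n, n), dtype=int))
        partition = delimit_species(m)
        assert [sorted(b) for b in partition.blocks] == [["a"], ["b"], ["c"], ["d"]]
        assert partition.conflict_flags == []

    def test_planted_panel_recovered_without_conflicts(
        self, default_panel, default_barcodes
    ):
        partition = delimit_species(cbc_hcbc_matrix(default_barcodes))
        got = {frozenset(b) for b in partition.blocks}
        want = {
            frozenset(s for s, sp in default_panel.truth.species_of.items() if sp == block)
            for block in set(default_panel.truth.species_of.values())
        }
        assert got == want
        assert partition.conflict_flags == []

    def test_nontransitive_zero_cbc_merged_and_flagged(self):
        cbc = np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0]])
        m = CbcMatrix(list("abc"), cbc, np.zeros((3, 3), dtype=int))
        partition = delimit_species(m)
        assert [sorted(b) for b in partition.blocks] == [["a", "b", "c"]]
        assert partition.conflict_flags == [("a", "b", "c")]

    def test_species_level_collapse_takes_maximum(self):
        bcs = [
            Barcode("a1", (1, 3, 3)),
            Barcode("a2", (1, 3, 8)),
            Barcode("b1", (2, 4, 3)),
        ]
        m = cbc_hcbc_matrix(bcs)
        partition = delimit_species(m)
        collapsed = collapse_matrix(m, partition)
        # a1 vs b1 shows 2 CBCs, a2 vs b1 only 1 (third slot not comparable)
        assert collapsed.cbc_between("species_1", "species_2") == 2


class TestPDistance:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "ACGUACGUAC")
        assert p_distance(a, SequenceRecord("b", a.residues)) == 0.0

    def test_one_difference_in_ten(self):
        a = SequenceRecord("a", "ACGUACGUAC")
        b = SequenceRecord("b", "ACGUACGUAG")
        assert p_distance(a, b) == pytest.approx(0.1)

    def test_gap_and_ambiguity_columns_excluded(self):
        a = SequenceRecord("a", "ACGUA-GUAC")
        b = SequenceRecord("b", "GCGUACGUAN")
        # col 6 gap in a, col 10 N in b -> 8 compared, 1 differing (col 1)
        assert p_distance(a, b) == pytest.approx(1 / 8)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(errors.UndefinedDistanceError):
            p_distance(SequenceRecord("a", "--"), SequenceRecord("b", "AC"))

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_identity_of_indiscernibles(self, seed):
        rng = np.random.default_rng(seed)
        s1 = "".join(rng.choice(list("ACGU"), size=30))
        s2 = "".join(rng.choice(list("ACGU"), size=30))
        a, b = SequenceRecord("a", s1), SequenceRecord("b", s2)
        assert p_distance(a, b) == p_distance(b, a)
        assert (p_distance(a, b) == 0.0) == (s1 == s2)


class TestKOverTheta:
    def _distances(self, values):
        ids = sorted({x for pair in values for x in pair})
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for (x, y), d in values.items():
            mat.loc[x, y] = mat.loc[y, x] = d
        return mat

    def test_ratio_four_at_default_threshold(self):
        distances = self._distances(
            {("a1", "a2"): 0.02, ("a1", "b1"): 0.08, ("a2", "b1"): 0.08}
        )
        partition = {"a1": "A", "a2": "A", "b1": "B"}
        results = {(r.reference_block, r.other_block): r for r in k_over_theta(partition, distances)}
        r = results[("A", "B")]
        assert r.K == pytest.approx(0.08)
        assert r.theta == pytest.approx(0.02)
        assert r.ratio == pytest.approx(4.0)
        assert r.flagged

    def test_zero_theta_gives_undefined_ratio_not_exception(self):
        distances = self._distances(
            {("a1", "a2"): 0.0, ("a1", "b1"): 0.08, ("a2", "b1"): 0.08}
        )
        partition = {"a1": "A", "a2": "A", "b1": "B"}
        results = {(r.reference_block, r.other_block): r for r in k_over_theta(partition, distances)}
        assert not results[("A", "B")].defined
        assert not results[("B", "A")].defined  # singleton reference block

    def test_planted_two_population_divergence_exceeds_threshold(self):
        """Sequences with within-group diversity ~1 substitution and planted
        between-group divergence ~10 substitutions give K/theta > 4."""
        rng = np.random.default_rng(7)
        L = 400
        base = rng.choice(list("ACGU"), size=L)

        def mutate(seq, k, rng):
            out = seq.copy()
            for pos in rng.choice(L, size=k, replace=False):
                out[pos] = rng.choice([b for b in "ACGU" if b != out[pos]])
            return out

        other_base = mutate(base, 40, rng)
        records = []
        for name, backbone in (("A", base), ("B", other_base)):
            for i in range(4):
                records.append(
                    SequenceRecord(f"{name}{i}", "".join(mutate(backbone, 2, rng)))
                )
        distances = p_distance_matrix(records)
        partition = {r.id: r.id[0] for r in records}
        results = {
            (r.reference_block, r.other_block): r
            for r in k_over_theta(partition, distances)
        }
        assert results[("A", "B")].ratio > 4
        assert results[("B", "A")].ratio > 4
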