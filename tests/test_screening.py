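"""Marker-region extraction, pairwise identity, and query classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from its2barcode import errors
from its2barcode.barcode import Barcode
from its2barcode.io_formats import SequenceRecord
from its2barcode.screening import (
    CLASS_ORDER,
    PanelEntry,
    RegionDefinition,
    ScreeningThresholds,
    classify_query,
    extract_alignment_region,
    global_identity,
)


def _random_seq(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


class TestRegionExtraction:
    def test_inclusive_interval_arithmetic(self):
        records = [SequenceRecord("a", "ACGUACGUAC")]
        aligned, ungapped = extract_alignment_region(
            records, RegionDefinition("X", 5, 8)
        )
        assert aligned[0].residues == "ACGU"
        assert len(aligned[0]) == 4

    @pytest.mark.parametrize(
        ("name", "width"), [("V4", 230), ("V9", 107)]
    )
    def test_default_marker_regions_span_printed_columns(self, name, width):
        """The V4 (616-845) and V9 (1631-1737) intervals of the reference
        alignment span 230 and 107 columns respectively."""
        region = RegionDefinition.default(name)
        assert region.width == width
        rng = np.random.default_rng(0)
        records = [SequenceRecord("a", _random_seq(rng, 1800))]
        aligned, _ = extract_alignment_region(records, region)
        assert len(aligned[0]) == width

    def test_gaps_preserved_in_slice_but_dropped_in_copies(self):
        records = [SequenceRecord("a", "AC--GUACGU")]
        aligned, ungapped = extract_alignment_region(
            records, RegionDefinition("X", 2, 6)
        )
        assert aligned[0].residues == "C--GU"
        assert ungapped[0].residues == "CGU"

    def test_interval_exceeding_alignment_rejected(self):
        records = [SequenceRecord("a", "ACGU")]
        with pytest.raises(errors.UsageError):
            extract_alignment_region(records, RegionDefinition("X", 2, 9))


class TestGlobalIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 100)
        identity, coverage = global_identity(
            SequenceRecord("q", seq), SequenceRecord("r", seq)
        )
        assert identity == 100.0
        assert coverage == 100.0

    def test_three_substitutions_in_hundred(self):
        rng = np.random.default_rng(2)
        ref = _random_seq(rng, 100)
        mutated = list(ref)
        for pos in (10, 50, 90):
            mutated[pos] = {"A": "C", "C": "G", "G": "U", "U": "A"}[mutated[pos]]
        identity, coverage = global_identity(
            SequenceRecord("q", "".join(mutated)), SequenceRecord("r", ref)
        )
        assert identity == pytest.approx(97.0)
        assert coverage == 100.0

    def test_prefix_query_has_full_coverage_via_overhang_rule(self):
        rng = np.random.default_rng(3)
        ref = _random_seq(rng, 100)
        identity, coverage = global_identity(
            SequenceRecord("q", ref[:50]), SequenceRecord("r", ref)
        )
        assert identity == 100.0
        assert coverage == 100.0

    def test_ambiguity_counts_as_mismatch(self):
        identity, _ = global_identity(
            SequenceRecord("q", "ACGUNCGUAC"), SequenceRecord("r", "ACGUNCGUAC")
        )
        assert identity == pytest.approx(90.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(errors.UsageError):
            global_identity(SequenceRecord("q", "-"), SequenceRecord("r", "ACGU"))

    @given(st.text(alphabet="ACGU", min_size=5, max_size=60))
    def test_self_identity_is_always_100(self, seq):
        identity, coverage = global_identity(
            SequenceRecord("q", seq), SequenceRecord("r", seq)
        )
        assert identity == 100.0
        assert coverage == 100.0


def _panel(rng, with_barcodes=True):
    base = _random_seq(rng, 200)
    other = list(base)
    for pos in range(0, 24, 2):  # a clearly different second species
        other[pos] = {"A": "G", "C": "U", "G": "A", "U": "C"}[other[pos]]
    bc1 = Barcode("r1", (1, 2, 3, 4) * 5) if with_barcodes else None
    bc2 = Barcode("r2", (3, 4, 1, 2) * 5) if with_barcodes else None
    return base, [
        PanelEntry(SequenceRecord("r1", base), "species_1", bc1),
        PanelEntry(SequenceRecord("r2", "".join(other)), "species_2", bc2),
    ]


def _mutate(seq, n, rng):
    out = list(seq)
    for pos in rng.choice(len(out), size=n, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "U", "U": "A"}[out[pos]]
    return "".join(out)


class TestClassifyQuery:
    def test_exact_copy_is_species_match(self):
        rng = np.random.default_rng(4)
        base, panel = _panel(rng)
        hit = classify_query(SequenceRecord("q", base), panel)
        assert hit.classification == "species_match"
        assert hit.reference_id == "r1"

    def test_high_identity_zero_cbc_is_same_species_candidate(self):
        rng = np.random.default_rng(5)
        base, panel = _panel(rng)
        query = SequenceRecord("q", _mutate(base, 2, rng))
        hit = classify_query(query, panel, query_barcode=panel[0].barcode)
        assert hit.classification == "same_species_candidate"
        assert hit.cbc_count == 0

    def test_high_identity_with_cbc_is_putative_new_lineage(self):
        rng = np.random.default_rng(6)
        base, panel = _panel(rng)
        query = SequenceRecord("q", _mutate(base, 2, rng))
        q_codes = list(panel[0].barcode.codes)
        q_codes[0] = 3  # A-U -> G-C: both partners substituted
        hit = classify_query(query, panel, query_barcode=Barcode("q", tuple(q_codes)))
        assert hit.classification == "putative_new_lineage"
        assert hit.cbc_count >= 1

    def test_sequence_only_evidence_below_strict_bound_is_genus_level(self):
        rng = np.random.default_rng(7)
        base, panel = _panel(rng, with_barcodes=False)
        query = SequenceRecord("q", _mutate(base, 5, rng))  # 97.5 %
        hit = classify_query(query, panel)
        assert hit.identity == pytest.approx(97.5)
        assert hit.classification == "genus_level_only"

    def test_sequence_only_evidence_above_strict_bound_is_candidate(self):
        rng = np.random.default_rng(8)
        base, panel = _panel(rng, with_barcodes=False)
        query = SequenceRecord("q", _mutate(base, 2, rng))  # 99 %
        assert classify_query(query, panel).classification == "same_species_candidate"

    def test_low_identity_is_unassigned(self):
        rng = np.random.default_rng(9)
        base, panel = _panel(rng)
        query = SequenceRecord("q", _mutate(base, 20, rng))  # 90 %
        assert classify_query(query, panel).classification == "unassigned"

    def test_low_identity_with_diagnostic_cbcs_is_foreign_taxon(self):
        rng = np.random.default_rng(10)
        base, panel = _panel(rng)
        query = SequenceRecord("q", _mutate(base, 20, rng))
        q_codes = list(panel[0].barcode.codes)
        q_codes[0] = 3  # CBC against every panel barcode at position 1
        hit = classify_query(
            query,
            panel,
            query_barcode=Barcode("q", tuple(q_codes)),
            diagnostic_positions=[1],
        )
        assert hit.classification == "foreign_taxon"

    def test_empty_panel_rejected(self):
        with pytest.raises(errors.UsageError):
            classify_query(SequenceRecord("q", "ACGU"), [])

    def test_bad_thresholds_rejected(self):
        with pytest.raises(errors.UsageError):
            ScreeningThresholds(min_identity=0)
        with pytest.raises(errors.UsageError):
            ScreeningThresholds(v4_strict_identity=101)

    @given(st.integers(0, 2**31 - 1))
    def test_classification_monotone_in_identity(self, seed):
        """More substitutions never promote a query up the class ladder."""
        rng = np.random.default_rng(seed)
        base, panel = _panel(rng, with_barcodes=False)
        rank_prev = None
        for n_mut in (0, 2, 5, 8, 20, 40):
            query = SequenceRecord("q", _mutate(base, n_mut, rng))
            rank = CLASS_ORDER.index(classify_query(query, panel).classification)
            if rank_prev is not None:
                assert rank <= rank_prev
            rank_prev = rank
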