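"""Local emulation of the marker-based database screening workflow.

Instead of a live BLAST query, marker regions (SSU V4 and V9 slices of the
study alignment, or the ITS-2 barcode region) are screened against a
user-supplied reference panel with deterministic global pairwise alignment.
Queries are then classified following the published guideline: perfect
identity and coverage identify a species; high-identity hits are examined for
compensatory base changes against the reference barcode; V4-only evidence
below a strict identity bound can only support a genus-level call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio import Align

from .barcode import Barcode
from .cbc_delimit import ChangeClass, classify_code_pair
from .errors import UsageError
from .io_formats import SequenceRecord

#: Marker regions as 1-based inclusive columns of the study alignment.
DEFAULT_REGIONS = {
    "V4": (616, 845),
    "V9": (1631, 1737),
}


@dataclass(frozen=True)
class RegionDefinition:
    """A named marker region on the alignment (1-based inclusive columns)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise UsageError(f"invalid region interval ({self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def default(cls, name: str) -> "RegionDefinition":
        start, end = DEFAULT_REGIONS[name]
        return cls(name, start, end)


def extract_alignment_region(
    records: Sequence[SequenceRecord], region: RegionDefinition
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Column slice of an alignment plus per-record ungapped copies."""
    length = len(records[0].residues)
    if region.end > length:
        raise UsageError(
            f"region {region.name} ({region.start}-{region.end}) exceeds "
            f"alignment length {length}"
        )
    aligned = [
        SequenceRecord(r.id, r.residues[region.start - 1 : region.end], r.was_dna)
        for r in records
    ]
    ungapped = [SequenceRecord(r.id, r.ungapped, r.was_dna) for r in aligned]
    return aligned, ungapped


@dataclass(frozen=True)
class AlignmentScores:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


def global_identity(
    query: SequenceRecord,
    reference: SequenceRecord,
    scores: AlignmentScores = AlignmentScores(),
) -> tuple[float, float]:
    """Percent identity and query coverage from one global alignment.

    Terminal-overhang columns (leading/trailing columns where one sequence
    has not started or has already ended) are excluded from the identity
    denominator, approximating the "100% coverage" semantics of a database
    hit.  Coverage is the percentage of query bases inside the overhang-free
    core.  Ambiguity letters never count as matches.
    """
    if not query.ungapped or not reference.ungapped:
        raise UsageError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scores.match,
        mismatch_score=scores.mismatch,
        open_gap_score=scores.gap_open,
        extend_gap_score=scores.gap_extend,
    )
    aln = aligner.align(query.ungapped, reference.ungapped)[0]
    row_q, row_r = str(aln[0]), str(aln[1])

    def overhang(row: str) -> tuple[int, int]:
        lead = len(row) - len(row.lstrip("-"))
        trail = len(row) - len(row.rstrip("-"))
        return lead, trail

    lead = max(overhang(row_q)[0], overhang(row_r)[0])
    trail = max(overhang(row_q)[1], overhang(row_r)[1])
    core_q = row_q[lead : len(row_q) - trail]
    core_r = row_r[lead : len(row_r) - trail]
    if not core_q:
        raise UsageError("alignment has no overhang-free core")
    matches = sum(
        1 for a, b in zip(core_q, core_r) if a == b and a in "ACGU"
    )
    identity = 100.0 * matches / len(core_q)
    coverage = 100.0 * sum(1 for c in core_q if c != "-") / len(query.ungapped)
    return identity, coverage


@dataclass(frozen=True)
class PanelEntry:
    """One reference strain: region sequence, species label, optional barcode."""

    record: SequenceRecord
    species: str
    barcode: Barcode | None = None


@dataclass(frozen=True)
class ScreeningThresholds:
    min_identity: float = 97.0
    v4_strict_identity: float = 99.0

    def __post_init__(self) -> None:
        for value in (self.min_identity, self.v4_strict_identity):
            if not (0 < value <= 100):
                raise UsageError(f"identity threshold {value} outside (0, 100]")


CLASS_ORDER = [
    "foreign_taxon",
    "unassigned",
    "genus_level_only",
    "putative_new_lineage",
    "same_species_candidate",
    "species_match",
]


@dataclass(frozen=True)
class ScreeningHit:
    query_id: str
    reference_id: str
    species: str
    identity: float
    coverage: float
    classification: str
    cbc_count: int | None = None


def _cbc_count(a: Barcode, b: Barcode) -> int:
    return sum(
        1
        for ca, cb in zip(a.codes, b.codes)
        if classify_code_pair(ca, cb) is ChangeClass.CBC
    )


def classify_query(
    query: SequenceRecord,
    panel: Sequence[PanelEntry],
    query_barcode: Barcode | None = None,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    diagnostic_positions: Sequence[int] | None = None,
    scores: AlignmentScores = AlignmentScores(),
) -> ScreeningHit:
    """Classify one query against the reference panel.

    Decision ladder on the best hit (highest identity, first reference on
    ties):

    * identity 100 and coverage 100 -> ``species_match``;
    * identity >= the minimum (default 97) with barcodes available:
      zero CBCs against the best reference -> ``same_species_candidate``,
      one or more CBCs -> ``putative_new_lineage``;
    * identity >= the minimum on sequence-only (V4-style) evidence:
      below the strict bound (default 99) -> ``genus_level_only``,
      at or above it -> ``same_species_candidate``;
    * identity below the minimum -> ``unassigned``, or ``foreign_taxon`` when
      the query's barcode shows a CBC at every genus-diagnostic position
      (1-based barcode positions, e.g. the V4/V9 signature positions that
      separate the genus from its outgroup).
    """
    if not panel:
        raise UsageError("reference panel is empty")
    eps = 1e-9
    best: PanelEntry | None = None
    best_identity = best_coverage = -1.0
    for entry in panel:
        identity, coverage = global_identity(query, entry.record, scores)
        if identity > best_identity + eps:
            best, best_identity, best_coverage = entry, identity, coverage
    assert best is not None

    cbc = None
    if query_barcode is not None and best.barcode is not None:
        cbc = _cbc_count(query_barcode, best.barcode)

    if best_identity >= 100 - eps and best_coverage >= 100 - eps:
        classification = "species_match"
    elif best_identity >= thresholds.min_identity - eps:
        if cbc is not None:
            classification = (
                "same_species_candidate" if cbc == 0 else "putative_new_lineage"
            )
        elif best_identity >= thresholds.v4_strict_identity - eps:
            classification = "same_species_candidate"
        else:
            classification = "genus_level_only"
    else:
        classification = "unassigned"
        if query_barcode is not None and diagnostic_positions:
            diagnostic_cbcs = [
                pos
                for pos in diagnostic_positions
                for entry in panel
                if entry.barcode is not None
                and classify_code_pair(
                    query_barcode.codes[pos - 1], entry.barcode.codes[pos - 1]
                )
                is ChangeClass.CBC
            ]
            if diagnostic_cbcs:
                classification = "foreign_taxon"

    return ScreeningHit(
        query_id=query.id,
        reference_id=best.record.id,
        species=best.species,
        identity=best_identity,
        coverage=best_coverage,
        classification=classification,
        cbc_count=cbc,
    )


def screen_queries(
    queries: Sequence[SequenceRecord],
    panel: Sequence[PanelEntry],
    query_barcodes: dict[str, Barcode] | None = None,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    diagnostic_positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Classify a batch of queries; returns one hit row per query."""
    query_barcodes = query_barcodes or {}
    hits = [
        classify_query(
            q,
            panel,
            query_barcode=query_barcodes.get(q.id),
            thresholds=thresholds,
            diagnostic_positions=diagnostic_positions,
        )
        for q in queries
    ]
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "reference_id": h.reference_id,
                "species": h.species,
                "identity": h.identity,
                "coverage": h.coverage,
                "classification": h.classification,
                "cbc_count": h.cbc_count,
            }
            for h in hits
        ]
    )
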