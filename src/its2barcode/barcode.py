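"""The number-coded ITS-2 barcode.

The conserved barcode region is the concatenation of the first 14 pairs of
the 5.8S/LSU stem, the first 5 pairs of Helix I, the first 11 pairs of Helix
II (which include the diagnostic pyrimidine-pyrimidine mismatch) and all
pairs of Helix III, each block ordered from the helix base outward.  Every
pair slot is coded by the ordered nucleotide pair:

    A-U = 1,  U-A = 2,  G-C = 3,  C-G = 4,  G.U = 5,  U.G = 6,
    any other paired combination (mismatch) = 7,
    deletion / unpaired / single bases = 8.

An IUPAC ambiguity letter at a paired slot yields the ``unknown`` sentinel
(code 0, serialized ``?``): an N cannot assert a real mismatched pairing, so
it is excluded from CBC counting rather than coded 7.

Helix III's pair count is not fixed a priori; it is taken from the consensus
pairing, which defines the shared position axis all strains are coded on.
With the canonical geometry (14 + 5 + 11 + 43) the barcode has 73 positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from string import ascii_lowercase
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AnnotationError, CrossReferenceError, FormatError
from .io_formats import HelixAnnotation, SequenceRecord
from .structure_model import GAP, PAIRED, BasePair, PairTable

#: Ordered (5' base, 3' base) -> code for the six canonical/wobble pairs.
CODE_FROM_PAIR: dict[tuple[str, str], int] = {
    ("A", "U"): 1,
    ("U", "A"): 2,
    ("G", "C"): 3,
    ("C", "G"): 4,
    ("G", "U"): 5,
    ("U", "G"): 6,
}
PAIR_FROM_CODE: dict[int, tuple[str, str]] = {v: k for k, v in CODE_FROM_PAIR.items()}

MISMATCH_CODE = 7
ABSENT_CODE = 8  # deletion, unpaired, or single (partner-less) base
UNKNOWN_CODE = 0  # ambiguity sentinel, serialized '?'

VALID_CODES = frozenset(range(0, 9))

#: Pair quotas of the barcode region (helix -> number of slots; None = all).
BARCODE_QUOTAS: tuple[tuple[str, int | None], ...] = (
    ("STEM", 14),
    ("HI", 5),
    ("HII", 11),
    ("HIII", None),
)


@dataclass(frozen=True)
class Barcode:
    """A strain's code series on the shared consensus position axis."""

    strain_id: str
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = set(self.codes) - VALID_CODES
        if bad:
            raise FormatError(f"invalid barcode codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.codes)

    def as_string(self) -> str:
        return "".join("?" if c == UNKNOWN_CODE else str(c) for c in self.codes)

    @classmethod
    def from_string(cls, strain_id: str, text: str) -> "Barcode":
        codes = tuple(UNKNOWN_CODE if ch == "?" else int(ch) for ch in text)
        return cls(strain_id, codes)


@dataclass(frozen=True)
class HaplotypeLabel:
    """BC-style label: species number plus optional within-species letter."""

    species_index: int
    variant_letter: str | None = None

    @property
    def label(self) -> str:
        suffix = self.variant_letter or ""
        return f"BC-{self.species_index}{suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def hiii_quota_from_consensus(consensus: PairTable) -> int:
    """Helix III slot count defined by the consensus pairing."""
    n = len(consensus.pairs_in_helix("HIII"))
    if n == 0:
        raise AnnotationError("consensus has no Helix III pairs")
    return n


def extract_barcode_pairs(
    table: PairTable, hiii_quota: int | None = None
) -> list[BasePair]:
    """Select the barcode pair slots from one strain's pair table.

    Returns 14 stem + 5 HI + 11 HII + Helix III slots, each block ordered
    from the helix base outward.  A helix with fewer realized pairs than its
    quota contributes gap-status placeholders for the missing distal slots,
    so every strain's barcode shares one position axis.

    ``hiii_quota`` is normally taken from the consensus; ``None`` means "all
    Helix III pairs of this table" (appropriate for the consensus itself).
    """
    names = table.helix_names() or {p.helix for p in table.pairs}
    missing = {"STEM", "HI", "HII", "HIII"} - names
    if missing:
        raise AnnotationError(
            f"pair table {table.sequence_id!r} lacks helix annotation(s) "
            f"{sorted(missing)}"
        )
    out: list[BasePair] = []
    for helix, quota in BARCODE_QUOTAS:
        pairs = table.pairs_in_helix(helix)
        want = quota
        if helix == "HIII":
            want = hiii_quota if hiii_quota is not None else len(pairs)
            if want == 0:
                raise AnnotationError("Helix III contributes no barcode slots")
        out.extend(pairs[:want])
        for _ in range(want - len(pairs[:want])):
            out.append(
                BasePair(None, None, None, None, status=GAP, helix=helix)
            )
    return out


def encode_pair(pair: BasePair) -> int:
    """Code one pair slot; total over all inputs (never raises)."""
    if pair.status != PAIRED:
        return ABSENT_CODE
    b5, b3 = pair.five_prime_base, pair.three_prime_base
    if b5 in ("-", None) or b3 in ("-", None):
        return ABSENT_CODE
    if b5 not in "ACGU" or b3 not in "ACGU":
        return UNKNOWN_CODE
    return CODE_FROM_PAIR.get((b5, b3), MISMATCH_CODE)


def encode_barcode(pairs: Sequence[BasePair], strain_id: str) -> Barcode:
    """Translate extracted barcode pairs into the 1-8/unknown code series."""
    return Barcode(strain_id, tuple(encode_pair(p) for p in pairs))


def barcode_from_table(table: PairTable, hiii_quota: int | None = None) -> Barcode:
    return encode_barcode(extract_barcode_pairs(table, hiii_quota), table.sequence_id)


def barcodes_from_panel(
    records: Sequence[SequenceRecord],
    structures: Mapping[str, str],
    annotations: Sequence[HelixAnnotation],
    consensus_threshold: float = 0.5,
) -> list[Barcode]:
    """Full extraction pipeline for a strain panel.

    Builds one pair table per strain, derives the consensus pairing (which
    fixes the Helix III quota and hence the shared position axis), and codes
    every strain against that axis.
    """
    from .structure_model import build_pair_table, consensus_pairing

    tables = [build_pair_table(rec, structures[rec.id], annotations) for rec in records]
    consensus = consensus_pairing(tables, threshold=consensus_threshold)
    quota = hiii_quota_from_consensus(consensus)
    return [barcode_from_table(t, quota) for t in tables]


def assign_haplotypes(
    barcodes: Sequence[Barcode],
    partition: Mapping[str, str] | Sequence[Iterable[str]],
) -> dict[str, HaplotypeLabel]:
    """Label strains BC-n(letter) from their code series and species blocks.

    ``partition`` maps strain -> species block (or is a sequence of blocks).
    Species numbers follow first occurrence of each species in the barcode
    order; within a species, distinct code series receive letters a, b, ... in
    first-occurrence order, and a species with a single variant carries no
    letter.  Identical code series always share one label.
    """
    if not isinstance(partition, Mapping):
        partition = {
            strain: f"block{i}" for i, block in enumerate(partition) for strain in block
        }
    missing = [b.strain_id for b in barcodes if b.strain_id not in partition]
    if missing:
        raise CrossReferenceError(f"strains missing from partition: {missing}")

    species_order: list[str] = []
    variants: dict[str, list[tuple[int, ...]]] = {}
    assignment: dict[str, tuple[str, tuple[int, ...]]] = {}
    for bc in barcodes:
        block = partition[bc.strain_id]
        if block not in species_order:
            species_order.append(block)
            variants[block] = []
        if bc.codes not in variants[block]:
            variants[block].append(bc.codes)
        assignment[bc.strain_id] = (block, bc.codes)

    labels: dict[str, HaplotypeLabel] = {}
    for strain, (block, codes) in assignment.items():
        species_index = species_order.index(block) + 1
        if len(variants[block]) == 1:
            letter = None
        else:
            letter = ascii_lowercase[variants[block].index(codes)]
        labels[strain] = HaplotypeLabel(species_index, letter)
    return labels


def barcode_table(
    barcodes: Sequence[Barcode], labels: Mapping[str, HaplotypeLabel] | None = None
) -> pd.DataFrame:
    """Tabular export: strain, haplotype label, contiguous code string."""
    rows = []
    for bc in barcodes:
        rows.append(
            {
                "strain_id": bc.strain_id,
                "haplotype": labels[bc.strain_id].label if labels else "",
                "codes": bc.as_string(),
            }
        )
    return pd.DataFrame(rows, columns=["strain_id", "haplotype", "codes"])


def write_barcode_table(
    barcodes: Sequence[Barcode],
    path: str | Path,
    labels: Mapping[str, HaplotypeLabel] | None = None,
) -> None:
    barcode_table(barcodes, labels).to_csv(path, sep="\t", index=False)


def read_barcode_table(path: str | Path) -> tuple[list[Barcode], dict[str, str]]:
    """Read a barcode TSV back; returns barcodes and strain -> label map."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"strain_id", "codes"} <= set(df.columns):
        raise FormatError("barcode table needs 'strain_id' and 'codes' columns")
    barcodes = [
        Barcode.from_string(row.strain_id, row.codes) for row in df.itertuples()
    ]
    labels = {
        row.strain_id: row.haplotype
        for row in df.itertuples()
        if "haplotype" in df.columns and row.haplotype
    }
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise CrossReferenceError(
            f"barcodes on different position axes: lengths {sorted(lengths)}"
        )
    return barcodes, labels
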