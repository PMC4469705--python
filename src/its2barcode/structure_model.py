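"""Base-pair tables from dot-bracket structures and majority consensus pairing.

A :class:`PairTable` records, for one sequence on one coordinate axis, every
base pair asserted by its secondary structure together with the helix that
pair belongs to (from the annotation sidecar).  A consensus table across
strains keeps the pairs present in at least a threshold fraction of the
per-strain tables; the consensus fixes the barcode position axis downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .errors import AnnotationError, CrossReferenceError, UsageError
from .io_formats import (
    HELIX_NAMES,
    HelixAnnotation,
    SequenceRecord,
    check_dot_bracket,
    validate_annotations,
)

PAIRED = "paired"
GAP = "gap"  # placeholder emitted when a helix falls short of its quota


@dataclass(frozen=True)
class BasePair:
    """One (possibly placeholder) base pair.

    Positions are 1-based alignment columns with ``five_prime_pos <
    three_prime_pos`` when paired.  Placeholder pairs (status ``gap``) carry
    no positions or bases; they stand for a pair slot the sequence does not
    realize.
    """

    five_prime_pos: int | None
    three_prime_pos: int | None
    five_prime_base: str | None
    three_prime_base: str | None
    status: str = PAIRED
    helix: str = "OTHER"

    def __post_init__(self) -> None:
        if self.status == PAIRED:
            if self.five_prime_pos is None or self.three_prime_pos is None:
                raise UsageError("paired BasePair needs both positions")
            if self.five_prime_pos >= self.three_prime_pos:
                raise UsageError(
                    f"5' position {self.five_prime_pos} must precede 3' "
                    f"position {self.three_prime_pos}"
                )


@dataclass
class PairTable:
    """All base pairs of one sequence (or of a consensus) on one axis."""

    sequence_id: str
    length: int
    pairs: list[BasePair]
    annotations: tuple[HelixAnnotation, ...] = field(default_factory=tuple)

    def pairs_in_helix(self, helix: str) -> list[BasePair]:
        """Pairs of one helix ordered from the helix base outward.

        For a hairpin arm and for the enclosing 5.8S/LSU stem alike, the
        basal pair is the one with the smallest 5' column, so ascending 5'
        order is base-outward order.
        """
        return sorted(
            (p for p in self.pairs if p.helix == helix),
            key=lambda p: p.five_prime_pos,
        )

    def helix_names(self) -> set[str]:
        return {a.helix_name for a in self.annotations}

    def to_dot_bracket(self) -> str:
        """Regenerate the dot-bracket string (gap/placeholder slots excluded)."""
        chars = ["."] * self.length
        for p in self.pairs:
            if p.status != PAIRED:
                continue
            chars[p.five_prime_pos - 1] = "("
            chars[p.three_prime_pos - 1] = ")"
        return "".join(chars)


def _helix_of(column: int, annotations: Sequence[HelixAnnotation]) -> str | None:
    for ann in annotations:
        if column in ann.columns():
            return ann.helix_name
    return None


def build_pair_table(
    sequence: SequenceRecord,
    structure: str,
    annotations: Sequence[HelixAnnotation],
) -> PairTable:
    """Match brackets into :class:`BasePair` rows labelled by helix.

    Every matched bracket pair is labelled with the helix whose annotated
    interval contains its 5' column; its 3' column must fall in the same
    helix's intervals, otherwise the annotation splits a pair across helices
    and the input is rejected.  Pairs outside all annotations are ``OTHER``.
    """
    check_dot_bracket(structure)
    validate_annotations(annotations)
    if len(structure) != len(sequence.residues):
        raise UsageError(
            f"structure length {len(structure)} != sequence length "
            f"{len(sequence.residues)} for {sequence.id!r}"
        )
    for ann in annotations:
        if max(ann.columns()) > len(sequence.residues):
            raise AnnotationError(
                f"annotation {ann.helix_name} exceeds sequence length"
            )

    pairs: list[BasePair] = []
    stack: list[int] = []
    for col, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(col)
        elif ch == ")":
            i = stack.pop()
            helix5 = _helix_of(i, annotations)
            helix3 = _helix_of(col, annotations)
            if helix5 != helix3:
                raise AnnotationError(
                    f"pair ({i},{col}) split across helices "
                    f"{helix5 or 'OTHER'} / {helix3 or 'OTHER'}"
                )
            pairs.append(
                BasePair(
                    five_prime_pos=i,
                    three_prime_pos=col,
                    five_prime_base=sequence.residues[i - 1],
                    three_prime_base=sequence.residues[col - 1],
                    helix=helix5 or "OTHER",
                )
            )
    pairs.sort(key=lambda p: p.five_prime_pos)
    return PairTable(
        sequence_id=sequence.id,
        length=len(sequence.residues),
        pairs=pairs,
        annotations=tuple(annotations),
    )


def consensus_pairing(
    tables: Sequence[PairTable], threshold: float = 0.5
) -> PairTable:
    """Majority-rule consensus of per-strain pair tables.

    A pair (i, j) enters the consensus iff the same two alignment columns are
    paired in at least ``threshold`` of the tables (ties at the threshold are
    retained).  Consensus pairs inherit the majority helix label, broken
    deterministically by the canonical helix order.
    """
    if len(tables) < 2:
        raise UsageError("consensus needs at least 2 pair tables")
    if not (0 < threshold <= 1):
        raise UsageError(f"threshold {threshold} outside (0, 1]")
    lengths = {t.length for t in tables}
    if len(lengths) > 1:
        raise CrossReferenceError(
            f"pair tables on different axes: lengths {sorted(lengths)}"
        )

    counts: Counter[tuple[int, int]] = Counter()
    helix_votes: dict[tuple[int, int], Counter[str]] = {}
    for table in tables:
        for p in table.pairs:
            if p.status != PAIRED:
                continue
            key = (p.five_prime_pos, p.three_prime_pos)
            counts[key] += 1
            helix_votes.setdefault(key, Counter())[p.helix] += 1

    n = len(tables)
    helix_rank = {name: i for i, name in enumerate(HELIX_NAMES + ("OTHER",))}
    consensus: list[BasePair] = []
    # small epsilon so that e.g. 2/3 >= 0.6666666666666666 holds despite rounding
    for (i, j), c in sorted(counts.items()):
        if c / n + 1e-12 >= threshold:
            votes = helix_votes[(i, j)]
            best = max(votes, key=lambda h: (votes[h], -helix_rank[h]))
            consensus.append(
                BasePair(
                    five_prime_pos=i,
                    three_prime_pos=j,
                    five_prime_base=None,
                    three_prime_base=None,
                    helix=best,
                )
            )
    return PairTable(
        sequence_id="consensus",
        length=tables[0].length,
        pairs=consensus,
        annotations=tables[0].annotations,
    )
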