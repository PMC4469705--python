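"""Readers and writers for the file dialects the pipeline touches.

Formats: FASTA (aligned or unaligned, via Biopython), Vienna-style dot-bracket
structure files (one ``>id`` header plus one structure line per record), a
helix-annotation TSV sidecar, Newick trees (via scikit-bio), and CSV matrices.

The internal alphabet is RNA: ``T`` is transcribed to ``U`` on input and the
fact is recorded on the record so output can restore the original alphabet.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .errors import (
    AlignmentError,
    CrossReferenceError,
    FormatError,
    StructureError,
    UsageError,
)

#: Residue characters accepted in sequence records: RNA bases, gap, and the
#: IUPAC ambiguity letters.
RNA_ALPHABET = set("ACGU-") | set("NRYSWKMBDHV")

HELIX_NAMES = ("STEM", "HI", "HII", "HIII", "HIV")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, internally RNA, optionally gapped.

    ``was_dna`` records whether the source spelled the sequence with T so
    that writers can restore the original alphabet.
    """

    id: str
    residues: str
    was_dna: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HelixAnnotation:
    """Named helix with its 5' and 3' strand intervals on the alignment.

    Intervals are 1-based inclusive ``(start, end)`` column ranges; the 5'
    interval must lie entirely left of the 3' interval.  For hairpin helices
    the two intervals are the two arms; for the 5.8S/LSU stem they are the
    flanking arms that enclose the whole spacer.
    """

    helix_name: str
    five_prime_range: tuple[int, int]
    three_prime_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.helix_name not in HELIX_NAMES:
            raise FormatError(
                f"helix name {self.helix_name!r} not one of {HELIX_NAMES}"
            )
        for lo, hi in (self.five_prime_range, self.three_prime_range):
            if not (1 <= lo <= hi):
                raise FormatError(
                    f"helix {self.helix_name}: invalid interval ({lo}, {hi})"
                )
        if self.five_prime_range[1] >= self.three_prime_range[0]:
            raise FormatError(
                f"helix {self.helix_name}: 5' range must lie entirely left of 3' range"
            )

    def columns(self) -> set[int]:
        return set(range(self.five_prime_range[0], self.five_prime_range[1] + 1)) | set(
            range(self.three_prime_range[0], self.three_prime_range[1] + 1)
        )


def validate_annotations(annotations: Sequence[HelixAnnotation]) -> None:
    """Reject annotation sets whose helix intervals overlap."""
    seen: dict[int, str] = {}
    for ann in annotations:
        for col in ann.columns():
            if col in seen and seen[col] != ann.helix_name:
                raise FormatError(
                    f"column {col} claimed by both {seen[col]} and {ann.helix_name}"
                )
            seen[col] = ann.helix_name


def _to_rna(raw: str) -> tuple[str, bool]:
    up = raw.upper()
    was_dna = "T" in up
    return up.replace("T", "U"), was_dna


def read_fasta(path: str | Path, aligned: bool = True) -> list[SequenceRecord]:
    """Read FASTA into records, in file order, transcribing T to U.

    With ``aligned=True`` all residue strings must have equal length.
    Duplicate ids and empty files are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues, was_dna = _to_rna(str(rec.seq))
        records.append(SequenceRecord(rec.id, residues, was_dna))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"aligned FASTA {path} has unequal lengths {sorted(lengths)}"
            )
    return records


# Alias matching the aligned-input entry point used by the pipeline stages.
def read_aligned_fasta(path: str | Path) -> list[SequenceRecord]:
    return read_fasta(path, aligned=True)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records, restoring the DNA alphabet where the source used it."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues.replace("U", "T") if rec.was_dna else rec.residues
            fh.write(f">{rec.id}\n{seq}\n")


def check_dot_bracket(structure: str) -> None:
    """Validate a dot-bracket string: balanced, nested, no pseudoknots.

    Allowed characters are ``(``, ``)``, ``.`` and ``-`` (gap column).
    Bracket layers beyond one (``[]{}<>`` or letters) are rejected because the
    four-helix ITS-2 consensus is strictly nested.
    """
    bad = set(structure) - set("().-")
    if bad:
        raise StructureError(
            f"unsupported structure characters {sorted(bad)!r} (pseudoknots rejected)"
        )
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureError("unbalanced brackets: ')' without '('")
    if depth != 0:
        raise StructureError(f"unbalanced brackets: {depth} unclosed '('")


def read_structure_file(
    path: str | Path,
    sequences: Sequence[SequenceRecord],
    aligned: bool = True,
) -> dict[str, str]:
    """Read a Vienna-style dot-bracket file keyed to ``sequences``.

    Each record is a ``>id`` header followed by one structure line.  In
    aligned mode the structure must match the aligned sequence length and
    carry ``-`` exactly at the sequence's gap columns; in unaligned mode it
    must match the ungapped length.
    """
    by_id = {rec.id: rec for rec in sequences}
    structures: dict[str, str] = {}
    current: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].strip()
            continue
        if current is None:
            raise FormatError(f"structure line before any '>' header in {path}")
        if current in structures:
            raise FormatError(f"duplicate structure for id {current!r}")
        if current not in by_id:
            raise CrossReferenceError(
                f"structure id {current!r} has no matching sequence"
            )
        check_dot_bracket(line)
        seq = by_id[current]
        expected = len(seq.residues) if aligned else len(seq.ungapped)
        if len(line) != expected:
            raise StructureError(
                f"structure length {len(line)} != sequence length {expected} "
                f"for {current!r}"
            )
        if aligned:
            for i, (s, c) in enumerate(zip(seq.residues, line), start=1):
                if (s == "-") != (c == "-"):
                    raise StructureError(
                        f"gap mismatch at column {i} between sequence and "
                        f"structure of {current!r}"
                    )
        structures[current] = line
        current = None
    if not structures:
        raise FormatError(f"no structures in {path}")
    return structures


def write_structure_file(structures: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, struct in structures.items():
            fh.write(f">{sid}\n{struct}\n")


_HELIX_TSV_COLUMNS = ["helix_name", "five_start", "five_end", "three_start", "three_end"]


def read_helix_tsv(path: str | Path) -> list[HelixAnnotation]:
    """Read the helix-annotation sidecar (TSV with 1-based inclusive columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_HELIX_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"helix TSV missing columns {sorted(missing)}")
    annotations = [
        HelixAnnotation(
            str(row.helix_name),
            (int(row.five_start), int(row.five_end)),
            (int(row.three_start), int(row.three_end)),
        )
        for row in df.itertuples()
    ]
    validate_annotations(annotations)
    return annotations


def write_helix_tsv(annotations: Sequence[HelixAnnotation], path: str | Path) -> None:
    rows = [
        {
            "helix_name": a.helix_name,
            "five_start": a.five_prime_range[0],
            "five_end": a.five_prime_range[1],
            "three_start": a.three_prime_range[0],
            "three_end": a.three_prime_range[1],
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_HELIX_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with full-precision branch lengths.

    Labels containing Newick metacharacters are quoted by the writer.  A
    single-leaf tree is rejected: it carries no topology.
    """
    n_tips = tree.count(tips=True)
    if n_tips < 2:
        raise UsageError(f"tree has {n_tips} leaf/leaves; need at least 2")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise UsageError("negative branch length in tree")
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")


def write_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
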