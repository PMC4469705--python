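"""CBC/HCBC classification, pairwise matrices, species delimitation, and the
p-distance / K-over-theta diagnostics.

A compensatory base change (CBC) replaces both partners of a retained base
pair (e.g. A-U -> G-C); a hemi-CBC (HCBC) replaces exactly one partner
(e.g. G-C -> G.U).  Under the standard CBC species criterion, one or more
CBCs in the conserved ITS-2 region separate species: strains are grouped
into species as connected components of the zero-CBC relation, with
non-transitive triples flagged rather than failing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from math import isnan
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import (
    ABSENT_CODE,
    Barcode,
    MISMATCH_CODE,
    PAIR_FROM_CODE,
    UNKNOWN_CODE,
    VALID_CODES,
)
from .errors import CrossReferenceError, UndefinedDistanceError, UsageError
from .io_formats import SequenceRecord


class ChangeClass(Enum):
    IDENTICAL = "identical"
    CBC = "CBC"
    HCBC = "HCBC"
    NOT_COMPARABLE = "not_comparable"


def classify_code_pair(a: int, b: int) -> ChangeClass:
    """Classify one barcode position between two strains.

    Both codes in 1-6: expand to ordered nucleotide pairs and count differing
    partners (2 -> CBC, 1 -> HCBC, 0 -> identical).  Codes 7 (mismatch), 8
    (deletion/unpaired) and 0 (ambiguity) are non-diagnostic: equal 7-7 or
    8-8 positions are identical-by-convention and anything else involving
    them is not comparable.  Symmetric in its arguments.
    """
    for code in (a, b):
        if code not in VALID_CODES:
            raise UsageError(f"code {code!r} outside the barcode alphabet 0-8")
    if a == b:
        if a in (MISMATCH_CODE, ABSENT_CODE):
            return ChangeClass.IDENTICAL
        if a == UNKNOWN_CODE:
            return ChangeClass.NOT_COMPARABLE
        return ChangeClass.IDENTICAL
    if a not in PAIR_FROM_CODE or b not in PAIR_FROM_CODE:
        return ChangeClass.NOT_COMPARABLE
    pa, pb = PAIR_FROM_CODE[a], PAIR_FROM_CODE[b]
    diffs = (pa[0] != pb[0]) + (pa[1] != pb[1])
    return ChangeClass.CBC if diffs == 2 else ChangeClass.HCBC


@dataclass
class CbcMatrix:
    """Strain-by-strain CBC (upper triangle) and HCBC (lower triangle) counts.

    Both underlying count matrices are symmetric; the triangle convention
    only governs the combined tabular export, mirroring the usual published
    layout (upper right = CBCs, lower left = HCBCs).
    """

    ids: list[str]
    cbc: np.ndarray
    hcbc: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name, m in (("cbc", self.cbc), ("hcbc", self.hcbc)):
            if m.shape != (n, n):
                raise UsageError(f"{name} matrix shape {m.shape} != ({n}, {n})")
            if (m < 0).any() or not np.array_equal(m, m.T):
                raise UsageError(f"{name} matrix must be symmetric and non-negative")
            if np.diag(m).any():
                raise UsageError(f"{name} matrix must have a zero diagonal")

    def cbc_between(self, a: str, b: str) -> int:
        return int(self.cbc[self.ids.index(a), self.ids.index(b)])

    def hcbc_between(self, a: str, b: str) -> int:
        return int(self.hcbc[self.ids.index(a), self.ids.index(b)])

    def combined_frame(self) -> pd.DataFrame:
        """Single table: CBC counts above the diagonal, HCBCs below."""
        combined = np.triu(self.cbc, k=1) + np.tril(self.hcbc, k=-1)
        return pd.DataFrame(combined, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.combined_frame().to_csv(path)


@dataclass
class SpeciesPartition:
    """Blocks of strains plus any zero-CBC transitivity violations found."""

    blocks: list[list[str]]
    conflict_flags: list[tuple[str, str, str]] = field(default_factory=list)

    def block_of(self) -> dict[str, str]:
        return {s: f"species_{i + 1}" for i, block in enumerate(self.blocks) for s in block}

    def as_mapping(self) -> dict[str, str]:
        return self.block_of()


def cbc_hcbc_matrix(barcodes: Sequence[Barcode]) -> CbcMatrix:
    """Count CBC and HCBC positions for every strain pair.

    Positions classified not-comparable (either code in {0, 7, 8} unless both
    equal) contribute to neither count.
    """
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise CrossReferenceError(
            f"barcodes on different position axes: lengths {sorted(lengths)}"
        )
    n = len(barcodes)
    cbc = np.zeros((n, n), dtype=int)
    hcbc = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        n_cbc = n_hcbc = 0
        for a, b in zip(barcodes[i].codes, barcodes[j].codes):
            cls = classify_code_pair(a, b)
            if cls is ChangeClass.CBC:
                n_cbc += 1
            elif cls is ChangeClass.HCBC:
                n_hcbc += 1
        cbc[i, j] = cbc[j, i] = n_cbc
        hcbc[i, j] = hcbc[j, i] = n_hcbc
    return CbcMatrix([b.strain_id for b in barcodes], cbc, hcbc)


def delimit_species(matrix: CbcMatrix) -> SpeciesPartition:
    """Group strains into species as zero-CBC connected components.

    Single linkage: strains joined by any chain of zero-CBC pairs share a
    species.  Triples (a, b, c) with CBC(a,b) = CBC(b,c) = 0 but CBC(a,c) > 0
    violate transitivity; they stay merged in one block and are recorded in
    ``conflict_flags``.
    """
    ids = matrix.ids
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if matrix.cbc[i, j] == 0:
            parent[find(i)] = find(j)

    blocks_by_root: dict[int, list[str]] = {}
    for i, sid in enumerate(ids):
        blocks_by_root.setdefault(find(i), []).append(sid)
    # deterministic block order: first strain occurrence
    blocks = sorted(blocks_by_root.values(), key=lambda blk: ids.index(blk[0]))

    conflicts: list[tuple[str, str, str]] = []
    for a, b, c in itertools.combinations(range(n), 3):
        trio = [(a, b, c), (b, a, c), (a, c, b)]  # middle element is the hinge
        for x, h, y in trio:
            if (
                matrix.cbc[x, h] == 0
                and matrix.cbc[h, y] == 0
                and matrix.cbc[x, y] > 0
            ):
                conflicts.append((ids[x], ids[h], ids[y]))
                break
    return SpeciesPartition(blocks=blocks, conflict_flags=conflicts)


def collapse_matrix(matrix: CbcMatrix, partition: SpeciesPartition) -> CbcMatrix:
    """Per-species matrix: maximum count over all cross-block strain pairs."""
    names = [f"species_{i + 1}" for i in range(len(partition.blocks))]
    k = len(names)
    idx = {s: i for i, s in enumerate(matrix.ids)}
    cbc = np.zeros((k, k), dtype=int)
    hcbc = np.zeros((k, k), dtype=int)
    for a, b in itertools.combinations(range(k), 2):
        pairs = [
            (idx[x], idx[y])
            for x in partition.blocks[a]
            for y in partition.blocks[b]
        ]
        cbc[a, b] = cbc[b, a] = max(matrix.cbc[i, j] for i, j in pairs)
        hcbc[a, b] = hcbc[b, a] = max(matrix.hcbc[i, j] for i, j in pairs)
    return CbcMatrix(names, cbc, hcbc)


def p_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Uncorrected p-distance over comparable columns.

    Columns where either sequence carries a gap or an ambiguity letter are
    excluded from both numerator and denominator.
    """
    if len(a.residues) != len(b.residues):
        raise CrossReferenceError(
            f"sequences {a.id!r}/{b.id!r} have different aligned lengths"
        )
    sa = np.frombuffer(a.residues.encode(), dtype="S1")
    sb = np.frombuffer(b.residues.encode(), dtype="S1")
    bases = np.frombuffer(b"ACGU", dtype="S1")
    plain = np.isin(sa, bases) & np.isin(sb, bases)
    compared = int(plain.sum())
    if compared == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {a.id!r} and {b.id!r}"
        )
    differing = int((sa[plain] != sb[plain]).sum())
    return differing / compared


def p_distance_matrix(records: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Symmetric matrix of pairwise uncorrected p-distances."""
    ids = [r.id for r in records]
    n = len(records)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = p_distance(records[i], records[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass(frozen=True)
class KThetaResult:
    """Between-block divergence K over within-block diversity theta.

    ``theta`` comes from the reference (first-named) block only; ``ratio`` is
    NaN when the reference block is a singleton or its diversity is zero.
    Ratios at or above the threshold flag candidate species pairs.
    """

    reference_block: str
    other_block: str
    K: float
    theta: float | None
    ratio: float
    flagged: bool

    @property
    def defined(self) -> bool:
        return not isnan(self.ratio)


def k_over_theta(
    partition: SpeciesPartition | Mapping[str, str],
    distances: pd.DataFrame,
    threshold: float = 4.0,
) -> list[KThetaResult]:
    """K/theta screen for every ordered block pair.

    K = mean between-block p-distance, theta = mean pairwise p-distance
    within the reference block.  The default threshold of 4 follows the
    population-genetic argument that sister clades whose divergence exceeds
    four times the within-clade diversity are unlikely to be one random-mating
    population.
    """
    if threshold <= 0:
        raise UsageError("K/theta threshold must be positive")
    if isinstance(partition, SpeciesPartition):
        block_map = partition.block_of()
    else:
        block_map = dict(partition)
    blocks: dict[str, list[str]] = {}
    for strain, name in block_map.items():
        blocks.setdefault(name, []).append(strain)

    results: list[KThetaResult] = []
    for ref_name, other_name in itertools.permutations(sorted(blocks), 2):
        ref, other = blocks[ref_name], blocks[other_name]
        K = float(np.mean([distances.loc[x, y] for x in ref for y in other]))
        if len(ref) < 2:
            theta = None
        else:
            theta = float(
                np.mean(
                    [distances.loc[x, y] for x, y in itertools.combinations(ref, 2)]
                )
            )
        if theta is None or theta == 0:
            ratio = float("nan")
        else:
            ratio = K / theta
        flagged = (not isnan(ratio)) and ratio >= threshold
        results.append(
            KThetaResult(ref_name, other_name, K, theta, ratio, flagged)
        )
    return results


def k_theta_frame(results: Sequence[KThetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_block": r.reference_block,
                "other_block": r.other_block,
                "K": r.K,
                "theta": r.theta,
                "ratio": r.ratio,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )


def partition_frame(partition: SpeciesPartition) -> pd.DataFrame:
    conflicted = {s for trio in partition.conflict_flags for s in trio}
    rows = [
        {"strain_id": s, "species": f"species_{i + 1}", "conflict": s in conflicted}
        for i, block in enumerate(partition.blocks)
        for s in block
    ]
    return pd.DataFrame(rows, columns=["strain_id", "species", "conflict"])
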