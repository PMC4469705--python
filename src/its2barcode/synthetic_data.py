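"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, each a pure function of its spec plus a seed:

* :func:`simulate_barcode_panel` emits an ITS-2-like strain panel — sequences,
  dot-bracket structures and a helix annotation — whose molecules carry a
  14-pair closing 5.8S/LSU stem, Helix I, Helix II with a fixed
  pyrimidine-pyrimidine mismatch, Helix III and Helix IV.  Species are
  separated by planted compensatory base changes (both partners substituted),
  within-species haplotype variants differ only by hemi-CBCs and by pairs
  removed from the distal end of Helix III (coded 8 downstream), so the
  planted partition is exactly recoverable.
* :func:`simulate_growth_curves` emits exponential fluorescence trajectories
  N0 * exp(mu t) with multiplicative lognormal noise over the six-salinity,
  four-replicate, 24-hour design.
* :func:`simulate_query_set` mutates reference sequences to controlled
  identity levels for screening-rule tests.

Every generator returns its truth tables alongside the data so downstream
stages can be checked without re-deriving anything: pairwise CBC/HCBC truth
is counted by brute-force nucleotide expansion of the code alphabet, not by
the classifier under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from string import ascii_lowercase
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import ABSENT_CODE, Barcode, MISMATCH_CODE, PAIR_FROM_CODE
from .errors import SpecError
from .io_formats import (
    HelixAnnotation,
    SequenceRecord,
    write_fasta,
    write_helix_tsv,
    write_structure_file,
)
from .screening import PanelEntry

# Deterministic substitution partners on the code alphabet: ``CBC_PARTNER``
# changes both nucleotides of the pair, ``HCBC_PARTNER`` exactly one.
CBC_PARTNER = {1: 3, 2: 4, 3: 1, 4: 2, 5: 2, 6: 1}
HCBC_PARTNER = {1: 5, 2: 6, 3: 5, 4: 6, 5: 3, 6: 4}


def expanded_change_count(a: int, b: int) -> int | None:
    """Brute-force oracle: differing partners between two expanded codes.

    Returns 0/1/2 for codes that both expand to real base pairs, or None for
    positions that are not comparable (mismatch, deletion, ambiguity).  This
    is the ground-truth route the generators use; it never calls the
    classifier under test.
    """
    if a in PAIR_FROM_CODE and b in PAIR_FROM_CODE:
        pa, pb = PAIR_FROM_CODE[a], PAIR_FROM_CODE[b]
        return (pa[0] != pb[0]) + (pa[1] != pb[1])
    return None


@dataclass(frozen=True)
class PanelSpec:
    """Layout of a synthetic strain panel.

    ``variants_per_species`` mirrors the observed haplotype structure (three
    variants in the first species, two in the last, ... — twelve haplotypes
    over seven species by default).  ``cbcs_between`` / ``hcbcs_between`` are
    the diagnostic positions planted per species; any two species then differ
    by the union of their diagnostic sets (at least one CBC, as the species
    concept requires).  Geometry quotas default to the canonical 73-position
    barcode: 14 stem + 5 Helix I + 11 Helix II + 43 Helix III pairs.
    """

    n_species: int = 7
    variants_per_species: tuple[int, ...] = (3, 1, 3, 1, 1, 1, 2)
    strains_per_variant: int = 1
    cbcs_between: int = 2
    hcbcs_between: int = 1
    stem_pairs: int = 14
    hi_pairs: int = 5
    hii_pairs: int = 11
    hiii_pairs: int = 43
    hiv_pairs: int = 4
    loop_len: int = 4
    spacer_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.variants_per_species) != self.n_species:
            raise SpecError("variants_per_species must list every species")
        if self.cbcs_between < 1:
            raise SpecError("at least one CBC must separate each species pair")
        if min(self.variants_per_species) < 1 or self.strains_per_variant < 1:
            raise SpecError("every species needs at least one variant and strain")

    @property
    def barcode_length(self) -> int:
        return self.stem_pairs + self.hi_pairs + self.hii_pairs + self.hiii_pairs


@dataclass
class PanelTruth:
    """Planted ground truth for one synthetic panel."""

    species_of: dict[str, str]
    haplotype_of: dict[str, str]
    codes: dict[str, tuple[int, ...]]
    cbc: pd.DataFrame
    hcbc: pd.DataFrame

    @property
    def n_species(self) -> int:
        return len(set(self.species_of.values()))

    @property
    def n_haplotypes(self) -> int:
        return len(set(self.haplotype_of.values()))


@dataclass
class SyntheticPanel:
    spec: PanelSpec
    records: list[SequenceRecord]
    structures: dict[str, str]
    annotations: list[HelixAnnotation]
    truth: PanelTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "panel.fasta",
            "structures": out / "panel.dbn",
            "helices": out / "helices.tsv",
            "truth_strains": out / "truth_strains.tsv",
            "truth_cbc": out / "truth_cbc.csv",
            "truth_hcbc": out / "truth_hcbc.csv",
        }
        write_fasta(self.records, paths["fasta"])
        write_structure_file(self.structures, paths["structures"])
        write_helix_tsv(self.annotations, paths["helices"])
        pd.DataFrame(
            {
                "strain_id": list(self.truth.species_of),
                "species": list(self.truth.species_of.values()),
                "haplotype": [
                    self.truth.haplotype_of[s] for s in self.truth.species_of
                ],
            }
        ).to_csv(paths["truth_strains"], sep="\t", index=False)
        self.truth.cbc.to_csv(paths["truth_cbc"])
        self.truth.hcbc.to_csv(paths["truth_hcbc"])
        return paths


def _panel_layout(spec: PanelSpec):
    """Column layout of the synthetic molecule and its helix annotation."""
    pos = 1
    segments: dict[str, tuple[int, int]] = {}

    def claim(name: str, width: int) -> None:
        nonlocal pos
        segments[name] = (pos, pos + width - 1)
        pos += width

    claim("stem5", spec.stem_pairs)
    claim("sp1", spec.spacer_len)
    claim("hi5", spec.hi_pairs)
    claim("hi_loop", spec.loop_len)
    claim("hi3", spec.hi_pairs)
    claim("sp2", spec.spacer_len)
    claim("hii5", spec.hii_pairs)
    claim("hii_loop", spec.loop_len)
    claim("hii3", spec.hii_pairs)
    claim("sp3", spec.spacer_len)
    claim("hiii5", spec.hiii_pairs)
    claim("hiii_loop", spec.loop_len)
    claim("hiii3", spec.hiii_pairs)
    claim("sp4", spec.spacer_len)
    claim("hiv5", spec.hiv_pairs)
    claim("hiv_loop", spec.loop_len)
    claim("hiv3", spec.hiv_pairs)
    claim("sp5", spec.spacer_len)
    claim("stem3", spec.stem_pairs)
    length = pos - 1

    annotations = [
        HelixAnnotation("STEM", segments["stem5"], segments["stem3"]),
        HelixAnnotation("HI", segments["hi5"], segments["hi3"]),
        HelixAnnotation("HII", segments["hii5"], segments["hii3"]),
        HelixAnnotation("HIII", segments["hiii5"], segments["hiii3"]),
        HelixAnnotation("HIV", segments["hiv5"], segments["hiv3"]),
    ]

    # barcode slot -> (5' column, 3' column), blocks ordered base-outward
    slot_columns: list[tuple[int, int]] = []
    for five_name, three_name, n in (
        ("stem5", "stem3", spec.stem_pairs),
        ("hi5", "hi3", spec.hi_pairs),
        ("hii5", "hii3", spec.hii_pairs),
        ("hiii5", "hiii3", spec.hiii_pairs),
    ):
        f_lo, _ = segments[five_name]
        _, t_hi = segments[three_name]
        for k in range(n):
            slot_columns.append((f_lo + k, t_hi - k))
    hiv_columns = [
        (segments["hiv5"][0] + k, segments["hiv3"][1] - k)
        for k in range(spec.hiv_pairs)
    ]
    return length, annotations, slot_columns, hiv_columns


def simulate_barcode_panel(spec: PanelSpec = PanelSpec()) -> SyntheticPanel:
    """Generate a strain panel with planted species/haplotype structure.

    The planted design: one backbone code series over the barcode slots (with
    the Helix II pyrimidine-pyrimidine mismatch fixed at code 7 for all
    strains); each species carries CBC substitutions at its own diagnostic
    slots (drawn from the stem/HI/HII blocks) and hemi-CBC substitutions at
    slots in the proximal part of Helix III; within-species variants remove
    pairs from the distal end of Helix III only, which downstream coding
    turns into trailing code-8 positions without shifting any other slot.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.barcode_length
    # the pyrimidine-pyrimidine mismatch sits inside Helix II (6th pair when
    # the helix is long enough)
    mismatch_slot = spec.stem_pairs + spec.hi_pairs + min(6, spec.hii_pairs)
    hiii_start = spec.stem_pairs + spec.hi_pairs + spec.hii_pairs + 1

    max_tail = max(v - 1 for v in spec.variants_per_species)
    cbc_pool = [
        s for s in range(1, hiii_start) if s != mismatch_slot
    ]  # stem + HI + HII slots
    hcbc_pool = list(range(hiii_start, L - max_tail + 1))  # proximal Helix III
    need_cbc = spec.n_species * spec.cbcs_between
    need_hcbc = spec.n_species * spec.hcbcs_between
    if need_cbc > len(cbc_pool) or need_hcbc > len(hcbc_pool):
        raise SpecError(
            f"spec plants {need_cbc} CBC and {need_hcbc} HCBC slots but only "
            f"{len(cbc_pool)}/{len(hcbc_pool)} are available"
        )
    if spec.hiii_pairs <= max_tail:
        raise SpecError("Helix III too short for the requested variant deletions")

    cbc_slots = rng.choice(cbc_pool, size=need_cbc, replace=False)
    hcbc_slots = rng.choice(hcbc_pool, size=need_hcbc, replace=False)

    backbone = rng.integers(1, 7, size=L)  # codes 1..6
    backbone[mismatch_slot - 1] = MISMATCH_CODE

    species_codes: list[np.ndarray] = []
    for s in range(spec.n_species):
        codes = backbone.copy()
        for slot in cbc_slots[s * spec.cbcs_between : (s + 1) * spec.cbcs_between]:
            codes[slot - 1] = CBC_PARTNER[int(codes[slot - 1])]
        for slot in hcbc_slots[s * spec.hcbcs_between : (s + 1) * spec.hcbcs_between]:
            codes[slot - 1] = HCBC_PARTNER[int(codes[slot - 1])]
        species_codes.append(codes)

    length, annotations, slot_columns, hiv_columns = _panel_layout(spec)

    # one shared unpaired backbone so strains differ only at planted slots
    unpaired = rng.choice(list("ACGU"), size=length)
    paired_cols = {c for cols in slot_columns + hiv_columns for c in cols}

    records: list[SequenceRecord] = []
    structures: dict[str, str] = {}
    species_of: dict[str, str] = {}
    haplotype_of: dict[str, str] = {}
    codes_of: dict[str, tuple[int, ...]] = {}

    for s in range(spec.n_species):
        n_variants = spec.variants_per_species[s]
        for v in range(n_variants):
            variant_codes = species_codes[s].copy()
            for slot in range(L - v, L):  # remove v distal Helix III pairs
                variant_codes[slot] = ABSENT_CODE
            letter = ascii_lowercase[v] if n_variants > 1 else ""
            for r in range(spec.strains_per_variant):
                strain = f"sp{s + 1}{letter or 'a'}_{r + 1}"
                seq = unpaired.copy()
                struct = np.array(["."] * length)
                for slot, (c5, c3) in enumerate(slot_columns, start=1):
                    code = int(variant_codes[slot - 1])
                    if code == ABSENT_CODE:
                        continue  # pair removed: columns stay unpaired
                    if code == MISMATCH_CODE:
                        b5, b3 = "U", "U"  # pyrimidine-pyrimidine
                    else:
                        b5, b3 = PAIR_FROM_CODE[code]
                    seq[c5 - 1], seq[c3 - 1] = b5, b3
                    struct[c5 - 1], struct[c3 - 1] = "(", ")"
                for c5, c3 in hiv_columns:
                    b5, b3 = PAIR_FROM_CODE[int(rng.integers(1, 7))]
                    seq[c5 - 1], seq[c3 - 1] = b5, b3
                    struct[c5 - 1], struct[c3 - 1] = "(", ")"
                records.append(SequenceRecord(strain, "".join(seq)))
                structures[strain] = "".join(struct)
                species_of[strain] = f"species_{s + 1}"
                haplotype_of[strain] = f"BC-{s + 1}{letter}"
                codes_of[strain] = tuple(int(c) for c in variant_codes)

    # Helix IV differs freely between strains; it is outside the barcode.
    ids = [r.id for r in records]
    n = len(ids)
    cbc_truth = np.zeros((n, n), dtype=int)
    hcbc_truth = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            n_cbc = n_hcbc = 0
            for a, b in zip(codes_of[ids[i]], codes_of[ids[j]]):
                diffs = expanded_change_count(a, b)
                if diffs == 2:
                    n_cbc += 1
                elif diffs == 1:
                    n_hcbc += 1
            cbc_truth[i, j] = cbc_truth[j, i] = n_cbc
            hcbc_truth[i, j] = hcbc_truth[j, i] = n_hcbc

    truth = PanelTruth(
        species_of=species_of,
        haplotype_of=haplotype_of,
        codes=codes_of,
        cbc=pd.DataFrame(cbc_truth, index=ids, columns=ids),
        hcbc=pd.DataFrame(hcbc_truth, index=ids, columns=ids),
    )
    return SyntheticPanel(spec, records, structures, annotations, truth)


# --- growth curves ---------------------------------------------------------

#: Planted per-day rate profiles spanning the three observed response types.
DEFAULT_RATE_PROFILES: dict[str, dict[float, float]] = {
    "syn-sensitive": {0.2: 1.2, 0.6: 0.4, 1.2: 0.2, 1.8: 0.1, 2.5: 0.06, 3.3: 0.05},
    "syn-mid-high": {0.2: 1.1, 0.6: 1.0, 1.2: 0.8, 1.8: 0.5, 2.5: 0.4, 3.3: 0.35},
    "syn-mid-low": {0.2: 1.0, 0.6: 0.95, 1.2: 0.9, 1.8: 0.7, 2.5: 0.6, 3.3: 0.55},
    "syn-robust": {0.2: 0.9, 0.6: 0.92, 1.2: 0.9, 1.8: 0.85, 2.5: 0.82, 3.3: 0.8},
}


@dataclass(frozen=True)
class GrowthSpec:
    """Design of a synthetic growth experiment.

    Defaults mirror the study design: six salinities, four replicates,
    fluorescence sampled every 24 h for ten days, 5 % multiplicative
    lognormal noise.  ``profiles`` maps strain -> salinity -> planted mu_max
    in per-day units.
    """

    profiles: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: DEFAULT_RATE_PROFILES
    )
    replicates: int = 4
    times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 241, 24))
    n0: float = 100.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.times_h:
            raise SpecError("time grid is empty")
        if self.replicates < 1:
            raise SpecError("need at least one replicate")
        for strain, profile in self.profiles.items():
            if any(mu < 0 for mu in profile.values()):
                raise SpecError(f"negative planted rate for {strain!r}")


@dataclass
class SyntheticGrowth:
    spec: GrowthSpec
    data: pd.DataFrame  # long format: strain_id, salinity, replicate, time_h, fluorescence
    planted_mu: pd.DataFrame  # strain x salinity
    planted_sensitivity: pd.Series  # strain -> percentage, reference = 100

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "growth": out / "growth.csv",
            "truth_mu": out / "truth_mu.csv",
            "truth_sensitivity": out / "truth_sensitivity.csv",
        }
        self.data.to_csv(paths["growth"], index=False)
        self.planted_mu.to_csv(paths["truth_mu"])
        self.planted_sensitivity.rename("sensitivity").to_csv(
            paths["truth_sensitivity"]
        )
        return paths


def simulate_growth_curves(
    spec: GrowthSpec = GrowthSpec(),
    reference_id: str | None = None,
    optimal: Sequence[float] = (0.2, 0.6),
    pessimal: Sequence[float] = (1.8, 2.5, 3.3),
) -> SyntheticGrowth:
    """Exponential trajectories N0 exp(mu t) with multiplicative noise.

    The planted sensitivity truth is computed arithmetically from the planted
    rates (extremal decline relative to the reference strain, which defaults
    to the strain with the largest planted decline).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times_h)
    rows = []
    for strain, profile in spec.profiles.items():
        for salinity, mu_day in profile.items():
            mu_h = mu_day / 24.0
            for rep in range(1, spec.replicates + 1):
                noise = (
                    np.exp(rng.normal(0.0, spec.noise_sigma, size=len(times)))
                    if spec.noise_sigma > 0
                    else np.ones(len(times))
                )
                values = spec.n0 * np.exp(mu_h * times) * noise
                rows.extend(
                    {
                        "strain_id": strain,
                        "salinity": salinity,
                        "replicate": rep,
                        "time_h": float(t),
                        "fluorescence": float(v),
                    }
                    for t, v in zip(times, values)
                )
    data = pd.DataFrame(rows)

    planted_mu = pd.DataFrame(
        {strain: dict(profile) for strain, profile in spec.profiles.items()}
    ).T.sort_index(axis=1)
    covered = all(
        any(s in profile for s in optimal) and any(s in profile for s in pessimal)
        for profile in spec.profiles.values()
    )
    if covered:
        declines = {
            strain: max(
                0.0,
                max(profile[s] for s in optimal if s in profile)
                - min(profile[s] for s in pessimal if s in profile),
            )
            for strain, profile in spec.profiles.items()
        }
        if reference_id is None:
            reference_id = max(declines, key=lambda s: declines[s])
        if declines[reference_id] == 0:
            raise SpecError("planted reference strain has zero decline")
        sensitivity = pd.Series(
            {s: 100.0 * d / declines[reference_id] for s, d in declines.items()}
        )
    else:
        # profiles that do not span both salinity ranges carry no
        # sensitivity truth (rate-recovery studies)
        sensitivity = pd.Series(dtype=float)
    return SyntheticGrowth(spec, data, planted_mu, sensitivity)


# --- query panels ----------------------------------------------------------


@dataclass
class SyntheticQuerySet:
    queries: list[SequenceRecord]
    barcodes: dict[str, Barcode]
    truth: pd.DataFrame  # query_id, source_id, target/achieved identity, class

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"queries": out / "queries.fasta", "truth": out / "truth_queries.tsv"}
        write_fasta(self.queries, paths["queries"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _expected_class(
    achieved: float,
    has_barcode: bool,
    planted_cbc: bool,
    min_identity: float,
    v4_strict: float,
) -> str:
    if achieved >= 100.0:
        return "species_match"
    if achieved >= min_identity:
        if has_barcode:
            return "putative_new_lineage" if planted_cbc else "same_species_candidate"
        return (
            "same_species_candidate" if achieved >= v4_strict else "genus_level_only"
        )
    return "unassigned"


def simulate_query_set(
    panel: Sequence[PanelEntry],
    identities: Sequence[float],
    seed: int = 0,
    with_barcodes: bool = True,
    plant_cbc: bool = False,
    min_identity: float = 97.0,
    v4_strict: float = 99.0,
) -> SyntheticQuerySet:
    """Queries mutated to target identity levels, with rule-derived truth.

    Substitutions are placed only at columns where every reference agrees
    (and are forced to a base none of them carries is not required — any
    different base strictly lowers identity to all references by the same
    amount), so the achieved identity to the best hit is exactly
    (L - k) / L.  The expected class in the truth table is evaluated from
    the achieved identity with the documented threshold ladder.  With
    ``plant_cbc`` the emitted query barcode carries one compensatory change
    at a slot where all panel barcodes agree, so the truth is a putative new
    lineage whenever the identity stays at or above the minimum.
    """
    if not panel:
        raise SpecError("reference panel is empty")
    rng = np.random.default_rng(seed)
    refs = [e.record.ungapped for e in panel]
    L = len(refs[0])
    if any(len(r) != L for r in refs):
        raise SpecError("panel references must share one region length")
    shared_cols = [
        i for i in range(L) if len({r[i] for r in refs}) == 1 and refs[0][i] in "ACGU"
    ]

    barcode_ok = with_barcodes and all(e.barcode is not None for e in panel)
    cbc_slot = None
    if barcode_ok and plant_cbc:
        panel_codes = [e.barcode.codes for e in panel]
        for slot in range(len(panel_codes[0])):
            column = {codes[slot] for codes in panel_codes}
            if len(column) == 1 and next(iter(column)) in CBC_PARTNER:
                cbc_slot = slot
                break
        if cbc_slot is None:
            raise SpecError("no shared codeable slot to plant a query CBC")

    queries: list[SequenceRecord] = []
    barcodes: dict[str, Barcode] = {}
    rows = []
    for q_index, target in enumerate(identities):
        if not (0 < target <= 100):
            raise SpecError(f"target identity {target} outside (0, 100]")
        entry = panel[q_index % len(panel)]
        k = round(L * (1 - target / 100.0))
        achieved = 100.0 * (L - k) / L
        if abs(achieved - target) > 0.5:
            raise SpecError(
                f"target identity {target}% unreachable on length {L} "
                f"(nearest {achieved:.2f}%)"
            )
        if k > len(shared_cols):
            raise SpecError(
                f"target identity {target}% needs {k} substitutions but only "
                f"{len(shared_cols)} shared columns exist"
            )
        seq = list(entry.record.ungapped)
        for col in rng.choice(shared_cols, size=k, replace=False):
            current = seq[col]
            seq[col] = str(rng.choice([b for b in "ACGU" if b != current]))
        qid = f"query_{q_index + 1}_t{target:g}"
        queries.append(SequenceRecord(qid, "".join(seq)))

        planted = False
        if barcode_ok:
            codes = list(entry.barcode.codes)
            if plant_cbc and k > 0:
                codes[cbc_slot] = CBC_PARTNER[codes[cbc_slot]]
                planted = True
            barcodes[qid] = Barcode(qid, tuple(codes))

        rows.append(
            {
                "query_id": qid,
                "source_id": entry.record.id,
                "target_identity": target,
                "achieved_identity": achieved,
                "n_substitutions": k,
                "planted_cbc": planted,
                "expected_class": _expected_class(
                    achieved, barcode_ok, planted, min_identity, v4_strict
                ),
            }
        )
    return SyntheticQuerySet(queries, barcodes, pd.DataFrame(rows))
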