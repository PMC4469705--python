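# Methods

## The barcode model

ITS-2 folds into a conserved secondary structure: a 5.8S/LSU closing stem
and four helices, of which Helix II carries a pyrimidine-pyrimidine mismatch
and Helix III is the longest and most conserved. The barcode region is the
structurally conserved core — first 14 stem pairs, first 5 Helix I pairs,
first 11 Helix II pairs, all Helix III pairs — coded position-by-position by
the ordered base pair (A-U = 1, U-A = 2, G-C = 3, C-G = 4, G·U = 5,
U·G = 6, other paired combinations = 7, deletion/unpaired = 8).

Two modelling choices deserve justification:

* **The consensus fixes the axis.** "All Helix III pairs" is only
  well-defined against a reference; we take a majority-rule consensus
  pairing (threshold 0.5, ties retained) over the per-strain pair tables.
  Each strain is then coded against per-helix quotas — 14/5/11/consensus —
  with shortfalls padded by code 8 at the distal end of the block. This
  makes all barcodes share one position axis with no re-alignment step, at
  the cost that a strain whose Helix III genuinely has *extra* pairs beyond
  the consensus contributes nothing from them. Published consensus
  structures in this field were built with alignment tools plus manual
  editing; majority rule is the transparent, reproducible stand-in, so
  exact reproduction of a hand-curated consensus is not guaranteed.
* **Ambiguity codes to `?`, not 7.** Code 7 asserts a real, sequenced
  mismatch pairing; an N cannot assert that. Unknown positions are excluded
  from CBC counting and from code distances.

## CBC classification and delimitation

A position is a CBC between two strains when both codes are in 1–6 and both
implied nucleotides differ; an HCBC when exactly one differs. Positions
involving 7, 8 or `?` are never diagnostic (equal 7-7/8-8 positions are
identical by convention): within-species variants frequently differ only by
missing distal pairs, and treating 8-vs-pair as evidence would split
haplotypes into spurious species.

Species are single-linkage connected components of the zero-CBC relation.
Zero-CBC is not guaranteed transitive; rather than failing, triples
(a, b, c) with CBC(a,b) = CBC(b,c) = 0 < CBC(a,c) stay merged and are
reported in `conflict_flags`, matching the species-as-lineage reading while
surfacing the ambiguity. Because published pairwise tables are per-species,
`collapse_matrix` also reports the species-level matrix as the maximum over
cross-block strain pairs (the most conservative collapse; the counting rule
for published tables is not stated anywhere we could follow).

K/θ uses uncorrected p-distances (columns with a gap or ambiguity in either
sequence excluded from numerator and denominator). θ is computed from the
reference block only and every ordered block pair is reported, so both
directions are visible; the candidate-species threshold defaults to 4,
following the population-genetics argument for that ratio in the
delimitation literature. Ratios are undefined (NaN, never an exception) for
singleton or zero-diversity reference blocks.

## Distance phylogeny

No canonical metric exists for number-coded barcodes, so the simplest
symmetric choice is used: normalized Hamming distance over comparable
positions, excluding positions with `?` in either strain and positions where
both strains lack the pair (8-8); 8-vs-pair counts as a difference.
Neighbor joining is implemented in-package because reproducibility demands a
pinned tie-break (lowest row/column index in the current taxon order) and a
stated negative-branch policy (clamped to zero, deficit logged); the test
suite cross-checks topologies against scikit-bio's independent NJ and
verifies exact topology and path-length recovery on additive matrices.

## Screening

Screening replaces a live database query with deterministic global pairwise
alignment (match +1, mismatch −1, gap open −2, gap extend −0.5) against a
user-supplied panel. Identity excludes terminal-overhang columns,
approximating the 100 %-coverage semantics of database hits; coverage is the
fraction of the query inside the overhang-free core; IUPAC ambiguity never
counts as a match (conservative: screening assumes accurate sequences).
The classification ladder: 100 % identity × 100 % coverage → species match;
≥ 97 % with barcode evidence → same-species candidate (0 CBCs) or putative
new lineage (≥ 1 CBC); sequence-only (V4-style) evidence in [97 %, 99 %) →
genus level only, at ≥ 99 % → same-species candidate (forced by
monotonicity: more identity can never demote a call); below 97 % →
unassigned, or foreign taxon when the query's barcode carries a CBC at the
configured genus-diagnostic positions. The default V4 (columns 616–845) and
V9 (1631–1737) intervals span 230 and 107 columns; the marker literature
sometimes quotes 229 bp and 106 bp for these regions — the column ranges are
treated as authoritative and the one-column discrepancy is noted here rather
than silently corrected.

## Growth fitting and salinity sensitivity

μ_max is fitted by least squares on log-fluorescence over every contiguous
window of ≥ 4 samples, keeping the steepest slope among windows with
R² ≥ 0.95 — a transparent replacement for unspecified "iterative
optimization" fitting, and robust to lag and stationary phases. Two known
properties: (i) a series with no qualifying window, or only non-positive
slopes, returns a flagged no-growth rate of 0 rather than an error; (ii) the
max-over-windows rule is upward-biased under noise — at 5 % multiplicative
lognormal noise on the default 11-point/24-h grid the median fitted rate
runs ≈ 3–4 % above truth, within the 5 % recovery bound the tests enforce
but worth remembering for low signal-to-noise data.

Sensitivity is the decline max(μ at 0.2, 0.6 %) − min(μ at 1.8, 2.5, 3.3 %),
floored at 0, as a percentage of the reference strain's decline (reference
= 100 by construction). The extremal reading is deliberate: the verbal
definition ("decline from the optimal to the pessimal condition") does not
pin which salinity anchors each end, and the extremal rule dominates every
specific pairing. Response classes (robust < 33 ≤ intermediately sensitive
< 66 ≤ sensitive) are configuration defaults — the class names are
observational, no numeric boundaries are canonical. Cell-shape summaries
use standard box-plot conventions (quartiles, 1.5×IQR whiskers; outliers
excluded from whiskers, retained in the data).

## Synthetic data: what it does and does not emulate

`simulate_barcode_panel` plants, on a uniform-random paired backbone, one
CBC-diagnostic slot set per species (drawn from the stem/HI/HII blocks) and
one HCBC set (proximal Helix III), with within-species variants created by
removing pairs from the *distal end* of Helix III only. End-removal is
load-bearing: removing an interior pair would shift the base-outward
ordering of every later pair and desynchronise the position axis, so the
planted truth would no longer be exact. Default scale mirrors the design
case: 7 species, 12 haplotypes (variant pattern 3/1/3/1/1/1/2), geometry
14/5/11/43 → 73 positions, ≥ 1 CBC between every species pair. Truth
CBC/HCBC counts are computed by brute-force nucleotide expansion of the code
alphabet — an independent route from the classifier under test.

What the generator does **not** model: realistic base composition (backbone
is uniform over A/C/G/U), indel evolution, alignment uncertainty (all
strains share one axis by construction), pseudoknots, within-helix bulges,
or folding errors. Passing the recovery tests therefore shows the pipeline
is exact under its own assumptions — clean structures on one axis — not that
it is robust to mis-folded or mis-aligned real data.

`simulate_growth_curves` draws N₀·exp(μt) trajectories with i.i.d.
multiplicative lognormal noise (σ = 0.05 default) on the 6-salinity ×
4-replicate × 24-h design; planted rate profiles (0.05–1.2 d⁻¹) span the
sensitive/intermediate/robust response types. It does not model lag or
stationary phases (tested separately with piecewise curves), autocorrelated
measurement error, or replicate-level batch effects.

`simulate_query_set` substitutes k = round(L·(1−t/100)) bases at columns
where all references agree, so achieved identity to the best hit is exactly
(L−k)/L; targets unreachable within ±0.5 % raise a spec error. Truth
classes are evaluated from the *achieved* identity (a 97 % target on a
230-base region yields 7 substitutions = 96.96 %, which is below the 97 %
threshold and therefore truth-labelled unassigned).

## Numerical choices

* Consensus threshold comparisons use a 1e-12 epsilon so exact fractions
  (2/3 ≥ 0.6667) behave as stated; ties at the threshold are retained.
* Identity thresholds compare with a 1e-9 epsilon so "100 %" is robust to
  float division.
* NJ final three-taxon branch lengths use the closed-form three-point
  solution; all agglomeration is O(n³) on dense numpy matrices — panels in
  this domain are tens of strains, far below any performance concern.
* Problem sizes in the acceptance script (20 panels, 200 NJ matrices,
  50 noise replicates, 5 identity targets × 2 CBC conditions × 5 panels)
  were chosen to estimate each rate stably while keeping a from-scratch run
  in the seconds range.

## Known limitations

* The consensus-quota coding cannot express pairs a strain has *beyond* the
  consensus Helix III; they are silently outside the barcode.
* Single-linkage delimitation is order-independent but can chain distinct
  lineages through intermediate zero-CBC strains; conflicts are flagged, not
  resolved.
* Screening alignment is exact global alignment — appropriate for panels of
  tens of references, not a database-scale search.
* The foreign-taxon call depends on user-configured genus-diagnostic
  positions; without them, low-identity queries are simply unassigned.
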