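# Methods

This note documents the models, parameter choices, and limitations behind
`cdr3scope`. Everything stated here is computed by the package's tests or
by `scripts/acceptance.py`; nothing is quoted from external runs.

## Sequence model

A VHH is represented as an amino-acid sequence with a per-position IMGT
annotation (position 1–128, optional insertion code, residue). The IMGT
partition used throughout is FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65,
FR3 66–104, CDR3 105–117, FR4 118–128. CDR3 loops longer than 13 residues
receive insertion codes at positions 111 (ascending letters) then 112
(descending letters), giving a loop-ordered, position-non-decreasing
numbering; shorter loops gap the middle of the 105–117 range. Insertions
inherit the region of their anchor position, so region slicing needs only
position membership.

### Cleaning filter

`filter_repertoire` applies, in a fixed order: (1) read count ≥ `min_count`
(default 5) — suppresses PCR/sequencing artifacts; (2) deduplication at the
amino-acid level — the highest-count representative is kept and the summed
count recorded as metadata, preserving abundance information without
changing the survivor's provenance; (3) CDR3-length z-score — the mean and
*sample* standard deviation are computed on the set that survives steps 1–2
and members with |z| ≥ `z_max` (default 2.5, strict inequality for
survival) are dropped. The order matters: deduplicating before the count
filter could rescue sequences whose duplicate counts sum past the
threshold; a unit test documents this on a crafted fixture.

Caveat: the z-filter is not strictly idempotent in general. Trimming a
near-normal sample at |z| < 2.5 shrinks the standard deviation by a few
percent, so a second pass can remove borderline survivors. On typical
discrete length data the survivor set is stable; the idempotence test uses
a fixture where no length falls in the shrink window.

### Biophysical scales

Net charge at pH 7.4 is a counting model: D, E → −1; R, K → +1; H → +0.1
(histidine's partial protonation); everything else 0. `X` contributes 0
with a warning; other non-standard letters are validation errors.
Hydropathy is the Kyte–Doolittle index averaged over the region (undefined,
reported as NaN, for empty regions). The seven-class residue grouping is
aliphatic {A,V,L,I,G,P}, aromatic {F,W,Y}, sulfur-containing {C,M},
hydroxyl {S,T}, basic {K,R,H}, acidic {D,E}, amine {N,Q}. Placing Y with
the aromatics (rather than hydroxyls) and G/P with the aliphatics is a
deliberate choice consistent with reading amine-class trends as N/Q-driven;
the mapping is a plain dict argument and can be overridden wholesale.

### Usage screens

Regional usage correlates each residue's per-sequence frequency within a
region against CDR3 length — the correlation is computed on all data
points, not on per-length aggregates. Positional usage tests, for each
(position, residue) cell, the presence/absence indicator across the
sequences occupying that position; since each sequence carries exactly one
residue at a position, this is equivalent to frequency-vs-length at that
position. Cells at positions occupied by fewer than `min_n` sequences
(default 100; tests use 20 at small n) are masked, monomorphic cells are
reported with undefined r, and never-observed residues are simply absent.
BH-FDR is applied over the whole tested family within a screen.

## Statistics layer

Pearson r uses the two-sided t-approximation (scipy). Mann–Whitney U is
two-tailed, with exact enumeration for min(n) ≤ 8 without ties and the
tie-corrected normal approximation otherwise. The variance-ratio statistic
is F = s₁²/s₂² with the numerator exactly as given by the caller (no
reordering — F < 1 is meaningful) and a two-sided p of 2·min(lower tail,
upper tail) on F(n₁−1, n₂−1). BH adjustment is the standard step-up
procedure (statsmodels); note that step-up adjustment is not idempotent, so
adjusted p-values must not be re-adjusted. Significance stars use half-open
bins ns (> 0.05), `*` (0.01, 0.05], `**` [0.001, 0.01], `***`
[0.0001, 0.001), `****` ≤ 0.0001; the conventional printed map is ambiguous
at exactly 0.01 and that boundary is closed into `**` here. Binned-mean
regression fits OLS to per-length mean values (unweighted by bin size) and
is for presentation only — reported correlations always use all points.

## Structure model

Structures are flat atom tables keyed by (chain, IMGT position, insertion
code). PDB ingestion (gemmi) uses model 1 only, drops waters/heteroatoms,
resolves alternate locations to the highest-occupancy conformer, and either
trusts IMGT renumbering in the file or applies an author→IMGT mapping table
from the chain map; unmapped VHH residues abort with a full list. Residue
order within a chain is file order, which defines sequence adjacency and
CDR3 loop order. DSSP labels (H,G,I,E,T,S,C) are ingested from
classic-format DSSP files, never computed.

* **Contacts.** Two residues are in contact when any atom pair lies within
  4 Å (KD-tree search; each record carries the minimum interatomic
  distance). Intra-domain contacts exclude residue pairs adjacent within ±1
  in chain order to suppress trivial backbone neighbours (configurable).
* **FR2_CDR3_Dis.** Residue "central coordinates" are unweighted heavy-atom
  centroids (crystal structures typically lack hydrogens). The metric is
  the minimum centroid distance between the position-42 residue and CDR3
  residues after trimming the loop's first and last two residues; loops
  shorter than 5 leave nothing to measure and yield NaN.
* **Conformation classes.** A Gaussian KDE (Scott's rule, 512-point grid
  spanning the data) over FR2_CDR3_Dis values; the threshold is the density
  minimum between the two highest local maxima, values below it are bent,
  at/above extended (ties labeled extended). The peaks count as distinct
  only if the trough dips below 0.8× the smaller peak — without this
  prominence rule, jagged KDEs of small unimodal samples split spuriously.
  A unimodal density yields no threshold: all values take one fallback
  class (bent if the peak is below 10 Å, a nominal midpoint between typical
  bent and extended centroid geometries) with a warning. At least 20 values
  are required.
* **SASA.** Shrake–Rupley point sampling on a deterministic golden-spiral
  sphere (default 960 points/atom, probe 1.4 Å) with a fixed per-element
  van der Waals radius table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, …),
  both configurable. Buried surface areas are monomer-SASA minus
  complex-SASA bookkeeping, total and per side; by construction
  interface BSA = paratope BSA + epitope BSA. Surface hydrophobicity is
  Σ residues SASA × hydropathy index over the monomeric VHH.
* **Interfaces.** Paratope/epitope at the 4 Å contact threshold; complexes
  with fewer than 6 epitope residues are flagged rejected and excluded from
  correlation input (guards against crystal-packing artifacts); the
  FR2-involved flag is ≥ 1 paratope residue in FR2. Structure-set
  redundancy removal drops exact amino-acid-identity duplicates of the VHH
  sequence (an identity-threshold cutoff would need an aligner and is out
  of scope).

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; they are deterministic given a seed and record every planted
effect in a ground-truth sidecar.

**Repertoires** (defaults: n = 10,000, species alpaca). CDR3 lengths are
drawn from a normal distribution, rounded and truncated at ≥ 5 residues
(natural loops run down to about 5 residues); the pre-truncation moments
are solved numerically so the realized mean/std match the recipe targets
(default 15.7 ± 4.6, the scale observed in alpaca-like repertoires). Four
germline profiles with weights 0.35/0.25/0.20/0.20 shift the length mean by
−2.5/+2.5/+1.0/0 residues and fix hallmark residues — the short-preferring
germline carries Y at IMGT 42 and I in CDR1, the long-preferring ones carry
F at 42 and Y in CDR1 — so the Y↔F switch and CDR1 composition drift arise
through germline–length coupling, the mechanism the analysis is meant to
detect. Within-germline length variance is reduced so the marginal std
still matches the recipe. Planted CDR3 composition effects: the expected
acidic-residue count rises linearly with length (slope −d(charge)/dL,
default 0.1 per residue), per-residue C probability rises (0.01/length
unit) and N-at-105 probability falls (0.04/length unit) with length; the
CDR3 background pool excludes charged residues and the hallmark letters so
the planted slopes are exact in expectation. Read counts are 1 + geometric
(p = 0.12, mean ≈ 9, so roughly 60% of rows pass the count-5 filter, as in
noisy NGS libraries); amino-acid duplicates are injected at rate 0.05 and
far-length outliers (mean + 4 sd) at rate 0.005 to exercise the dedup and
z-filter stages. Scaffold positions off the hallmark set mutate at 1%.

**Structures** (defaults: n = 200, bent fraction 0.5). Each residue is one
backbone pseudo-atom plus two side-chain pseudo-atoms (1.5 Å offsets) —
enough to exercise all-atom contact, centroid, and SASA code without
claiming physical realism. The framework scaffold is fixed: FR2 is a strand
with position 42 at a known anchor, CDR1/CDR2 are rings, FR1/FR3 helices,
FR4 a strand near the loop base. The CDR3 hairpin is a Bezier arc; extended
loops rise away from the framework with apex height growing with length,
bent loops keep a low arc but pull an apex window down toward the
position-42 anchor, with the nearest-apex residue snapped onto the dip
target so CDR3–FR2 and CDR3–CDR2 contacts are guaranteed rather than
probable (and extended loops provably clear CDR2). P(bent) increases with
loop length (slope 0.07 per residue around the mean, clipped to
[0.02, 0.98]; exactly 0 or 1 for degenerate recipes). The antigen chain
docks one residue 3.5 Å off each outer-band loop residue (so the CDR3
paratope grows with length), plus an FR2-adjacent patch for extended
structures only and a CDR1-adjacent pad for bent ones — FR2 involvement
therefore tracks conformation, and lengths ≥ 9 guarantee ≥ 6 epitope
residues. DSSP-style labels are emitted per conformation (bent loops
coil/bend-rich, extended loops strand-rich).

What the generator does **not** emulate: real backbone stereochemistry,
side-chain packing, sequence–structure consistency beyond region labels,
insertion-code usage in crystals, B-factors/altlocs, or realistic epitope
chemistry. Passing tests therefore demonstrate that the pipeline recovers
planted statistical structure of the stated form — not that real
repertoires or crystal datasets exhibit it.

## Problem sizes and numerical choices

The test suite and acceptance script run the repertoire branch at 10,000
sequences and the structure branch at 200 complexes, the package's chosen
validation scale; smaller fixtures (hundreds of sequences, tens of
structures) back the unit tests. Dataset-scale SASA uses 240 sample points
per atom (the operation default is 960; the rotation-invariance test uses
10,000) — at 240 points per-structure SASA noise is well under the effect
sizes screened. Strata with fewer than 10 structures are suppressed from
correlation reports. Correlation screens require ≥ 3 distinct CDR3 lengths
and ≥ 3 complete pairs; zero-variance inputs yield undefined r reported as
missing, never 0. KDE troughs are located on a 512-point grid; bandwidth,
grid size, prominence ratio, and the unimodal fallback cut are all
arguments.

## Known limitations

* Numbering and germline assignment are consumed, not computed; malformed
  annotations are rejected rather than repaired.
* The charge model ignores termini and pKa shifts; hydropathy is
  structure-blind (the SASA-weighted score addresses this only for
  structures).
* Electrostatic surface potential, largest charge-patch areas, solubility
  scores, and typed interatomic interactions (hydrogen bonds, π-stacking,
  …) are out of scope.
* The conformation classifier assumes a two-population geometry; genuinely
  trimodal datasets would need the threshold logic extended.
* Exact-identity redundancy removal will keep near-duplicate structures
  that an alignment-based cutoff would merge.
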