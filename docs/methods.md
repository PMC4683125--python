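# Methods

## Binding-site definition

A protein residue is labeled *binding* at cutoff c when

1. min over all residue atoms a and nucleic-acid atoms b of ‖a − b‖ ≤ c, and
2. ΔASA = ASA(apo) − ASA(complex) > 0 Ų (strict inequality),

where the apo state is all protein chains with the nucleic atoms removed
and the complex state includes them. The cutoff ladder defaults to
3.5, 4.0, …, 6.0 Å. The ΔASA gate is applied identically at every cutoff;
labels are therefore nested in c (binding at c₁ ⇒ binding at c₂ ≥ c₁),
which makes 3.5 Å labels, read as predictions against 6.0 Å truth,
incapable of false positives (specificity exactly 1).

Distances use every atom present in the file, hydrogens included: the
definition is "any atom", and deposited crystal structures rarely carry
hydrogens, so the practical impact is nil. Waters are always removed;
ions and other non-polymer chains are excluded from both the protein and
the nucleic atom sets. Only the first model of multi-model files is used.
Alternate locations keep the highest-occupancy conformer (ties: first
encountered). Modified residues inside polymer chains are mapped to
parent types through an alias table for chain classification but still
contribute atoms to distances and SASA.

## SASA engine

Shrake–Rupley with a deterministic golden-spiral (Fibonacci) lattice of
n points per atom; atom i's area is the accessible fraction of
4π(rᵢ + p)², a lattice point being accessible when outside every
neighbouring inflated sphere. Defaults: probe p = 1.4 Å, n = 960 points,
Chothia-style radii C 1.87, N 1.65, O 1.40, S 1.85, P 1.90, H 1.00,
fallback 1.80 Å (all configurable). The lattice is fixed rather than
randomized or environment-oriented so that labels are bit-reproducible.

Quadrature accuracy, measured on overlapping-carbon fixtures: per-atom
areas at 960 points are within ~1–2% of converged values; at 1920 points
doubling the lattice moves no atom by ≥1%, and a rigid rotation of all
coordinates moves areas by <2% (a fixed lattice is translation-invariant
but only approximately rotation-equivariant; exact equivariance would
require environment-dependent local frames, which are ill-defined for
isolated or symmetric atoms and would sacrifice reproducibility).
The isolated-atom and two-sphere cases have closed forms (4π(r+p)² and
2π·r_eff·(r_eff + d/2) per sphere) used as analytic oracles. The radii
table is a pinned stand-in for classical NACCESS defaults; analyses that
used NACCESS itself may label borderline residues (ΔASA ≈ 0) slightly
differently.

## Metrics

Per-protein AUC uses the Mann–Whitney formulation with midrank ties,
AUC = (Σ ranks of positives − n₊(n₊+1)/2)/(n₊ n₋); it is undefined (not
0 or 0.5) when a protein has a single label class at a cutoff, and such
proteins are excluded from wAUC/mAUC/sAUC with their count reported.
wAUC weights by the length of included proteins only. sAUC is the sample
standard deviation (divisor N−1). tAUC pools all residues into one ROC
and is reported as a reference only — it inherits the cross-protein
comparison problem described in the README.

Binary metrics use the standard definitions (sen = TP/(TP+FN),
spc = TN/(TN+FP), ppv, acc, F1, MCC with the TP·TN − FP·FN numerator);
any zero denominator yields 0 together with a degenerate flag. Dataset-
level binary metrics pool confusion counts over all residues of all
proteins; continuous scores are binarized at a caller-supplied threshold
(default 0.5), binary-coerced predictors (score ∈ {0,1}) are used as-is
and flagged, since their AUC reflects a single operating point.

Stability over the cutoff ladder: Δ terms are absolute differences of
wAUC (or mAUC/tAUC) over consecutive ascending cutoff pairs; Δd is the
pair spacing. MAV = max |Δ|, MAVR = max |Δ|/Δd, CAVR = Σ |Δ|/Δd. Signed
consecutive sums would telescope to the end-to-end difference and make
CAVR degenerate, hence the absolute values; an all-pairs mode is
available behind a flag for sensitivity analysis. Minimum performance is
the minimum wAUC over all (dataset, cutoff) cells, with the argmin
reported; ties break to the smallest cutoff, then the lexicographically
smallest dataset name, for deterministic reports.

The funnel correlation is the Pearson ρ between per-residue minimum
distance and prediction score over residues with min distance ≤ 12 Å
(configurable); it is undefined with fewer than 3 qualifying residues or
a constant series. The signed ρ is the primary value (funnel-shaped
predictors give ρ < 0); |ρ| is carried alongside for ranking predictors
by funnel strength irrespective of score orientation.

RNA-vs-DNA discrimination: binding residues at 3.5 Å from a dataset of
the predictor's own nucleic-acid type are positives, binding residues
from a dataset of the other type are negatives, and the pooled AUC of
the predictor's scores over the concatenation measures whether it can
tell the two apart.

## Prediction I/O conventions

One canonical TSV dialect (`chain resnum icode score`, author numbering)
is defined instead of per-program parsers: predictor outputs are
heterogeneous, and what must be encoded are the normalization rules —
residues a predictor skipped (e.g. termini) are filled with score 0 and
flagged, binary calls become scores 1/0, and scores are never rescaled
or clipped (all metrics are rank-based). Ties introduced by fill-zero
are handled by the midrank rule, not jitter, for determinism. Alignment
demands ≥50% key overlap with the target chain to catch wrong-chain
files, and is idempotent.

## Curation

Structure-intrinsic exclusion filters with machine-readable reason
codes: `short_peptide` (chain < 20 residues), `weak_binder` (< 3 binding
residues at the largest cutoff), `ca_only` (≥95% of residues carry only
a Cα heavy atom), `split_peptides` (a protein of exactly two chains,
both short). Filters requiring external services — sequence-identity
culling, superseded-entry detection — are out of scope.

## Synthetic data generator

The generator emulates the statistical structure the assessment assumes:
labels determined by geometry, and scores correlated (or not) with
distance to the interface. Each complex is a "ladder": pseudo-nucleotide
atoms every 1 Å along a straight axis, and 5-atom alanine-like protein
pseudo-residues whose anchor atom sits at a scripted distance from the
axis, sharing a z coordinate with a nucleic atom so the true minimum
distance equals the script exactly (the other four atoms sit strictly
farther). Residues within ~6.5 Å of the axis are occluded by the nucleic
spheres, so binding residues have ΔASA > 0 by construction.

Defaults are the study conditions used throughout the tests: 10 proteins
of 200 residues, linear distance profile from 2.5 to 20 Å (≈20% binding
residues at 6 Å and a non-degenerate 3.5-vs-6 Å split, so every default
complex passes curation), per-protein jitter ±0.2 Å, funnel score model
s = e^(−d/4 Å) + N(0, 0.05). Score variants: `ideal` (s = −d, AUC 1 by
construction), `random` (U(0,1)), `funnel`, and `binary` (funnel score
thresholded at its median). All randomness flows from
numpy `default_rng` seeded by (seed, structure index, variant), so a
spec reproduces its corpus byte-for-byte.

What the generator does not emulate: real backbone chemistry and packing
(pseudo-residues are geometric, not stereochemically valid), surface
curvature, crystal contacts, sequence signal, or homology between
proteins. Passing tests therefore demonstrate correctness of the
labeling and metric machinery and recovery of known score–distance
signal — not predictor performance on real complexes.

## Problem sizes and numerical choices

Tests run the generator at 25–200 residues per protein and SASA at
240–1920 lattice points depending on whether quadrature accuracy is the
property under test; the chance-level check uses the default
10 × 200-residue corpus, whose mAUC band [0.45, 0.55] follows from
binomial Monte-Carlo bounds at that size. Distance computations are
exact (dense pairwise distances per residue); the SASA neighbour search
uses a k-d tree with radius rᵢ + r_max + 2p, which cannot miss an
occluder. Degenerate inputs (single-class proteins, constant score
series, empty discrimination sides, fewer than two stability points)
return explicit undefined flags or raise, never silently substitute
values.
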