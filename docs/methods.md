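# Methods notes

This note records the modelling assumptions, defaults and numerical
choices behind `uaatol`, and what the synthetic benchmarks do and do
not demonstrate.

## Structural model and conventions

Structures are reduced to heavy atoms. Hydrogens are excluded from all
contact and surface computation: crystallographic inputs rarely carry
them, and dropping them keeps WT/mutant feature parity when only one
side of a pair has been protonated. Backbone atoms are exactly
{N, CA, C, O, OXT}; polarity follows the element (N/O polar, C/S
nonpolar — sulfur is grouped with the hydrophobic elements because the
contact scheme is hydrophobicity-oriented; other elements default to
nonpolar with a warning). Alternate locations resolve to the
highest-occupancy conformer, first-in-file on ties. Residue numbering
is taken from the input file as deposited; no renumbering.

Cα RMSD is offered both with Kabsch superposition and in the shared
input frame. Locally refined replicate models of one starting
structure already share a frame, so the un-superposed mode is the
natural one for convergence checks; both are provided because either
convention is defensible.

## Contact features

A contact is an unordered heavy-atom pair at distance strictly less
than 4.0 Å (a pair at exactly 4.0 Å does not count). Pairs separated
by one or two covalent bonds are excluded — bonded geometry is not a
contact — using bond templates for the 20 standard residues and
distance-inferred bonds (≤ 1.8 Å) for unknown residue codes, plus the
eight 1-2/1-3 pairs across each peptide junction. Mixed polar/nonpolar
pairs count as polar: "nonpolar contact" is read as a fully
hydrophobic pairing. Both the bonded-exclusion and the mixed-pair
policy are configurable (`exclude_bonded`, `mixed_polarity`), since
reasonable implementations differ. Inter-residue contacts are counted
once per pair, never doubled.

The production path uses a k-d tree for neighbour queries; a quadratic
all-pairs oracle in the test suite (and acceptance script) verifies
exact agreement on random structures.

## Accessibility

Surface areas use the Shrake–Rupley rolling-probe approximation with
probe radius 1.4 Å (water), 960 deterministic golden-spiral sample
points per atom, and Bondi-type van der Waals radii (bundled table;
unknown elements fall back to 1.70 Å with a warning). At 960 points
the isolated-sphere error is well under 1% and two-sphere overlap
agrees with a Monte-Carlo surface estimate to better than 1%. RSA
normalises by the Tien et al. (2013) theoretical Gly-X-Gly maxima, so
RSA can exceed 1 in extended conformations. ASA/RSA are properties of
the *wild-type* residue about to be mutated (absolute values, not
deltas).

## Bioinformatics lookups

BLOSUM62 comes from biopython's `substitution_matrices`. The three
hydrophobicity scales are bundled side-chain transfer free energies
(cyclohexane→water and vapor→water from the Wolfenden measurements,
octanol→water from the Fauchère–Pliska π scale); proline has no
side-chain analogue in the first two and is entered as 0.0, flagged in
the table header. The melting-temperature-change-vs-glycine table is a
**synthetic stand-in** (filename `delta_tm_vs_gly.synthetic.tsv`)
constructed from helix-propensity differences referenced to glycine;
all three tables are plain TSV and swappable without code changes.
Evolutionary-conservation and secondary-structure features are
accepted as user-supplied columns, not computed (they would need MSAs
or DSSP).

## Energy features

Score tables are assumed pre-weighted (REU); no weight set is applied,
and `residue_total_score` is treated as just another term. Replicates
(typically five) are averaged per residue and term; the `t_8A` feature
is the *mean* (not sum) of the per-residue deltas over the contact
sphere, defined as residues with Cα–Cα distance ≤ 8.0 Å of the site
(closed boundary, site excluded). An empty sphere yields 0 with a
warning. Note the sampling arithmetic: each delta subtracts two
independent five-replicate averages, so its standard error is
σ·√(2/5) per cell — √2 larger than a single average's — which the
recovery benchmarks account for.

## Responses, labels and the holdout

A value strictly above the cutoff is active; ties are inactive
(anchored to the "equal to or below" convention of the soluble-fraction
colouring), applied uniformly at 520 nM / 1600 nM / 39%. The holdout
is round(0.2·n) rows (half-away-from-zero), split equally between the
proteins. Representativeness is implemented as stratified sampling
over the global response quartiles within each protein
(largest-remainder allocation, seeded within-bin draws), followed by a
reconciliation pass that swaps rows within a protein until the
holdout's above/below-median composition is within one sample of the
dataset's proportion — per-protein rounding can otherwise compound to
a two-sample imbalance. An explicit-membership mode accepts a fixed
holdout list when an externally published membership should be
mirrored.

## Learning protocol

Feature selection is one-way ANOVA F, top-k with ties to the earlier
column, capped at 10 features; constant features score 0 with a
warning. The feature count is chosen per algorithm by stratified CV5
accuracy at default hyperparameters (ties to the smaller k), then
hyperparameters by exhaustive grid search (mean per-fold CV accuracy,
ties to the first declared grid point). Selection and scaling live
inside the CV pipeline so no held-out rows leak into them; a probe
test confirms that in-fold selection scores at chance on permuted
labels while deliberately leaky selection scores far above it.

Kernel ridge regression participates as a classifier by fitting
−1/+1-encoded labels and thresholding predictions at 0 (ties
inactive). Bernoulli naive Bayes sees features binarized at their
training-fold medians instead of z-scores; every other algorithm is
standardized (harmless for the discriminants, applied for uniformity).
The per-algorithm grids are deliberately small, desk-scale defaults
declared in `ALGORITHMS`; they are repo choices, not canonical values,
and are trivially editable.

CV metrics pool out-of-fold predictions into one confusion matrix —
that is the quantity a printed integer CV confusion matrix can
correspond to — while hyperparameter *selection* uses mean per-fold
accuracy. Metric reporting rounds half away from zero to 3 decimals;
undefined ratios (zero denominators) propagate as NaN with warnings
rather than silent zeros. `reconstruct_confusion` inverts printed
(accuracy, precision, recall) triples back to integer confusion
matrices by exhaustive enumeration, as a consistency checker for
published tables. The stratified dummy baseline draws i.i.d. from the
training class frequencies; its expected accuracy is p² + (1−p)².

Logistic feature importance is 100·|c_i|/max_j|c_j| on the
standardized-model coefficients, so the top feature always scores 100.

## Correlation screens and regression

Feature screens use Pearson R for continuous responses and
point-biserial (Pearson on 0/1 coding) for binary ones, ordered by
|R| with ties kept in column order. The regression report follows the
summary-table convention: R = √R², adjusted R = sign-preserving
√(adjusted R²) floored at 0, overall F and its p-value.

Backward selection starts from the 10 most |R|-correlated candidates
and repeatedly drops the least significant coefficient. Because those
candidates are already selected from a larger pool, an uncorrected
per-coefficient threshold of 0.05 keeps a spurious "best noise
feature" in roughly a third of pure-noise datasets (the survivor is
effectively the minimum of ~10 p-values). The default rule therefore
Bonferroni-corrects the threshold by the screened-candidate count,
which restores null calibration (≈95% intercept-only on noise) while
leaving genuine planted signals untouched; `multiplicity="none"`
recovers the plain rule.

## Synthetic data: what it emulates and what it does not

The helix generator builds ideal α-helical backbones (φ=−57°, ψ=−47°,
standard bond geometry via internal-coordinate chain construction)
with small template sidechains; the bulky mutant replaces the site
sidechain with a planar hexagonal-lattice ring system of nonpolar
pseudo-atoms (1.4 Å spacing) along the CA–CB direction — a geometric
caricature of a tricyclic acridone sidechain. Score-table generation
plants a site shift δ=2.0 REU and sphere shift γ=0.5 REU over
Gaussian noise σ=0.3 REU across 5 replicates. Labeled datasets have
51 samples tagged 32:19 to two pseudo-proteins, 30 i.i.d. standard
normal features of which 3 carry a linear signal with coefficients
(3, 2, 1); the latent noise is set from the target Bayes accuracy
(default 0.95) through the closed form acc = 1/2 + arcsin(ρ)/π with
ρ = |β|/√(|β|²+σ²), and labels cut at the latent median so classes
balance.

Passing these benchmarks shows the machinery is correct and honestly
evaluated at the study's data shape; it does *not* show that real
Acd-mutant structures are predictable at any particular accuracy —
real features are correlated, non-Gaussian and structure-derived, and
real effect sizes are unknown a priori. No conformational sampling,
rotamer physics or chemical parameterization of the unnatural residue
is emulated.

One statistical caveat worth knowing: with a fixed overall class
composition, a 10-row holdout's composition is hypergeometrically
anti-correlated with the training majority, so a no-signal classifier
scores *below* 0.5 on such holdouts for reasons unrelated to leakage.
Permutation-null controls therefore use pooled cross-validated
accuracy at fixed default hyperparameters (the `permutation_test_score`
convention), which is calibrated at the class prior.

## Problem sizes

Benchmarks run at the study's own scale: 51-sample datasets, 5
replicates, 10-feature caps, 50–200 seed repetitions for the
statistical checks, 100 random structures (≤ 300 atoms) for the
contact oracle, 960-point spheres and ~10⁵-sample Monte-Carlo surface
references. These sizes were chosen so every check is a faithful,
deterministic instance of the claim it tests.

## Known limitations

- No structure refinement or energy calculation: energies are ingested
  as tables; structure pairs must come pre-modelled.
- The ΔTm table is a documented synthetic stand-in until measured
  values are substituted.
- The backward-selection stopping rule and the per-algorithm grids are
  package defaults, configurable but not canonical.
- With n≈51 and a 10-row holdout, single-run holdout metrics are
  quantized in steps of 0.1 and inherently noisy; conclusions should
  rest on the cross-validated and multi-seed quantities.
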