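# Methods

## The prediction problem

A peptide presented by an MHC class I molecule (here the HLA-A2 allele,
which presents 9-mers) is *immunogenic* when the T-cell receptor (TCR)
repertoire recognises the peptide–MHC complex and mounts a response.
MHC binding is necessary but not sufficient: among presented peptides,
sequence features at the TCR-facing positions decide reactivity.  The
package treats this as binary classification of fixed-length amino-acid
sequences (+1 immunogenic, −1 non-immunogenic) and couples the classifier
with interpretation machinery that asks *which positions* and *which
physicochemical properties* carry the signal.

## Weighted degree string kernel

For equal-length sequences s₁, s₂ of length L and degree d,

  k(s₁, s₂) = Σ_{p=1..d} β_p Σ_{l=1..L−p+1} I(u_{p,l}(s₁) = u_{p,l}(s₂)),

where u_{p,l}(s) is the substring of length p starting at position l and
β_p = 2(d−p+1)/(d(d+1)).  The weights decay linearly with substring
length and sum to one; the self-kernel is the closed form
Σ_p β_p (L−p+1) (19/3 for L = d = 9), so the Gram diagonal is constant.

Implementation: a maximal run of m consecutive positional matches
contributes Σ_{p≤min(m,d)} β_p (m−p+1); equivalently each position ending
a forward match-run of length r contributes the cumulative weight
Σ_{p≤min(r,d)} β_p.  Kernels are therefore computed in O(L) per pair from
the run-length profile, vectorised over whole peptide sets.  The naive
substring enumeration survives only as the independent oracle in the test
suite, where the two routes must agree to 1e−12.

No cosine normalization is applied by default (`KernelSpec(normalize=True)`
exists but is off): raw kernel values feed the SVM, and because the
diagonal is constant for fixed-length input, normalization would only
rescale the Gram matrix uniformly.

Non-canonical residues (B, J, O, U, X, Z) are rejected at parse time with
a named error rather than scored as mismatches; sequences with modified
amino acids should be filtered upstream.

## Classifier

A soft-margin SVM is solved in the dual on the precomputed Gram matrix
(scikit-learn's `SVC(kernel="precomputed")`, i.e. the libsvm SMO solver,
tolerance 1e−8, shrinking off).  A query q scores
f(q) = Σ_i α_i y_i k(x_i, q) + b and is called immunogenic exactly when
f(q) > 0; a score of exactly 0 maps to non-immunogenic.  No probability
calibration and no class weighting are applied — the decision value itself
is the reported immunogenicity score, and the intended datasets are nearly
class-balanced.  After every fit the dual box constraints
(0 ≤ α_i ≤ C) and the equality constraint Σ α_i y_i = 0 are checkable via
`TrainedModel.check_dual_feasibility`.  The production configuration
(`train_final_model`) is C = 1.0, d = 9 on the full dataset.

Models serialize to a self-describing JSON archive with floats stored as
IEEE-754 hex strings, so a load→predict round trip is bit-identical.

## Evaluation protocol

ACC and MCC follow the closed confusion-matrix formulas (MCC defined as 0
when a marginal is empty); AUC is the Mann–Whitney statistic with
half-credit ties (`sklearn.metrics.roc_auc_score`).

Nested cross-validation: the data are split into 10 stratified outer
folds; for each outer fold, a 10-fold inner CV on the remaining 9/10
grid-searches C ∈ {2⁻⁴ … 2⁴} and d ∈ {1 … 9}, selecting the pair with the
highest mean inner AUC (ties resolve to the smallest d, then the smallest
C); a model trained on the full 9/10 with the winning pair is scored on
the held-out fold.  Runs are repeated with independent fold
randomisations and summarised as mean ± sd; per-run metrics pool the
outer-fold predictions so each peptide is scored exactly once per run.
Stratification is a deliberate strengthening of plain random folding: on
small synthetic datasets unstratified folds can go single-class and make
inner AUC undefined.

The learning curve uses one stratified 50/25/25 train/validation/test
split; for each requested size s the first s peptides of the shuffled
training pool are used (so larger training sets nest smaller ones), with
C = 1, d = 9 fixed by default and optional re-tuning per size.

The position-blind baseline encodes each peptide as the vector of
per-property means over its residues and trains an RBF-kernel SVM
(k(x,y) = exp(−γ‖x−y‖²)), tuning C and γ ∈ {2⁻⁴ … 2⁴} under the identical
nested protocol.  Averaging destroys positional information by
construction, which is exactly the contrast the benchmark suite probes.

## Position and property analysis

*Position-deletion importance*: for each position, every peptide is
shortened by excising that position, the full nested-CV protocol is re-run
on the shortened data with the degree grid capped at the remaining length
L−1 (8 for 9-mers), and the drop in mean MCC relative to the intact
baseline (ΔMCC) is reported.  Baseline and deleted runs share one seed so
fold randomisation is matched.  A position is flagged important when its
ΔMCC exceeds twice the across-run sd of the deleted-run MCC — a concrete
operationalisation chosen here for "significantly decreased".

*Two-sample logo*: for each position and symbol, the per-peptide 0/1
occupancy indicator is compared between the immunogenic and
non-immunogenic sets with a two-sample t-test.  Welch's unequal-variance
form is the default because binary indicators with different rates have
unequal variances by construction; a pooled-variance option exists.  The
Bonferroni family is all L × |alphabet| tests (180 for 9-mers over amino
acids, 27 over S/M/L), recorded in every report.  Indicators constant in
both sets give p = 1 (no evidence) rather than an error.  Logo images are
rendered with matplotlib from the numeric report; all analysis consumes
the report, never the pixels.

*S/M/L recoding*: residues map to small/medium/large classes by
thresholding a scalar property — hydrophobicity at 0.5 and 2.5, normalized
van der Waals volume at 2.0 and 6.0.  The volume scale is the standard
normalized side-chain volume (G = 0.00 … W = 8.08).  The bundled
hydrophobicity scale is a synthetic scalar constructed so these thresholds
reproduce the standard polar/neutral/hydrophobic trisection used in
composition-transition-distribution encodings; any user scale can be
substituted.

*Feature usage*: peptides are encoded as mean-property vectors over all
complete records of an AAindex-format table, and a single binary
information-gain decision tree is grown (no pruning, minimum leaf size 5,
deterministic lowest-feature-index tie-breaks).  A property's usage is the
percentage of training cases whose root-to-leaf path tests it at least
once — the root feature of any non-trivial tree scores 100% — and
properties are ranked by usage.  This reproduces the *construct* of
commercial rule-induction tools (rank properties by how much of the data
their rules touch); exact usage percentages from any particular tree
software are configuration-dependent and are not a comparison surface.

## Synthetic data

The generator plants position-specific residue structure over a 20-letter
background (uniform by default; a frequency table can be supplied):

* **deterministic mode** — label +1 iff one (position, residue) predicate
  holds; perfectly separable by construction;
* **probabilistic mode** — each motif element (position, residue,
  freq_pos, freq_neg) draws the motif residue at its class rate and
  otherwise draws from the background *excluding* that residue, so the
  planted frequency is exact rather than inflated by background leakage.

The benchmark suite fixes four conditions: a deterministic single-position
rule (G at position 4); a logo-style probabilistic enrichment (G@4, V@6,
T@8 enriched in positives, I@9 depleted — echoing the published HLA-A2
preferences); a label-shuffled null; and a composition-matched
position-swap set (positives G@4+V@6, negatives V@4+G@6) whose classes
have identical residue composition, separating positional from
compositional methods.

Positions are independent given the class, and the background is
position-exchangeable.  Real epitope data violates both (anchor-position
biases from MHC binding, residue correlations); passing the recovery tests
therefore demonstrates correctness of the machinery, not real-data
accuracy.  Published real-data figures (e.g. mean nested-CV ACC ≈ 0.68 /
AUC ≈ 0.74 on the IMMA2 HLA-A2 set) require that external dataset, which
ships with no public accession; given such a file, `popisk evaluate`
runs the identical protocol on it.

## Problem sizes and numerical choices

Routine tests and the acceptance script run the full nested 10×10
protocol on n = 200 datasets with reduced grids (e.g. C ∈ {2⁻², 1, 2²},
d ∈ {1,3,5,7,9}; C = 1 with the capped d-grid for the 10 position-deletion
re-runs at 2 repetitions) — the protocol is never thinned, only the grid
and repetition counts.  Solver tolerance 1e−8 keeps permutation and
label-flip contracts below 1e−6 on the score scale.  Kernel identities are
asserted at 1e−12; Gram PSD at eigenvalue ratio ≥ −1e−8.  All randomness
descends from explicit integer seeds, and every CV report records its
seed and grid.

## Known limitations

* Independent-position generation cannot express residue co-variation;
  motif-interaction recovery is untested.
* The classifier is allele-specific by construction; nothing transfers
  across MHC alleles without retraining.
* Exact decision scores depend on solver configuration (tolerance,
  solver family); contracts are therefore stated about score *properties*
  (sign, antisymmetry, round-trip identity), not absolute values.
* The hydrophobicity S/M/L scale is synthetic (see above); analyses that
  depend on fine-grained hydrophobicity ordering should supply a
  literature scale.
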