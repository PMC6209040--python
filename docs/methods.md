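# Methods

## Model

The package assumes a single, constant referencing offset δ on the ¹³C
dimension: every Cα and Cβ shift in a dataset is the true shift plus δ. Each
residue's (Cα, Cβ) pair is treated as an i.i.d. draw from a bivariate normal
distribution specific to its amino-acid class and secondary structure. The
class space has 60 bivariate members — 18 standard non-glycine, non-cysteine
residues, plus oxidized and reduced cysteine, × helix (H), sheet (E), coil
(C) — and 3 univariate glycine (Cα-only) members. Composition vectors live in
the 57-dimensional cysteine-merged space (19 residues × 3 SS): a protein
sequence knows it has a cysteine, not its oxidation state, so the two state
probabilities are merged by summation. Glycine is excluded from composition
throughout: its Cα-only evidence is weak and its sheet/coil distributions
overlap almost completely, which (when included) inflates the matrix-product
terms of the residual and degrades the estimate; the glycine models and the
3×3 glycine overlap block are implemented behind an `include_glycine` flag
for ablation but are off by default.

Scoring uses the Mahalanobis statistic χ\* = (v−μ)Σ⁻¹(v−μ)ᵀ, which is
χ²-distributed with 2 df under the class model; the survival probability is
the closed form exp(−χ\*/2) (equal to the integrated upper tail to machine
precision, asserted in the tests). Pairs are unordered: both orderings are
evaluated and the larger probability kept per model. This never discards the
correct ordering and keeps every derived quantity invariant under swapping
the two shifts.

## Composition estimation and the overlap prior

Each pair's 57 class probabilities are normalized to unit mass; the
normalized vectors are averaged over the dataset to give the estimated
composition Y′. The overlap matrix Ω is built the same way from a corpus
with known true classes: row t is the average normalized probability vector
of class-t records, renormalized. With both sides using per-pair
normalization, a large dataset of true composition Y satisfies Y′ → Y·Ω
exactly — the self-consistency on which the prior logic rests. (Summing
*unnormalized* probabilities before a single normalization breaks this
identity measurably — L1 mismatch ≈ 0.4 at n = 6000 versus ≈ 0.02 for the
per-pair convention — and was rejected for that reason.) Rows of Ω are
normalized — so Y·Ω conserves mass — and the diagonal ω = diag(Ω) weights
the residual toward the most self-identifiable classes.

The correction minimizes R(c) = Σᵢ ωᵢ|Y′ᵢ(c) − (Y·Ω)ᵢ| over candidate
corrections c subtracted from both carbons. Round 1 evaluates 50 evenly
spaced candidates on [−5, 5] ppm (spacing 10/49 ≈ 0.204 ppm; "50 candidates"
wins over a nominal 0.2 ppm increment, which would need 51 points); round 2
evaluates 50 candidates on [M₁−1, M₁+1] (spacing 2/49 ≈ 0.041 ppm). Ties
break toward the candidate of smallest absolute value. The reported M₂ *is*
the estimated offset present in the data; corrected shifts are observed
values minus M₂.

## Class statistics

Sample statistics use n−1 denominators throughout. Cysteine records are
split into oxidation states per secondary structure by K-means with K = 2
(scikit-learn, 10 restarts, fixed seed, raw ppm coordinates); the cluster
with the larger mean Cβ is labeled oxidized, since disulfide-bonded Cβ sits
near 41 ppm versus ≈ 28 ppm for the free thiol. Covariance-matrix variants:
A (pooled variances, zero covariance), B (per-SS variances, zero
covariance), C (pooled variances and covariance), D (per-SS variances,
covariance averaged over the three SS), E (fully per-SS), E-revised (per-SS
with refined covariances). Pooling weights per-SS variances and covariances
by sample count.

Covariance refinement addresses shifts assembled from multiple spectra,
whose Cα/Cβ correlation is weakened or destroyed. Each corpus entry carries
two RMSD quality figures (Cα and Cβ); the statistic
Q = (|RMSDα − RMSDβ| / (RMSDα + RMSDβ))^(1/3) ∈ [0, 1] is small when both
nuclei were predicted about equally well (the single-experiment signature);
the cube root symmetrizes the skewed ratio. Entries are sorted by Q and every
observed Q value is tried as a cutoff (an exhaustive, deterministic superset
of a recursive bisection, whose stopping rule is otherwise unspecified);
pooled deviation-from-class-mean correlations r₁ (low Q) and r₂ (high Q) are
compared by the standard Fisher r-to-z two-sample test, and the split with
the smallest p-value wins. Correlations are computed on deviations from
class means, not raw shifts — required for pooling across residue types.
Splits leaving fewer than 10 entries on either side are skipped; with no
admissible split all entries are selected with p = 1. E-revised replaces the
covariances (only) with those recomputed from the selected entries, clipped
to |cov| ≤ sd·sd to keep every matrix positive semi-definite.

## Assigned mode

With residue types and secondary structure known, each row is scored against
exactly one class model (cysteine: the better of its two state models) and
the mean χ\* over rows is minimized over a single offset by differential
evolution (scipy, population 40, 50 iterations, bounds ±10 ppm, fixed seed;
the objective's error surface is smooth enough that the optimizer choice is
uncritical). The objective itself — mean χ\* — is this package's documented
choice; alternatives such as summed negative log-likelihood behave
equivalently near the optimum for a shared offset.

## Peak grouping

HN(CO)CACB lists hold two peaks per residue (one for glycine) sharing an
amide (¹H, ¹⁵N) root. Registration estimates per-dimension match tolerances
from the list itself: mutual nearest neighbors in the (standardized) (h, n)
plane are intra-residue pairs; the tolerance is 3× the median per-dimension
intra-pair distance, floored at 0.001 ppm (¹H) / 0.01 ppm (¹⁵N). This
estimator is a stand-in satisfying the registration contract; the original
registration algorithm is specified elsewhere and not reproduced. Grouping
runs DBSCAN on ((h/tol_h), (n/tol_n)) with neighborhood radius √9 (a
3-sigma-per-dimension χ² cutoff) and minimum cluster size 1, so glycine
singletons survive. Clusters larger than two are resolved by repeatedly
extracting the closest pair; if a competing pairing lies within 2× the best
pair distance the peaks involved are flagged ambiguous (coincident amide
roots) rather than paired arbitrarily — plain "keep closest pair, discard
the rest" could not both salvage well-separated merged clusters and reject
coincident roots. Ungrouped leftovers are retried up to 5 times with
tolerances re-estimated on the leftover subset (doubled when fewer than 4
remain); final leftovers surface as ambiguous singletons, never silently
dropped. Ambiguous groups and singletons are excluded (with a logged reason)
from the carbon-pair dataset.

## Synthetic data

Generators are pure functions of (spec, seed). Datasets draw one pair per
non-glycine residue from its class model (cysteine state by fair coin,
recorded in the ground truth), add the true offset after all random draws
(so offsets are exactly additive under a fixed seed), and drop
⌈missing_fraction × n⌉ pairs uniformly. Peak lists place amide roots
uniformly on (7.5–9.5) × (105–130) ppm with rejection enforcing a minimum
normalized spacing of 5 jitter-sd, and jitter each peak's root independently
(defaults 0.004 / 0.04 ppm, typical digital resolutions). Corpora distribute
records over 40 synthetic entries; a configurable fraction of entries is
"decorrelated" (independent Cα/Cβ draws and lopsided RMSD pairs, Q ≈ 0.78)
versus correlated entries (full model covariance, near-equal RMSDs,
Q ≲ 0.29), emulating multi-spectrum contamination for the refinement
machinery.

The shipped default parameters are a stated world, not fitted values:
literature random-coil Cα/Cβ means; helix offsets (+2.6, −0.4) and sheet
offsets (−1.4, +2.1) ppm; standard deviations 1.1–1.6 ppm (wider outside
helices); Cα/Cβ correlation −0.30 except alanine and the two cysteine
states, which use the per-SS values reported for re-referenced corpus data
(e.g. oxidized cysteine +0.22/+0.35/+0.45 for E/C/H). Synthetic data drawn
from these models reproduce the method's assumptions exactly; green tests
therefore establish correctness of the machinery and the self-consistency
of the statistics, *not* real-data performance, which additionally faces
non-Gaussian tails, ring-current and deuteration outliers, secondary
structures beyond three states, and predictor errors in the SS string.

## Numerical choices and limitations

- Per-pair probability vectors are guarded against total underflow
  (denominator floored at 1e−300); χ\* never underflows exp(−χ\*/2) for
  offsets within the ±10 ppm search bounds.
- Completeness below 50% of expected spin systems warns but does not fail.
- Determinism: identical inputs and seeds give bit-identical results; the
  grid search is deterministic outright, K-means and differential evolution
  carry fixed seeds.
- The single-dataset accuracy of the unassigned method on ~100-residue
  proteins has an intrinsic sampling-noise floor of roughly ±0.12 ppm
  (median absolute error) even on model-matched data, since the composition
  estimate rests on ~90 draws; accuracy improves with protein size and with
  the assigned variant (±0.02 ppm at 2000 residues).
- Not covered: ¹H/¹⁵N referencing, per-nucleus separate corrections,
  intrinsically disordered proteins, spectral artifacts and peak overlap in
  the carbon dimension.
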