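# Methods

## Model

A sample's mutation spectrum is modeled as a finite mixture over known
signatures. With signature profiles ω_cs (probability of context c
under signature s) and per-sample relative activities w_si ≥ 0,
Σ_s w_si = 1, the probability that a mutation in sample i falls into
context c is

    W_ci = Σ_s ω_cs · w_si ,

and the observed context counts of a sample with burden m are one
multinomial draw of size m over (W_1i, …, W_96i). This is equivalent to
first attributing each mutation to a signature with probability w_si
and then to a context with probability ω_cs. The generator makes no
distributional assumption about per-signature mutation counts beyond
the multinomial (no log-normal burden model, no zero inflation):
heterogeneity across samples comes entirely from the empirical weight
table that the per-sample weights are resampled from.

Refitting inverts the mixture: given counts and a reference R, estimate
w̃ ≥ 0 with m_norm ≈ R w̃. The NNLS baseline minimizes
‖m_norm − R w‖₂ subject to w ≥ 0 per sample and normalizes the result
to sum 1; the greedy baseline selects a signature subset by forward
addition (largest cosine reconstruction-similarity gain, while the gain
is at least `greedy_tol`) and backward pruning (drop signatures whose
removal costs less than `greedy_tol`), refitting by NNLS on each
candidate subset.

## Ground-truth filtering

A signature expected to contribute fewer than `min_contribution`
(default 10) mutations cannot survive the standard output cutoff of any
fitter, so demanding its recovery would only add irreducible error.
Truth weights with m·w_si < 10 are therefore removed and the remaining
weights renormalized before mixing. One pass is a fixed point: weights
only grow under renormalization, so no new violations appear. Corner
case: if *every* weight of a drawn donor fails the cutoff (possible at
m ≈ 100), the single largest-weight signature is kept at weight 1 and a
warning is logged — dropping the sample would silently change the
cohort size.

## Output cutoff and unassigned mass

Estimated activities contributing fewer than `min_mutations` (default
10) mutations are set to zero. The surviving weights are deliberately
*not* renormalized: the removed mass is reported as the per-sample
unassigned fraction. Renormalizing would manufacture confidence in the
surviving signatures; the metric layer scores whatever sums the fitter
reports. The external-tool adapter exposes renormalization as an option
because published pipelines differ on this point.

## Metrics

All metrics align truth and estimate on the union of signature names
(absent = 0) and average per-sample values over samples.

- Fitting error ½ Σ_s |w_si − w̃_si| ∈ [0, 1]: 0 iff exact, 1 when the
  estimate's full mass is misassigned.
- False-positive weight Σ_{s: w_si=0} w̃_si.
- Precision/sensitivity/F1 classify signatures as active iff their
  weight is strictly positive (cutoffs are the fitter's job, not the
  metric's). A sample with no predictions has undefined precision: it
  is excluded from the precision average (and counted in the report)
  and contributes F1 = 0 when its truth is non-empty; 0/0 is never
  fabricated. A sample with empty truth and no predictions counts
  sensitivity 1.
- Pearson agreement: per sample with support-union ≥ 3, the correlation
  between the two weight vectors restricted to that union; samples
  where a restricted vector is constant are skipped and counted.
- FP decomposition: *irrelevant* FP weight lies outside the union of
  the cohort's true supports; *relevant* FP weight is on cohort-active
  signatures inactive in the given sample, plus positive excess
  max(w̃ − w, 0) on the sample's own active signatures. The two terms
  are reported separately, so either reading of "excess weight on
  cohort-active signatures" is recoverable.
- Consensus truth over k ≥ 2 estimates: per signature and sample, the
  mean of the positive weights when at least two estimates find it
  active, else 0; columns renormalized.

## Reference pruning

Two-step procedure: fit all samples with the full reference; keep the
signatures whose relative weight strictly exceeds w₀ in at least
`min_samples` (default 5) samples; refit with the reduced catalog
(reapplying the usual output cutoff). Default w₀ tracks the burden —
0.1 at m = 100, 0.03 at m = 2000, 0.01 at m = 50,000 (absolute
contributions 10/60/500); between anchors, the log-nearest anchor's
value (m = 10,000 is an exact tie, resolved to the smaller anchor).
Support counting uses the post-cutoff first-fit weights. An
`always_keep` list (with a preset naming the 18 COSMICv3 artifact
signatures) exempts signatures from pruning.

## Power experiment

The group-difference injection multiplies one signature's weight by f
in even-indexed samples (0-based) and divides by f in odd-indexed ones,
then renormalizes each column. Detection uses the two-sided Wilcoxon
rank-sum test on the *estimated* weights of the two groups; samples in
which the fitter reports the signature absent enter as zeros (dropping
them would bias toward detection). Small tie-free groups (≤ 12 per
group) are tested exactly; otherwise the normal approximation with tie
correction is used. The success rate over cohorts is reported with a
Wilson score interval (default 95%, z = 1.959964). Degenerate tests
(all observations equal) yield NaN and count as non-detections.

## Randomness

Every generator takes one integer seed. Per-sample streams are spawned
from the root seed sequence, so sample i's draw does not change when
the cohort grows, and per-cohort seeds in multi-cohort experiments are
spawned the same way (each cohort re-draws its donors). Same seed ⇒
bit-identical output, which the tests assert.

## Synthetic fixtures and what they do not show

Tests and examples run on generated stand-ins rather than downloaded
reference data:

- `synth_signature_catalog` draws signature profiles from a symmetric
  Dirichlet over the 96 contexts. The concentration parameter sets
  profile flatness (≈0.05 gives peaked, easy, realistic-looking
  signatures with effective context counts of a few; 10³ approaches the
  flat profile at 96). Real COSMIC signatures additionally share
  correlated peak structure (e.g. the C>T-rich clock-like signatures),
  which independent Dirichlet draws do not reproduce — synthetic
  references are therefore less collinear, i.e. *easier*, than COSMIC.
- `synth_weight_table` activates 1–11 signatures per donor with
  Dirichlet(0.5) weights, emulating the heavy-tailed per-sample
  activity patterns of tumor cohorts.
- `glioblastoma_like_weight_table` is a synthetic stand-in for a WGS
  glioblastoma activity table (63 donors): SBS40 active in every donor
  with median relative weight ≈ 0.485 (stratified Beta(8, 8.5)
  quantiles, so the median is a property of the table rather than of
  one random draw), the remainder mostly split between SBS1 and SBS5,
  occasional minor contributions of SBS8/11/15/30/37. Only these
  summary statistics are emulated; it is not patient data.

Consequently, passing tests demonstrate correctness of the machinery
and the qualitative tool-class behaviors (NNLS: near-exact weights,
full sensitivity, overfitting-driven low precision; greedy: high
precision, reduced sensitivity; error scaling ≈ m^(−1/2)), not absolute
performance numbers on real tumor catalogs. Checks that require the
real COSMIC catalog or activity tables read them from `data/external/`
and fail with a pointer when absent.

## Numerical choices and problem sizes

- NNLS via an active-set solver on the 96-dimensional normalized
  spectrum; linear dependence in the reference triggers a warning, not
  an error (real catalogs are near-collinear; one minimizer is still
  returned).
- Greedy tie-break: candidates are scanned in catalog order, so equal
  gains resolve to the lowest catalog index; `greedy_tol` defaults to
  0.01 cosine gain.
- Catalog column sums are validated to 1 within 1e-4 on file read
  (published files are rounded) and 1e-6 for internally constructed
  catalogs; exposure column sums may not exceed 1 + 1e-9.
- TSV round trips are lossless to 12 significant digits (`%.12g`).
- Cosine distance is 1 − cosine similarity; zero vectors are errors.
- Test-suite problem sizes (cohorts of 30–100 samples, 3–50 cohort
  replicates, burdens 100–50,000) are chosen so the full suite runs in
  well under a minute per module while keeping Monte-Carlo assertions
  (4-SE bands, chi-square at α = 0.001, rank-sum calibration over 1000
  replicates) statistically meaningful.

## Known limitations

- No trinucleotide-opportunity renormalization (genome vs exome) and no
  non-SBS signature spaces (DBS/indel/CN/SV).
- The published fitting tools are not bundled; they are evaluated only
  through their exposure files via the adapter.
- Bootstrap confidence intervals for estimates are out of scope; the
  0.06 weight floor used by some tools is available only as an optional
  post-filter.
- The difficulty score's similarity factor is the mean cosine
  similarity to the other catalog signatures by default (max is
  available); which aggregation best predicts empirical fitting
  difficulty is left to the user's data.
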