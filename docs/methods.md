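# Methods

## The model

`dcmscreen` implements a diagnostic classification model (DCM) workflow for
binary questionnaires whose items map onto a fixed set of K binary symptom
criteria through a Q-matrix (q_jk = 1 when item j measures symptom k). The
latent space is the lattice of all 2^K attribute profiles
α = (α_1, …, α_K); for the nine DSM-V schizotypal-personality criteria this
is 512 latent classes. Profiles are ordered by binary counting with symptom
1 as the most significant bit, so index 0 is the all-zero profile; every
module shares this ordering.

The item response function is the saturated identity-link G-DINA model:

    P(X_j = 1 | α*) = δ_j0 + Σ_k δ_jk α*_k + Σ_{k<k'} δ_jkk' α*_k α*_k' + …

where α* is the profile restricted to the symptoms item j measures. The
identity link is used exactly (no logit/log variants). Because the model is
saturated, the δ vector is a linear bijection of the vector of endorsement
probabilities over the item's 2^{K*_j} reduced profiles; estimation works on
the probability scale and maps back through the design matrix. For
single-attribute items — the entire default instrument — the model collapses
to a two-parameter latent-class item with guessing δ_j0 and slipping
1 − (δ_j0 + δ_j1), and every common DCM (DINA, DINO, ACDM, …) coincides with
it.

## Estimation

Calibration maximizes the marginal likelihood
Σ_i log Σ_l ν_l Π_j P_jl^{x_ij}(1−P_jl)^{1−x_ij} by EM:

* **E-step** — per-respondent posteriors over the 2^K classes, accumulated
  in log space (so 74-item response patterns do not underflow), plus
  expected exposure and endorsement counts per item per reduced profile.
* **M-step** — each reduced-profile probability becomes its expected
  endorsement rate (closed form under the identity link); the class
  distribution ν becomes the average posterior. An empty expected cell
  carries its previous value forward with a warning.

Numerical choices, all defaults overridable:

* Probability clamp ε = 1e-4 keeps estimates off the boundary and the
  log-likelihood finite.
* Monotone projection is ON by default: reduced-profile probabilities are
  projected onto the cone where adding a required symptom never lowers the
  endorsement probability (weighted pooling of violating pairs; exact
  isotonic regression for single-attribute items). This keeps the
  discrimination index non-negative and prevents label-degenerate items.
* Initialization is deterministic — baseline 0.2, full-mastery 0.8, linear
  in the number of possessed symptoms in between, uniform ν — so repeated
  runs are bit-identical without any seed.
* Convergence requires both max |ΔP| < 1e-4 and relative log-likelihood
  change < 1e-6, with max_iter = 1000; non-convergence returns a flagged
  result rather than raising.
* The structural model is the saturated ν over all 2^K classes by default;
  an independent-attributes option (ν_l as a product of per-symptom
  prevalences) is available for small samples.
* Missing responses are ignored item-wise in the likelihood
  (missing-at-random); respondents with no observed responses are rejected.
* Standard errors come from the per-item outer-product-of-gradients
  (empirical information) block, inverted and mapped to the δ scale.
  Cross-item and structural-parameter information is ignored; see
  limitations.

Respondent summaries: EAP marginals P_ik (posterior mass on classes with
α_k = 1) and the MAP profile (argmax class, ties to the lowest lattice
index).

## Item diagnostics and selection

Three per-item statistics drive selection, mirroring standard DCM item
screening:

* **Discrimination** Disc_j = P(X_j=1 | all required symptoms) − P(X_j=1 |
  none). Under the monotone fit it lies in [0, 1].
* **S-X² fit** (Orlando–Thissen style): model-implied endorsement rates per
  total score, computed by convolving item probabilities over the
  latent-class mixture with the studied item held out of the rest score,
  are compared with observed rates by Pearson X². Adjacent score groups are
  collapsed until both expected cells reach the collapse threshold
  (default 1.0); df = #groups − #item parameters. Score 0 carries no
  information about any item (nobody endorses anything) and is excluded
  before collapsing. The threshold is configurable because published
  applications differ in their (usually unstated) grouping schemes; the
  default is validated by type-I simulation rather than by reproducing any
  particular printed df.
* **Wald DIF**: the studied item gets group-specific parameters in a joint
  fit anchored by all other items; the statistic contrasts the two δ
  vectors with the sum of the per-group OPG covariances, df = #item
  parameters (2 for single-attribute items), run item by item with the
  pooled calibration as warm start.

Selection excludes an item when Disc_j < 0.30, S-X² p < .01, or DIF
p < .01 — strict inequalities, so boundary values are retained — with
reason codes LOW_DISC / MISFIT / DIF / NOT_EVALUABLE. Diagnostics are
computed once on the full-scale calibration (single pass, no iterative
re-selection). Symptoms left with no retained item are dropped from the
reduced Q-matrix with a loud warning, and the retained items are refit.

Reliability: per-symptom classification consistency is computed
analytically as the mean of P_ik² + (1−P_ik)² — the expected agreement of
two independent classifications drawn from each respondent's posterior.
This deterministic form was chosen over simulated parallel classifications;
it is bounded in [0.5, 1]. The classical Guttman split-half coefficient
2(1 − (V_A + V_B)/V_{A+B}) is provided on complete cases (even–odd split by
default).

## Screening

PP-SPD, the posterior probability of meeting the DSM-V rule of at least
five of nine criteria, is computed two ways:

* `pp_spd_marginal` (default): Σ over the 256 qualifying profiles of
  Π_k P_ik^{l_k}(1−P_ik)^{1−l_k}, i.e. the aggregation formula that treats
  symptoms as independent given the marginals, by exact enumeration
  (K ≤ 16).
* `pp_spd_exact`: the posterior mass on qualifying latent classes. The two
  agree exactly when the posterior factorizes over symptoms and differ
  otherwise; both are exposed because published screening reports are
  ambiguous about which aggregation they use, and the marginal form is the
  one printed.

Cut semantics are strict: a symptom is flagged present when P_ik > 0.5 and
a respondent is high-risk when PP-SPD > 0.5; values exactly at the cut are
scored negative. Validity against an external criterion uses the 2×2
table (sensitivity, specificity, odds ratio with Haldane–Anscombe 0.5
correction and Wald log CI) and a rank-based AUC with midrank ties (PP-SPD
clusters near 0 and 1). Agreement between two binary ratings uses Cohen's
κ with the Fleiss H0 variance for the z-test and upper-inclusive
Landis–Koch bands (0–0.20 slight, …, 0.81–1.0 almost perfect; κ < 0
"poor"). Symptom co-occurrence is summarized by pairwise phi
correlations.

## Synthetic data

The generator emulates the population and instrument regime the screening
design assumes, since no respondent-level data are available:

* True profiles: probit copula — a latent multivariate normal with a given
  correlation matrix thresholded at the quantile matching each symptom's
  prevalence. Defaults: prevalences (0.32, 0.43, 0.41, 0.31, 0.27, 0.34,
  0.36, 0.48, 0.31) and a latent correlation matrix in the 0.04–0.68 range
  echoing the published symptom-classification correlations. Non-PD
  matrices are repaired by eigenvalue clipping with a warning.
* Instrument: 74 single-attribute items interleaved over 9 criteria
  (8,8,8,8,8,8,8,9,9 per symptom, mean 8.2), baselines δ_j0 ~ U[0.05,
  0.30], discriminations ~ U[0.30, 0.60] — the reported 0.302–0.569
  discrimination regime. DIF items shift the focal group's baseline up and
  main effect down by `dif_shift`, leaving full-mastery endorsement
  unchanged. In planted-defect tests a DIF shift of 0.25 is used — a
  moderate-to-large effect that a 1,000-respondent calibration should
  detect — and planted low-discrimination items use Disc ≈ 0.12, clearly
  below the 0.30 rule.
* External criterion: each true symptom indicator flipped independently
  with probability 0.1, then the ≥6-symptom high-risk rule (the cutoff
  reported for comparable student samples with the reference instrument).
* One master seed spawns independent substreams per stage (profiles,
  instrument, responses, criterion, group, missingness), so everything is
  reproducible bit for bit and stages can be regenerated independently.

What the generator does **not** emulate: item-specific content effects,
lie-detection/validity items, non-MCAR missingness, acquiescence or other
response styles, and any dependence of item quality on symptom content.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the assumed generating process, not the
field-data behavior of any particular questionnaire.

## Problem sizes used in the test suite

Simulation-based tests are scaled so the whole suite runs on one CPU in a
few minutes, as the package's own choice of desk-scale study conditions:

* Parameter recovery: N = 2000 respondents, 47 single-attribute items over
  9 symptoms (512 classes); recovery demanded to MAE ≤ 0.05 on endorsement
  probabilities and ≥ 0.80 per-symptom classification accuracy.
* Wald DIF type-I calibration: 500 no-DIF replicates at N = 2000 with the
  instrument's 8-items-per-symptom ratio (J = 24, K = 3), α = .05,
  acceptance within the 95% binomial band.
* S-X² type-I calibration: 200 replicates at N = 1000 (J = 12, K = 3),
  α = .01, same band criterion.
* Planted-defect selection: one 74-item, 9-symptom, N = 1000 dataset with
  six planted low-discrimination and four planted DIF items.

## Known limitations

* The OPG item-block covariance behind the Wald DIF test ignores
  cross-parameter information and is mildly anti-conservative in small
  samples (empirically ~0.07–0.09 rejection at nominal .05 with N = 1000
  and few items per symptom, nominal by N = 2000). A joint-information
  covariance did not remove the small-sample inflation in our experiments,
  so the simpler standard form is kept; treat DIF p-values near the
  threshold with caution in small samples.
* The marginal PP-SPD form inherits the independence approximation;
  `pp_spd_exact` is the coherent alternative when the full posterior is
  available.
* A symptom measured only by uninformative items leaves its latent
  dimension unidentified; EM can then drift that dimension toward a single
  item's noise (a generic latent-class degeneracy). The Q-matrix validator
  warns about un-measured symptoms, but cannot detect weakly measured ones.
* Isotone projection for multi-attribute items uses iterative pair pooling,
  which is monotone on exit but not the exact least-squares projection for
  K* > 1.
* Exact PP-SPD enumeration is limited to K ≤ 16.
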