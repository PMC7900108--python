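# Methods

`lldnet` analyses weighted structural brain networks from a three-arm
clinical design: healthy older adults (HOA) and depressed MCI patients with
and without cerebral amyloid accumulation (LLD-MCI-A+ / LLD-MCI-A−), with
group sizes 21 / 26 / 27. The pipeline starts from subject-level
connectivity matrices — symmetric, nonnegative, streamline-count-scale
weights over the 90 cortical and subcortical AAL regions — and ends at
group differences in network topology and correlations between topology
and cognition. Image processing and tractography are out of scope.

## Network measures

For an undirected weighted network with weights `w_ij ≥ 0` over N nodes:

* **Nodal degree** `k_i = #{j : w_ij > 0}` and **nodal strength**
  `s_i = Σ_j w_ij`.
* **Edge density** = existing edges / (N(N−1)/2); **total strength** =
  sum of weights over unordered pairs.
* **Nodal clustering** uses the Onnela geometric-mean form
  `C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1))`, with `C_i = 0`
  for `k_i < 2`. Weight normalisation (`ŵ = w / max w`) is a flag,
  **default off**: on raw streamline counts the clustering values live on
  the count scale (tens, not [0, 1]), matching how these cohorts'
  clustering statistics are reported (e.g. group means near 28 ± 4 on our
  synthetic cohorts and in comparable published tables). The network
  **clustering coefficient** C is the mean of the nodal values, isolated
  nodes contributing zero.
* **Shortest paths** are computed by Dijkstra's algorithm
  (`scipy.sparse.csgraph`) on edge lengths `l_ij = 1 / w_ij`, the standard
  connectivity-to-length mapping for count-weighted networks: stronger
  connections are shorter. **Characteristic path length** (CPL) L is the
  mean distance over reachable unordered pairs; unreachable pairs are
  excluded with a warning rather than failing or substituting a penalty,
  because tractography networks are near-fully connected and exclusion is
  what the common toolboxes do. A network with no reachable pair is an
  error.
* **Regional efficiency** `E_i = (1/(N−1)) Σ_{j≠i} 1/d_ij` with
  `1/∞ = 0`. Note that describing this measure verbally as "the average
  shortest path length from the node" (as is sometimes done) actually
  describes average distance; the implementation uses the standard
  inverse-distance efficiency, which is what the widely used connectivity
  toolboxes compute.
* **Small-worldness** is defined here as the literal ratio `S = C / L`.
  The conventional sigma (clustering and CPL each normalised by random
  null networks) is deliberately not computed; S is only meaningful as a
  within-study comparative quantity.

Ties in shortest paths never matter because only distances enter any
output. Input validation is strict: asymmetry beyond a relative 1e-8 is an
error; asymmetry within tolerance is repaired by mirroring the upper
triangle, with a log message. Nothing else is silently fixed.

## Group comparison

Each measure is compared across the three groups with a **permutation
ANCOVA**. The observed statistic is the partial F for the group factor
from the linear model `y ~ 1 + group + age + sex + education` against the
covariates-only reduction. The permutation null uses **Freedman–Lane**:
residuals of the covariates-only model are permuted and the covariate fit
is added back before recomputing F. This choice matters because the
covariates are genuinely confounded with group (controls are younger,
more educated, more often male): naive label shuffling has no calibration
guarantee in that situation, while Freedman–Lane is asymptotically exact.
A `labels` scheme is retained for comparison only. The p-value estimator
is `(b + 1) / (m + 1)` (never zero), with m = 10,000 permutations by
default (tests and bundled experiments use smaller m, stated per run).
An exhaustive-enumeration mode covers small two-group problems and is
used to verify the Monte-Carlo path exactly.

Multiplicity is handled at two levels, both Benjamini–Hochberg step-up:
across the 90 nodes within each nodal measure (omnibus), and across the
three pairwise contrasts within each post-hoc family. Post-hoc pairwise
permutation ANCOVAs run on all nodes by default, with a `survivors` mode
restricting them to omnibus-FDR survivors. Global measures are reported
with raw p-values only — a five-element heterogeneous family is not a
natural FDR unit. Zero-variance features are skipped with a warning
rather than aborting the run.

**Adjusted group means** are model predictions at the covariate grand
means, with t-based confidence intervals (default 95%; the level is a
parameter) on `n − g − q` degrees of freedom. When covariate
distributions are balanced across groups these reduce to raw group means.

## Correlations with cognition

Within each patient group separately (HOA excluded by default), Pearson
**partial correlations** between each measure and each cognitive score
control age, sex and education: both variables are residualised on
`[1 | covariates]` by least squares and the residuals correlated.
Significance uses `t = r √((n−2−q)/(1−r²))` on `n−2−q` degrees of
freedom. FDR families are the 90 nodes within one (group, score, nodal
measure) triple; global-measure correlations are reported unadjusted.
Missing scores are handled pairwise complete-case with the effective n
recorded per cell; a cell with `n ≤ q + 2` complete cases is skipped with
a warning. Between-group contrasts of correlations are provided as
descriptive Fisher-z tests with effective n reduced by q — at these group
sizes they are underpowered and labelled accordingly.

## Demographic statistics from printed moments

Pooled-variance two-sample t, one-way ANOVA F and Pearson χ² depend on
the data only through per-group (n, mean, SD) or counts, so the published
demographic table is exactly recomputable. `moment_matched_sample`
affinely rescales a seeded normal draw to hit a target mean and (n−1) SD
to machine precision; any statistic consuming only those moments is
seed-invariant (tested). Recomputation findings, frozen into the packaged
fixture as per-statistic consistency flags:

* All χ² values for the sex distribution match **uncorrected** Pearson χ²
  to better than 0.1%, and do *not* match Yates-corrected values, despite
  the source table's footnote labelling them Yates'. The implementation
  follows the numbers: the default is no continuity correction, with a
  `yates` flag available.
* One row (word-list recall z-score) reproduces only if the second
  group's printed mean `2.05` is read as `−2.05` — a sign typo; its F and
  two of its t statistics are flagged inconsistent.
* A handful of rows (trail-making A raw and z, COWAT lexical tests,
  Boston naming z, COWAT market z, and scattered third-contrast t values)
  miss 1% reproduction under a complete-data assumption, most plausibly
  because those tests were not administered to every subject. These are
  flagged in the fixture and reported descriptively rather than asserted.
* Printed pairwise-t signs are not uniform across rows; magnitudes are
  compared.

The amyloid-status rule is exactly as defined for florbetaben-PET visual
reads: BAPL 1 → negative, BAPL 2 or 3 → positive.

## Synthetic cohorts

No subject-level matrices are deposited for this kind of clinical DWI
study, so validation uses synthetic cohorts whose ground truth is known.
The generator's defaults *are* the study conditions:

* **Covariates**: normal draws at the published per-group age and
  education moments; sex Bernoulli at the published proportions. The
  confounding structure (younger, more educated, more often male
  controls) is therefore reproduced, which is exactly the regime the
  Freedman–Lane choice targets.
* **Connectomes**: one shared template per study — nodes placed uniformly
  in the unit cube, the closest pairs connected up to density 0.30,
  log-normal weights (median 40, log-SD 0.6; chosen once so nodal
  strengths land in the published 600–2700 streamline range at that
  density). Each subject gets the template times a global scale factor
  (SD 0.10, emulating per-subject tractography yield), additive edge
  noise (SD 6), a covariate leak (−0.4 weight units per year of age per
  edge, so age depresses connectivity), and any planted additive effects
  on a chosen node's incident edges for a chosen group. All perturbations
  apply to template edges only, so topology (hence degree and density) is
  constant across subjects; group effects are planted in the weighted
  channels (strength, clustering, efficiency) that the analysis targets.
  Negative weights are clipped at zero; the clip rate is logged and is
  ~0.3% at defaults.
* **Scores**: covariate terms plus noise; a linked score adds
  `β × (measure residualised on covariates)` with β and the noise SD
  solved so the partial correlation given covariates equals the target r
  at unit conditional scale. A noise floor (0.2) bounds the feasible |r|
  at √(1 − 0.04) ≈ 0.98; infeasible targets raise an error stating the
  bound.

What the generator does **not** emulate: distance-dependent streamline
attenuation beyond the geometric template, hemispheric symmetry,
topology variation across subjects, heavy-tailed subject outliers, and
site/scanner effects. Passing tests therefore demonstrate correctness and
calibration of the *statistics*, not that real cohorts would show any
particular effect. One realistic consequence visible in the bundled
experiments: the shared global scale factor makes nodal measures strongly
correlated across nodes, so correlation "discoveries" arrive as whole
node families; within-family |r| ranking is only node-specific when
node-level variation dominates.

## Validation experiments (what the numbers mean)

* **Oracle equivalence**: on 200 random graphs with N ≤ 6, Dijkstra
  distances agree with a brute-force Floyd–Warshall to < 1e-10 and Onnela
  clustering with exhaustive triple enumeration to < 1e-10.
* **Permutation exactness**: on 6 subjects in two groups of 3 without
  covariates, the exhaustive-mode p equals independent enumeration over
  all 20 assignments exactly.
* **Type-I calibration**: 500 null cohorts at the study design (74
  subjects, confounded covariates, outcome driven by covariates only),
  500 permutations each: the Freedman–Lane rejection rate at α = 0.05
  must fall inside the binomial 95% band 0.05 ± 0.019 (observed ≈ 0.04–0.06
  across seeds).
* **Planted-effect recovery**: with a +6 weight-unit effect on the left
  calcarine's incident edges in the A+ group (≈ +160 strength at
  density-0.3 degree ≈ 27), the planted node ranks first by omnibus F for
  strength in ≥ 80% of 20 independent cohorts (observed 100%). A partial
  correlation planted at r = 0.6 is recovered within ±0.05 at n = 2000.

Monte-Carlo sizes (500 × 500 calibration, 20 recovery cohorts, n = 2000
for correlation recovery) were chosen as the smallest sizes at which the
binomial/Fisher sampling error is well below the tolerances being
checked; the full acceptance run completes in well under a minute per
experiment on one core.

## Numerical choices and degenerate inputs

* Residual projectors are formed via QR; partial F is computed from
  residual sums of squares under both models, vectorised over features
  and permutations (all features of a family share one permutation set,
  the standard choice).
* Permuted F values are counted as ≥ observed with a 1e-12 absolute
  cushion so exact ties under enumeration are not lost to float jitter.
* Group indicator coding is reference-based; F and adjusted means are
  invariant to the coding and to the 0/1 sex polarity (tested).
* Degenerate cases: zero-variance features are skipped (NaN + warning);
  constant residual vectors raise a degenerate-data error; |r| = 1 maps
  to the smallest positive p with a warning; zero pooled variance with
  unequal means is an error for t and +inf for F.
* BH adjustment uses a stable sort; equal p-values get equal adjusted
  values, and adjusted values never fall below the raw p (tested).

## Known limitations

* Small-worldness as C / L is scale-dependent (units of inverse length ×
  clustering); it is comparable within a study, not across weighting
  conventions.
* The pipeline treats matrices as given; no thresholding, consistency
  filtering, or density matching across subjects is applied.
* Fisher-z contrasts between groups of 26/27 subjects have low power;
  they are descriptive output, not inference.
* Parametric ANCOVA p-values exist only as a diagnostic; the permutation
  p is the primary inference everywhere.
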