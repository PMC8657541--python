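# Methods

## Model and procedure

The pipeline analyses *metabolic connectivity* in a two-group FDG-PET
design: each subject contributes one uptake value per volume of interest
(VOI), and connectivity within a group is the inter-subject Pearson
correlation between regions. The analysis is the composition

    uptake -> SUVR -> per-group correlation networks -> Fisher z
           -> label-permutation edge test -> increased/decreased edges

Assumptions worth making explicit:

- **Edges, not nodes.** The method tests region *pairs*; it says nothing
  about regional mean differences (those would be a separate univariate
  comparison, out of scope here).
- **Inter-subject correlation is a group-level quantity.** A group of n
  subjects yields a single correlation estimate per edge, based on n
  points; with n = 7 these estimates are individually noisy, which is
  precisely why inference goes through a permutation null rather than an
  asymptotic one.
- **Exchangeability under the null.** The permutation test assumes that
  under "no group difference" the group labels are exchangeable across the
  pooled subjects. Covariates that break exchangeability (age, weight,
  scanning batch) are not modelled.

## SUVR normalization

`suvr[s, v] = u[s, v] / ref[s]` with `ref[s]` the *unweighted mean* of the
subject's uptake over all atlas regions flagged `is_reference`. The
default atlas flags both medulla hemispheres. Pooling bilaterally is a
deliberate choice: with a single reference region, that region's SUVR is
identically 1, has zero variance across subjects, and every correlation
involving it is undefined; with a bilateral pool, each medulla node keeps
between-subject variance and remains a usable network node. No volume
weighting is applied (mask volumes are rarely published); the pooled
regions and method are recorded in `reference_definition` and in
`run_metadata.json`.

Consequences tested in the suite: per-subject scale invariance (the point
of reference normalization), and mean reference SUVR exactly 1 per subject
(to 1e-12).

## Correlation and Fisher transform

Pearson correlation on SUVR values directly — no ranking, no partial
correlation, no covariate regression. Matrices are symmetrized and clipped
to [-1, 1] to remove floating-point dust; the diagonal is exactly 1.

Fisher z = atanh(r) is applied after clamping r to `[-1+eps, 1-eps]`.

- `clamp_epsilon = 1e-6` (default): with 7 subjects per group, sample
  correlations of exactly +/-1 have positive probability in permuted
  pseudo-groups; clamping keeps every edge finite and testable. At the
  clamp, |z| ~ 7.25 — far above any realistic observed difference, so
  clamped edges behave as "maximally extreme" without producing infinities.
- The z diagonal is set to 0 by convention; self-edges are never tested.

## Permutation edge test

- **Statistic:** `delta_z = z_a - z_b` per edge (group a = mutant by
  convention). Two-sided on |delta_z|; direction recovered from the sign.
  A studentized statistic would be an alternative; the plain z difference
  is the simplest statistic consistent with a shared-label permutation
  null and is what the package documents and tests.
- **Null:** pooled subjects re-partitioned uniformly at random into
  pseudo-groups of the original sizes, with replacement across iterations
  (the identity split is not excluded; with C(14,7) = 3432 distinct splits
  and 5000 draws, duplicates are expected and harmless). One permutation
  stream is shared by all edges, preserving the dependence structure
  across edges within a permutation.
- **p-value:** `(1 + #{|delta_z_perm| >= |delta_z_obs|}) / (N + 1)`
  (add-one smoothing). Ties count toward the numerator. Both choices are
  conservative and guarantee p in [1/(N+1), 1] with validity at every
  nominal level.
- **Tie guard (`TIE_ATOL = 1e-9`):** permutations that reproduce the
  observed grouping are exact ties in exact arithmetic, but the vectorized
  null path sums in a different order than the observed path, so without
  an absolute tolerance such ties would be counted only ~half the time,
  biasing p downward by ~1/(number of distinct splits). Gaps between
  genuinely different |delta_z| values in continuous data are many orders
  of magnitude above 1e-9. The exhaustive-enumeration test (4+4 subjects,
  all 70 splits) pinned this down.
- **Thresholds:** tiers at p < 0.05, 0.01, 0.005 with *strict* inequality
  (p = 0.05 is not significant); the tier is the smallest threshold
  passed.
- **Multiplicity:** no correction by default — the tiered, uncorrected
  thresholds are the method being implemented. An optional
  Benjamini–Hochberg column (`scipy.stats.false_discovery_control`)
  annotates but never filters edges; at 1378 edges and alpha = 0.05, ~70
  null edges are expected to pass the weakest tier, and the README says
  so.
- **Group-swap symmetry:** subjects are pooled in table row order, so with
  equal group sizes the same seed produces the same splits whichever group
  is called "a": every delta_z is negated, labels swap, p-values are
  identical (tested).

## Synthetic cohorts

The generator emulates the study conditions: two groups of n = 7, 53 VOIs,
positive SUVR-like values, group-specific correlation structure, and
injectable single-edge differences.

- **Marginals:** Gaussian with per-region mean 1.0 (1.2 for reference
  regions, so reference pooling has something to divide by) and
  coefficient of variation 0.1 — a small-CV, SUVR-like scale. Gaussianity
  makes the Pearson correlation targets exact; positivity is enforced by
  rejecting any subject draw containing a non-positive value. At cv = 0.1
  a non-positive value is a ~10-sigma event, so rejection essentially
  never fires and the realized correlation structure is the target one
  (tested empirically at n = 2000; a configuration error is raised if the
  rejection rate exceeds 50%, long before truncation could distort
  correlations).
- **Effect injection:** setting r(i, j) = t in one group's matrix can
  leave the correlation cone; the matrix is projected back by iterated
  eigenvalue clipping at 0 plus diagonal renormalization (tolerance 1e-10,
  max 100 iterations). Only the post-conditions (symmetric, unit diagonal,
  eigenvalues >= -1e-10) are contractual; the *post-projection* matrix is
  the ground truth the generator reports and tests converge to.
- **Randomness:** one root seed; child streams are spawned per group in
  lexicographic label order, so adding a group never changes another
  group's draws. Identical spec + seed gives bit-identical tables.
- **What it does not emulate:** scanner noise, image-space smoothing and
  registration error, anatomical covariance of real brains, non-Gaussian
  uptake tails, or litter/batch structure. Passing tests therefore
  validate the *statistical procedure*, not PET acquisition; real-data
  conclusions still depend on acquisition quality upstream of this
  pipeline.

## Default atlas

53 VOI names with hemisphere labels, the bilateral medulla flagged as
reference. The name list is a best-effort reconstruction from published
edge tables of this design (including their inconsistent spellings, e.g.
`mamilothalamic_tract_L` vs `mammilothalamic_R`, kept verbatim because
column matching is deliberately exact and case-sensitive — silent fuzzy
matching would hide data errors). Nine contralateral counterparts were
added to reach 53. The atlas is illustrative and fully user-replaceable;
nothing downstream depends on the specific names.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` use the following experiment
sizes, chosen to exercise the study-scale design while keeping replicate
studies comfortably sized:

- **Exhaustive oracle:** 6 regions, 4+4 subjects — all C(8,4) = 70 label
  splits enumerable; Monte-Carlo p (5000–20000 draws) must sit inside the
  binomial 99% CI of the exact p at every edge.
- **Type-I calibration:** 200 null cohorts, 20 regions, exchangeable
  rho = 0.3, 7+7 subjects, 500 permutations; mean flagged fraction at
  alpha = 0.05 expected in [0.035, 0.065], and the pooled p-value ECDF
  must not exceed the uniform CDF by more than the one-sided 1%
  Kolmogorov bound (anti-conservatism check).
- **Power/recovery:** single injected edge, KO target r in
  {0, 0.3, 0.6, 0.9} vs WT r = 0, 7+7 subjects, 6 regions, 200 replicates,
  500 permutations. Replicates share derived seeds across effect sizes
  (common random numbers), so the monotonicity of the detection curve is
  compared replicate-for-replicate rather than through independent noise.
- **Full scale:** 53 regions, 7+7, 5000 permutations — 1378 edges, run
  end-to-end twice to confirm byte-identical artifacts.

## Known limitations

- Uncorrected tiered thresholds are faithful to the method but liberal at
  1378 edges; the BH annotation is the honest companion.
- n = 7 per group gives very noisy per-edge correlation estimates; power
  at |r| differences below ~0.6 is poor (the detection study quantifies
  this), so absence of significance is weak evidence of absence.
- The permutation p-value resolution is 1/(N+1); at N = 5000 the smallest
  attainable p is ~2e-4, which is adequate for the 0.005 tier but not for
  genome-scale-style thresholds.
- Whether reference regions should remain network nodes is a design
  choice; here they do (bilateral pooling keeps their variance), and
  excluding them is a one-line atlas edit.
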