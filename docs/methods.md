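# Methods

`wellnets` implements a pipeline for asking whether individual differences
in a multi-item wellbeing questionnaire are mirrored by individual
differences in brain activity patterns during a shared naturalistic
stimulus, and for organising the implicated voxels into networks and sets
of co-active networks. This note describes the statistical model of every
stage, the synthetic cohorts the package generates to exercise them, the
numerical choices made where the procedure is underdetermined, and the
known limitations — including one substantive inferential limitation of
the procedure itself that the test suite demonstrates.

## Searchlight spatial inter-participant RSA

For participants i, j, any pattern vectors x_i, x_j are compared with the
correlation distance

    d(x_i, x_j) = 1 − (x_i − x̄_i)·(x_j − x̄_j) / (‖x_i − x̄_i‖₂ ‖x_j − x̄_j‖₂) ∈ [0, 2].

At every mask voxel v and timepoint t, the local pattern is the recording
restricted to a searchlight sphere centred at v intersected with the mask.
The participant-pair distance matrix of these patterns is compared with
the pair distance matrix of the 7-item wellbeing profiles (T-score scale,
population mean 50, SD 10) by a partial Spearman rank correlation: both
strict upper triangles are rank-transformed (average ranks for ties),
residualised by least squares on an intercept, the ranked pairwise
absolute age differences, and the ranked same-gender indicator (same = 1,
different = 0), and the Pearson correlation of the residuals is ρ(v, t).
A positive ρ means participants with more similar local activity also
report more similar wellbeing profiles.

Numerical contracts:

- Searchlight radius is given in voxel units; the default 2.0 produces the
  33-voxel sphere (inclusive ‖δ‖² ≤ r²). A 6 mm radius on a 3.2 mm grid
  would give 27 voxels; because the protocol this reproduces prints "33
  voxels", the voxel-unit radius is the primitive and any mm conversion is
  the caller's responsibility.
- Spheres are clipped to the grid and mask; fewer than 3 usable voxels
  marks the searchlight undefined (NaN). A participant whose local
  pattern is constant has their pairs dropped listwise; fewer than 6
  usable pairs marks the voxel undefined.
- Collinear covariate columns after ranking (e.g. a single-gender cohort)
  are dropped with a warning, which makes the partial correlation degrade
  gracefully to fewer controls. Because ranking is invariant to strictly
  monotone recoding, the direction of the 1/0 gender coding is immaterial.
- The vectorised driver (gathered sphere patterns, one einsum per sphere
  size, a fixed rank-space projector) is required by tests to agree with a
  naive per-voxel loop to 1e-10 and to be invariant to participant order.

## Network discovery

The ρ field (mask voxels × timepoints, undefined entries imputed to 0 with
a warning) is decomposed by spatial ICA — FastICA with whitening, voxels
as samples — into component maps and timecourses whose product
reconstructs the field. Maps are z-scored over mask voxels (zero mean,
unit variance; the compensating scale moves into the timecourse) and the
sign convention makes each map's largest-magnitude loading positive. ICA
sign is otherwise arbitrary, and the convention pins down peak-timepoint
and thresholding behaviour. Non-convergence triggers a documented seeded
restart schedule (5 attempts, seed + 1000·attempt); if none fully
converges the final fit is used with a warning — on noise-dominated
desk-scale fields FastICA routinely stops at its iteration cap while the
fit is already stable, and determinism is preserved because the iteration
count is fixed.

Component timecourses are clustered with Ward linkage on Euclidean
distance and the dendrogram is cut into a requested number of clades
(scipy's agglomerative implementation). Full-scale defaults are 100
components and 8 clades, mirroring the protocol this package reproduces.

Component maps are thresholded by a two-component 1-D Gaussian mixture
fitted to the signed in-mask loadings (10 restarts, fixed seed): "active"
is the component with the larger mean, and voxels with posterior > 0.5 and
positive loading are retained. The mixture is fitted to signed rather than
absolute loadings because the sign convention already orients each map.
Thresholded maps are cleaned by removing connected clusters of ≤ 50
voxels (strictly more than 50 survive) under a configurable 6/18/26
neighbourhood rule (default 26). Clade maps are the voxelwise nonzero
mean of their surviving member maps.

## Mantel inference

Per component: loadings are normalised by the maximum; nine masks are
built at normalised thresholds 0.1 … 0.9 (strictly above, then the
cluster filter; empty results dropped, all-empty marks the component
untestable). At the component timecourse's peak (argmax, earliest on
ties), the whole-mask pattern distance matrix is computed for each
candidate mask and the mask with the highest partial Spearman ρ against
wellbeing is selected (ties to the larger mask, which maximises
downstream testability). The Mantel test jointly permutes rows and
columns of that brain distance matrix — wellbeing and covariate matrices
are never permuted — recomputes the partial Spearman per permutation, and
reports the one-tailed p = (1 + #{ρ_perm ≥ ρ_obs}) / (n_perm + 1); the +1
smoothing guarantees p ≥ 1/(n_perm+1). Component p-values are
Benjamini–Hochberg adjusted with significance at adjusted p < 0.01.
Screening before testing removes user-listed artefact components and
components whose GMM-thresholded positive maps leave no surviving
cluster.

## Annotation regression

Six annotation channels at 3 s resolution (valence, arousal, social,
speaking, plus brightness and amplitude as low-level controls) are
standardised and upsampled to 1 s by repetition (the channels are
segment-constant, so interpolation would only blur block edges). The
component timecourse is shifted by a fixed 4 s haemodynamic lag (index
shift at 1 s resolution; no HRF convolution) and regressed by OLS with
intercept on all six channels. Significance per channel is by
permutation: the target channel's 3 s series is shuffled, re-upsampled
and refit (others fixed; implemented exactly via Frisch–Waugh
projection), two-tailed on |β| with +1 smoothing. The component ×
annotation family is BH-corrected at 0.05.

## Decoding

Merged clade maps are correlated (demeaned Pearson over the analysis
mask) with labelled term-association volumes; per clade the top-k terms
by r are reported and r ≥ 0.10 is flagged as interpretable. Term maps are
plain volumes supplied by the user; no database access is involved.

## Synthetic cohorts

The generator emulates the statistical structure the searchlight analysis
assumes, with full ground truth:

- Profiles: 7 items, multivariate normal on the T-score scale with
  pairwise inter-item correlation 0.5 (the questionnaire's items are
  moderately to highly correlated in practice; the exact joint
  distribution is a free choice). Ages uniform integers 19–55, binary
  gender, both independent of wellbeing by default; a `confound_demographics`
  flag couples them to the profile mean so tests can verify partialling.
- Geometry: 12³ grid, full-volume mask, 300 timepoints at 1 s, 20
  participants, 2 disjoint compact 75-voxel networks (grown over the
  6-neighbourhood), comfortably above the 50-voxel cluster filter.
- Activity: network k is active in a balanced binary block design
  (25-timepoint blocks; active when bit k of the block index is set), so
  envelopes of different networks are exactly orthogonal and each network
  is active half the time.
- Coupling: inside an active network, participant p's pattern is
  signature + c · B v_p + noise, where the signature (SD 0.5) is shared,
  B has orthonormal columns, and v_p is p's mean-centred unit-norm item
  vector. Orthonormality makes planted-deviation inner products equal
  item-profile Pearson correlations exactly, so pattern distance is
  monotone in profile distance by construction. The default coupling
  c = 4.0 with unit noise yields whole-network partial Spearman ρ of
  roughly 0.4–0.7 across seeds — the magnitude of effect this type of
  analysis reports on real cohorts — and was fixed at design time from a
  power sweep of the planted effect.
- Annotations: each tested channel couples to exactly one network
  (valence → network 0, speaking → network 1, then arousal, social);
  coupling several channels to one envelope would make them collinear
  regressors that split the recovered coefficient. Continuous channels
  add Gaussian noise (SD 0.7); binary channels flip state with
  probability 0.1; controls are pure noise. Channels lead the planted
  response by the same 4 s lag the regression removes.
- Term maps: one lightly smoothed map per network plus distractor blobs.

What the generator does not emulate: haemodynamics beyond the fixed lag,
spatial noise correlation (noise is i.i.d. per voxel-timepoint; an AR(1)
flag adds temporal autocorrelation only), motion or scanner artefacts,
and anatomically realistic masks. Passing tests therefore demonstrate the
statistical machinery, not robustness to real-data artefacts.

## Desk-scale analysis settings

`PipelineConfig` defaults mirror the full-scale protocol (100 components,
8 clades, 10,000 permutations, FDR 0.01/0.05, 9 thresholds, >50-voxel
clusters, 4 s lag). `PipelineConfig.desk_scale()` adapts only the
decomposition and permutation sizes to the generated cohorts: 10
components cut into 4 clades (a 12³ field with two planted sources
supports far fewer meaningful dimensions than a whole-brain recording),
and 1,999 permutations so the smallest attainable BH-adjusted p
(≈ 0.0005 · m/rank) stays well below the 0.01 level with ~10 tested
components. Calibration suites use 500 replicates of 999 permutations.

## Limitations

- **The Mantel stage is anticonservative under a global null.** The
  tested brain distance matrix is computed at the component timecourse's
  own peak timepoint, inside the mask (one of nine thresholds) that
  maximises the observed ρ — both selected from the same data the Mantel
  statistic then re-uses. The permutation null shuffles participants of
  the selected matrix but does not repeat the selection, so the observed
  value is effectively a maximum over hundreds of chance draws compared
  against an unselected null. On null synthetic cohorts (no planted
  coupling) the selected ρ averages ≈ 0.2 and most components reach
  nominal significance, while the same mask evaluated at a random
  timepoint is perfectly calibrated (ρ ≈ 0) — as is the Mantel test
  itself on independent matrices. The effect is not a small-grid
  artefact (it persists, indeed grows, at 16³), and component screening
  does not remove it, because searchlight overlap makes even null
  component maps spatially smooth enough to pass the 50-voxel filter.
  The package implements the published selection-then-test procedure
  faithfully and documents the corresponding test as failing; a
  null-safe variant would need a selection-aware null (re-running
  threshold and peak selection inside every permutation), which is a
  different procedure from the one this package reproduces. Practical
  reading: a significant component indicates a strong
  wellbeing–pattern correspondence at its peak, but the permutation p
  alone overstates the evidence; the planted-recovery contrast (ρ ≈
  0.4–0.7 for real coupling vs ≈ 0.2 for selection noise) shows the
  effect sizes that survive honest scrutiny.
- GMM thresholding assumes a roughly two-regime loading distribution; on
  unimodal maps the split is arbitrary and only the cluster filter
  protects downstream stages.
- The annotation permutation shuffles 3 s segments freely; any run
  structure in real stimuli (scene boundaries, autocorrelation beyond
  segments) is not respected, which can make the regression null too
  liberal on strongly autocorrelated channels.
- Decoding is descriptive: spatial correlations with term maps carry no
  inferential statement.
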