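# Methods

## Shape model and superimposition

A specimen is a configuration of k labelled 2D points; its shape is what
remains after removing position, size and orientation. Size is measured as
centroid size, `CS = sqrt(Σ ||x_j − x̄||²)`. Generalized Procrustes analysis
(GPA) centres each configuration, scales it to CS = 1, and rotates it to
least-squares fit the consensus; the consensus is recomputed as the mean of
the aligned configurations and the loop repeats until the consensus moves by
less than `tol` (root summed squared coordinate difference). Rotations are
constrained to determinant +1: all specimens are assumed digitised in the
same orientation, so a reflection would be an error, not a fit.

Optimal rotations come from the SVD of the 2×2 cross-product matrix
`TᵀM` with the smaller singular direction sign-corrected (the 2D Kabsch
construction). After convergence the whole solution is rotated so the
consensus lies along its principal axes, with a third-moment sign rule to
pick between the two 180°-apart candidates. Without this canonicalisation
the output would inherit the arbitrary orientation of the first input
configuration and the similarity-invariance guarantee (identical output
under per-specimen rotation/translation/scaling of the inputs) would only
hold up to a global rotation.

### Sliding semi-landmarks

Outline semi-landmarks carry no point-wise homology, so between rotation
passes each one is allowed to slide along its local tangent — the chord
between its two curve neighbours (for a terminal semi-landmark, the chord
from the point to its single neighbour). The update projects the point's
deviation from the consensus onto the tangent direction,
`p ← p + ((c − p)·u) u`, which is the minimiser of squared distance to the
consensus achievable along the tangent line: the Procrustes-distance
criterion, not bending energy. Sliding therefore never increases a slid
point's deviation from the consensus. After each sliding pass every
configuration is re-centred and re-scaled so the unit-size/centred
invariants stay exact, then re-rotated.

### Numerical choices

- `tol = 1e-8` on consensus movement; `max_iter = 1000`. Plain GPA converges
  in a handful of iterations, but sliding introduces a slow tangential drift
  mode — the semi-landmarks' positions along the outline are nearly a gauge
  freedom, and the consensus follows them with a geometric decay of roughly
  0.975 per iteration — so reaching `tol` typically takes several hundred
  cheap iterations (about a second at n = 36, k = 36). Non-convergence
  returns the best state with `converged=False` and a warning rather than
  raising.
- Degenerate inputs: a configuration of identical points (CS = 0) is a hard
  error before scaling; coincident slider neighbours leave that point unslid
  with a warning; a rank-0 cross-product matrix yields the identity rotation
  with a warning.
- Rotation updates are batched over specimens (stacked 2×2 SVDs), which is
  what keeps the replicated simulations cheap.

## Ordination

PCA runs on the flattened aligned coordinates (x1, y1, …, xk, yk) about
their mean with covariance divisor n−1, via SVD; eigenvalues below 1e-12 of
the leading one are truncated as numerical rank deficiency. Axis signs are
fixed by making each axis's largest-magnitude loading positive, so repeated
runs are bit-identical; any comparison with published morphospaces must
still be sign-agnostic, since the convention is arbitrary. No projection to
tangent space is applied by default — shape variation in these samples is
small relative to the curvature of shape space — but
`pca(..., tangent_projection=True)` orthogonalises the centred data against
the mean-shape direction first, as a sensitivity switch. Group-wise analyses
subset the scores of one joint ordination rather than re-fitting PCA per
subset, so per-epoch or per-habitat plots share axes.

## Disparity statistics

- **Procrustes variance** of a group: mean squared deviation of its members'
  flattened coordinates from the group mean, divisor n (the group-wise
  disparity convention of the standard morphometrics tooling; `ddof=1`
  switches to the sample-variance convention). With divisor n, the
  whole-sample PV equals the sum of PC score variances computed with
  divisor n — a cross-module consistency identity the tests assert.
- **Pairwise significance**: the observed statistic for a pair of groups is
  `|PV_1 − PV_2|`; group labels are permuted (999 permutations by default; a
  seed is required in the pipeline configuration) and
  `p = (#{permuted ≥ observed} + 1)/(n_perm + 1)`. Comparisons involving a
  single-specimen group report the difference with an absent p-value: one
  specimen has zero deviation from its own mean by construction, so a test
  would be vacuous.
- **Convex-hull area** on a PC plane: monotone-chain hull, shoelace area;
  collinear points give 0; fewer than three points leave the statistic
  undefined (absent, never zero).
- **Weighted hull area**: for each unordered pair (i, j) of the first five
  PCs, the group's hull area on that plane times
  `propvar_i + propvar_j`, summed over the ten pairs. The weights are not
  renormalised — the wording of the source convention describes a weighted
  sum, not an average — but `normalize=True` divides by the total pair
  weight for users who want the average.
- **Sum of variances** of a score subset: per-axis variance (divisor n−1)
  summed over axes; equal to the total coordinate-space variance of the
  subset about its own mean.

## Geological time handling

Ages are in Ma and decrease toward the present. An interval owns the ages
`[end_ma, start_ma)`: an age exactly on a shared boundary belongs to the
older interval, consistent with first-appearance semantics, and the oldest
interval is additionally closed at its old end so the whole span is
covered. Species are assigned to the interval containing their FAD (the
"epoch of appearance"), regardless of how many intervals their range
crosses. Range-through richness counts a species in every interval its
[LAD, FAD] range intersects under the same ownership rule.

Two interval tables are shipped as CSV package data and are
user-overridable: the 7-epoch scale (Ludlow, Pridoli, Lower/Middle/Upper
Devonian, Mississippian, Pennsylvanian) and a 16-stage scale, both spanning
425.6–298.9 Ma with boundary ages taken from the international
chronostratigraphic chart. Equal-width binning divides the same 126.7-My
window into n contiguous bins (7 bins of 18.1 My by default), tiling the
span exactly. Intervals holding fewer than two species report absent (NaN)
disparity rather than zero — a zero would fabricate a signal where variance
is simply undefined.

## Pipeline and jackknife

One run aligns, ordinates, computes disparity tables for each requested
grouping variable (clade, epoch of appearance, habitat, palaeoenvironment —
species lacking a palaeoenvironment are dropped from that grouping only),
produces disparity-through-time curves on both the epoch scale and the
equal-bin scale, and the per-stage richness curve. All randomness flows from
one configured seed through named per-stage substreams (SHA-256-derived
child keys), so any stage is individually reproducible; the run log records
seed, input SHA-256 hashes and library versions. The locality jackknife
re-runs everything from scratch on the reduced sample — superimposition
depends on sample composition, so excluded species must not leave a trace in
the consensus — and reports baseline and reduced curves side by side.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure of a
Devonian–Carboniferous fish disparity study: a closed fish-like outline
template (fixed landmarks at anatomical extremes, semi-landmarks filling the
arcs, slider triples referencing adjacent outline points), eight clades with
a default census of 36 species (1, 6, 4, 6, 2, 12, 1, 4 — deliberately
including one- and two-species groups, the pathological sizes downstream
statistics must handle), three habitats, ten palaeoenvironment categories,
stratigraphic ranges inside 425.6–298.9 Ma, and a plantable
exceptional-preservation locality whose species get concentrated ages and
boosted shape variance.

Each simulated species is `mean shape + clade offset + isotropic N(0, s²)
noise per coordinate`, then randomly rotated, translated and scaled so
superimposition is genuinely exercised. Noise precedes the similarity
transform: digitisation error lives in shape units, and GPA is expected to
remove the transform, not the noise. Clade offsets are centred and
orthogonalised against the uniform-scaling direction so planted effects
survive superimposition. Default magnitudes — offset norm 0.08 and noise sd
0.02 in units of the unit-centroid-size template — put between-group
separation and within-group scatter at the few-percent-of-size level typical
of digitised fossil reconstructions.

For isotropic noise without sliding, superimposition removes 4 of the 2k
coordinate degrees of freedom (two translations, one rotation, one scale),
so the expected Procrustes variance is approximately `(s/CS)²(2k − 4)`; this
closed form is the recovery target for calibration tests at a 10–15%
tolerance. With sliding the tangential noise component of each semi-landmark
is also absorbed, so slid datasets fall below the closed form by design.

What the generator does not emulate: anatomically realistic deformations
(offsets are random directions in shape space, not fin or skull modes),
phylogenetically correlated variation, taphonomic or preservation-dependent
missingness, and non-isotropic digitisation error. Passing recovery tests
therefore demonstrates that the statistics recover planted variance
structure through the full pipeline — not that any biological conclusion
about real taxa would be robust to those unmodelled features.

## Problem sizes in the shipped checks

The replicated experiments use deliberately small configurations — schemes
of 10–36 landmarks, samples of 30–42 specimens, 50–500 replicates — chosen
so the whole suite exercises every code path at meaningful statistical
resolution (permutation calibration bounds of ±1.9 percentage points at 500
null datasets; recovery rates resolved to 1/200) while staying quick enough
to run habitually.

## Known limitations

- Sliding is tangent-projection only; bending-energy sliding and curve
  resampling are out of scope.
- Missing landmarks are a hard error; there is no estimation of absent
  points.
- The TPS reader handles the flat LM=/ID=/IMAGE=/SCALE= dialect; CURVES=
  blocks are not expanded.
- The stage/epoch boundary ages are a pinned snapshot of the
  chronostratigraphic chart; users tracking a different timescale revision
  should supply their own CSV.
- Richness is raw range-through counting; no sampling standardisation
  (rarefaction, coverage-based methods) is provided.
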