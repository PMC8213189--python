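# Methods

## The fixed-shift ensemble model

An 8-bit channel of an image is summarised by its intensity histogram
p_g, g = 0..255. For an ensemble of images of the same kind of sample,
assuming fully identical distributions is too rigid (staining intensity
varies from section to section) while assuming arbitrary per-image
distributions estimates nothing. The fixed-shift model sits between the
two: with ρ_g = ln p_g − ln p_0 the log-odds of each bin against the
reference bin g = 0 (defined on the support only, p_g > 0), image i is
allowed ρ_g → ρ_g + b_i for one image-specific constant b_i. A uniform
log-odds shift multiplies the odds of every non-zero intensity against
black by e^{b_i} — a global exposure/staining change that leaves the
*shape* of the distribution intact.

Maximising the multinomial ensemble likelihood over the common profile
and the nuisance shifts gives the closed form

    ρ̂_g = ln( d_g / (N_T − d_0) ),   g ≥ 1, d_g > 0,

where d_g are the pooled counts and N_T their total: pooled counts are
the sufficient statistic, and Σ_{g≥1} exp(ρ̂_g) = 1 holds exactly by
construction (asserted to 1e-12 in the tests). The estimate is reported
both as log-odds and as a probability histogram via p̂_0 = d_0/N_T,
p̂_g = (1 − p̂_0) e^{ρ̂_g} — the unique reconstruction consistent with the
estimate that sums to one, and algebraically identical to the pooled
relative frequencies d_g/N_T. The round trip
`logit_transform(mle_histogram(pooled)) == mle_log_odds(pooled)` is a
tested invariant (1e-10).

Conventions and degenerate cases:

* the reference bin is fixed at g = 0; if d_0 = 0 the log-odds remain
  computable but the reconstruction places bin 0 outside the support and
  a warning is emitted;
* N_T = d_0 (every pixel black) is a hard error — the model is
  degenerate;
* bins absent from the ensemble are excluded from the support, never
  smoothed; no pseudocounts (the estimator's sums are restricted to
  non-zero bins);
* all logarithms are natural.

Per-image shifts b_i themselves are not estimated and no uncertainty
bands are attached to ρ̂ — out of scope by design.

## Channel extraction and histogram descriptors

Red/green/blue are taken verbatim from the raster. Gray is the luma
combination with scikit-image's `rgb2gray` weights (0.2125, 0.7154,
0.0721) by default, rounded half-to-even and clipped to [0, 255]; the
ITU-R BT.601 weights are selectable because the original processing
toolbox convention cannot be asserted with certainty. Images deeper than
8 bits are rejected rather than rescaled, since bin identity matters.

The cumulative distribution is the strict partial sum F_g = Σ_{h<g} p_h
(F_0 = 0). The median is the smallest g whose inclusive cumulative mass
reaches 1/2 (deterministic tie-break to the smaller intensity). One arm
is "darker" than the other iff its CDF dominates everywhere with strict
inequality somewhere — mass concentrated at lower intensities, with 0 =
black; crossing or identical CDFs are incomparable.

## Kolmogorov–Smirnov comparison

D = max_g |F_p(g) − F_q(g)| over all 256 bins (verified in tests against
a brute-force scan). The p-value uses the asymptotic two-sample
Kolmogorov distribution at n = n₁n₂/(n₁+n₂). What n *should* be for
pooled image ensembles (number of images, or pooled pixel counts) is a
genuinely open modelling question — pixel counts overstate the
information content of spatially correlated images — so the effective
sample sizes are a required explicit parameter, with `images` /
`pixels` / explicit-value policies offered at the pipeline level.
Default significance threshold: 0.05. No multiple-testing correction is
applied across (staining × channel) pairs.

## Escort families, Hellinger distance, entropy difference

The escort family P_g(β) ∝ p_g^β (normalised over the support) scans a
histogram: β = 1 is the identity (returned bit-for-bit, short-circuited),
β = 0 is uniform on the support, large β accentuates common intensities,
small/negative β accentuates rare ones. Escorts are computed in the log
domain, ln P_g = β ln p_g − logsumexp(β ln p_h), so negative and large
|β| are stable; a non-representable exponent raises an error naming the
offending β. The composition law escort(escort(h, a), b) = escort(h, ab)
on a fixed support is a tested property (1e-9, a, b ∈ [−3, 3]).

The Hellinger distance is implemented in its standard form
H² = ½ Σ (√p − √q)², H ∈ [0, 1], evaluated over the union of supports.
(A plain squared-difference variant √(½ Σ (p − q)²) is available behind
`form="squared_diff"` for sensitivity checks only; it is not a Hellinger
distance.) Shannon entropy S = −Σ p ln p is in nats, zero-mass bins
contributing nothing; 0 ≤ S(escort(h, β)) ≤ ln|support| with the maximum
at β = 0.

`beta_scan` evaluates H(β) and ΔS(β) = S(treated escort) − S(control
escort) on a grid — default 101 even points on [−5, 5] plus exact 0
and 1, deduplicated after rounding to 12 decimals. Escorts are formed on
each histogram's own support and compared over the union; consequently
H(β = 0) = 0 is guaranteed only for equal supports, and is asserted only
there. H(β) profiles are classified with two tolerances: `flat` if the
relative range is below tol_flat = 0.05, `monotonic_growth` if
successive differences are ≥ −tol_mono = 1e-6, else `non_monotonic` with
the argmax β reported. The source classes are verbal, so these numeric
tolerances are this package's own operationalisation.

## The synthetic-study generator

The generator realises the model the estimator assumes, plus the one
violation of interest (clusters), with full ground truth:

| parameter | default | meaning |
|---|---|---|
| `staining_tag` | H | selects the RGB tint and the default arm size |
| `n_images_per_arm` | 7 (H, M) / 8 (S) | the emulated study's group sizes |
| `image_height × width` | 1024 × 1360 | the emulated study's raster size; tests use 64 × 64 |
| `shift_sigma` | 0.5 | SD of the Normal(0, σ²) per-image logit shift b_i |
| `cluster_params` | 3 discs, r = 6 px, offset +60 | treated-arm cluster proxy |
| `seed` | 0 | master seed |

The reference gray histogram is a point mass of 0.15 at g = 0 (the dark
reference bin — substantial mass there makes the logit shift a genuine
perturbation rather than a no-op) plus a two-component Gaussian mixture
(tissue mode at 95, background mode at 165) truncated to the band
40..190. The bounded support is deliberate: a stained section occupies a
limited dynamic range, and the empty upper bins are where the cluster
offset moves mass, so clusters raise entropy by opening new support —
the mechanism the entropy indicator is designed to detect.

Per image: b_i ~ Normal(0, shift_sigma²); the reference is tilted
(p'_0 = p_0/(p_0 + e^b(1−p_0)), p'_g = e^b p_g/(p_0 + e^b(1−p_0)));
pixels are drawn i.i.d. by inverse-CDF sampling (this i.i.d. draw *is*
the pixel noise); treated images get `n_clusters` hard discs at
uniform-random centres (overlap allowed, ≥ 3 by default, echoing the
at-least-three-cells definition of a chondrocyte cluster) whose pixels
are offset and clipped; the gray field is tinted to RGB by per-staining
channel scalings (H magenta-purple, S red-orange, M blue-green — chosen
only to make channel dependence testable, with no histological realism
claimed). All randomness derives from the master seed through
`SeedSequence(seed, spawn_key=(arm, image))`, so generating more images
never perturbs earlier ones; studies are byte-identical given a spec.

What a green test does and does not establish: the generator produces
i.i.d. pixels with no spatial correlation beyond the discs, no texture,
no optics or staining physics, and deterministic tints rather than
colour covariance. Passing tests establish correctness of the
estimators and functionals and the calibration/effect-direction
behaviour *under the model's own assumptions* — not performance on real
histology.

## Numerical choices

* Histogram normalisation tolerance 1e-9; MLE identities asserted at
  1e-12; escort composition 1e-9.
* Gray quantisation: round half-to-even, then clip.
* Escort β = 1 returns the input object exactly (identity member).
* Hellinger's H² is clipped into [0, 1] before the square root to guard
  sign noise at the boundaries.
* KS p-values are clipped to ≤ 1.

## Known limitations

* The asymptotic KS p-value is inaccurate for very small effective
  sample sizes (n_eff of order a few images) and the test is
  conservative on discrete 256-bin data; rejection decisions at
  image-level n_eff are therefore blunt, which matches the intended
  auxiliary-screening use.
* The pooled MLE converges to the shift-mixture of the reference, not
  the reference itself; with substantial p_0 and large shift_sigma the
  recovery error has a bias floor that pooling cannot remove.
* Inter-channel correlations, cluster shape/size analysis, and spatial
  structure are out of scope.
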