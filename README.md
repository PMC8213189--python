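# escorthist

Statistical comparison of two arms of a microscopy-image study (medically
treated vs control) through their 8-bit intensity histograms. The package
was built for stained histological sections — haematoxylin–eosin (H),
Safranin O (S) or Masson's trichrome (M) — where staining intensity varies
image to image and the interesting group difference hides in the shape of
the intensity distribution, but it applies to any two ensembles of 8-bit
RGB images.

## The model and statistics

**Fixed-shift MLE.** Each image's channel histogram p_g (g = 0..255) is
taken through the logit transform ρ_g = ln p_g − ln p_0 against the
reference bin g = 0, and images within an ensemble are assumed to share one
log-odds profile up to an image-specific additive shift b_i (absorbing
staining-intensity variation). The maximum-likelihood estimate of the
common profile has the closed form

    ρ̂_g = ln( d_g / (N_T − d_0) ),    g ≥ 1, d_g > 0,

with d_g the pooled counts over the ensemble and N_T the pooled total, and
satisfies Σ exp(ρ̂_g) = 1. The reconstructed probability histogram
(p̂_0 = d_0/N_T, p̂_g = (1 − p̂_0) e^{ρ̂_g}) equals the pooled relative
frequencies.

**Comparison.** The two arms' estimates are compared with the two-sample
Kolmogorov–Smirnov statistic D = max_g |F_p(g) − F_q(g)| (significance
threshold p ≤ 0.05; the effective sample size entering the p-value —
image counts or pixel counts — is an explicit caller choice). To locate
*which* intensities drive a significant difference, each histogram is
scanned through its escort family

    P_g(β) = p_g^β / Σ_{p_h≠0} p_h^β,    β ∈ ℝ,

(β = 1 the original histogram, β = 0 uniform on the support, β > 1
accentuating common intensities, β < 1 and negative β accentuating rare
ones), and the Hellinger distance H(β) with H² = ½ Σ (√P − √Q)² plus the
Shannon-entropy difference ΔS(β) = S(treated) − S(control) are evaluated
on a β grid. H(β) profiles are classified as monotonic growth / flat /
non-monotonic (with the maximising β reported); ΔS > 0 is the histogram
signature of cluster formation in the treated tissue.

A synthetic-study generator (`escorthist.simulate`) emulates exactly this
statistical structure — shared reference histogram, Normal(0, σ_b²)
per-image logit shifts, i.i.d. pixel sampling, disc-shaped "cluster"
intensity offsets in the treated arm, staining-dependent RGB tints — with
full ground truth retained, so estimation and calibration are testable.

## Worked example

```python
from escorthist import (Channel, FixedShiftModel, SyntheticStudySpec,
                        generate_study)

spec = SyntheticStudySpec(staining_tag="H", image_height=64,
                          image_width=64, seed=7)
study = generate_study(spec)
fit_t = FixedShiftModel.from_images(study.treated, Channel.GRAY).fit()
fit_c = FixedShiftModel.from_images(study.control, Channel.GRAY).fit()
print(fit_c.summary())
print(fit_t.compare(fit_c, n_eff="images").summary())
```

prints

```
Fixed-shift MLE of ensemble intensity histogram
================================================
channel:         gray
images pooled:   7
total pixels:    28672
support size:    98
mean intensity:  69.708
median:          77
entropy (nats):  4.1455

Group comparison (treated vs control)
================================================
KS statistic:      0.041469
KS p-value:        1  (not significant at alpha=0.05)
n_eff:             7, 7
H(beta) profile:   non_monotonic (argmax beta = -5)
darkness verdict:  incomparable
dS at beta=1:      +0.211551
treated mean/med:  74.28 / 82
control mean/med:  69.71 / 77
```

The two arms share one reference histogram up to shifts, so the KS test
(at image-level effective sample size) finds no distributional difference,
the CDFs cross (`incomparable` darkness), and means/medians are close —
yet the treated arm's entropy is 0.21 nats higher at β = 1: the cluster
discs have moved pixel mass into otherwise empty intensity bins, exactly
the effect the entropy difference is designed to flag. The Hellinger
profile peaks at negative β, i.e. the arms differ most in their *rare*
intensities.

## Command line

```bash
escorthist simulate --staining H --height 64 --width 64 --seed 7 --out study/
escorthist analyze --staining H --channel all \
    --treated study/treated --control study/control \
    --n-eff images --out results/ --plots
escorthist compare-histograms --cells results/H_gray_treated_mle.tsv \
    --control results/H_gray_control_mle.tsv --n-eff 7 --out cmp/
```

`analyze` writes, per channel: MLE histogram and cumulative TSVs for both
arms, the β-scan TSV (beta, hellinger, delta_entropy), and a JSON summary
(KS result, profile class, darkness verdict, group descriptors, full
config echo).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a synthetic study from the given seed, runs the complete
pipeline (fixed-shift MLE, KS comparison, escort β-scans) over all four
channels, sanity-checks the outputs, and writes the results manifest.
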