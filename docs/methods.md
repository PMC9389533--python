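# Methods

## The video-level decision rule

A frame-wise detector assigns each video frame one of four tags (cancer,
benign, background, none). `ttroi` turns the tag stream of one video into a
binary diagnosis in two steps.

**ROI merging (gap rule).** Let t₁ < t₂ < … be the timestamps carrying a
cancer tag (duplicate timestamps — multiple boxes on one frame — are first
collapsed by the priority cancer > benign > background > none). Consecutive
tags belong to the same region of interest iff tᵢ₊₁ − tᵢ ≤ g, with gap
g = 3 s. This is single-linkage clustering at threshold g on the time axis;
the test suite verifies the linear-time implementation against an O(n²)
transitive-closure oracle. Conventions, each genuinely open given only the
verbal rule:

* *Closed comparison*: a gap of exactly g joins ("within 3 s" includes the
  boundary).
* *ROI end* = timestamp of the last cancer tag (`roi_end="last_tag"`). The
  alternative — extend each ROI by g, clipped to the video end
  (`"last_tag_plus_gap"`) — is implemented but not the default, since it
  inflates every ROI by up to 3 s.
* A single isolated tag is a zero-duration ROI, so "video has an ROI" ⇔
  "video has ≥1 cancer tag". The "no ROI" group statistics rely on this.
* Timestamps are used as-is (seconds, not frame indices); streams with
  dropped frames need no special handling.

**TTROI and cutoff.** TTROI = Σ(endᵢ − startᵢ) over the ROIs. The video is
called cancer iff TTROI ≥ c. Default c = 1 s (the reference operating
point); `cutoff="auto"` selects c on a cohort by maximising Youden's
J = sens + spec − 1 over candidate thresholds = unique observed TTROI values
plus +∞ (sufficient for a step-function ROC; no midpoints, so the choice is
reproducible from the data alone). J ties break toward the smaller
threshold, favouring sensitivity — the rule is used to *rule out* cancer, so
a low negative likelihood ratio is the priority. The closed inequality makes
"cutoff = smallest positive observed TTROI" a well-behaved selection on
cohorts where most negatives have TTROI = 0. AUC is the trapezoidal area of
the ROC polyline from (0,0) to (1,1), which equals the tie-corrected
Mann–Whitney U/(n₁n₂); the equivalence is tested on 1,000 random instances.

## Statistics

* **Proportion CIs — Wilson score** (via statsmodels). Chosen because it
  reproduces the reference intervals at small n (21/24 → 0.69–0.96) where
  Wald degenerates and Clopper–Pearson over-covers.
* **Likelihood-ratio CIs — Simel log method**: exp(ln LR ± z·SE) with
  SE²(ln PLR) = 1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn), and symmetrically for
  the NLR. fp = 0 makes the PLR infinite: reported as such with an undefined
  CI and a `plr_defined=False` flag rather than an exception (likewise NLR
  at tn = 0).
* **Pearson χ², no continuity correction**, df = 1, with a degenerate-margin
  error; equals N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) (property-tested). The
  Yates correction is deliberately off — the univariate 2×2 tables here have
  expected counts where the corrected test is markedly conservative. Fisher's
  exact test is provided as the small-sample companion.
* **McNemar — exact binomial** on the discordant counts (b, c) with p = ½
  (two-sided), because discordance in a ~117-case paired comparison is small;
  the asymptotic χ² form is available by flag. b = c = 0 → p = 1.
* **Cohen's κ** with the large-sample SE √(p₀(1−p₀)/(n(1−pₑ)²)), CI clipped
  to [−1, 1]; undefined (error) when both raters are constant. Cross-checked
  against scikit-learn's implementation in the tests.
* **Mann–Whitney U**: exact enumeration when n₁·n₂ ≤ 400 and untied,
  otherwise the tie-corrected normal approximation with continuity
  correction. At group sizes 5–8 the approximation tracks exact enumeration
  with mean |Δp| < 0.01 (worst case < 0.02, measured); fully tied input
  returns U = n₁n₂/2, p = 1.
* **Display rounding** is decimal half-up (10/16 → 0.63), two decimals for
  proportions and likelihood ratios, three for p-values; full precision is
  kept internally and in the JSON reports.

## The synthetic stream generator

No real per-frame streams exist to test against, so `ttroi.simulate` draws
them from a two-layer model — a viewing process crossed with an emission
confusion — rather than sampling TTROI values directly: the ROI stage must
be exercised on realistic clustered tag streams, not on pre-aggregated
numbers.

**Viewing process.** Video duration is log-normal (median 300 s, σ = 0.4;
117 videos ≈ 10.5 h of footage). Each video contains max(1, Poisson(3))
lesion-viewing episodes with Gamma(shape 2, mean 25 s) durations placed
uniformly; outside episodes the scope sees background mucosa. Cancer-truth
videos view EGC tissue during episodes, benign-truth videos view
benign-lesion tissue.

**Emission.** Each frame draws a tag from P(tag | viewed tissue):

| tissue | cancer | benign | background | none |
|---|---|---|---|---|
| EGC | 0.85 | 0.06 | 0.05 | 0.04 |
| benign lesion | 0 | 0.75 | 0.15 | 0.10 |
| background | 0 | 0.03 | 0.77 | 0.20 |

With probability ρ = 0.8 a frame instead copies the previous frame's tag
(first-order persistence; ρ = 0 recovers i.i.d. draws, verified by a
chi-square goodness-of-fit test). No per-frame error rates are available
anywhere, so these rows are calibration choices constrained only by the
video-level statistics below, and are documented as such.

**False positives are bursts, not frame noise.** The cancer column is zero
for benign and background tissue. Instead, a non-cancer video contains (with
per-video probability p) one burst — an Exp(mean 10 s) interval during which
the emission row switches to the EGC row. The reason is arithmetic: 78.1% of
real benign videos carry *no* cancer tag at all, and with ~9,000 frames per
video any i.i.d. per-frame false-positive rate that is not absurdly small
would tag essentially every video at least once. Burst probabilities are
0.375 for atrophy+IM (6/16), 4/7 ≈ 0.571 for LGIN (4/7) — the two subtypes
the detector confuses with cancer — and 4/41 for the remaining benign
subtypes, making the default-cohort marginal exactly 14/64 ≈ 0.219 (the
reference false-positive count over the benign cohort). Symmetrically, a
cancer video is *silent* with probability 5/53 ≈ 0.094 (its episodes fall
back to the benign emission row), mirroring the cancer videos with no ROI.

**Cohort.** Default composition 24 inflammation / 10 atrophy / 7 IM /
16 atrophy+IM / 7 LGIN / 5 poorly differentiated EGC / 48 differentiated EGC
(53 cancer + 64 benign = 117). Covariates: sex male with probability 45/53
(cancer) or 40/64 (benign); location upper with 24/53 or 24/64; severity
(11/16 moderate-severe) and range (7/16 diffuse) drawn only for atrophy+IM.
Vienna categories are assigned benign → C1, LGIN → C3, differentiated EGC →
C4, poorly differentiated → C5.

**Determinism and coupling.** Per-video generators derive from
`SeedSequence([master_seed, video_index])`, so cohorts are bit-reproducible
and any video can be regenerated alone. Within a video the random draws are
consumed in a fixed order that does not depend on the probability values,
and the label sampler maps the uniform u to *cancer* iff u ≤ P(cancer |
tissue): raising that probability with the same seed can only add cancer
tags. TTROI is monotone in the tag set, so video-level sensitivity is
provably non-decreasing in P(cancer | EGC) under paired seeds — the
parameter-recovery property the tests exercise.

**What the generator does not model.** Bounding-box geometry and confidence
scores (ROI merging is purely temporal here); multiple lesions with distinct
error profiles in one video; at most one false-positive burst per video;
drift or fatigue effects within a procedure; expert readers. Passing tests
therefore show that the *pipeline* is correct and that the generator meets
its video-level calibration targets — not that the emission rows match any
real detector's per-frame behaviour.

## Problem sizes

The calibration check simulates 6,400 benign videos (the benign mix ×100,
~16 h of simulated footage at 30 frames/s); at that size the binomial
standard error of the zero-ROI percentage is ≈0.5 points, comfortably inside
the ±1.5-point band around 78.1%. Oracle-equivalence checks use 1,000 random
instances each; the monotonicity sweep uses 35 cancer videos at four
frame-level operating points.

## Known limitations

* ROC and cutoff selection are in-sample by design (the evaluation
  reproduces a single-cohort analysis); no cross-validation or ROC
  confidence bands.
* Only two-rater agreement (κ, McNemar); no multi-rater statistics, no
  multivariable error models.
* The per-frame emission defaults are identifiable only up to the
  video-level constraints used to calibrate them; conclusions about
  frame-level behaviour should not be drawn from them.
* The exact Mann–Whitney path is limited to untied samples with
  n₁·n₂ ≤ 400; TTROI data are heavily tied at zero, so cohort-scale
  comparisons use the tie-corrected normal approximation.
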