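# Methods

`leafqtl` maps quantitative trait loci for whole-leaf shape in a two-altitude
panel of clonal tree lines. This note documents the models, the estimators,
the synthetic-data generator and the numerical choices, and states what the
package's tests do and do not demonstrate about real data.

## Shape phenotypes

A leaf enters the pipeline as a closed margin trace. It is resampled at K
landmarks on equal-angle rays from the polygon's area centroid, with landmark
0 anchored on the ray through the blade-base (petiole junction) point and
traversal clockwise in image coordinates. K is chosen from a candidate list
by AIC: each candidate's order-4 elliptic Fourier reconstruction is scored
against the same shape on a fixed 360-point equal-angle grid, so that scores
are comparable across candidates, with a pooled Gaussian residual variance
and p = 4N + 2 coefficients per shape. Because a coarser landmark polygon has
real chord-shrinkage error against the dense margin, denser candidates win
whenever the margin carries structure the coarse polygon misses; exact AIC
ties break toward the smaller count.

Location, scale and rotation are removed by generalized Procrustes analysis:
centring on the landmark mean, scaling to unit centroid size (root mean
square landmark distance from the centroid), and rotating — never reflecting,
since leaves have chirality from imaging — against an iterated consensus.
The consensus is initialized at the normalized mean shape (making an
already-aligned set an exact fixed point; the global orientation of GPA is a
neutral direction, so a first-shape initialization would drift on
re-alignment) and converged to 1e-11 with at most 100 passes. The final
frame is canonical: the consensus base-tip axis points along +y, so the
aligned coordinates do not depend on how the input was globally oriented.
Leaves are aligned jointly, averaged coordinate-wise per clonal line
(averaging out heterophylly and block micro-environment), and the line
averages are superimposed once more. A line's phenotype is
z = (x_1..x_K, y_1..y_K).

## Elliptic Fourier descriptors

A closed contour (x(t), y(t)) is expanded in a truncated Fourier series;
harmonic n contributes (a_n, b_n, c_n, d_n) and the DC terms are (A0, C0).
Coefficients come from the classical piecewise-linear closed-form integrals.
The default parameterization is *uniform* (landmarks equally spaced in the
curve parameter): it is the natural parameter for equal-angle landmarks, it
keeps A0 = C0 = 0 for centred shapes, and it makes a uniformly sampled
ellipse decompose exactly to its first harmonic. Chord-length (arc-length)
parameterization is available as an option; note that under arc length an
eccentric ellipse is *not* a single harmonic (a 2:1 ellipse acquires a third
harmonic of amplitude ~0.13), which is why uniform is the default.

"Shape information explained" by harmonics 1..N is reconstruction
R² = 1 − SSE(N)/SST per shape, averaged over shapes, computed exactly via
Parseval from the discrete Fourier spectrum of the landmark sequences (the
least-squares fit on the uniform-parameter basis is the truncated DFT).
A normalized-power variant is exposed as an option. The working order is the
smallest N whose cumulative fraction exceeds 95%; on the simulator's default
leaves this selects harmonic 4.

## The association scan

For one SNP with genotype classes J ∈ {2, 3} (testcross / intercross), the
null model fits one elliptic Fourier mean curve to all lines and the
alternative fits one per genotype class; the test statistic is
LR = 2(lnL_H1 − lnL_H0), clamped at zero.

* **Mean model.** The group mean curve is the least-squares projection of
  the coordinate-wise group mean onto the fixed uniform-parameter Fourier
  basis of order N (default 4; 2N+1 columns per coordinate block). Using
  one fixed basis for both hypotheses makes H0 exactly nested in H1 and
  lets the projection matrix be precomputed once per (K, N).
* **Covariance model.** Residuals are two independent AR(1) Gaussian blocks
  (x and y landmarks), shared across genotype groups and re-estimated under
  each hypothesis. The log-density uses the closed forms
  ln|Σ| = K ln σ² + (K−1) ln(1−ρ²) and the tridiagonal inverse quadratic
  form, so each likelihood is O(K). (σ², ρ) are profile-ML estimates: σ² is
  closed-form given ρ, and ρ is maximized on a 100-point grid over
  (−0.99, 0.99) with one parabolic refinement (agrees with a scalar
  optimizer to ~1e-6 in log-likelihood at a fraction of the cost). The
  block-AR(1) form without cross-coordinate covariance is a modeling
  choice that keeps the scan O(K) per marker; planted-recovery tests show
  ρ is recovered within ±0.05 at n = 100.
* **Missing data and small classes.** Lines with missing calls, or in
  genotype classes below `min_group_size` (default 5), are dropped per
  marker; markers with fewer than two usable classes are recorded as
  skipped, never silently lost.
* **Thresholds.** Genome-wide significance is calibrated by permutation
  within segregation type: each of `n_perm` (default 1000) replicates
  applies one shared shuffle of line phenotypes against genotype rows and
  records the maximal LR over that type's markers; the threshold is the
  empirical (1−α) quantile (type-7 interpolation) of the maxima. With 200
  replicates this rule's exact level is (1−190.05/201) ≈ 5.45% rather than
  5.00% — the small excess is the price of the interpolated quantile with
  the observed statistic outside the reference set. A per-marker quantile
  variant is exposed by flag.
* **Null behaviour.** Under H0 the LR tracks a chi-square with
  df = 4N(J−1) + 2 as a sanity envelope only; profiled variances inflate
  the statistic by a few percent in finite samples, so no chi-square
  inference is performed anywhere — thresholds always come from
  permutation.

Per-SNP heritability of a scalar trait is the count-weighted
between-genotype variance ratio h² = 1 − SS_within/SS_total; cumulative
heritability over a marker set is the sum of per-marker values, which
overcounts shared variance when markers are collinear.

## QTL pattern classes

Significant markers are classified from their raw coordinate-wise genotype
mean contours (not the order-4 smoothed scan means, whose truncation blurs
localized divergence into neighbouring regions):

* **LENGTH** — long-narrow vs short-broad: both the relative length range
  ΔL and width range ΔW across genotypes exceed τ_rel (default 0.02).
* **WIDTH** — width differs at an equal axis length.
* **BASE / TIP** — divergence confined to the basal or apical axial third
  (regional divergence at least τ_ratio = 3 times the opposite region's).
  BASE additionally requires a consistent blade-tip contour, and TIP
  requires ΔW ≤ τ_rel (an apical QTL leaves the broadest chord, in the
  lower blade, untouched); both require the dominant divergence to exceed
  a floor of τ_rel/2 of centroid size, without which identical shapes would
  satisfy the ratio test vacuously.

Two measurement details matter in centred, unit-size shape space. First, a
localized margin change shifts the centroid and the centroid size, so the
*rest* of the contour appears translated and uniformly rescaled; the
classifier therefore registers genotype means by a median-based similarity
fit before measuring divergence (translation always; uniform scale only when
at least 60% of landmarks are consistent with the fit — the signature of a
localized change — so that genuine width/length trade-offs, whose radius
ratios vary continuously along the margin, keep their scale signal).
Second, equal-angle ray correspondence is ill-conditioned where the margin
runs radially (landmarks slide along the contour), so regional divergence is
the symmetric nearest-margin (point-to-polyline) distance, which measures
only true normal displacement.

Genotype effect tables report per-genotype, per-deme mean area/width/length
from the fitted mean contours, with cross-deme percent differences
100·|a−b|/min(a,b) (two decimals); genotypes absent in one deme stay
missing, and markers significant in exactly one deme are flagged
deme-specific.

## Population-genetic contrasts

Markers are filtered with strict inequalities: site mean depth > 12, exact
Hardy-Weinberg p > 0.05 (Wigginton-style conditional enumeration), minor
allele frequency > 0.05, missing fraction < 0.10, and heterozygote *excess*
(observed minus HWE-expected frequency) < 0.10 — a literal observed-
heterozygosity cap would discard every intercross SNP near allele frequency
one half, so the literal variant is exposed only as a config option. Depth
can alternatively be enforced per call.

Neutral-marker divergence is the Weir-Cockerham (1984) θ, combined across
loci as a ratio of averages (Σa over Σ(a+b+c)); monomorphic loci are
skipped. Nm = (1 − FST)/(4 FST) converts θ to an island-model migrant
number. QST per trait is σ²GB/(σ²GB + 2σ²GW) from one-way ANOVA
method-of-moments components of per-line traits across demes (the stated
denominator with 2σ²GW; negative between-deme estimates truncate to zero
with a warning).

The per-leaf trait ANOVA is a sequential (type-I) fixed-effects fit in the
order altitude, genotype(altitude), position, block, altitude×position,
genotype(altitude)×position, with F = MS_term/MS_residual. The altitude×
position interaction must precede genotype(altitude)×position: the latter's
column span contains the former, so the reverse order leaves altitude×
position with no estimable contrast. Sums of squares are computed by
incremental least squares with ranks from SVD; a term adding no rank raises
an error naming it.

## The synthetic-data generator

The generator emulates the emulated study design end to end with exact
planted truth. Defaults are the study conditions: 119 + 141 clonal lines in
a high and a low deme, six leaves per line (two per crown section), 70
landmarks, weak neutral divergence F = 0.0075, AR(1) landmark noise with
sd 0.02 and ρ = 0.6, a 2% cross-deme width offset (high-altitude leaves
slender — the visible magnitude of the divergence the study describes), a 1%
per-line polygenic width/length jitter, and ±2% heterophylly width effects
by crown position. All randomness flows from one seed through named
(hash-derived) streams; identical configs give byte-identical bundles.

Genotypes follow the Balding-Nichols model: per-deme allele frequencies are
Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral frequencies uniform on the
MAF range, with genotypes drawn under within-deme HWE — F is a direct FST
dial (recovered as 0.05 ± 0.01 at 2000 loci). QTL markers are forced to
their required segregation class and share frequencies across demes, so
planted shape effects, not drift, carry their signal. Markers are
independent (no linkage blocks) — sufficient for calibration and power
testing, not for fine-mapping studies.

The base leaf is a bilaterally symmetric parametric ovate (broadest ~0.28 of
the length from the base, width/length 0.55) with harmonic content through
order 4 in both coordinates, so that order selection on simulated leaves
lands at harmonic 4 as it does for real leaves, and with a minimum radius of
curvature of 0.24 so that 70 equal-angle chords resolve the margin. Planted
QTL effects are designed to be faithful *in aligned shape space*, because
Procrustes normalization re-expresses any raw change:

* **WIDTH** widens x by (1 + effect·dose/dose_max) while a composed
  monotone interior y-squeeze absorbs the size change, solved against the
  equal-angle-landmark centroid size (the exact metric alignment normalizes
  by). A plain x-scaling would read as a length-width trade-off after
  normalization — i.e. as a LENGTH-class QTL. Raw genotype-group mean widths
  differ by the nominal effect within ±1%.
* **LENGTH** scales the axis by (1 + effect·dose/dose_max) and shrinks
  width by half that factor (long-narrow vs short-broad).
* **BASE** enlarges the basal-third margin with signed sine lobes (outward
  lobe full strength, inward lobe solved for landmark-size neutrality).
* **TIP** displaces the upper shoulders toward the apex (blunt vs acute
  blade tip at equal axis length and width; amplitude = effect × blade
  half-length). The upper lateral margin runs nearly radially, so lateral
  displacement there is ill-conditioned for equal-angle landmarks; the
  axial form is the well-conditioned expression of a tip-contour QTL, and
  its residual size coupling is exactly what the classifier's similarity
  registration removes.

Warped line means are re-landmarked at equal angles before noise (uneven
vertex density would bias noisy resampled extents dose-dependently); the
narrow tip/base displacement fields are applied after re-landmarking, since
an extra resampling pass would low-pass them away. Leaves violating the
star-shape precondition of equal-angle resampling are redrawn (up to six
times) and, at extreme noise settings where no redraw can succeed, the noise
is damped locally around the offending landmarks until the margin is valid —
at the default sd 0.02 roughly 1% of leaves need a redraw and none need
damping.

## Problem sizes and verification scope

The default test-suite and acceptance-script runs use desk-scale versions of
the study: 100-260 lines, tens of markers, 200 permutation replicates, and
10-20 replicate seeds per stochastic property — sizes at which each check
completes in seconds to a few minutes while the measured quantities
(type-I level, power, recovery rates) are already stable. The generator
emulates genotype-dependent contour effects, deme divergence, heterophylly
and AR(1) landmark noise; it does not emulate linkage disequilibrium,
genotyping error beyond missingness, imaging artefacts, or non-AR residual
covariance, so passing tests demonstrate correctness of the estimators under
the stated model, not robustness to every property of field data. The
study's own dataset-level numbers (significant-SNP counts, its FST/QST
values, heritabilities) depend on undeposited landmark phenotypes and are
deliberately not reproduction targets.

Known limitations: equal-angle landmarks under-resolve the apical third of
slender leaves (any apical feature narrower than a few landmark spacings is
attenuated by resampling); localized QTLs carry far less likelihood-ratio
signal than global width/length changes of equal nominal effect, so their
detection needs larger panels or effects — mirroring their rarity among
significant loci in real data; and cumulative per-SNP heritabilities
overcount under collinearity.
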