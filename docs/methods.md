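# Methods

## The measurement model

### Integrated backscatter indices

An IBS exam is modelled as a dB-scale intensity trace sampled at a fixed
frame rate over at least three cardiac cycles:

    I(t) = B + (MCV/2) · cos(2π · HR/60 · t) + ε,   ε ~ N(0, σ_trace)

the simplest periodic form consistent with a peak-to-peak definition of
cyclic variation. The phantom reference is a constant level plus small
noise at the same depth. **CC-IBS** is the mean of the tissue trace divided
by the mean of the phantom trace, taken on the dB-scale readouts — this is
the scale on which densitometry packages report their "average intensity"
and the one that produces ratios near 1.1; a linearized-power ratio is
available behind the `linear_power` flag. **MCV** is the mean per-cycle
(max − min) over the first three complete cycles. Cycle windows are fixed
length (60/HR seconds) tiled from the trace start rather than detected from
troughs: at 20 frames/cycle trough detection is fragile, and the fixed
window matches how the traces are synthesized. A partial trailing window is
discarded; fewer than one full cycle is an error, and fewer than 4
frames/cycle is a sampling error at generation time.

With the defaults (HR 300 bpm, 100 Hz, 3 cycles) a trace is 60 frames of
0.6 s; each 20-frame window contains the exact cosine extrema, so noiseless
traces recover the target CC-IBS and MCV to machine precision (the
1e-9 oracle-equivalence tests rely on this). The max−min estimator is
upward-biased under noise by roughly 2·σ_trace·E[max of ~20 standard
normals]/√1 ≈ 0.2 dB at σ_trace = 0.1 dB; the default trace noise is kept
at 0.1 dB (clean densitometry curves) so this bias stays an order of
magnitude below the basal MCV group spread.

Phantom calibration requires depth agreement within ±0.1 cm; a
non-positive phantom mean is a hard error.

### Echocardiographic function

Teichholz cube-corrected volumes, V(D) = 7.0·D³/(2.4+D) with D in cm and V
in mL, give EF from the end-diastolic/end-systolic diameter pair; SF is the
relative diameter shortening. Whether a 3-cycle protocol averages the
diameters or the derived indices is a genuinely open choice; this package
averages the **derived per-cycle indices**, and the difference against
averaging diameters first is below half a percentage point at
physiological rat dimensions and cycle jitter (tested). EF ≥ SF for every
valid diameter pair (the cubic volume amplifies relative shortening); SF is
exactly invariant to a common rescaling of both diameters while EF is not
(the volume formula is not scale-free) — the asymmetry is asserted in the
tests rather than assumed away.

### Histology

Each sacrificed heart contributes ten equal-sized stained fields. A field
is synthesized as Bernoulli(p) collagen-positive pixels (p = the animal's
true collagen fraction) with stain/background intensity levels 0.75/0.25,
Gaussian pixel noise (default σ = 0.05) and optional blur. Segmentation is
a global intensity threshold; `segment_collagen` defaults to per-image
Otsu, but the pipeline computes one **staining-batch threshold** — Otsu on
the pooled histogram of every field in the dataset. Per-image Otsu fails
catastrophically on near-collagen-free control fields (with extreme class
imbalance it splits the background mode, reporting tens of percent of
spurious collagen); pooling keeps both intensity modes represented, the way
an operator calibrates one colour threshold per staining batch. Collagen %
is the positive-pixel fraction per field; the heart-level value is the
unweighted mean over fields (fields are equal-sized; no aggregation rule
beyond that is imposed). Lowering the threshold can never decrease the
collagen % (monotonicity test).

At zero pixel noise the generator switches to deterministic positive-pixel
counts (round(p·N) per field), so exact-recovery checks are limited only by
pixel quantization (≤ 8·10⁻⁴ % at 256²).

## The synthetic cohort

### What it emulates

Sixty baseline animals; exams at cumulative doses 0, 8, 10, 12, 14,
16 mg/kg with examined-group sizes 60/23/21/14/9/7; sacrifices for
histology of 6 control, 8, 6 and 10 hearts at 0, 8, 12 and 16 mg/kg.
Group means and spreads per variable and dose are configured inputs
(defaults: the published group statistics of the study design this
emulates, with printed "±" values read as SDs — the per-group SE reading is
dimensionally implausible for the echo rows at n = 60). LVEF is never
generated: the generator draws SF and LVEDD, and LVEF emerges through the
Teichholz stage, so the derived LVEF group means (85.7 basal, 67.8 at
16 mg/kg from SF 50 %/33.4 % at LVEDD 0.8 cm) agree with the published
LVEF row to within a percentage point.

The examined-N row and the sacrifice schedule are mutually inconsistent
under nested exam cohorts (ten hearts at 16 mg/kg versus seven exams; eight
sacrifices at 8 mg/kg versus an N drop of only two). The generator
therefore treats exam cohorts as **non-nested**: an animal must be alive at
a dose to be examined or sacrificed there, but need not have attended every
exam. Feasibility is validated by the backward recursion
R_j = max(N_j, sacrifices_j + R_{j+1}) over doses; spontaneous deaths make
up the remainder and remove the highest-injury animals first, while
sacrifice selection is random among the alive (sacrifice was scheduled, not
injury-informed — injury-ordered sacrifice would stratify the latent injury
by histology group and destroy the within-group variance that the
slope–collagen coupling rests on).

### The latent-injury model

Each animal carries a log-normal injury severity s (mean 1, log-SD
`injury_sigma`, default 0.7). Within each realized dose group, a variable
with group mean m_d = m_0 + e_d is drawn as

    value = m_0 + e_d · h + residual,   h = s^(κ·w) / mean_group(s^(κ·w))

where κ is `injury_coupling` and w a per-variable weight (CC-IBS and
collagen 1.0, SF 0.3, MCV 0.2, matching the observed pattern that the
backscatter ratio couples to collagen strongly while the functional indices
couple weakly). The positive multiplicative gain h keeps every animal's
expected trajectory direction-consistent with the group dose effect for
*any* positive κ — a zero-injury animal has a flat trajectory — and the
group normalization makes configured group means exact at zero noise
regardless of attrition. The injury deviation's realized SD is capped at
the configured group SD (rescaling h toward 1, which preserves positivity
and monotonicity), and the residual SD is shrunk so the total group spread
matches the configured one. When the cap binds the residual vanishes and
the group mean is exact even under noise; the dose-8 collagen group is in
this regime by default.

κ defaults to 6, at the saturation plateau that maximizes the attainable
slope–collagen coupling. With the published per-dose spreads this plateau
yields a median Spearman correlation between the per-animal CC-IBS dose
slope and terminal collagen of ≈ 0.2 across seeds (consistently positive,
and clearly above the MCV coupling of ≈ −0.1): per-animal OLS slopes rest
on only 2–4 exam points whose group SDs (0.26–0.27 for CC-IBS) swamp the
injury deviation, the published CC-IBS spreads shrink with dose (0.26 →
0.1), capping the within-group deviation, and the published means give
dose-16 animals the smallest per-dose CC-IBS slope while their collagen is
high. Stronger couplings (≈ 0.45, as real cohorts can show) are not
reachable without departing from the published group statistics; this is a
documented limitation of what the synthetic cohort can demonstrate.

### Disease labelling and ROC

Only sacrificed hearts enter the correlation and ROC analyses. The disease
label is terminal collagen % strictly above the control-derived threshold
(control mean + k·SD, k = 2, sample SD with n−1). The default ROC score is
an animal's **last observed** marker value (the scale on which an operating
cutoff like "CC-IBS ≥ 1.2" is meaningful); per-animal slopes are available
via `--score beta`, with the caveat that control animals have no dose
variation and hence no slope. Markers are oriented before ROC (CC-IBS up
with disease; MCV, LVEF, SF down), and the reported cutoff is mapped back
to the marker's own scale with its call direction (`>=` / `<=`). AUC uses
the rank (Mann–Whitney) estimator with half-credit for ties — checked
against a brute-force pairwise oracle and an independent library
implementation — with a DeLong CI by default and a seeded stratified
bootstrap (2000 resamples) as an option. The operating cutoff maximizes
Youden's J with ties broken toward higher specificity. No multiplicity
correction is applied; p-values are raw.

Under the published group statistics the synthetic LVEF discriminates the
collagen label about as well as CC-IBS (median AUC ≈ 0.83 vs ≈ 0.81 across
seeds), because the published 18-point LVEF drop at 16 mg/kg is large
relative to its spread. A real cohort in which LVEF is near-uninformative
(AUC ≈ 0.5) while CC-IBS is accurate is therefore *not* reproducible from
those group statistics alone; the multi-seed test asserts the reproducible
orderings (slope–collagen coupling positive for CC-IBS and absent for MCV;
CC-IBS AUC well above chance).

## Numerical and reproducibility choices

- All randomness derives from one seed through named substreams
  (`SeedSequence([seed, crc32(name)])`), so stages can regenerate their own
  fixtures independently; identical config + seed reproduces numeric tables
  byte-for-byte.
- Cycle segmentation tolerates 1e-9 relative slack so a trace covering
  exactly k cycles yields k windows despite accumulated float error.
- Degenerate inputs are errors, not NaNs: identical doses in a slope fit,
  zero-variance rank vectors, single-class ROC labels, non-positive phantom
  means, LVESD ≥ LVEDD. All-identical values across Kruskal–Wallis groups
  return H = 0 rather than an error.
- Sample SDs use n−1 throughout; group summaries emit both SD and SE so
  either reading of a "mean ± spread" table can be compared.
- Drawn values are clipped to physical ranges (CC-IBS ≥ 0.05, MCV ≥ 0,
  SF within (2, 98) %, collagen within [0.05, 97] %); with the default
  spreads clipping is inactive in practice.
- The problem sizes in the test suite and acceptance script are the study's
  own (60 animals, 134 exams, 30 hearts × 10 fields of 256²); multi-seed
  ordering studies use the tables-only fast path (no trace/image
  synthesis), which is exact for the statistics involved.

## Known limitations

- No acoustic physics: speckle, attenuation, anisotropy and B-mode image
  formation are out of scope; traces are the cosine-plus-noise abstraction
  above, so estimator behaviour under realistic speckle decorrelation is
  untested.
- Histology fields are two-level stain/background images; colour
  deconvolution of real picrosirius-red RGB slides and fibre-orientation
  effects are out of scope.
- Printed group statistics are treated as exact population parameters;
  uncertainty in those published summaries is not propagated.
- The latent-injury coupling attainable under the published spreads is
  weaker than real slope–collagen correlations (see above), and the
  synthetic LVEF is more label-informative than a real early-toxicity
  cohort's LVEF; passing tests validate the measurement and inference
  chain, not those two biological effect sizes.
- Mixed-effects longitudinal modelling and survival analysis of mortality
  are deliberately absent: repeated measures are collapsed to per-animal
  slopes, and attrition is compared only by a contingency test.
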