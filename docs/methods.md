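# Methods

## Signal model

An acquisition is a sequence of ~1 s CCD frames on a uniform wavenumber
grid (default 500–1800 cm⁻¹ at 2 cm⁻¹; analysis crop 600–1700 cm⁻¹). The
averaged raw spectrum is modelled as a non-negative linear mixture of four
max-normalized reference libraries — reduced/oxidized hemoglobin and
reduced/oxidized mitochondria — on top of a smooth fluorescence background:

    S_raw(ν) = a·S_HbR(ν) + b·S_HbO(ν) + m_r·S_mitoRed(ν) + m_o·S_mitoOx(ν) + S_FL(ν) + ε(ν)

The model assumes (i) the fluorescence background is well approximated by a
5th-degree polynomial over the crop window, (ii) library shapes are
invariant between calibration and measurement (grids matched by exact
wavenumber equality; off-grid libraries are linearly interpolated at load
time), and (iii) coefficients scale linearly with analyte concentration ×
laser power, so ratios of coefficients taken on the same day and animal are
power-invariant.

## Decomposition

1. **Dark subtraction** (per frame; linearity makes per-frame vs
   per-average equivalent, we subtract per frame).
2. **Despiking**: a channel in one frame is a cosmic spike when it exceeds
   the across-frame median by > 8 robust SDs (MAD × 1.4826); spikes are
   replaced by the channel median. Channels with zero MAD (noiseless or
   saturated) treat any positive excursion as a spike. Needs ≥ 3 frames;
   shorter sequences pass through with a warning.
3. **Averaging**: channel-wise mean of the final min(window, n) frames,
   window 180 (one acquisition yields one spectrum; a live rolling output
   is intentionally not provided).
4. **Baseline**: iterative polynomial lower-envelope fit (ModPoly scheme):
   fit degree-5 polynomial, clamp the working spectrum to min(y, fit),
   repeat until the fit changes by < 1e-4 (relative, max over channels) or
   100 iterations. A final refinement re-fits the polynomial on the
   channels the envelope marks as peak-free (residual below 3 robust sigma
   of the negative residuals), removing the downward bias plain clamping
   acquires inside peak regions. The scalar fluorescence magnitude `c` is
   the mean of the baseline over the crop window — the polynomial's six
   coefficients are reduced to one number because the downstream index
   only needs a magnitude.
5. **Library regression**: non-negative least squares of the four cropped
   libraries against the baseline-subtracted residual
   (`scipy.optimize.nnls`). The design condition number is reported and an
   effectively collinear library pair is rejected by name. Nonnegativity
   encodes that the weights are concentrations; a nonphysical residual
   (e.g. pure negative signal) lands on the zero boundary.
6. **Alternating refinement** (`decompose`, default 30 rounds): the
   baseline polynomial is re-fit to the spectrum minus the current library
   contribution, then NNLS is re-run. This is block-coordinate descent on
   the convex joint least-squares objective, keeping the baseline-first
   step order while removing the coupling bias between broad library tails
   and the envelope (pseudo-Voigt Lorentzian tails are smooth enough that
   a lower envelope absorbs ~1–2% of the hemoglobin signal otherwise).
   With noiseless input the refinement converges to the exact generating
   coefficients (observed ≲1e-9 relative; tested at 1e-3). Setting
   `refine_iters=0` gives the plain one-shot two-step split.

## Indices

HI = (a+b) of the wound measurement divided by the mean (a+b) of exactly
four healthy-skin measurements of the same pig on the same day; FI is the
same ratio on `c`. Cross-pig or cross-day normalization is refused. The
per-wound index is the mean of the (post-screening) two central-site
values; a lone survivor is flagged `single-site`, zero survivors mark the
wound missing that day. A missing POD-7 category mean may be imputed as
mean(POD 3, POD 14) for heatmap aggregation only, never for per-day
inference.

## Outlier screening

Site-level HI values of one category on one day (all pigs pooled) are
screened by a one-group ROUT-style procedure at Q = 2%: center = median,
spread = RSDR (68.27th percentile of |residuals| × n/(n−1)), two-sided
t-like p-values with n−1 df, Benjamini–Hochberg-style outside-in removal
restricted to the 30% most extreme values. This follows the published
description of the method; exact numerical agreement with the commercial
implementation is not guaranteed, so correctness rests on behavioral
invariants (shift/scale equivariance, monotone removal, false-removal rate
≤ a few % on clean normal data — measured ≈0.2% of values at n = 10).
Q = 0 disables removal. Groups under 3 values pass through with a warning.

## Categorization and classification

Primary rule from the burn protocol: 45 °C → Superficial, 96 °C →
Full-thickness, 63 °C with 15–20 s → PT-Superficial, 30–45 s → PT-Deep
(durations in the protocol gap are errors, not guesses). Secondary rule:
PT-Superficial is confirmed by complete healing by POD 56, PT-Deep by
incomplete healing at study end (POD 64); partial-thickness wounds failing
their rule are excluded with reason `secondary-criterion`. Depth-score QC
windows: < 250 µm (Superficial), ≤ 680 µm (PT-Superficial), > 680 µm
(PT-Deep), > 1750 µm (Full-thickness); scores from biopsies missing the
epidermis get +100 µm first. The 680 µm boundary itself is assigned to
PT-Superficial (configurable); the same value-at-cutoff-is-negative
convention applies to the HI classifiers (strictly HI > 3.54 ⇒ partial
thickness, strictly HI < 6.58 ⇒ PT-Deep).

ROC analysis treats the deeper category as positive in every pairing; AUC
is the Mann–Whitney concordance with ties counted half, SE by
Hanley–McNeil, p from the two-sided Mann–Whitney U test. The Youden
cutoff maximizes sensitivity + specificity − 1 with ties broken toward the
midpoint of the flanking observed values (mid-gap for separable groups);
a degenerate ROC returns the lowest threshold flagged degenerate. Whether
the published cutoffs were Youden-optimal is unknown, so reports show the
fixed-cutoff confusion and the data-derived Youden cutoff side by side.

## Statistics

Per-day one-way fixed-effects ANOVA across categories (≥ 2 categories with
≥ 2 wounds); identical constant groups report F = 0, p = 1 by convention.
Tukey HSD within a day; no adjustment across days (matching the original
analysis plan — noted in report output). Pearson correlations with
t-transform p-values. The heatmap is the category × day mean-HI matrix
(values stored unclamped; the 0–10 clamp is display-only) with
hierarchical row clustering (Euclidean, average linkage) — the first merge
identifies the closest pair of category trajectories — plus seeded k-means
labels (k = 2 default; k is not dictated by the source analysis, and with
only four rows the hierarchical ordering is the stable statement).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: 3 pigs × 8 wounds
(4 Superficial / 8 PT-Superficial / 6 PT-Deep / 6 Full-thickness attempts,
seed-randomized over positions), 12 assessment days (POD 0–64), 2 central
wound sites + 4 healthy sites per pig-day, 180 frames per acquisition,
Gaussian channel noise (default sd = 1% of the max library peak), sparse
cosmic spikes (probability 0.005 per frame), and a positive degree-5
fluorescence baseline scaled so its window mean equals the target `c`.
Wound hemoglobin amplitude = category multiplier × healthy amplitude
(default 1.0), split 70:30 HbO:HbR — the split is immaterial to HI, which
uses the sum (asserted by test). Per-category HI multipliers use every
published category mean as an anchor (e.g. PT-Superficial POD 3 = 9.19,
Full-thickness POD 3 = 0.18, POD 64 = 2.63) with linear interpolation on
unprinted days; the Superficial POD 3 anchor uses the top of the published
cross-day range (1.67), since no individual value was printed for that
day. FI multipliers follow the published late-phase trends the same way.

The default library shapes are pseudo-Voigt peak sets at heme-band-like
positions (ν4 ~1355–1380 cm⁻¹, ν2/ν10 ~1500–1640 cm⁻¹, low-frequency
~750 cm⁻¹), chosen mutually distinguishable (pairwise cosine < 0.99,
design condition number ≈ 1.7); they are configuration, not recovered
instrument truth.

Not emulated: real pig skin line shapes and melanin/skin optics, the
instrument's internal acetaminophen drift standard, and — important for
interpreting the statistics — **between-wound biological variance**. Site
spectra differ only by measurement noise, so simulated category means are
recovered far more tightly than real data would allow (per-day F
statistics are astronomically large, ROUT removes almost nothing, and the
PT-Superficial vs PT-Deep ROC separates perfectly on simulated data, where
the real study reported AUC 85%). The published within-category spread is
represented instead by the deterministic POD-3 fixture: for each category
the unique symmetric equally-spaced n-point set with exactly the printed
mean and SD (= SEM·√n); its sample variance is d²·n(n+1)/12, which pins
the spacing. The Full-thickness set (mean 0.18, n = 6) necessarily dips
below zero — kept for exact moments, flagged, with a clamped variant
behind a flag. On this fixture the published operating points reproduce:
AUC = 1 for Superficial vs PT and PT vs Full-thickness, HI > 3.54
classifies it perfectly, and HI < 6.58 yields 80% specificity (exactly one
of five PT-Superficial wounds below threshold). The PT-Superficial vs
PT-Deep comparison on the fixture is qualitative only: AUC in (0.5, 1)
with deeper burns lower — the published 85% AUC, 75% sensitivity and the
r ≈ ±0.86–0.91 correlations depend on unpublished per-wound values and are
not desk-reproducible.

One ambiguity in the published per-day numbers: the Full-thickness POD-3
HI is quoted with SEM 0.21 in one passage and 0.09 in the per-day plot
context; the fixture uses 0.09 and the discrepancy is recorded here.

## Numerical choices and problem sizes

Polynomial fits use `numpy.polynomial.Polynomial.fit` (scaled domain) for
conditioning. Baseline tolerance 1e-4, max 100 iterations; refinement stops
at 1e-10 relative change or 30 rounds. NNLS is deterministic; `c` is
clamped at 0 (physical nonnegativity; the clamp only engages on noise-floor
spectra). Analysis runs decompose the full 720-acquisition study in ~15 s;
tests use a one-pig, four-wound design with 8-frame acquisitions where the
full design adds nothing. The acceptance script simulates POD 3 only
(60 acquisitions), which carries every quantity it reports.

## Known limitations

- ROUT is validated behaviorally, not against the commercial tool's exact
  output.
- The fluorescence scalar `c` summarizes a six-coefficient polynomial; two
  differently-shaped baselines with equal window means are
  indistinguishable downstream — adequate for FI, not for fluorophore
  unmixing (explicitly out of scope).
- Whether the original device constrains its regression non-negative is
  unknown; the nonnegativity choice here is physical and surfaced in
  diagnostics rather than silently applied.
- HI/FI cannot be negative under this pipeline; negative fixture values
  exist only in the moment-exact POD-3 construction and carry flags.
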