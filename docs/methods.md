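# Methods

`rnrkit` models the computational workflow of an EPR + qPCR + sequence
study of class Ia ribonucleotide reductase (RNR) small subunits in an
anoxia-tolerant fish: simulation and analysis of tyrosyl-radical and
mixed-valent di-iron EPR powder spectra, radical-stability kinetics,
efficiency-corrected relative mRNA quantification against an exogenous
standard, and distance-based protein phylogenetics. This note documents
the models, the numerical choices, and what the synthetic data do and do
not emulate.

## EPR powder simulation (`rnrkit.epr_sim`)

**Model.** S = 1/2 spin systems with an anisotropic g-tensor and up to
eight hyperfine-coupled nuclei, treated to first order. For a molecular
orientation `n` (unit vector in the g principal frame) the resonance
field of the transition with nuclear quantum numbers `m_i` is

    B(n, m) = h v / (g_eff(n) mu_B) + sum_i m_i a_i(n),
    g_eff(n)^2 = sum_k g_k^2 n_k^2,     a_i(n)^2 = sum_k (A_ik n_k)^2.

Hyperfine principal frames are taken collinear with the g frame — the
published parameter sets for these radicals print principal values only,
so any Euler angles would be invented. First-order perturbation is
adequate for the couplings in scope (|A| <= 22 G << B even at X-band;
second-order shifts < 0.1 G). Each transition carries a Gaussian
first-derivative lineshape with direction-interpolated peak-to-peak width
`dB(n)^2 = sum_k n_k^2 dB_k^2` (sigma = dB_pp / 2). Gaussian is the
standard choice for frozen-solution tyrosyl radicals; the source
parameter sets state widths (4.5/3.5/4.4 G) without a shape.

**Powder average.** A deterministic equal-area ring ("igloo") grid over
one octant: rings uniform in cos(theta), azimuthal points per ring
proportional to ring radius, solid-angle weights attached per point. One
octant suffices because every orientation-dependent quantity depends only
on squared direction cosines. The default 2000 orientations leave
turning-point positions stable to well under one field-grid step when
refined to 5000 (tested).

**Accumulation.** Stick positions are binned onto the field grid with
linear weight splitting, grouped into 96 linewidth classes, and each
class histogram is convolved (FFT) with its Gaussian-derivative kernel.
This reproduces a direct dense summation to < 1% of the peak amplitude —
far below measurement noise — at ~10 ms per spectrum, which is what makes
grid-presearch fitting affordable.

**Units.** Fields are mT internally; hyperfine couplings and linewidths
cross the API in Gauss (1 G = 0.1 mT) because the experimental
literature for these systems prints Gauss. Field grids default to 4096
points with an auto-range of [lowest resonance − 10 widths, highest + 10
widths]; a window that clips within 5 widths triggers a warning.
Modulation amplitude and microwave power are metadata only (ideal,
non-saturating derivative).

**Presets.** The seven tyrosyl systems (four carp paralogs, mouse R2,
human and mouse p53R2) share the mouse R2 proton hyperfine set
(A_beta1 = 21.4/19.0/21.5, A_beta2 = 9.5/2.5/5.7,
A_3,5-H1 = −9.1/−4.4/−6.6, A_3,5-H2 = −7.3/−4.8/−5.8 G) with their
published g-tensors — the observed spectra of all these species are
essentially superimposable on mouse R2, which motivates sharing the
parameter set. The five mixed-valent Fe(II)Fe(III) presets carry no
resolved hyperfine and, since no widths are published for these broad
signals, a default 10 mT per-axis linewidth (overridable); the
g-extraction tolerance for these species is set to ±0.01 accordingly.
`cu_edta_standard` is a **synthetic** stand-in for a Cu(II)EDTA
quantification standard — a typical axial Cu(II) parameter set
(g = 2.29/2.065/2.06, A(Cu, I = 3/2) = 150/15/15 G, 60/40/40 G widths);
only its double integral matters downstream.

**Fitting.** `fit_spin_system` refines selected parameter blocks ("g" or
one hyperfine tensor) by `scipy.optimize.least_squares` on the normalized
residual. The documented basin is ±0.002 in g and ±5 G in A. Because a
g-shift of 0.001 displaces a 285 GHz feature by ~5 mT — comparable to the
feature's own width — a cold least-squares start can strand in flat
tails; the fit therefore runs a deterministic presearch first (a rigid
shift scan of each block across the basin, then a per-coordinate
refinement), at the full orientation count, before the polish. Scaled
steps: 1e-3 per g value, 1 G per hyperfine component; finite-difference
step 2% of scale; iteration cap 200 function evaluations, with
non-convergence flagged on the result rather than raised.

## EPR analysis (`rnrkit.epr_analysis`)

**Turning points.** g1 is read from the low-field derivative maximum, g2
from the steepest central zero crossing, g3 from the high-field minimum
(parabolic/linear sub-grid interpolation), each converted through the
resonance condition. When a resolved hyperfine doublet flanks an outer
feature (two extrema of comparable height within 1.5x the largest
coupling), the midpoint is used, removing the ~0.0002 bias the beta1
doublet otherwise introduces at high field. A spectrum showing exactly
one peak and one trough with the crossing midway is treated as an
unresolved (quasi-isotropic) line and all three g-values are taken from
the crossing — the outer extrema of a single Gaussian derivative sit a
half-linewidth off-center and are not g positions.

**Quantification.** Double integration is trapezoidal-cumulative applied
twice. The default baseline subtracts the straight line through the
averaged endpoint regions (first/last 2% of points); single-sample
endpoints would tilt the baseline by local noise, which double
integration amplifies quadratically. Spin concentration is
`standard_conc x DI_sample / DI_standard`, requiring identical frequency
metadata. An optional field-sweep g-factor correction (after Aasa and
Vanngard; the isotropic 1/g average) is OFF by default because the
reference procedure compares raw double integrals recorded under
identical conditions.

**Decay kinetics.** `I(t) = I0 exp(-k t)`, least squares with k bounded
at zero (two points solved in closed form; an intensity increase clamps
k to 0 with a warning). The printed fractional losses give the frozen
oracle values: a 31% loss over 24 h corresponds to k = 0.01546 h^-1 and
t1/2 = 44.8 h; a 40% loss over 10 min to t1/2 = 13.6 min. Only a single
exponential is fitted — the stability assays report single fractional
losses, which cannot constrain a multi-component model.

## qPCR quantification (`rnrkit.qpcr`)

**Cp calling.** Second-derivative maximum: Savitzky–Golay smoothing
(window 5, **order 4**), quintic-spline interpolation, argmax of the
spline's second derivative on a 0.001-cycle grid. Order 4 rather than a
low-order kernel because the SG(5,2) smoother shifts the asymmetric
second-derivative peak of a logistic by −0.25 cycles, while the
near-interpolating order-4 kernel keeps the bias at 0.01 cycles
(analytic logistic oracle: Cp = c0 − s ln(2 + sqrt(3))). A cubic spline
would be useless here — its second derivative is piecewise linear and
snaps the maximum to integer cycles.

**Efficiency.** Per-reaction E from the best-R^2 sliding window (4–6
cycles) of the log10 baseline-subtracted fluorescence. The raw window
slope systematically underestimates E once amplification decelerates
(for a logistic, the local log-slope is `(1 − f) log10 E` at plateau
fraction f), so the slope is divided by `(1 − f_bar)` — the window's mean
plateau fraction, clipped at 0.8 — before exponentiating. Estimates
outside (1, 2.1] are flagged and excluded from gene x tissue means. No
attempt is made to reproduce every heuristic of the LinReg program; the
window-of-linearity principle is the same.

**Relative levels.** `level = E_std^Cp_std / E_tar^Cp_tar` with the
exogenous standard mw2060 as numerator, duplicate Cp values averaged
(discordant duplicates > 1 cycle flagged, never auto-dropped), and
efficiencies tissue-matched. Cp values must lie in (0, 42) — the run is
42 cycles.

**Statistics.** Mean ± s.e.m. per exposure group; one-way ANOVA followed
by two-sided Dunnett many-to-one comparisons against normoxia under the
homogeneous-variance assumption. The critical value of the max-|t| null
is obtained by seeded Monte Carlo (default 100 000 draws) using the exact
decomposition of the one-way layout — independent group means and a
pooled chi-square variance — rather than printed tables, which are
edition-dependent; scipy's multivariate-t implementation serves as an
independent cross-check in the tests (agreement to ~0.01 in adjusted
p-values), and the familywise type-I error calibrates to 0.05 ± 0.02
over 2000 null simulations. Adjusted p-values are Monte Carlo tail
probabilities with the (1 + count)/(n + 1) estimator.

## Phylogenetics (`rnrkit.phylo`)

Translation uses the standard code and stops at the terminal stop codon
(internal stops are errors in strict mode). Pairwise identity comes from
a global BLOSUM62 alignment (gap open 10 / extend 0.5) as matches over
alignment columns; the original study does not state its alignment
method, so this standard contract is the package's choice and identity
comparisons should be read with ±1 percentage point of slack.

Distances use pairwise gap deletion (robust for partial-length
paralogs) under p, Poisson (`−ln(1−p)`) or Kimura
(`−ln(1 − p − 0.2 p^2)`) models; Kimura is the default stand-in for a
PAM-style protein distance. Saturated pairs (argument of the log <= 0)
are capped at 10 substitutions/site with a warning.

Neighbor joining is the standard Saitou–Nei Q-criterion agglomeration
with deterministic tie-breaking by taxon-label order and negative branch
lengths clamped to zero (deficit moved to the sibling). It is exact on
additive matrices (tested against direct tree construction up to n = 8
and against dendropy on arbitrary matrices). Bootstrap supports resample
alignment columns with replacement (default 300 replicates, seeded),
rebuild distance + NJ per replicate, and count recoveries of each
full-data bipartition; supports are mapped onto the full-data tree (no
consensus-tree construction), and nodes recovered in more than half the
replicates are flagged — the display convention of the study's figures
(scores over 150 of 300). The KEN-box scanner reports 1-based spans of
the minimal K-E-N tripeptide, with an optional extended consensus
`KEN-x-x-x-[DN]`.

## Synthetic data (`rnrkit.synth`)

Every generator is a pure function of (config, seed) built on numpy's
`default_rng`; identical inputs give identical outputs.

* **EPR**: a preset simulation rescaled so its double integral equals the
  spin concentration in uM (one a.u. per uM — the synthetic analogue of
  recording everything under identical spectrometer settings), plus
  Gaussian noise as a fraction of the maximum derivative amplitude
  (default 0.02, i.e. SNR 50; >= 0.5 refused). The sweep window uses a
  3-linewidth margin, as an operator would choose, so that the double
  integral is not dominated by signal-free noise. For quantification
  scenarios the acceptance tests use SNR 200 for the 200 uM sample and
  SNR 500 for the 1 mM standard — quantification-grade acquisitions of
  concentrated samples.
* **Decay**: I0 exp(−kt) at the assay's design points (0 h control, 24 h
  anoxic at 0 C, +1 h normoxic), default k = 0.01546 h^-1 (the 31%/24 h
  observation); optional multiplicative noise.
* **qPCR**: six exposure groups (normoxia, hypoxia, anoxia 1/3/5 d,
  reoxygenation), n = 8 fish per group (inside the study's 6–10),
  duplicate wells, the study's mean primer efficiencies per gene and
  tissue pre-filled, and the normalizer mw2060 spiked at a fixed level.
  Fold-changes are planted through dCp = −log_E(fold) with per-fish
  biological scatter (SD 0.15 cycles) and per-well technical scatter
  (SD 0.08 cycles); raw curves are 4-parameter logistics whose
  exponential phase embodies E and whose second-derivative maximum sits
  at the planted Cp (c0 = Cp + ln(2+sqrt(3))/ln E). The default scenario
  plants the study's clearest effect, a 10x Ki67 increase in all anoxic
  brain groups.
* **Protein families**: equal-rates substitutions over the 20-letter
  alphabet along a Newick guide tree (Poisson event counts per site, each
  event replacing the residue with one of the other 19), no indels. This
  is deliberately non-biological (no empirical exchange matrix, no rate
  heterogeneity); it is sufficient for topology-recovery and bootstrap
  calibration tests but says nothing about model misspecification on
  real proteins.

What passing tests therefore show: the analysis chain recovers planted
parameters under the study's design and realistic noise. What they do
not show: robustness to baseline drift or saturation in real EPR
spectra, to inhibitors or probe chemistry in real qPCR, or to alignment
error and heterotachy in real protein families.

## Problem sizes

The default test and acceptance workloads use 2000 powder orientations x
4096 field points per spectrum, 300 bootstrap replicates, 100 000 Monte
Carlo draws for Dunnett critical values, 2000 null datasets for the
type-I calibration, and n = 8 per exposure group — the sizes at which the
recovery criteria above were validated.

## Known limitations

* No second-order hyperfine corrections, no Euler rotations between
  tensor frames, no g/A-strain, no saturation or temperature effects.
* The mixed-valent linewidth (10 mT) is a documented guess; turning-point
  g-values for those species are only trusted to ±0.01.
* `fit_spin_system` refines g and hyperfine blocks but not linewidths.
* Efficiency estimation assumes a logistic-like plateau for its curvature
  correction; exotic curve shapes fall back to the (biased-low) raw
  window slope.
* Dunnett's procedure assumes homoscedastic groups; no Welch-type
  fallback is provided.
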