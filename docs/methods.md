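# Methods

## Problem and pipeline

The package estimates potato leaf chlorophyll content from canopy
hyperspectral reflectance measured on a uniform 1 nm grid over 350–1830 nm
(1481 bands). Two expressions of the trait are modelled side by side:
chlorophyll per unit leaf area (LCC_A, mg·dm⁻²) and per unit fresh weight
(LCC_W, mg·g⁻¹). The chain is: Savitzky–Golay smoothing → fractional-order
differentiation → spectral feature construction → correlation screening →
regression, with every stage seeded and deterministic.

## Fractional differentiation (Grünwald–Letnikov)

The order-α derivative of a discrete series R on a grid with step h is

    D^α R(t) = h^(−α) · Σ_{k=0..t} w_k R(t−k),
    w_0 = 1, w_k = w_{k−1}(k − 1 − α)/k.

Conventions chosen here:

* **Full expanding history** from the series start; left-boundary values
  (fewer history terms) are retained rather than masked, because bands near
  350 nm are far from the red-edge region the results depend on, and
  masking would shift band indexing. A `truncation` parameter limits the
  memory window when speed matters.
* The convolution is evaluated **directly** (not via FFT) so that integer
  orders are exact: α = 0 returns the input bit-for-bit, α = 1 reproduces
  the backward first difference, and a constant spectrum has an exactly
  zero derivative — which in turn makes the SDr/SDy trilateral ratio
  correctly flag as undefined on degenerate input instead of returning
  round-off noise.
* α is restricted to [0, 2]; the default order set is {0, 0.5, 1, 1.5, 2}.
* Order 0 means the **smoothed** spectrum: differentiation is always applied
  after smoothing, so the 0-order series is the SG output, not raw
  reflectance.

Smoothing uses window 9 / polynomial order 2 (mid-range defaults, exposed
in config), with polynomial extrapolation in the terminal windows.

## Spectral features

* **Empirical indices**: fixed-band formulas on the smoothed reflectance.
  IPVI is computed as R800/(R800 + R670); the product variant
  R800·(R800 + R670) appears in some printed sources and is available via
  `ipvi_as_printed=True`, but the ratio is the literature-standard form and
  the default. SIPI on a constant spectrum is 0/0 and is flagged NaN, as is
  any division by zero; NaNs propagate as missing and are excluded from
  ranking.
* **Trilateral parameters**: extrema and sums of the order-1 derivative
  over the blue edge (490–530 nm), yellow edge and red edge (670–760 nm),
  plus reflectance extrema Rg (510–560) and Rr (650–690). The yellow-edge
  window defaults to 462–642 nm to match the source convention this
  analysis follows; the conventional 560–640 nm window is available via
  config (`yellow_edge: conventional`). Window endpoints are inclusive.
* **Two-band indices**: DI(i,j) = Rᵢ − Rⱼ and SAVI(i,j) with soil factor
  L = 0.16, where R is the order-α transformed reflectance. Band lookup is
  exact integer-nm matching — no interpolation, since the grid is defined
  at 1 nm.

## Exhaustive band-pair screening

For each index kind and derivative order, Pearson r against the trait is
computed for every **ordered** pair (full square matrix, mirroring the
published heatmap convention; a triangular mode halves the cost). The
evaluation is blockwise — peak memory O(block_size × n_bands × n_samples) —
and evaluates the index values explicitly before correlating, so the
covariance-identity shortcut for DI remains an independent cross-check in
the tests. Cells with zero variance or non-finite index values are NaN and
excluded. The selected pair is the |r| argmax; exact ties (including the
antisymmetric DI twin) break to the smallest i, then smallest j, for
determinism. |r| rather than signed r is the criterion throughout, since a
strongly negative correlate is as useful to a regressor as a positive one.

When several traits are screened, the expensive pair evaluation is shared
across traits in one pass (`two_band_correlation_multi`); results are
identical to trait-by-trait screening.

## Input combinations

Four designs of k = 7 features each:

1. top-7 empirical indices by |r|,
2. top-7 trilateral parameters,
3. top-7 two-band features,
4. top-7 of the pooled union of all three families.

The two-band family pools the per-(kind, order) argmax features — ten
candidates per trait (2 kinds × 5 orders) — rather than all ~2.2 M matrix
cells. Pooling raw cells would fill the combination with seven nearly
identical neighbouring-band copies of the single best pair; the
per-order-optimum pooling matches how optimal wavelength combinations are
tabulated per differential order and keeps the combination diverse.

## Chlorophyll chemistry

Extract concentrations follow the two-wavelength ethanol equations
Ca = 12.7·D663 − 2.69·D645, Cb = 22.9·D645 − 4.68·D663,
Ct = 20.21·D645 + 8.02·D663 (mg/L). The Cb coefficient ordering is the
standard one — it is the only ordering for which Ca + Cb ≡ Ct holds
identically, since 12.7 − 4.68 = 8.02 and 22.9 − 2.69 = 20.21; a transposed
variant seen in print is available behind `as_printed=True` for fidelity
testing. Concentration converts to content as C·(V/1000)/m with V = 25 mL
(i.e. a 1/(40·m) factor), m being leaf area in dm² for LCC_A or fresh
weight in g for LCC_W. Content is homogeneous of degree −1 in m and +1
in V. Nine 1-cm leaf disks give the default area 9·π·0.25 cm² =
0.070686 dm².

## Models and evaluation

* **Split**: deterministic and target-stratified — samples sorted by the
  trait (ties shuffled by `split_seed`), the middle of each consecutive
  triple goes to validation (2:1, so 60 samples → 40/20). Both splits span
  the trait range and the validation extremes lie strictly inside the
  overall range.
* **SVM**: RBF kernel, C = 20, γ = 0.02 (a polynomial kernel is
  configurable); **RF**: 100 CART trees; **BPNN**: one hidden layer of 10
  logistic units trained with L-BFGS (full-batch is appropriate at n = 40,
  and it removes the learning-rate tunable; `bpnn_max_epochs` caps
  iterations and the optimizer's tolerance provides the stopping plateau).
* SVM and BPNN inputs are z-scored using modeling-split statistics only;
  RF uses raw features.
* Each model is fitted `n_repeats = 10` times with seeds spawned from
  `model_seed`; the reported prediction is the per-sample mean across
  repeats. Repeats re-randomize model initialization only, not the split.
* Metrics: R² = 1 − SS_res/SS_tot, RMSE in trait units, and mean relative
  error MRE = (100/n)·Σ|y − ŷ|/y in percent. Zero-variance truth flags R²
  as NaN.

## Synthetic data generator

The generator defines the study conditions: n = 60 samples, LCC_A uniform
on 32–55 mg·dm⁻², SLW drawn from 13–27 g·dm⁻², leaf-water latent with 10%
relative spread, multiplicative (1%) then additive (0.004 reflectance
units) Gaussian noise, red-edge shift of 0.4 nm per mg·dm⁻². Spectra come
from a documented closed form, not a radiative-transfer code: Gaussian
chlorophyll absorption terms at 450 and 670 nm with saturating
(Beer–Lambert-style) depth, leaving a green maximum near 550 nm; a logistic
red-edge ramp whose inflection moves linearly with chlorophyll; an NIR
plateau set by a structure scalar; and water-scaled dips at 1200, 1450 and
1780 nm. R(670) is strictly decreasing in chlorophyll by construction.

Labels are made self-consistent: LCC_W = LCC_A/SLW, SLW is pushed down as
water rises (so LCC_W, but not LCC_A, is confounded with water), and
absorbance pairs are back-solved from the extract equations assuming a
chlorophyll a:b ratio of 3:1, so recomputing the traits from (D663, D645,
fresh weight, leaf area) recovers the latent values to machine precision.
Latent truth (chlorophyll, water, structure, red-edge position) is stored
alongside the labels for recovery tests.

What the generator does **not** emulate: radiative-transfer physics,
canopy/soil geometry, treatment structure (nitrogen or biochar levels),
within-plot replication, instrument-specific noise spectra, or atmospheric
water-vapour artifacts. Passing tests therefore demonstrate that the
pipeline recovers chlorophyll-correlated structure it is pointed at — not
that the specific published correlation values would be reproduced on real
canopies.

## Numerical choices and degenerate inputs

* Wide-CSV I/O writes %.17g and reads with round-trip float parsing, so
  write∘read is a bit-level identity; grids are validated as strictly
  increasing with constant step.
* The |r| argmax scan is row-major, making tie-breaking exact and platform
  independent.
* Constant targets: the forest interpolates them (RMSE 0); the scaled
  learners refuse them.
* All pipeline outputs are byte-identical across runs with the same config
  and seeds.

## Problem sizes used in the test suite

Unit and property tests run on reduced grids (e.g. 24 samples × 551 bands)
chosen so each oracle comparison stays well-conditioned; the
parameter-recovery tests and the acceptance script use the full default
conditions (60 × 1481, five orders, DI + SAVI) with a 20-seed
random-forest replication for the stochastic contrasts (mean validation R²
of LCC_A vs LCC_W, and two-band vs empirical inputs).

## Known limitations

* The GL left boundary is biased for α > 0 (few history terms); analyses
  relying on bands within a few tens of nm of the grid start should mask
  them or use a truncation window deliberately.
* Feature selection uses all samples before the modeling/validation split,
  as the original workflow does; validation metrics are therefore
  optimistic about selection generalization.
* SDr/SDy and SIPI are undefined on (near-)flat spectra and propagate as
  missing rather than being imputed.
* The BPNN is a small fixed architecture; no hyper-parameter search is
  performed anywhere, by design.
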