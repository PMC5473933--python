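# Methods

## Scope

`enoseml` fits a statistical model — Gaussian-kernel ridge regression
(KRR) with cross-validated hyperparameters and exhaustive feature-subset
selection — to kinetic features extracted from the response cycles of a
nanomechanical sensor array, to predict the alcohol content of a liquid
sample's headspace vapour.  Because no raw sensor traces are publicly
available, the package includes a synthetic response generator whose
defaults define the study conditions used throughout the tests.  This
note records the model, the generator, the parameters that matter, the
numerical choices, and what the synthetic results do and do not show.

## Acquisition model

A run is a 20 s clean-air baseline followed by five cycles of 10 s vapour
introduction and 10 s purge, sampled at 20 Hz (2400 points over 120 s).
The baseline length is a design choice, not a measured fact: it is the
only schedule under which five cycles coexist with late-cycle onsets at
60, 80 and 100 s.  Cycle onsets are therefore 20, 40, 60, 80, 100 s, and
the five cycles share one continuous trace (no per-cycle baseline reset).
The first two cycles are treated as a burn-in with a multiplicative
instability factor; features are only read from cycles 3–5.

## Feature extraction

Per cycle, anchors a–d are the trace values at the sample instants
nearest t_a, t_a+1, t_a+10 and t_a+11 s, and e is the maximum over the
half-open cycle window [t_a, t_a+20).  Anchors are read on the grid with
no interpolation — every default anchor time falls exactly on the 20 Hz
grid, and nearest-sample reads are bit-reproducible.  No baseline or
drift correction is applied before extraction: constant offsets cancel
in all four parameters (the three slopes difference pairs of anchors;
p4 = e − a differences two anchors of the same cycle), and the default
drift (2 µV/s) moves anchors 1 s apart by far less than the noise floor.

Normalization divides each feature column by its population
(divisor-*n*) standard deviation computed over the *training* (known)
rows only, and applies those sds to held-out rows.  Computing the sds on
all rows, or with divisor n−1, would be equally defensible; training-only
divisor-n was chosen to avoid any leakage from held-out samples and is
recorded on the `FeatureMatrix` so saved models can be applied to raw
features later.

## Regression and model selection

KRR follows the dual form A*(x) = k(x)ᵀ(K + λI)⁻¹A with the Gaussian
kernel exp(−|u−v|²/2σ²).  I is the N×N identity.  The dual weights are
obtained by a Cholesky solve with a generic symmetric solve as fallback,
never by explicit inversion; a relative residual above 1e−8·‖A‖ raises
an error advising λ > 0.  λ = 0 is permitted (and yields exact
interpolation) whenever the kernel matrix is numerically invertible.

The cross-validation error Δ(λ,σ) averages per-fold mean-square
deviations over S folds; the per-model prediction error is the grid
minimum Δ = Δ(λ*,σ*).  Choices the procedure leaves open, and what this
package does:

* **Grid** (not stated by the procedure): λ log-spaced over 1e−6…1e2 and
  σ over 1e−2…1e2, 9×9 by default; a 5×5 `reduced_grid` (σ restricted to
  1e−1…1e1, the pairwise-distance scale of unit-variance features) is
  the default for pipeline-scale searches.  Both are configurable.
* **Fold grouping**: by default the three cycles of one liquid stay in
  one fold (`grouping="sample"`).  The three rows of one sample are
  near-duplicates; splitting them across folds (`grouping="row"`,
  also available) leaks them into training and flatters Δ
  substantially.  Reports always name the mode used.
* **Normalization inside CV**: the sds are computed once on the full
  training set, not per fold, mirroring the single normalization step of
  the original procedure.
* **Tie-breaking**: grid order for (λ,σ); smaller mask integer for equal
  Δ.  Both make reruns byte-identical.
* **Per-mask independence**: each mask's grid search is independent (no
  warm starts); only the σ-independent per-column squared-difference
  matrices are shared across masks, which is what makes the 65,535-mask
  joint search tractable.

Subset labels follow the bitmask convention: binary digit i (least
significant first) is 1 iff parameter i is used, e.g. 13 = 1101 ↔
{p1, p3, p4}; for multi-channel searches the bits run channel-major over
the 16 columns.  The default pipeline runs the four per-channel 15-mask
searches (the single-channel material-comparison setting); the joint
65,535-mask search over all 16 features is implemented and exposed but
not the default, since it costs hours rather than seconds on one CPU.
The "optimal-mask model" used for held-out evaluation is the Δ-argmin
over all masks evaluated in the run.

## Synthetic data generator

Each channel's noiseless response is a sum of independent first-order
sorption relaxations, one per headspace component j:

    injection:  ds_j/dt = (S_mj·c_j − s_j)/τ_ads,mj
    purge:      ds_j/dt = −s_j/τ_des,mj

evaluated in closed form segment by segment (no numerical integration
error), then scaled by the instability factor on cycles 1–2, plus linear
drift and i.i.d. Gaussian noise.  This is the simplest kinetic model that
produces the observed rise–plateau–decay cycle shape; diffusion-limited
tailing is approximated by τ_des > τ_ads.

**Periodic steady state.**  At the start of cycle 3 each component's
state is set to the exact fixed point of the per-cycle affine map
s → (S·c(1−e^(−Ti/τa)) + s·e^(−Ti/τa))·e^(−Tp/τd), so cycles 3–5 of a
noiseless trace are strictly periodic for *any* time constants rather
than only for fast kinetics.  For the default τ values the cycle-2 end
state is already within O(10⁻⁵) of the fixed point, so the imposed jump
is far below the noise floor; the benefit is that the feature rows from
t_a = 60, 80, 100 s are exactly exchangeable up to noise, as late-cycle
reproducibility assumes.

**Component library and composition** (concentrations in arbitrary
headspace units; ethanol a.u. ≡ alcohol vol %):

* ethanol: c = alcohol content;
* water: c = 100 − 0.3·alcohol + U(−10, 10) per vial — water activity is
  nearly flat over 0–45 vol % ethanol, and the jitter models vial-to-vial
  headspace variation;
* six "flavor" components: log-normal (median 3 a.u., σ_log = 0.8) per
  named liquid, zero for the water/EtOH calibration mixtures.  These are
  what make equal-alcohol liquors smell different and single-feature
  prediction fail.

**Channel archetypes** (sensitivities in mV per a.u.): two hydrophobic
(C18-like: ethanol 0.50, water 0.05; Phenyl-like: 0.40/0.06) and two
hydrophilic (Aminopropyl-like: 0.06/0.50; Vinyl-like: 0.10/0.35), with
flavor sensitivities ≈0.03–0.07 (hydrophobic) and ≈0.09–0.15
(hydrophilic).  Ethanol and water sorb fast (τ_ads = 0.2 s), flavors
slower (0.8–1.5 s); desorption is retarded (τ_des 1.8–5 s).  Sensor
noise is 0.05 mV per point, drift 0.002 mV/s, instability factor 0.9.

These defaults were fixed by a signal-budget calculation, not by fitting
to test outcomes: on a hydrophobic channel the flavor background
contributes ≈0.5 mV sd to p4 (≈1 vol % equivalent at 0.5 mV/vol %),
water jitter ≈0.3 mV (≈0.6 vol %), and sensor noise ≈0.1 vol %, so the
irreducible prediction error for a held-out liquor is ≈1 (vol %)² in
mean square — the intended calibration.  Measured behaviour under these
conditions (seeds 0–4): held-out MSE 0.45–1.9 (vol %)², per-channel
optimal Δ 0.5–1.5 for hydrophobic vs 145–200 for hydrophilic channels.

With τ_ads = 0.2 s, ethanol reaches >99 % of its plateau within 1 s, so
the quasi-equilibrium slope p2 carries essentially no alcohol signal
(rank correlation ≈0.05 vs ≈0.99 for p1/p4 on hydrophobic channels) —
the intended correlation structure.  A subtlety worth recording: p2 still
carries *flavor* kinetics, and the kernel regression exploits that to
deconfound the amplitude features, so p2 can appear in well-ranked masks
on the default data.  Only when p2 is made pure noise (all kinetics
faster than the 1 s anchor) does the classical result emerge — adding p2
to any subset never lowers Δ and its usage rate is the lowest — which is
how the corresponding test instantiates it.

## What the synthetic results do not show

The generator emulates the statistical structure the analysis needs —
channel-dependent multi-component kinetics, flavor confounding at equal
alcohol content, initial-cycle instability, noise and drift — but not
real sensor physics: no surface-stress mechanics, no Henry's-law
partitioning, no humidity/temperature dependence, no sensor aging, and
flavors are i.i.d. across samples rather than correlated with beverage
type.  Passing tests therefore demonstrate that the pipeline recovers
what the data contain under controlled conditions; they do not reproduce
the numerical prediction errors of any particular experimental dataset,
which depend on undeposited raw traces.

## Degenerate inputs and numerical tolerances

* Non-uniform sampling is refused (no silent resampling); uniformity is
  checked to 1e−9 s.
* Signal and feature tables are written with 17 significant digits and
  parsed with correctly rounded floats, so write→read is bit-exact.
* Zero-variance feature columns abort normalization with the column
  named; constant columns yield NaN rank correlations.
* Singular kernel systems (e.g. duplicate rows at λ = 0) raise with
  advice to increase λ; within the grid search such points are recorded
  as NaN and skipped, and only an all-NaN surface is fatal.
* Problem sizes in the default tests — 35 samples × 4 channels, 15-mask
  per-channel searches on 5×5 or 3×3 grids, five seeds — were chosen so
  the whole suite exercises every stage at full fidelity in well under a
  minute of CPU per seed; the joint 65,535-mask search is exercised for
  its combinatorics (enumeration, encoding) rather than run end-to-end.

## Known limitations

* The joint 16-feature search is O(2^16 · |grid| · S) linear solves;
  practical but slow (hours) on one CPU.  No greedy or heuristic search
  is provided by design.
* Only the Gaussian kernel and exact dual solves are implemented — no
  alternative kernels, sparse approximations, or uncertainty estimates.
* PCA reporting uses centered, sd-scaled features with deterministic
  axis signs (largest-magnitude loading positive); it is a descriptive
  view, not part of the prediction path.
* The alcohol-content vector is treated as exact; measurement error in
  the labels is not modelled.
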