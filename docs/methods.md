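# Methods

## Model

`dcmident` analyses the deterministic bilinear dynamic causal model (DCM) of
fMRI effective connectivity.  Hidden neuronal states `Z(t) ∈ R^m` of `m`
brain regions evolve under

    dZ/dt = (A + Σ_i u_i(t) B(i)) Z + C u(t),        Z(0) = 0,

where `A` (Hz) holds the condition-averaged directed couplings with
inhibitory self-connections on the diagonal, each `B(i)` the change in
coupling induced by modulatory input `i`, and `C` the gains of driving
inputs.  The second-order (state-dependent) modulation term of the full
nonlinear DCM is not modeled (`D = 0`), matching the bilinear variant used in
practice.  Inputs are unit-height boxcars on half-open intervals
`[onset, onset + duration)`; "stick" events are one-microtime-bin boxcars.

The observable is the BOLD signal, modeled as the causal convolution of each
region's neuronal state with the canonical hemodynamic response function

    HRF(t) = Γpdf(6, 1, t) − (1/6) Γpdf(16, 1, t)

(6 s peak, 16 s undershoot, 1:6 peak-to-undershoot ratio), sampled once per
TR.  The canonical kernel replaces a full biophysical hemodynamic model; it
is completely determined, so it cannot itself introduce structural
non-identifiability, and it makes the thousands of objective evaluations a
profile-likelihood analysis needs affordable.  `Γpdf(h, l, ·)` is the gamma
density with shape `h` and **rate** `l` (the rate/scale distinction is moot
for `l = 1` but fixed for user-supplied kernels).

## Numerical integration

The neuronal ODE is piecewise linear: inputs are piecewise constant, so the
session is split into bins at every input change point and integrated on the
microtime grid `ts = TR / n_slices`.  Within each bin the frozen system
`dz/dt = M z + c` is solved in closed form through the eigendecomposition of
`M` (equivalently a matrix exponential), evaluated at all microtime samples
of the bin at once; bin boundaries coincide exactly with input change points,
so the solution carries no time-stepping error.  When `M` is defective or
(with nonzero forcing) singular, the code falls back to stepwise augmented
matrix exponentials.  A trajectory whose state magnitude exceeds `1e6` (or
turns non-finite) is flagged divergent and truncated; downstream, divergent
parameter regimes return a capped objective of `1e12` instead of raising.

The convolution is the Riemann-sum approximation of the convolution integral
on the microtime grid (`ts`-scaled discrete convolution via FFT), truncated
at a 32 s kernel support; TR sampling takes the first microtime bin of each
TR period (configurable offset).  Doubling `n_slices` changes the fixture
BOLD by ~1e−3 relative, so 8 microtime bins per TR are sufficient for the
sweep experiments (the bundled fixture ships the original 32).

## Estimation

With known per-region noise SDs `σ_i`, the objective is the weighted sum of
squared residuals

    χ²(θ) = Σ_i Σ_k (Y_i(t_k) − Ŷ_i(t_k, θ))² / σ_i²,

which equals `const − 2 log L(θ)` for Gaussian noise, so its minimizer is
the MLE.  The σ² (not σ) denominator is forced by that identity and by the
Gaussian likelihood; both conventions appear in the literature, so it is
stated here explicitly.  Minimization is Levenberg–Marquardt on the weighted
residual vector (MINPACK via `scipy.optimize.least_squares`), forward
finite-difference Jacobians (relative step 1e−6), gradient tolerance 1e−8,
step tolerance 1e−10, at most 500 iterations.  Start values for simulated
data are the generating parameters shifted by ±0.1 with random signs — close
enough to converge reliably, far enough not to start at the optimum.  If the
optimizer lands in a divergent regime, the fit restarts with sign-flipped
off-diagonal `A` entries (all of them first, random subsets after), up to 5
restarts; self-connections keep their sign because they are the inhibitory
terms preventing run-away excitation.

## Profile likelihood and confidence intervals

For each parameter `θ_i` the profile likelihood
`χ²_PL(θ_i) = min_{θ_j≠i} χ²(θ)` is traced by scanning `θ_i` outward from
`θ̂_i` in both directions, re-optimizing all other parameters at each grid
point, warm-started from the neighboring point's optimum (falling back to
`θ̂` after a capped point).  The scan is adaptive: initial step
`max(0.01, 0.05·|θ̂_i|)`, grown ×1.5 when a step raised χ² by less than
`Δα/10`; a step raising χ² by more than `Δα/3` is rejected and retried at
half size (floor: 1e−3 of the initial step), which keeps the grid near the
threshold crossing fine enough that linear interpolation locates bounds to
well under 1% of the CI width (verified against a closed-form linear-model
oracle and a brute-force 2-D grid, both to <2%).  A direction stops once the
profile exceeds the threshold by 0.5·Δα (so the crossing is bracketed), at
the point budget (default 100 per direction), or at the divergence cap.

The likelihood-based CI at level `1 − α` is
`{θ_i : χ²_PL(θ_i) − χ²(θ̂) < Δα}` with `Δα = Q(χ²_df, 1 − α)`, `df = 1`
point-wise (α = 0.05 → Δα = 3.84).  Classification:

* both crossings found → **identifiable** (finite CI);
* a minimum but a missing crossing on one/both sides → **practically
  non-identifiable** (infinite bound on that side; better data can resolve
  it);
* flat profile (total variation < 0.01·Δα across the scanned range, no
  crossing) → **structurally non-identifiable** (exact compensation by other
  parameters; more data of the same kind cannot help).

Divergence-capped points are *not* counted as crossings: the jump reflects
an exploding trajectory, not an exclusion at the stated confidence level, so
a side whose only exceedance is capped keeps its infinite bound.
`contains_zero` is reported per CI because an identifiable parameter whose
CI includes zero is compatible with the connection not existing.

The design score is the mean CI width across all parameters (A-optimality);
it is infinite as soon as any parameter is non-identifiable, so a single
weak parameter disqualifies a design.

## Design variants

* **TR**: session *length* is held fixed (volume count rescaled, rounding
  down — never sampling past the stimulus-covered period); slices per volume
  and absolute stimulus timing are preserved.  A hold-volumes comparison can
  be had by composing `vary_session` after `vary_tr`.
* **Session duration**: volume count changes at fixed TR; stimuli past the
  new end are dropped/clipped, extensions repeat the base pattern with its
  original onset spacing.
* **Epoch duration**: every stimulus keeps its onset and count; only the
  "on" length changes (rejected if epochs would overlap).
* **SNR**: per-region noise SD is `sd(signal)/SNR` — the SD-ratio
  convention; noise is Gaussian, independent across regions and time points
  (no temporal autocorrelation, drift, or physiological noise).

Sweep seeds are `base_seed + 1000·variant_index + replicate_index`, logged
per row, so every variant×replicate uses a distinct, reproducible noise
realization.

## Bundled fixtures and what they do (not) show

The `forward`/`backward` fixtures encode the three-region attention-to-
visual-motion network (V1 ↔ V5 ↔ SPC; Photic → V1; Motion and Attention
modulations) with the classic blocked acquisition: TR 3.22 s, 32 slices,
360 volumes (19.32 min), 32.2 s epochs.  Stimulus trains are rule-generated
alternating blocks with 64.4 s onset spacing; Motion covers every second
Photic block and Attention every fourth (attention blocks ⊂ motion blocks).
The parameter values are **documented plausible choices, not estimates from
any real recording**: inter-regional couplings +0.3 Hz, driving gain +0.8,
modulations +0.4, self-connections −0.8 Hz.  The self-connections are
stronger than the −0.5 Hz shrinkage-prior convention because both
modulations act on V1→V5: with −0.5 the combined modulated coupling
(1.1 Hz) makes the frozen system transiently unstable (~150× amplification
within an epoch), which is run-away excitation in all but the formal sense;
−0.8 keeps the system Hurwitz under every input combination.

Consequences for interpretation: quantities computed on these fixtures
characterize the *method under these documented conditions*, not the
original single-subject dataset (whose posterior estimates were never
published).  In particular, with these moderately strong, well-separated
couplings the information content of the simulated data is higher than in
the original study: at SNR 10 all 10 parameters are identifiable with
mCI ≈ 0.21 (the connections into V5 widest, SPC→V5 compatible with zero —
the central-node effect), and at SNR 1 the intervals widen ~10-fold, with
practical non-identifiability appearing in a subset of noise realizations
rather than in every single draw.  Exact published mCI values (0.22 / 0.29 /
0.61 across TRs, etc.) are not reproducible without the unpublished
estimates and the particular noise draw, and are not targets of the test
suite; the qualitative design trends (shorter TR shrinks CIs; longer
sessions shrink CIs; low SNR degrades identifiability) are.

## Problem sizes used by the tests and the acceptance script

Profile scans in the end-to-end experiments use a reduced budget (15–60
points per direction instead of 100) and the sweep experiments use 8
microtime bins per TR instead of 32 (BOLD differs by ~1e−3 relative);
replicate counts are 2–10 per condition and the coverage experiment uses 100
replicates of a two-region, four-parameter model at SNR 5, profiling the
inter-regional coupling.  These sizes keep each experiment in the
seconds-to-minutes range while leaving the measured quantities (coverage
fraction, mCI orderings, identifiability counts) stable across seeds.

## Known limitations

* No biophysical (balloon-type) hemodynamic model, hence no region-specific
  HRF and no hemodynamically induced structural non-identifiability — by
  construction.
* Noise model is white and Gaussian with known SDs; real fMRI noise is
  autocorrelated and its SD must be estimated.
* The restart heuristic is local; it is not a global optimizer, and badly
  chosen start values on real data may still end in a local minimum.
* `import_dcm_mat` is a best-effort reader of SPM-style containers: it
  recovers structure, estimates, TR and boxcar trains, but ignores
  slice-timing/confound information.
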