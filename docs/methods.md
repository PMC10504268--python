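# Methods

## The 1-d Min oscillator

Five species are tracked as linear densities (molecules/µm) on a cell of
length L with reflecting ends: cytosolic MinD:ADP (`c_DD`), MinD:ATP
(`c_DT`) and MinE (`c_E`), and membrane-bound MinD (`m_d`) and MinDE
(`m_de`):

```
∂c_DD/∂t = D_D ∇²c_DD − k_exchange·c_DD + σ_de·m_de
∂c_DT/∂t = D_D ∇²c_DT + k_exchange·c_DD − [σ_D + σ_dD(m_d+m_de)]·c_DT
∂c_E/∂t  = D_E ∇²c_E  − σ_E·m_d·c_E + σ_de·m_de
∂m_d/∂t  = D_m ∇²m_d  + [σ_D + σ_dD(m_d+m_de)]·c_DT − σ_E·m_d·c_E
∂m_de/∂t = D_m ∇²m_de + σ_E·m_d·c_E − σ_de·m_de
```

MinD:ATP binds the membrane basally (σ_D) and cooperatively (σ_dD,
recruitment by both membrane MinD species); MinE is recruited onto membrane
MinD (σ_E) forming MinDE; hydrolysis (σ_de) releases MinD:ADP and MinE to
the cytosol; nucleotide exchange (k_exchange) regenerates MinD:ATP.  MinC is
not an explicit species: it co-localizes with membrane MinD, so
`m_d + m_de` is the MinCD occupancy proxy throughout.

**1-d reduction and parameter provenance.**  Bulk rate constants of the
classic parameterization of this model family are converted to effective
1-d units for a cylinder of radius r = 0.5 µm: surface binding (µm/s)
carries the surface-to-volume factor 2/r, and the bimolecular recruitment
terms (µm³/s) divide by the cross-section πr².  Defaults (one versioned
file, `src/minsize/data/defaults.yaml`): D_D = D_E = 2.5 µm²/s, D_m = 0,
σ_D = 0.025·(2/r) = 0.1 s⁻¹, σ_dD = 0.0015/πr² ≈ 1.91×10⁻³,
σ_E = 0.093/πr² ≈ 0.118 µm·s⁻¹·(molec/µm)⁻¹, σ_de = 0.7 s⁻¹,
k_exchange = 1 s⁻¹, dens_D = 785 molec/µm (1000 µm⁻³·πr²), dens_E = 275
(wild-type MinE/MinD = 0.35).  Whether the original simulations included
membrane diffusion is unknown; D_m defaults to 0 and is exposed.  With
these defaults a 4 µm cell shows sustained pole-to-pole oscillations with a
period of ≈ 35 s (autocorrelation of the pole signal, 200 s burn-in),
consistent with the ~40 s timescale observed in vivo.

**Numerics.**  Method of lines, second-order central differences with
ghost-cell no-flux boundaries, explicit RK4.  The step is
Δt = 0.4·dx²/max(D), additionally capped by a conservative bound on the
fastest linearized reaction rate so degenerate (coarse-grid) cases stay
stable.  The kernel is numba-compiled with a pure-numpy fallback, and an
optional Strang-split Crank–Nicolson diffusion mode exists for stiff
settings.  Defaults dx = 0.05 µm (0.1 µm for scans), sample_dt = 1 s,
burn-in 200 s.  Both totals (MinD and MinE) are checked every sample;
relative drift above 10⁻⁶ aborts the run (measured drift is ~10⁻¹⁴, i.e.
roundoff).  Densities below −10⁻¹²·dens_D abort; smaller negative
undershoots are clipped to zero and counted.  Initial condition: uniform
cytosol (MinD split evenly between ADP/ATP forms), empty membrane, and a
seeded random ±1 % multiplicative perturbation on MinD:ATP (with a small
deterministic odd component so the mirror symmetry always breaks),
compensated in MinD:ADP so totals are exact by construction.

**Period detection** takes the first autocorrelation peak of the
post-burn-in pole signal above a significance floor (max(2/√N, 0.1)),
refines it by parabolic interpolation, and reports "no oscillation" when
the amplitude ratio (max−min)/mean falls below 0.05.

## Mid-cell occupancy and the optimal length

A 0.5 µm window at mid-cell is integrated (partial grid intervals weighted
by overlap) at every sample; the **free-time fraction** is the fraction of
post-burn-in samples in which the windowed count is below a threshold θ.
θ is expressed relative to the window's share of the time-averaged total
membrane occupancy (the spatially uniform expectation), with default
θ = 0.65.  This value is a calibration, made once against the wild-type
physics: with the kinetics above, the oscillation sweeps through mid-cell
rather than vacating it, and the windowed occupancy never falls below
~45 % of the uniform expectation — a much stricter threshold (e.g. 0.2)
would score zero free time at every length and ratio and could not
discriminate anything.  At θ = 0.65 the free-time fraction is informative:
its argmax over length defines L_opt, and at L_opt the time-averaged
membrane profile has its minimum in the central fifth of the cell, the
signature of a division-permissive pattern.  A second criterion
(`min_length_above`, smallest length whose fraction reaches f_min,
default 0.5) is exposed; `argmax_free_time` is the default.  The reported
uncertainty of L_opt is always the length-grid spacing; an optional
parabolic refinement between grid lengths is recorded alongside.

`scan_ratios` raises the ratio through dens_E only (MinD fixed, as in
*minE* overexpression), runs one length scan per multiplier on a fixed
seed schedule, and fits L_opt = a + b·(R/R0) by least squares.

**The oscillatory band is narrow in the ratio — a structural property of
this model family.**  Linear stability analysis of the homogeneous steady
state (confirmed by nonlinear simulation, including strongly polarized
initial states) shows the oscillatory instability exists only for
MinE/MinD between ≈ 0.1 and ≈ 0.37 at these kinetics.  On the upper,
rising branch (ratio ≈ 0.28 → 0.37) the minimum oscillating length — and
with it L_opt — grows from ≈ 2 µm to beyond 6 µm: raising MinE pushes the
division-permissive length up, the central mechanism of the model.  But
the branch spans only ~1.3× in the ratio; just above ~1.05× wild type the
homogeneous state is stable at *every* length, mid-cell is never cleared,
and L_opt is undefined (the scan reports the degenerate case explicitly).
A broad parameter search over this five-equation family (σ's, k, D's,
membrane diffusion) found no parameterization that combines a ~40 s
wild-type period with a monotonically rising L_opt over a threefold ratio
window, so a 1.0→3.0 ratio scan from wild type cannot be completed here;
the corresponding acceptance test is left failing with this diagnosis
rather than weakened.  The mechanism itself is exercised and tested over
the attainable window (scan base at the lower edge of the rising branch,
multipliers up to ~1.2).

The chained pipeline therefore maps its scan window onto the induction's
ratio axis: the fitted line over scan multipliers [1, m_max] is rescaled
linearly onto [1, R_max] (R_max = minE_final/minE_initial) before it is
handed to the generational model.  This mirrors the qualitative use of the
simulated ratio–length relation against the experimental ratio range.

## Induction, dose–response and the generational model

The MinE rise after induction is the sigmoid
`MinE(t) = E0 + (E1−E0)/(1+e^{−(t−t_c)/t_s})`, evaluated exactly as
written: it does not pass exactly through E0 at t = 0 (the offset is
1/(1+e^{t_c/t_s})), and one timescale past t_c it reaches 1/(1+e⁻¹) ≈ 0.731
of the added amount — both properties are documented behaviour, not bugs.
With MinD constant the relative ratio is R/R0(t) = MinE(t)/E0.  The unit of
t_c/t_s (generations vs minutes) is configurable; the default is
generations, and in minutes mode the generational model evaluates the
sigmoid at each cycle's start time accumulated from its own cycle times.

The dose–response is the four-parameter logistic above; the fitter uses
data-driven initialization (offset = min R, amplitude = range,
inflection = median C, scale = C-range/4) with three documented restarts,
reports standard errors from the fit covariance, flags flat
(unidentifiable) data, and on noiseless 4PL data recovers all four
parameters to ≤ 10⁻⁶ relative error.

The generational recursion uses α (exponential growth rate, 1/min), τ
(fixed post-ring interval, min) and the linear map
L_stable = lopt_a + lopt_b·(R/R0).  T_z is clamped at 0 when a cell is
born at or beyond L_stable (the ring forms immediately); the ratio is
sampled once per generation at cycle start and held.  At constant ratio
the fixed point L0* = ½·L_stable·e^{ατ} is reached in a single generation
(the first equality of the recursion does not involve L0), and
α·(T_z* + τ) = ln 2 exactly.  Defaults: α = ln 2/25 min⁻¹ (25-min doubling,
fast-growth conditions), τ = 18 min, lopt_a = 1.5 µm, lopt_b = 1.0 µm per
unit relative ratio.  τ = 18 min places the uninduced T_z* = ln2/α − τ =
7 min at ~28 % of the cycle, matching the observation that under uninduced
conditions the ring reaches its 65 % point in roughly the first quarter of
the cycle; the resulting birth/division lengths (≈ 2.1/4.1 µm uninduced)
are realistic for fast-growing *E. coli*.

Sisters born at fractions f_A + f_B = 1 of the mother both divide at
L_stable·e^{ατ}, giving Δ_A − Δ_B = −(f_A − f_B)·L_mother exactly; this
closed form is verified against the recursion run on each sister.

## Synthetic mother-machine data

The generator mirrors the recursion cycle by cycle and adds noise:
unit-mean lognormal multiplicative factors on α, τ and L_stable
(positive quantities; CVs default to 5 %), truncated-normal division
fraction around ½ (SD 3 %, truncated to (0.05, 0.95)), Gaussian additive
noise plus constant background on intensities.  Ring intensity is a
two-slope piecewise-linear curve: it rises to 65 % of the plateau exactly
at the configured ring-stabilization time T_z, then at a slower configured
rate (default 2.5 units/min) to the plateau, reproducing the empirical
rate change at the 65 % point; the post-65 % rate and τ defaults are
chosen so the plateau is reached before division, which makes the
per-cycle maximum well defined.  Imaging cadence is 1 frame/min.  With all
noise off the tables coincide exactly with `run_generations` (a tested
oracle equivalence).  Only the old-pole mother is followed per lineage;
sister pairs are generated separately, with a deterministic spread of
division fractions (0.42–0.58) in noiseless mode, kept below the clamp
threshold e^{−ατ} so the closed-form identity holds exactly.

What the generator does **not** emulate: pixel-level images, segmentation
error, photobleaching, filamentation/multi-ring cells, correlated
mother–daughter noise, or stochastic partitioning of Min proteins.  Tests
passing on these data therefore validate the measurement pipeline's logic
and its noise robustness at the configured levels, not its behaviour on
raw microscopy.

## Trace analysis

Ring timing: background-subtract (negatives kept), threshold at 65 % of
the cycle's own corrected maximum, first crossing linearly interpolated
between frames; length at the crossing by exponential interpolation
between birth and division lengths (consistent with exponential growth).
Cycles whose corrected maximum is not positive are excluded and counted.
Per-generation aggregates report mean, SD and SEM = SD/√n with generations
indexed relative to induction; single-trace bins flag SEM as NaN.  The
sister regression uses OLS with equal-count bins (mean ± SD) for display.
Adder statistics (OLS of S_D − S_0 on S_0) are reported, never asserted:
the pure threshold-length model is a sizer (slope −1 under division noise
alone), and the suite pins that limit on constructed data while leaving
real-data behaviour an empirical question.  Moving the threshold to 0.5 or
0.8 shifts mean t65 but not the generation at which the post-induction
transient peaks (tested).

## Determinism and seeds

Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); scans use fixed per-simulation seed offsets,
the pipeline fans one global seed out by fixed stage offsets, and repeated
runs are byte-identical (tested).

## Known limitations

- The five-species 1-d reduction cannot sustain oscillations above
  ~1.05× the wild-type MinE/MinD ratio (see above); the threefold
  ratio–size scan is therefore out of its reach, and the ratio→length map
  used downstream rests on the attainable ~1.2× window plus linear
  rescaling.
- The Min simulation runs on a fixed domain; growth is handled
  generationally, not as a moving boundary within a run.
- The occupancy threshold θ = 0.65 and the 0.5 µm window are operational
  choices (calibrated once, then frozen); absolute L_opt values shift with
  them, though the qualitative ratio dependence does not.
- 2-d/3-d geometry, stochastic (particle) Min dynamics and explicit MinC
  are out of scope.
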