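# Methods

`pulsetemp` reproduces, end to end, a data-driven approach to real-time
thermal monitoring during irreversible-electroporation (IRE / H-FIRE)
treatment: temperatures near the ablation probe are estimated from
quantities already available at the generator — applied voltage, tissue
conductivity, and the treatment-induced change in electrical impedance —
through an identified linear state-space model.  Because no public
dataset exists for this protocol, the package also contains the coupled
electro-thermal phantom simulator that generates training and test data
and serves as the physics reference.

## 1. Phantom simulator

### Model

A cylindrical agar phantom (radius 29 mm, height 66 mm) holds a single
bipolar probe on its axis: shaft radius 0.825 mm, inserted 30 mm from
the top surface; from the tip upward a 7 mm ground electrode, an 8 mm
insulating gap, a 7 mm active electrode, and insulated shaft.  The real
mold is a truncated cone (top/bottom diameters 71/46 mm); it is modeled
as a cylinder because the wall lies at least 19 mm from the outermost
temperature sensor and far-field shape does not influence the sensor
readings on the 300 s timescale (thermal penetration depth
sqrt(4*alpha*t) ≈ 13 mm).  The rotational symmetry of the single
coaxial probe reduces the 3-D problem to a 2-D axisymmetric one.

Per 1 s burst the solver:

1. updates the agar conductivity, sigma(T) = sigma_ref (1 + alpha (T -
   37 degC)) with alpha = 2 %/degC, clipped at a small positive floor;
2. re-solves the electro-quasistatic potential -div(sigma grad phi) = 0
   with Dirichlet electrodes (+V on the proximal/active electrode, 0 on
   the distal) and zero normal current on insulator and exterior
   surfaces — on a cadence (every 10 s, or sooner when the temperature
   field moved more than 0.5 degC since the last solve), since sigma
   drifts at only 2 %/degC;
3. deposits the duty-cycled Joule power, duty p/tau = 100 us / 1 s;
4. advances the heat equation rho cp dT/dt = div(k grad T) + QJ one
   implicit (backward-Euler) step with convective exterior boundaries
   -k dT/dn = h (T - Text), Text = 18.8 degC.

Temperatures are sampled by bilinear interpolation at radial offsets
4 mm and 10 mm from the electrode surface, level with the midpoint of
the active electrode; the impedance Z(t) = V/I is recorded at 1 Hz and
reported as dZ(t) = Z(t) - Z(0) (negative under heating).

### Discretization

Node-centered finite volumes on a nonuniform tensor (r, z) grid with
grid lines placed exactly on every material boundary.  Face
conductivities are evaluated at face midpoints (electrical conduction:
harmonic mean of the nodal agar values), so interface nodes carry the
boundary condition while fluxes see the material actually between
nodes.  Both solves are sparse direct (SuperLU); the heat operator is
constant and factorized once per mesh, the potential matrix is
refactorized at each conductivity refresh.

Two deliberate numerical choices:

- Joule power inside the time loop is computed from the same discrete
  face fluxes as the impedance (P_face = G_face (dphi)^2, shared to the
  adjacent agar nodes).  The deposited power then equals V*I identically
  and the adiabatic energy balance is exact at the discrete level.  The
  pointwise operation QJ = sigma |E|^2 p/tau is exposed separately
  (`joule_source`, `electric_field`) for field maps and unit checks.
- Impedance between potential re-solves is updated variationally: the
  conductance functional is re-evaluated with the current sigma on the
  last solved potential pattern, exact at solve instants and
  second-order accurate in the sigma drift between them.

Defaults: 0.5 mm spacing within 12 mm of the probe (covering both
sensors), 2 mm beyond, dt = 1 s — about 3,100 nodes and ~1 s per 300 s
treatment.  A refinement study against a 0.25 mm / 1 mm grid changes
the sensor temperature rises by ~0.5 % and the impedance by 0.6–1.6 %;
all spacings and cadences are configuration.  The potential solver is
verified against the closed-form coaxial-cylinder resistance
ln(b/a)/(2 pi sigma L), to which it converges at second order.

### Conditions

Four groups cross voltage with agar conductivity: HV-HC (2500 V,
0.526 S/m at 37 degC), LV-LC (1250 V, 0.122), HV-LC (2500 V, 0.122),
LV-HC (1250 V, 0.526); 1 burst/s for 300 s.  Because conductivity is
quoted at 37 degC but pulsing happens near room temperature, each group
uses its measured initial conductivity (0.331, 0.085, 0.093,
0.331 S/m).  These values imply slightly different agar temperatures
per group (18.46, 21.84, 25.11, 18.46 degC) through the linear
conductivity law; the simulator honors them as initial temperatures
rather than forcing a single nominal value, with the air temperature
fixed at 18.8 degC.  The convective coefficient is not specified by the
experimental setup; the default h = 10 W/(m^2 K) is typical free-air
convection and is configuration.

## 2. FAST impedance spectroscopy

The diagnostic waveform interleaved between therapeutic bursts is a
high-frequency biphasic segment (1 us pulses, 50 us gaps, 164 us total
energized time) concatenated with a low-frequency segment (250 us
pulses, 10 us gaps, 1 ms energized).  Impedance is Z(f) =
FFT(v)/FFT(i) evaluated at the spectral peaks of the drive (local
maxima of |FFT(v)| above 1 % of the global maximum, rectangular
window); the peaks span roughly 0.5 kHz to 4.9 MHz.  The
"characteristic" reading is the low-frequency-segment peak nearest
1.8 kHz within a [1.5, 2.2] kHz window — the biphasic cycle of 520 us
puts the fundamental at 1.92 kHz, and the exact bin depends on record
length, so the window (not a specific bin) is the interface.  The
generator electronics are not modeled: synthetic currents come from
analytic loads (pure R, parallel RC), which matches the resistive
low-frequency behavior of the agar phantom.

Trace denoising follows the experimental processing chain: impedance
series are smoothed by a one-phase exponential decay fit
y = plateau + (y0 - plateau) exp(-k t) (nonlinear least squares, k >= 0,
initial guesses y0 = y[0], plateau = y[-1], k = 3/t_span, bounded
restarts), temperature series by an ordinary quadratic fit.  Both
operators are idempotent on already-fitted curves.  On noise-free
simulator traces the decay fit leaves a 5–10 % shape residual (the true
Z(t) is not single-exponential); this is inherent to the prescribed
processing and is accounted for by applying the same impedance
conditioning wherever the estimator receives inputs (training and
deployment alike).

## 3. State-space identification

The estimator is a discrete-time innovation-form model at the 1 s burst
period,

    x(t+1) = A x(t) + B u(t) + K e(t),  x(0) = 0
    y(t)   = C x(t) + e(t),             D = 0,

with inputs u = (V, sigma, dZ) and outputs y = (dT4, dT10) as
temperature *rise* from baseline — consistent with the zero initial
state.  Identification is subspace-based (N4SID, oblique-projection
variant): block-Hankel matrices of past/future data (horizon 10 block
rows), oblique projection of future outputs onto past data along future
inputs, SVD truncation to order 4, least squares on the state-shift
equations for (A, C), a simulation-error linear least squares for B
with D constrained to zero, and the steady-state Kalman gain K from the
residual covariances via the discrete algebraic Riccati equation
(K = 0 with a warning when the innovation covariance is numerically
zero or the Riccati solve fails).  Identified models are
basis-arbitrary; they are validated through Markov parameters C A^k B,
which the noiseless known-system oracle recovers to ~1e-15.

Since V and sigma are constant within an experiment, they are
informative only across conditions: training always merges all
experiments (Hankel blocks concatenated column-wise, never across an
experiment boundary) and single-condition datasets are rejected.
Inputs are scaled for conditioning (V in kV, dZ in units of 100 ohm)
and the scaling folded back into B.

Because the deployed estimator runs in pure simulation (no temperature
feedback is available in vivo), the pipeline's trainer follows the
subspace stage with a simulation-focused refinement: Gauss-Newton with
analytic sensitivities on (A, B, C), each output channel weighted by
the inverse of its signal norm so that every experiment and depth
contributes comparably — the same normalization used by the percent-fit
metric.  The refinement starts from the (spectrum-clipped) subspace
estimate and rejects steps whose spectral radius exceeds 1.05;
near-unit poles are flagged by a warning, not silently altered.  K is
taken from the subspace stage; it affects only one-step prediction
(`predict_ss`), never the deployed simulation path.

## 4. Quality metrics

- Percent fit: 100 (1 - ||y_pred - y|| / ||y - mean(y)||), Euclidean
  norms per output channel over the full series (the standard NRMSE
  goodness-of-fit of system identification); undefined for a constant
  reference.
- Maximum absolute error, per channel, in degC.
- Akaike's Final Prediction Error: FPE = V (1 + 2d/N) with
  V = det((1/N) sum eps eps^T).  The parameter count d counts the free
  entries of A, B, C and K with D fixed at zero: for the order-4,
  3-input, 2-output model d = 16 + 12 + 8 + 8 = 44.

## 5. Study protocol and synthetic data

The default study is 4 conditions x 5 replicates.  Replicate
variability and sensor realism: the initial conductivity is jittered by
2 % (relative, Gaussian) per replicate, Gaussian noise of 0.1 degC
(fiber-optic sensor class) is added to each temperature sample and
0.5 % multiplicative noise to each impedance sample, all *before* the
denoising fits.  No noise figures are reported for the original
experiment; these values reproduce the visual spread of its published
group traces and are configuration.  A fixed seed makes the whole
dataset, and every downstream report, bit-reproducible.

Validation is leave-one-replicate-out per group: one replicate of each
group is held out in turn, the model retrained on the rest (all four
voltage-conductivity combinations remain represented, which the
identification requires), and the simulation fit on the held-out
replicate reported per depth.  External testing feeds noise-free,
jitter-free simulator traces — the stand-in for an independent
finite-element test bench — through the trained model in pure
simulation and reports fit, maximum absolute error, and the overall
FPE.

What the synthetic data do not emulate: electrode polarization and
cable parasitics in the measured impedance, drift or calibration error
in the fiber-optic sensors, placement uncertainty of probe and sensors,
and any living-tissue electroporation dynamics (the phantom is
deliberately cell-free).  Passing tests therefore demonstrate the
internal consistency of the method under the stated physics, not
performance on biological tissue.

## 6. Known limitations

The central empirical finding of this reimplementation: under the
stated physics, the four treatment groups are *not* simultaneously
describable by one 4th-order linear model.  The simulated temperature
rises scale approximately like sigma V^2 amplified by the conductivity
feedback — HV-HC reaches a 35 degC rise at 4 mm (peak field temperature
above 100 degC) while LV-LC stays below 1.2 degC — and the
impedance-to-temperature gain varies about ninefold across groups
(dT4/|dZ| from 0.03 to 0.25 degC/ohm), i.e. the true input-output map
is close to multiplicative in (V, sigma, dZ).  A linear map cannot
reproduce that product structure: optimizing the normalized simulation
error to (verified) global optimality fits LV-LC at ~95-99 % and the
intermediate groups at ~80-90 % while HV-HC degenerates to negative
percent fits; conversely any weighting that rescues HV-HC requires
effectively deleting LV-LC from training, which the protocol forbids.
Absolute errors tell the complementary story: for the three groups with
rises below ~6 degC the estimator predicts to within a few tenths of a
degC, which is the clinically meaningful statement.  Extending the
input set with an interaction term (e.g. sigma*dZ) or a mild output
transform would relax the obstruction, but would leave the model class
being studied.

Other limitations: no perfusion term and no multi-electrode geometries;
no electroporation pore dynamics; the convective coefficient and probe
tip shape are documented assumptions; FPE values depend on the residual
scale of the synthetic study and are not comparable across datasets.
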