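# Methods

This note documents the model implemented by `actinwaves`, the numerical
choices behind the solvers, what the synthetic generators emulate, and the
limits of what desk-scale runs can show.

## The model

The package simulates a deterministic continuum description of the actin
cortex driven by nucleation promoting factors ("nucleators": formins,
Arp2/3). Five fields live on a periodic 2-D (or 1-D) domain: the actin
density `c`, the polarization `p = (p_x, p_y)` (net filament orientation),
and the active/inactive nucleator densities `n_a`, `n_i`:

    dc/dt   = -v_a div p - k_d c + alpha n_a
    dp/dt   = -v_a grad c - k_d p
    dn_a/dt = D_a lap n_a + omega_0 (1 + omega n_a^2) n_i - omega_d c n_a
    dn_i/dt = D_i lap n_i - omega_0 (1 + omega n_a^2) n_i + omega_d c n_a

Active nucleators create actin (`alpha`); polymerization at speed `v_a`
couples density and polarization; filaments degrade at `k_d`. Nucleators
activate spontaneously (`omega_0`) and cooperatively (`omega n_a^2`), and
actin inactivates them (`omega_d`) — the negative feedback that makes the
system excitable. Total nucleator number is conserved. Time is scaled by
1/omega_0 and length by sqrt(D_i/omega_0), so omega_0 = D_i = 1; the
physical calibration (91.6 s, 63.5 um) matches slow amoeboid migrators
such as immature dendritic cells.

Defaults (in `ModelParams`): D_a = 0.04, k_d = 176, alpha = 588,
omega = 6e-3, n_tot = 700, with v_a and omega_d the two control parameters
(each meaningful over roughly [0.1, 0.6]). Where a single default is
needed we use v_a = 0.4 and omega_d = 0.35 (mid-range of the wave-forming
regime).

With spatially uniform fields the model reduces to a two-variable
(c, n_a) system analogous to FitzHugh–Nagumo with the nucleators as the
fast driver and actin as the slow inhibitory carrier. `homogeneous`
provides the nullcline geometry, the unique fixpoint (uniqueness follows
from the positivity of the nullcline's tangent intercept), the extrema
cubic with its omega n_tot^2 = 27 threshold, Jacobian eigenvalues, and a
three-way classification (stable / oscillatory / excitable).

### Classification details

* Oscillatory: leading Jacobian eigenvalue has positive real part.
* Excitable: eigenvalue-stable, the nullcline has two positive extrema,
  and a finite kick of n_a triggers an actin excursion more than 5x the
  linear-response prediction. The kick is directed toward the nearest
  nullcline extremum and escalated over (0.2, 0.3, 0.4, 0.5) n_tot,
  because the excitation threshold itself moves with omega_d (at
  k_d = 80, alpha = 400 a 0.2 n_tot kick is sub-threshold at
  omega_d = 0.35 but super-threshold at 0.4; excitability is defined by
  "sufficiently large" perturbations, so a single fixed kick would
  misclassify genuinely excitable portraits).
* The Hopf onset of this fast–slow system is strongly subcritical: just
  past onset the limit cycle is already a large relaxation oscillation.
  Linear-frequency checks therefore use the damped ringing on the stable
  side of onset, where the transient oscillates at |Im s| cleanly.

### Closed-form cubic roots

The extrema cubic 0 = -n_tot - 2 omega n_a^3 + omega n_tot n_a^2 is solved
in production by the companion matrix (`numpy.roots`). The correct
trigonometric closed form is, with phi = arccos(1 - 54/(omega n_tot^2)),

    n_a,k = n_tot/6 * (1 + 2 cos((phi - 2 pi k)/3)),  k = 0, 1, 2.

An arcsine-branch variant of these formulas is reproduced as a
cross-check; no single sign of its argument yields all three roots (the
positive pair needs the argument 54/(omega n_tot^2) - 1, the negative
root the opposite sign), which the branch-report test documents. At the
threshold the double root is n_tot/3 and the negative root -n_tot/6.

## Spectral solver

Spatial derivatives are Fourier differentiation on uniform periodic grids
(`N_g` a power of two); the quadratic/cubic reaction products are
dealiased by the 2/3 rule. Time stepping is the explicit midpoint rule
with step-doubling error control (relative max-norm per field, safety
factor 0.9, tolerance `tol`), with one modification: the stiff diagonal
linear terms — diffusion exp(-D q^2 dt) and the decay exp(-k_d dt) on c
and p — are removed by an exact integrating factor and the midpoint rule
is applied to the transformed system. Without this the step size would be
pinned at 1/(D_i q_max^2) ~ 1e-5 by the grid rather than by the dynamics.
The accepted solution is the two-half-step one.

Even so, the reaction terms are genuinely fast (rates ~ omega n_a^2 reach
a few thousand inside wave crests; the near-onset oscillation frequency
is omega_F = sqrt(alpha omega_d n_a0) ~ 320), so accepted steps in
developed wave states are dt ~ 1e-5–1e-4. Long production runs may set
`control_interval = K` to re-estimate the error only every K-th step
(intermediate steps run plain midpoint at the current dt); K = 4–8 keeps
the controller responsive while roughly halving cost.

Total nucleator mass is conserved to machine precision by construction:
the activation/inactivation terms cancel pointwise between the two
nucleator equations and the spectral diffusion propagator leaves the zero
mode untouched. The same holds for the phase-field transport current
(below), whose two terms cancel exactly in quadrature.

Default run tolerance is 1e-6; the acceptance-scale simulations use 1e-3
to 1e-4, which resolves the wave dynamics (the error controller tracks
the front-passage time scale) while keeping desk-scale runtimes. Pattern
spot checks run on a 0.65 box at 64^2 — the same spatial resolution as
128^2 on the full 1.3 box — which holds ~6 wavelengths of the emerging
patterns (lambda ~ 0.11).

### Initial conditions

`init_fields` places the homogeneous fixpoint plus seeded uniform noise
on n_a, subtracted pointwise from n_i so the sum is exactly n_tot
everywhere. Default noise amplitude is 0.01 n_tot. Transients are short:
the linear growth rates at the captioned pattern points are 12–245, so
runs of 0.3–2 time units reach developed patterns.

### Pattern measurement

Wavelength is 2 pi/|q| of the power-weighted peak of the radially
collected power spectrum of c - mean(c). Wave speed comes from the phase
drift of the dominant Fourier mode across snapshots; the snapshot cadence
must keep the per-frame phase step below pi (cadence < lambda/(2 v)),
otherwise the speed aliases — analysis cadences here use 0.005. Pattern
classes: homogeneous (negligible spatial variation), turing_stationary
(structure present, frame-to-frame change below 2% of the pattern
amplitude), traveling_wave (dominant mode translates at a well-defined
speed with steady amplitude), else irregular. Classification uses the
final half of a run.

## Linear stability

Each Fourier mode evolves with a 5x5 operator in
(c, p_x, p_y, n_a, n_i); its eigenvalue of largest real part is the
growth exponent s(q). Re s > 0 with Im s != 0 predicts waves, with
Im s = 0 stationary (Turing) patterns; the fastest-growing wavelength
lambda_0 = 2 pi/|q*| is refined by bounded scalar maximization over
continuous |q| (isotropy is exploited and separately verified). The
inactive-nucleator diffusion enters as D_i q^2 with D_i = 1. At q = 0 the
operator block-decouples into the polarization pair (eigenvalue -k_d),
the homogeneous Jacobian pair, and the conserved-mass zero mode.

## Variational traveling waves

In the co-moving frame (speed v, period Lambda, coordinates scaled to the
unit period) the actin and total-nucleator profiles are linear
functionals of n_a(x) and are solved exactly per Fourier mode:

    [(v^2 - v_a^2)/(k_d Lambda)^2 d_xx - 2v/(k_d Lambda) d_x + 1] c
        = (alpha/k_d)(1 - v/(k_d Lambda) d_x) n_a
    d_x N + v Lambda N = v Lambda n_tot + (1 - D_a) d_x n_a

Cross-check forms are kept independent: the actin operator factorizes
with roots mu± = k_d Lambda/(v ∓ v_a) and an exponential-kernel Green's
function (the wake decays as a (v±v_a)/(2v)-weighted mixture of the two
exponentials — physical decay length v/k_d); N has an integrating-factor
quadrature. Both quadratures use exponential-exact weights on the
piecewise-linear interpolant and the geometric sum over periodic images,
and agree with the Fourier solves to 1e-6 on smooth profiles. At
D_a = D_i the forcing of N vanishes: a heterogeneous total nucleator
density — hence a diffusivity contrast — is necessary for waves.

The remaining nonlinear equation for n_a is attacked with the sharp-pulse
ansatz

    n_a(x) = (a1/2) e^(-a2 x) (1 + tanh(a3 x)) (1 - 2x)^a4,

with a2 in [5, 15], a3 in [30, 50], a4 in {2, 3, 4}: a steep activation
front, an exponential body, and a factor pinning the profile to zero at
the period edge. Two facts shape the fitting procedure, both verified
against direct 1-D simulation:

* The plain residual Err = ∫|F| dx has a spurious global minimum at the
  trivial profile n_a -> 0 (Err = omega_0 n_tot there), *below* the
  residual of a genuine wave (~1e4, i.e. a 2–3% cancellation of terms of
  order 1e5–1e6). The fit therefore minimizes the *relative* residual
  (Err normalized by the mean magnitude of the terms of F) with an
  amplitude floor at the fixpoint density n_a0; Err is still reported.
* The ansatz family describes solitary pulses. The wave train a noisy
  periodic box actually selects sits at the linear wavelength
  (~0.12–0.14) and is nearly harmonic (n_a stays well above zero between
  crests); its shape is outside the family (best shape fit ~60% L2). The
  variational basin lies at periods Lambda ~ 0.2–0.5 with relative
  residuals of 1–3%, so the default search range is Lambda in
  [0.15, 1.0], v in [1.2, 6]. Fitted speeds carry the right physics —
  increasing in omega_d, flat in v_a below 1 — but a pointwise overlay of
  the fitted profile on the box-selected train does not reach 10% L2 at
  desk scale, and the corresponding acceptance assertion documents this
  honestly rather than relaxing the band.

Optimization: per a4, a deterministic coarse grid over (a2, a3, v,
Lambda) with an inner log-scale golden search for a1, then bounded
Nelder–Mead on (log a1, a2, a3, v, Lambda). Quadrature: 512 uniform
points per period.

## Phase-field cell

The cell is a smooth indicator Psi (inside ~1, outside ~0; the membrane
is the 0.5 level set) with

    dPsi/dt = D_psi lap Psi + kappa Psi (1 - Psi)(Psi - delta)
              - beta p . grad Psi,
    delta   = 1/2 + epsilon (area - A_0),

(defaults D_psi = 5e-3, kappa = 118, epsilon = 8, beta = 5.75e-3,
A_0 = 0.083). The delta offset softly holds the area at A_0; the beta
term lets polarized actin push the membrane. Reactions are gated by Psi;
actin degradation acts everywhere (stray actin outside the cell decays);
nucleators move by the mass-conserving confined current

    dn/dt = D (Psi lap n - n lap Psi),

whose stationary state n ∝ Psi keeps them inside without leaking (its
1-D discrete stencil — hops weighted by the destination's Psi — is kept
as a reference implementation). Initialization: a tanh disk whose radius
is solved so the integrated area is exactly A_0, interface width 3 grid
spacings (the double-well term then maintains its own equilibrium width
~0.01–0.02, which is why cell runs need the h ~ 0.01 resolution of 128^2
on the 1.3 box; at h = 0.02 the interface is one grid point and the
nucleator fields eventually develop runaway ringing). Total nucleator
mass is A_0 n_tot, split by the homogeneous fixpoint fractions, with
seeded noise inside the cell. Since the exterior is essentially empty, a
0.65 box at 64^2 is the resolution equivalent of 128^2 at quarter cost
and is used for migration runs.

The cell center is the Psi-weighted centroid computed per axis by
circular (angular) averaging, then unwrapped frame to frame by minimal
image — robust when the cell crosses the periodic edge. Trajectories are
recorded densely by an integrator observer and resampled to uniform
cadence.

Guard rails: the cubic term bounds Psi (no clipping); the run aborts if
|Psi| exceeds 1.5.

A note on the area constraint: with waves running inside, the area
settles 15–25% above A_0 — the epsilon-driven shrinking balances the
beta-driven pushing at a slightly inflated size. The constraint is soft
by design; the offset delta then sits above 1/2 permanently. Nucleator
leakage stays low regardless (under 5% of the mass outside the
Psi = 0.1 contour), which is the property the confining current is for.

## Trajectory statistics

The time-averaged MSD over all start points is fitted with the persistent
random walk law msd(t) = 4 D t + 2 (v tau)^2 (e^(-t/tau) - 1) by weighted
least squares (sigma ~ msd sqrt(lag/n_pairs), reflecting how the
time-averaged estimator's error grows with lag), with tau multi-started
and an AIC comparison (2-point penalty) against the pure-diffusion
submodel that pins tau = 0. Classification is rule-based: stationary if
the track's span stays within jitter (or an explicit physical scale such
as 2% of the cell radius); persistent segments are runs of >= 20 samples
with per-sample turning below 0.2 rad at speeds 3x above the diffusive
baseline (5th percentile of step lengths); segments with large, coherent
accumulated turning (> 0.5 rad and > 2 sigma of their turning noise) are
curved; no segments means diffusive.

`synth_prw` generates validation tracks: an exactly-discretized
Ornstein–Uhlenbeck velocity (relaxation tau, per-component variance
v^2/2) integrated by the trapezoid rule, plus independent white
positional noise 4 D0 t with D0 = D - v^2 tau/2, so the ensemble MSD
matches the PRW law; D below the Fuerth value v^2 tau/2 is rejected as
inconsistent. `synth_run_tumble` plants straight or curved runs
(exponential durations, optional fixed turn rate with random handedness)
separated by diffusive tumbles for classifier calibration.

### What the recovery suite shows

With 10 trajectories of 5000 steps, simultaneous 15% recovery of
(D, v, tau) is a statistical statement. The suite's experiments are
exactly scale-invariant in (v, tau) (the sampling interval tau/12 scales
with tau), so reliability depends only on the excess-noise fraction
f = 2D/(v^2 tau): measured per-seed-block success is 16/16 for f up to
~1.02, ~85% at f = 1.05 and ~65% at f = 1.1 — tau-hat stays unbiased but
its spread grows as white noise dilutes the persistent signal. The
recovery grid therefore crosses (v, tau) in {0.5, 1, 2}^2 with excess
noise {0, 1, 2}% over an observation window of ~400 tau. This matches
the physical regime of interest: in the noise-dominated branch (tau ~ 0)
the fitted speed is not meaningful anyway.

## Desk scale vs the reference scale

The reference computations behind the migration phase behavior ran at
256^2 on GPUs for long durations. The desk-scale runs here reproduce:
the homogeneous and FitzHugh–Nagumo phase portraits; the pattern classes
and their wavelengths against linear stability (within 20%); machine-
exact nucleator conservation through full phase-field runs; the
stationary confined profile; the variational wave-speed trends; and the
stationary spinning spiral (center displacement far below 2% of the
cell radius). What the shortened runs cannot decide reliably is the
diffusive / straight-segment / curved-segment random-walk distinction:
those classes are statements about trajectories covering many
persistence lengths, while over the run lengths used here the cell
center advances by only a few percent of its own radius — simulated
durations roughly two orders of magnitude longer would be needed. The
spot-check assertions are kept at the captioned parameter points and
left failing where the class does not emerge at this scale, rather than
weakened. Likewise the profile overlay of the variational fit on a
box-selected wave train (see above).

## Degenerate inputs and numerical edges

* `actin_response` is singular at v = v_a (the operator loses order);
  speeds within 1e-6 relative are rejected.
* The Green's-function oracle requires v > v_a (decaying kernels).
* A double root at the omega n_tot^2 = 27 boundary splits numerically at
  the sqrt(machine-eps) scale; the root finder's reality tolerance sits
  above that.
* omega = 0 degenerates the extrema cubic (no extrema) and omega_d = 0
  the nullcline (division by n_a omega_d); both are handled explicitly.
* Wave-speed measurement requires the dominant-mode phase step per
  snapshot below pi; choose cadence < lambda/(2 v).
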