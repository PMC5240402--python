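# Methods

## Scope and model

`infusim` predicts transient dosing errors ("boluses") in multi-infusion
syringe-pump set-ups after a pump setting change, combining three
mechanisms in one chain:

1. **RC hydraulic network** (`network`). Each pump branch is a flow
   source in parallel with the syringe's mechanical compliance `C_i`
   (ml/Pa), feeding through its line resistance `R_i` into the common
   mixing point M; the catheter resistance `R_cath` drains to the venous
   reference, which is set to zero pressure (only pressure differences
   drive flows; the set-up has no patient-side source). The catheter's
   own compliance is neglected — it is small against the syringes' — so
   the flow entering the catheter equals the flow leaving it at every
   instant. For the canonical two-pump step the closed-form transient is
   a difference of two exponentials with time constants
   `ϑ₁,₂ = (b ∓ √(b²−4ac))/2` (Vieta: `ϑ₁ϑ₂ = ac`, `ϑ₁+ϑ₂ = b`); the
   excess volume of the unchanged syringe is `Q = C₂ R_cath u_downstep`,
   independent of the line resistances. A general linear state-space
   engine (one pressure state per compliance, Kirchhoff current law at M,
   clamp = open branch) covers any channel count and schedule and is the
   independent check on the closed forms.

2. **Catheter dead-volume memory** (`catheter`). The internal volume
   `V_cath` between M and the tip P is a FIFO: contents advance with the
   cumulative displacement `λ(t) = (L/V_cath)∫₀ᵗ u_cath dt'`. Voxel
   discretization uses `N` cells of length `γ = L/N`; `advect` is an
   exact finite-volume shift of a piecewise-constant profile (integer
   shift plus fractional carry, mass-conserving to round-off). The
   deviation history entering at M is resampled onto the entry-voxel
   index (`entry_sequence`): the voxel that entered when the displacement
   was `γj` carries fraction `u_diff(t_j)/u_cath(t_j)`.

3. **Poiseuille mixing** (`poiseuille`). The parabolic profile moves the
   centerline at twice the average velocity; a voxel pattern entering at
   M is stretched two-fold along the centerline and smeared by the time
   it reaches P. The tip composition is the convolution of the stretched
   entry sequence with the geometric kernel `w_i = γL/(γi+L)²`, plus the
   remnant term `L/(L+γk)` times the old/new mixing-ratio difference —
   the old mixture retained near the wall. The first arrival moves from
   `t_delay` to `t_delay/2`.

Bolus metrics (`metrics`) are method-of-moments: `Q` (zeroth), `t_central`
(first) and `σ` (root of the second central moment) of the delivered
deviation; the clinically quoted duration is `2σ`. Moments are evaluated
as index-weighted sums, the `z → 1` derivative limit of the Z-transform
formulation, so no inverse transform is needed.

## Units and sign conventions

Canonical internal units are seconds, millilitres and pascal; scenario
files may declare clinical units (ml/h, Pa/(ml/h)) per field. Standard
hardware values: `R_cath = 1145 Pa/(ml/h)`, `R₁ = R₂ = 23 Pa/(ml/h)`,
`C₁ = C₂ = 1.5·10⁻⁵ ml/Pa`, red rate 0.5 ml/h, green 12 → 6 ml/h
(`u_downstep = 6 ml/h`). `C₂R_cath = 61.83 s` is the characteristic time.
`V_cath`, `L` and `N` are scenario properties, not standardized hardware:
the packaged defaults are `V_cath = 1 ml`, `L = 1` (only length ratios
matter) and `N = 10⁴`, all overridable.

`u_downstep > 0` denotes a rate *decrease* of the changed pump. The
transient is written `(e^(−t/ϑ₂) − e^(−t/ϑ₁))·K` so that a decrease
yields a positive excess of the unchanged fluid: physically the pressure
drop at M discharges the unchanged syringe's stored elastic volume into
the catheter, and the state-space network confirms this sign.

## Index-to-time mappings (two conventions, deliberately)

The plug-flow (unstretched) entry sequence maps one index to one
entry-voxel duration `Δt = γV_cath/(L·u_final_total)`, taking the settled
final rate for the whole delivery — by the time the bolus exits, the flow
has stabilized, so exit spacing is uniform.

The stretched (Poiseuille) tip sequence uses **half** that step,
`Δt/2`. This is forced by internal consistency: the remnant's decay law
`L/(L+γk)` equals the exact parabolic-shell result `L/(2λ)` only if
`λ = (L+γk)/2`, i.e. if one stretched index advances the bulk
displacement by `γ/2`; the same mapping puts the first arrival at
`t_delay/2` and makes the convolution agree with the streamline simulator
to discretization error under constant flow. The closed form for
the Poiseuille width (`sigma_closed(with_poiseuille=True)`) instead
applies the full step to the stretched sequence — that is where its
factor-two compliance contribution (`σ_pois → 4CR_cath`) comes from — and
is implemented verbatim as the documented formula; the discrete pipeline
and the oracle comparisons use the half-step mapping. Both routes agree
on `Q` exactly and the package reports which route produced a number via
the metrics `method`/`truncation` tags.

## Displacement conventions for the closed-form moments

The closed-form `t_central` and `σ` are exact only when the displacement
history `λ(t)` counts the settled rate plus the *changed* branch's
relaxation, neglecting the unchanged branch's compliance discharge
(numerically verified: the closed-form central time matches quadrature
under that convention to 10⁻⁷ relative, while the full `u_cath` adds
≈18% on the standard scenario). `analytic_flow_trace` therefore exposes
`lambda_convention="total"` (physical, the default — it matches the
state-space network and the streamline oracle) and `"changed_branch"`
(the closed forms' own convention, used when validating them against the
discrete route). This is a documented model simplification, not a switch
to tune.

## Truncation

All semi-infinite sums and integrals are cut at
`T_max = max(10 ϑ₂, 3 V_cath/u_final)`: the exponential tails are below
`e⁻¹⁰`, and three catheter turnovers have passed. The kernel and remnant
tails decay only algebraically (`Σw` beyond index `k` is `L/(L+γk)`), so
a truncated Poiseuille bolus deliberately carries less than `Q` — about
14% of the deviation volume is still creeping along the wall at `T_max` —
and all analytic-vs-oracle comparisons are made over the *same* window.
Truncation indices and horizons are recorded in the metrics metadata.

## The streamline oracle

`oracle.simulate` divides the cross-section into `n_shells` equal-volume
annuli (default 200); shell `s` advects as an independent plug flow at
`f_s = 2(1−(r_s/R)²)` times the bulk displacement. Because each shell is
a pure delay line in `λ`, its tip concentration is obtained exactly by
inverting the displacement curve — no CFL-limited stepping (the grid must
still resolve one voxel of fastest-shell travel, which is checked). The
oracle shares no code with the kernel/stretch/Z-transform chain.

Two tip conventions are provided: `weighting="voxel"` (uniform average
over the equal-volume shells = the composition of the last voxel at P;
this is what the analytic tip bolus models, and under it a step inlet
follows the `x/(L+x)` concentration-distance law exactly) and
`weighting="flux"` (velocity-weighted; the composition of the fluid
actually crossing the tip, under which per-fluid volume conservation
holds to round-off). The difference between the two is a real feature of
laminar outflow, not an error; the analytic model's `β = ψ·u_cath`
approximates delivered flow by tip-voxel fraction times total flow.

Verification runs isolate the compliance-transient bolus by propagating
the entering deviation fraction as a tracer (`simulate_tracer`) so that
push-out and remnant effects do not contaminate the comparison; central
times are compared on the absolute axis from the setting change, the
origin both routes share.

## Numerical choices

* ODE integration: implicit Radau, `rtol 1e-10 / atol 1e-13`,
  segment-wise between schedule/clamp breakpoints (the two time constants
  differ by two orders of magnitude), resampled to the caller's grid.
* Quadrature: trapezoidal on the scenario grid (half a voxel of
  centerline travel per step); delay times by monotone root bracketing
  (Brent) on the cumulative volume.
* Convolution: FFT (`scipy.signal.fftconvolve`), with tiny negative
  round-off clipped on non-negative inputs.
* The Z-domain product moments (`z_product_moments`) use the product rule
  at `z → 1` with the literal `B(z) = A(z²)` substitution and are checked
  against brute-force index sums to 10⁻⁹.
* Degenerate inputs: zero compliance everywhere yields an identically
  zero transient (pure push-out scenarios); zero-mass boluses raise an
  explicit `ZeroMassError` (trace assembly then reports `Q = 0` with NaN
  moments); asymmetric set-ups are refused by the symmetric closed forms
  and routed to the discrete path.

## What the scenario generator emulates — and what it does not

`generate_fixtures` spans the standard scenario, resistance/compliance
sweep variants (×3/×2 catheter resistance, ×0.52/×0.36 monitored-syringe
compliance), syringe-exchange variants (line clamped, pump on/off) and
log-uniform random draws within a factor 10 of the standard values. All
fluids share one viscosity; flows are laminar and fully developed from
M; there is no axial or radial diffusion (no Taylor–Aris dispersion), no
non-return valves or filters, no pump-height changes, and a single-lumen
catheter. Passing tests therefore validate the mechanics of the
compliance/memory/mixing chain, not the behaviour of set-ups dominated by
those excluded effects.

## Known limitations

* The analytic tip mapping assumes the total flow has settled to
  `u_final` (constant-final-rate index mapping). Entries during the
  transient are therefore placed slightly late: on the standard scenario
  the Poiseuille-bolus central time sits ≈6% above the streamline oracle
  (absolute axis), while `Q` and `σ` agree to 0.4% and 2%. Single-event
  scenarios only; multi-event schedules must run through the oracle
  (superposition of overlapping boluses is not validated).
* The closed-form Poiseuille width inherits the full-step stretched
  mapping (see above); against the half-step discrete route it roughly
  doubles the compliance contribution to `σ_pois`. Its documented limits
  (4CR_cath, V_cath/u_final) are reproduced exactly by the formula
  itself.
* Algebraic remnant/kernel tails mean the assembled Poiseuille trace
  still carries a few percent of its peak at `T_max`; the plug-flow
  trace decays below 10⁻³ of peak there.
* The syringe-exchange error uses the two-exponential transient driven by
  the full old green rate; the clamped network's true relaxation has a
  different shape but the same saturation volume `C₂R_cath·u_old`, which
  is the clinically quoted number.

## Problem sizes used in the test suite

`N = 10⁴` voxels for quantitative closed-form/oracle agreement (coarser
`N` for structural tests), 200 shells (400 where the linear-concentration
law is checked), horizon `T_max` as above, and scenario grids resolving
half a voxel of centerline travel per step. At these sizes the full suite
runs in well under a minute on one CPU.
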