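# infusim

Dosing-error prediction for multi-infusion syringe-pump set-ups.

When several syringe pumps feed one catheter, three hardware effects
distort the dose that actually reaches the patient after a pump setting is
changed: the mechanical compliance of the syringes (a "capacitor" that
stores and releases fluid when pressures change), the catheter dead volume
(the old mixture still inside the line is pushed out at the new total
rate), and laminar Poiseuille mixing (the parabolic velocity profile
smears the mixture history axially, with the centerline moving twice as
fast as the average flow). `infusim` combines all three in one analytic
chain — an RC hydraulic network for the flows, a voxel/Z-transform model
for the catheter memory, and a discrete convolution for the Poiseuille
kernel — and characterizes every dosing-error bolus by its volume `Q`,
central time `t_central` and width `2σ` (method of moments). A radially
resolved streamline simulator, sharing no code with the analytic chain,
serves as the verification oracle.

It is written for clinical physicists, infusion-technology researchers and
device engineers who need fast, explicit predictions ("what happens to the
inotrope delivery if I halve the carrier rate?") rather than a CFD run.

## Model at a glance

For a two-pump set-up where the "green" pump rate drops by
`u_downstep` at `t = 0` while the "red" pump is untouched, the red
excess inflow at the mixing point is the two-exponential transient

    u_diff(t) = (e^(−t/ϑ₂) − e^(−t/ϑ₁)) · u_downstep · R_cath · C₂ / √(b²−4ac)

    ϑ₁,₂ = (b ∓ √(b²−4ac))/2,   a = R_cath R₁ + R_cath R₂ + R₁ R₂,
    b = C₁(R_cath+R₁) + C₂(R_cath+R₂),   c = C₁C₂

with total excess volume `Q = C₂ R_cath u_downstep`. The catheter
(internal volume `V_cath`, length `L`, `N` voxels of length `γ = L/N`)
advects this deviation as a FIFO memory via the cumulative displacement
`λ(t) = (L/V_cath)∫u_cath dt'`; Poiseuille mixing convolves the two-fold
stretched entry sequence with the geometric kernel `w_i = γL/(γi+L)²`
plus a slowly decaying `L/(L+γk)` remnant of the old mixture. Closed
forms for `t_central` and `σ` (symmetric case `C₁=C₂=C`, `R₁=R₂=R`,
`R ≪ R_cath`) are included, together with their documented limits
`σ → 2CR_cath`, `σ_pois → 4CR_cath` and `σ_pois → V_cath/u_final`.

## Worked example

```python
import infusim as I

setup = I.standard_setup()                 # Table of standard hardware values
down  = I.to_internal(6.0, "ml/h")         # green pump: 12 -> 6 ml/h at t=0
u_fin = I.to_internal(6.5, "ml/h")         # final total rate (6 + 0.5 ml/h)

tf = I.transient_flow(setup, down)
print(round(tf.theta_first, 3), round(tf.theta_second, 3))
print(round(I.dosing_error_volume(setup, down), 5))
print(round(I.t_central_closed(setup, down, u_fin), 1))
print(round(I.sigma_closed(setup, down, u_fin), 1))
print(round(I.sigma_closed(setup, down, u_fin, with_poiseuille=True), 1))
```

prints

```
1.242 124.902
0.10305
155.8
138.2
619.0
```

meaning: the network relaxes with time constants of 1.2 s and 125 s; the
red syringe delivers an unplanned extra 0.103 ml; without Poiseuille
mixing that bolus is centred 156 s into the tail of the delivery with a
width parameter of 138 s, and the parabolic flow profile broadens it to
619 s (the quoted clinical "duration" is twice these values). The same
numbers come from the command line:

```
infusim fixtures --seed 0 --out scenarios/
infusim metrics --config scenarios/standard.yaml
infusim verify  --config scenarios/standard.yaml   # analytic vs oracle
```

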