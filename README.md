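# pelage

Multi-scale simulation of the hair-follicle growth cycle and of skin-wide
hair-growth patterning.

Mouse skin regenerates its fur in waves: each hair follicle cycles through
growth (anagen), involution (catagen) and rest (telogen), and neighboring
follicles couple through diffusible WNT-family activators and BMP-family
inhibitors so that anagen spreads across the skin as a traveling wave,
faster-cycling ventral skin paces the dorsum into bilaterally symmetric
patterns, hyper-refractory ear skin blocks incoming waves, and hairless
landmarks (eyelids) bend them.  `pelage` is a research tool for exploring
how much of that phenomenology follows from a minimal mechanism: one
activator/inhibitor ligand–receptor pair reacting and diffusing on each
follicle's growing and shrinking 1D axis, coupled to follicle geometry by
two signal-threshold checkpoints, and coupled between follicles by ligand
exchange through the near-surface skin.

## The model in brief

Per follicle and per pathway p ∈ {act, inh}, on the depth axis x ∈ [0, ℓ(t)]:

    ∂L_p/∂t  = D_p ∂²L_p/∂x² + s_p(x, phase) − k_on,p L_p (R_p − LR_p) + k_off,p LR_p
    ∂LR_p/∂t = k_on,p L_p (R_p − LR_p) − (k_off,p + k_deg,p) LR_p + noise

Ligand is produced in the static bulge band (Region I) and in the moving
dermal-papilla band at the distal end (Region II, phase-scheduled rates);
receptors live in Region I.  The growth signal C = ⟨LR_act − LR_inh⟩ over
Region I drives elongation through a saturating phase-gated law, and its
threshold crossings switch the phase: upward through θ_act starts ~anagen,
downward through θ_term starts ~telogen (catagen retraction back to the
resting length).  On 1D arrays and 2D grids, follicles exchange free
ligand over the shared near-surface band at rate κ per neighbor, with
named parameter domains (Dorsal, fast-cycling Ventral, hyper-refractory
Ear), void barriers and aperture holes.  Model details, default parameter
values and their rationale are in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a solitary follicle on the default excitable parameters and read
off its cycle structure:

```python
from pelage import default_params, simulate_hf, phase_durations

act, inh, geom, thr, law = default_params()
traj = simulate_hf(act, inh, geom, thr, horizon=600.0, dt=0.0125,
                   growth_law=law, output_stride=1.0)
table = phase_durations(traj)
print(table[table.cycle > 1].round(2).to_string(index=False))
```

```
 cycle  anagen_duration  telogen_duration  period
     2            33.27             57.95   91.22
     3            33.27             57.95   91.22
     4            33.27             57.95   91.22
     5            33.27             57.95   91.22
     6            33.27             57.95   91.23
```

After a one-cycle transient the follicle settles into an autonomous limit
cycle — about 33 simulated days of ~anagen and 58 of ~telogen, stable to a
fraction of a percent, with no clock anywhere in the equations.  Scaling
all inhibitor sources up shortens ~anagen and lengthens ~telogen until
cycling stops in an extended telogen; scaling them down does the opposite
(`pelage.inhibitor_strength_scan`).

The same machinery runs on lattices.  From the shell:

```
pelage simulate-skin --preset two_domain --seed 1 --out runs/two_domain
pelage analyze --bundle runs/two_domain
pelage render  --bundle runs/two_domain
```

writes the spatiotemporal record (wide CSVs), the transition log, pattern
metrics (onset-order persistence, per-cycle bilateral-symmetry scores) and
phase-map images for a Ventral|Dorsal|Ventral skin in which symmetric
ventral-to-dorsal waves reorganize the dorsal pattern within two cycles.
Other presets: `homogeneous_grid`, `barrier`, `aperture`,
`hyper_refractory_ear`, `single_follicle`, `inhibitor_scan`.

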