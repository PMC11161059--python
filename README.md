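# poroedema

Multi-compartment poroelastic simulation of post-stroke cerebral oedema:
intracranial pressure (ICP), midline shift (MLS) and ventricle collapse on
synthetic idealized brain geometries.

After an ischaemic stroke, blood-brain-barrier (BBB) breakdown lets plasma
filter from the capillaries into the interstitial space. The accumulating
fluid raises ICP, swells the infarcted tissue, shifts the midline towards
the healthy hemisphere and can collapse the lateral ventricles. Clinicians
routinely read MLS off CT images as a proxy for ICP; this package exists to
quantify that ICP-MLS relationship and the factors that bend it — oedema
type (which arterial territory is occluded), BBB damage severity, and
geometry.

## Model

The brain is a porous medium with four fluid compartments (arteriole `a`,
capillary `c`, venule `v`, interstitial `w`) and an elastic solid skeleton.

**Perfusion** (steady, used to locate the ischaemic core):

    ∇·(K_a ∇p_a) = −ω_ac (p_a − p_c)
    ∇·(K_c ∇p_c) =  ω_ac (p_a − p_c) − ω_cv (p_c − p_v)
    ∇·(K_v ∇p_v) =  ω_cv (p_c − p_v)

with arteriole/venule pressures prescribed on the cortical (pial) surface
and no flux elsewhere. Occluding an arterial territory removes the
arteriole boundary data under that territory; cells whose tissue-feeding
flux `ω_cv (p_c − p_v)` drops by ≥ 70 % form the oedema core.

**Oedema** (transient, backward Euler): the same blood equations gain
storage terms `c_b ∂p/∂t`, and the interstitial compartment obeys

    c_w ∂p_w/∂t = ∇·(K_w ∇p_w) + S_cw,
    S_cw = (2 n_b L_p / R_c) [ (p_c − p_w) − σΠ_c ]   (core only, else 0)

— a Starling filtration law where `L_p` is the hydraulic permeability of
the damaged capillary wall, `σ` the (Donnan-corrected) reflection
coefficient and `Π_c` the plasma osmotic pressure.

**Mechanics** (quasi-static, each time step):

    G ∇²u + (G + λ) ∇(∇·u) = ∇p_w

with the pial surface fixed and the ventricle surface free of effective
traction except for self-contact: when the swelling closes a ventricle,
non-penetration of its opposing walls is enforced with an
augmented-Lagrangian scheme, `λ_N ← ⟨λ_N + ε_N g⟩` (Macaulay bracket of
the penetration `g`).

Outputs: ICP = max `p_w` over the domain (mmHg); MLS = signed maximum
right-to-left displacement on the midplane (mm); zero-intercept ICP-MLS
slopes; ABP-ICP confidence ellipses; stress and volume-change summaries.

## Worked example

```python
from poroedema import (
    IdealizedBrainSpec, build_idealized_brain, occlude_territories,
    OedemaParameters, Schedule, solve_steady_perfusion, extract_oedema_core,
    run_oedema_simulation, fit_icp_mls_slope,
)

domain = build_idealized_brain(IdealizedBrainSpec())   # 2D bihemispheric brain
params = OedemaParameters()                            # literature defaults

healthy = solve_steady_perfusion(domain, params.perfusion)
occluded = solve_steady_perfusion(
    domain, params.perfusion,
    occluded=occlude_territories(domain, ["right_MCA"]))
core, volume_ml = extract_oedema_core(domain, healthy, occluded, params.perfusion)

result = run_oedema_simulation(domain, params, core, Schedule(), abp_mmhg=90.0)
slope, r2 = fit_icp_mls_slope(result.icp[1:], result.mls[1:])
print(f"core {volume_ml:.2f} ml; ICP {result.icp[-1]:.2f} mmHg; "
      f"MLS {result.mls[-1]:.2f} mm; slope {slope:.3f} mm/mmHg (R2={r2:.4f})")
```

prints

```
core 4.32 ml; ICP 19.92 mmHg; MLS 8.60 mm; slope 0.891 mm/mmHg (R2=0.9968)
```

i.e. a middle-cerebral-artery occlusion on the default geometry produces a
4.3 ml core (2D area × 1 mm depth); over 1000 s of leakage the peak
interstitial pressure doubles from the 10 mmHg CSF baseline to ~20 mmHg
while the midline shifts ~8.6 mm towards the left, with MLS growing
linearly at 0.89 mm per mmHg of ICP rise.

There is also a CLI for the experiment presets
(`single`, `abp_sweep`, `lp_sweep`, `oedema_types`):

```
poroedema run --config config.yaml --preset oedema_types --outdir out/
poroedema mesh --out brain.msh
poroedema validate --config config.yaml
```

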