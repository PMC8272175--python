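# thyrotherm

Finite-element simulation of the heat signature of thyroid nodules on the
skin of the neck, and of the dynamic infrared thermography (DITI) protocol
used to look for it.

Infrared thermography is being explored as a non-invasive aid for thyroid
nodule assessment: a metabolically active, well-perfused nodule is a heat
source a few centimetres under the skin, and the question is whether (and
when) that heat survives the trip through gland, muscle, fat and skin well
enough for a thermal camera to see it. `thyrotherm` answers this with a
parametric 2D model of a neck cross-section — skin, fat and muscle layers,
the thyroid lobes, a trachea, and an elliptic nodule — swept over fat
thickness, nodule size, metabolic heat and blood perfusion, and coupled to
the exact time-series analysis applied to patient thermograms.

## Model

Tissue temperature follows the Pennes bioheat equation. At steady state

$$0 = \nabla\cdot(k\nabla T) + w_b\,\rho_b c_b\,(T_b - T) + Q_m,$$

and in transient form

$$\rho c\,\frac{\partial T}{\partial t} = \nabla\cdot(k\nabla T) + w_b\,\rho_b c_b\,(T_b - T) + Q_m,$$

where $k$ is thermal conductivity, $w_b$ blood perfusion, $\rho_b c_b$ the
blood volumetric heat capacity (taken per tissue), $T_b = 37$ °C the
arterial temperature and $Q_m$ the metabolic heat. Boundary conditions:
convective exchange $-\mathbf n\cdot k\nabla T = h\,(T - T_\text{air})$ on
the anterior skin ($\Gamma_1$), zero flux on the trachea wall ($\Gamma_2$),
and prescribed $T_p = 37$ °C on the posterior surface ($\Gamma_3$).

The exam protocol is simulated in three chained phases: steady state under
natural convection ($h = 10$ W/m²K, room air 25 °C), 300 s of forced fan
cooling ($h = 50$ W/m²K), and 300 s of natural reheating, with skin
temperatures sampled every 15 s — the camera schedule (20 frames in 5 min).

Everything is solved in-package with linear (P1) triangular finite elements
on a mirror-symmetric Delaunay-refinement mesh, backward-Euler time
stepping, and scipy sparse linear algebra. The solver is validated against
the closed-form 1D bioheat slab solution to < 0.01 °C.

## Worked example

Simulate the reference case — 0.6 cm of fat, the large (3.14 × 1.80 cm
diameter) nodule with $Q_m = 42{,}000$ W/m³ and $w_b = 0.465$ (mL/min)/mL:

```bash
cat > case.yaml <<EOF
fat_thickness: 0.006
nodule_size: large
mesh_target: 0.001
label: example
EOF
thyrotherm run-case --config case.yaml --out out/
```

which prints

```
example: delta_TCL=0.151 degC, delta_TF=1.831 degC, series 34.03 -> 29.97 -> 33.03 degC
```

Reading: the skin directly in front of the nodule is 0.151 °C warmer than
the mirror point on the healthy side (`delta_TCL`) — the contrast a camera
would have to resolve; the fat layer alone absorbs 1.83 °C of the drop
between the 38.2 °C nodule core and the 34.0 °C skin (`delta_TF`); during
the protocol that skin point cools from 34.03 °C to 29.97 °C under the fan
and recovers only to 33.03 °C after five minutes — reheating is always left
unfinished, which is why the dynamic exam carries more information than the
steady image. `out/` contains the full temperature series, the steady skin
profile along the neck arc, the annotated skin-to-trachea line profile, and
the run metadata (geometry, mesh, preset).

The same pipeline runs factorial sweeps (`thyrotherm sweep`), renders
synthetic camera sequences with NETD-scale noise and extracts the 11×11
ROI patient series from them (`thyrotherm synthesize`,
`thyrotherm analyze-thermograms`), and compares rebased reheating curves of
two cases (`thyrotherm compare-cases`).

A note on perfusion units: the literature values for gland and nodule
perfusion (0.098 and 0.465 (mL/s)/mL) clamp the gland to ≈ 37.02 °C if taken
literally as 1/s, which contradicts the reported 38.3 °C nodule core. Both
readings are kept as named presets — `as_printed` and `per_minute_gland`
(gland/nodule values divided by 60, giving a 38.4 °C core equilibrium) —
and every result records which one it used. See `docs/methods.md`.

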