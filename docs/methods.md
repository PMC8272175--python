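# Methods

## Model and assumptions

Tissue temperature is modelled by the Pennes bioheat equation on a 2D neck
cross-section: conduction plus a blood-perfusion exchange term
`wb·rho_b·c_b·(Tb − T)` and a metabolic source `Qm`. The 2D simplification
assumes thermal continuity along the body axis (no axial heat exchange).
All properties are constant per tissue (no temperature dependence), there
is no radiative or evaporative surface term, and the blood density and
specific heat are set equal to the host tissue's own `rho` and `c` — this
follows the convention of the parameter table the defaults come from.
Temperatures are carried in °C throughout; the model is linear in T, so no
offset to kelvin is needed.

Boundary conditions: Robin convection `−n·k∇T = h(T − Tair)` on the
anterior half of the outer circle (Γ1), zero flux on the trachea wall (Γ2),
and a strong Dirichlet value Tp = 37 °C on the posterior half (Γ3). The
posterior prescribed-temperature arc stands in for the deep body core; its
angular extent is configurable (`gamma1_half_angle`, default π/2).

## Geometry

The outer radius comes from a 36 cm neck perimeter (R = 36/2π ≈ 5.73 cm).
Skin (0.1 cm), fat (0–1.2 cm) and muscle (1.0 cm) are concentric annuli;
the remaining interior is muscle-equivalent tissue containing:

- a trachea hole, radius 0.8 cm, at the disc centre (insulated, so its
  exact size has little thermal effect; 0.8 cm is chosen to keep ≥ 2 mm of
  meshable clearance from the gland in the thickest-fat case);
- two mirror-image elliptic thyroid lobes whose centres sit at ±30° off the
  anterior midline, at polar distance `r_muscle_inner − b_lobe − 2 mm` —
  i.e. the gland is applied to the deep face of the strap muscles, so a
  thicker fat layer pushes it deeper, as it does anatomically. The lobes
  are sized as the largest nodule preset plus a 2 mm shell, major axis
  tangential; they may overlap across the midline (the isthmus);
- an elliptic nodule concentric with the left lobe.

The 30° offset places the skin point radially in front of the nodule at
arc coordinate −3 cm from the anterior midline (negative = nodule side),
matching where the reference study reads its skin probe. Lobe shape, depth
and the trachea are not stated in that study; the values above are this
package's reconstruction, chosen on anatomical grounds, fixed once across
all sweeps, and embedded in every run's JSON metadata.

Nodule size presets are quoted as diameter pairs (small 1.2 × 0.7 cm,
medium 2.2 × 1.26 cm, large 3.14 × 1.80 cm); the ellipses use half those
values as semi-axes. Reading the printed pairs as semi-axes instead can be
shown to be geometrically impossible here: under 1.2 cm of fat the interior
disc has radius 3.43 cm, and a 3.14 × 1.80 cm semi-axes ellipse placed
anywhere inside it contains the mirror of its own centre, so the
healthy-lobe probe point would lie inside the nodule and no mirror-
symmetric healthy lobe could exist. The diameter reading makes the quoted
ellipse areas (π·d1·d2) overstatements by 4×; the package reports true
areas π·a·b.

## Tissue parameters and the perfusion-units presets

Defaults (SI units, °C): skin k 0.37, ρ 1109, c 3391, wb 0.00196, Qm
1829.85; fat 0.21/911/2348/0.000501/464.61; muscle
0.47/1090/3421/0.000708/1046; thyroid 0.52/1050/3609/0.098/4200; nodule
0.89/1050/3770/0.465/42000; Tb = 37 for all.

Taken literally as 1/s, the gland and nodule perfusions clamp tissue to the
local equilibrium `Tb + Qm/(wb·ρb·cb)` ≈ 37.01–37.03 °C, which cannot
produce the reported 38.3 °C nodule core; divided by 60 (a per-minute
reading) the nodule equilibrium is 38.37 °C, which can. The true units in
the source literature are unresolved, so both interpretations are kept as
registry presets:

- `as_printed` — table values used literally (1/s);
- `per_minute_gland` — thyroid and nodule wb divided by 60 at solve time;
  all other tissues (whose printed values are plausible per-second rates)
  unchanged.

Every result records its preset. The two presets genuinely disagree about
which reported results are reproducible (see "Known misses" below); the
package reports both rather than silently rewriting the table.

## Discretization

Meshing is a distmesh-style force-equilibrium Delaunay triangulation
written on `scipy.spatial.Delaunay`. Points sampled on every boundary and
tissue-interface curve are held fixed; free interior points relax under
truss forces. A size field caps edge lengths at 1 mm inside the thin outer
layers, at ~b/2.5 near small nodules, and inside the narrow clearances
(gland–muscle, nodule–trachea), grading back to the global target `h` at
0.3 m/m. The mesh is generated on the half-domain x ≥ 0 and mirrored, so
meshes are exactly symmetric: a symmetric problem yields a symmetric
discrete solution (observed ≤ 1e-12 °C), and left/right skin differences
carry no mesh asymmetry. Across the full fat × size × h grid the minimum
interior angle stays above 20° (worst observed ≈ 23.9°) and the mesh area
matches the disc-minus-trachea area to ≪ 0.1%. Element region tags come
from centroid classification against the exact geometry; boundary edges
are tagged Γ1/Γ3 (outer circle, by anterior/posterior midpoint) and Γ2
(trachea).

The FEM uses P1 triangles, a consistent mass matrix, exact edge-length
quadrature for Robin terms and strong (row-replacement) Dirichlet
imposition. Steady solves are direct (SuperLU) with relative residual
checked < 1e-10. Transient integration is a θ-scheme, default backward
Euler (θ = 1) at dt = 1 s, with one LU factorization reused over all steps;
against a dt = 0.05 s reference the dt = 1 s solution differs by < 0.01 °C
at the end of the forced-cooling shock, the stiffest moment of the
protocol. Validation against the closed-form 1D bioheat slab (cosh/sinh
solution with Dirichlet/Robin ends) agrees to < 0.001 °C at h = 0.5 mm.

Point evaluation is barycentric interpolation; points that fall marginally
outside the polygonal boundary (e.g. exactly on the curved skin circle,
beyond the chordal facets — a sagitta of ~h²/8R ≈ 2e-6 m) are linearly
extrapolated from the nearest boundary element.

Default problem sizes: h = 1 mm gives ≈ 11.8k nodes / 23k triangles; one
full protocol case (steady + 600 s at dt = 1 s) runs in well under a
minute on one CPU, and the whole reference reproduction in a few minutes.
Qualitative and property tests run at h = 2–3 mm, where every ordering and
invariant already holds; the halving step h = 2 mm → 1 mm moves the front
skin probe by < 0.001 °C (`convergence_report`), so reported temperatures
are mesh-converged well below the 0.2–0.4 °C tolerances used.

## Protocol simulation

Three chained phases — steady (h = 10 W/m²K, Tair = 25 °C), cooling
(h = 50, 300 s), reheating (h = 10, 300 s) — each initialized with the
previous phase's final field; fields are retained every 15 s. The junction
sample belongs to the cooling phase; point series over the full exam have
(300+300)/15 + 1 = 41 samples. Fan cooling is modelled purely as the
increased convection coefficient at room temperature, not as a cooled air
stream. Cooling normally stops at the fixed 300 s; the clinical alternate
stop ("mean anterior skin temperature ≤ 30 °C, or five minutes") is
available as `cooling_stop="mean_skin_threshold"`.

## Synthetic thermograms

The generator emulates the camera output needed to exercise the patient
analysis pipeline, not a radiometric image of a neck: for each of the 20
reheating samples, the anterior skin-arc profile is painted across a
horizontal band of a 640 × 480 frame (≈ 0.28 mm/pixel; the marked column is
anchored exactly on the front-of-nodule arc), the background is room air,
and i.i.d. Gaussian noise with sd 0.04 °C — the camera's NETD bound — is
added from an explicit integer seed (fixed seed ⇒ bit-identical frames).
Real thermograms differ in every way that does not matter to the series
pipeline (2D scene content, spatial noise correlation, optics); what the
passing tests do show is that the 11 × 11 ROI mean recovers the simulated
skin series to < 0.05 °C and attenuates sensor noise by exactly the
window factor 11. Matrix I/O accepts comma- or semicolon-separated text
(decimal comma with semicolons) and enforces the −40…2000 °C capture
range; ROI windows that would cross the frame border are an error rather
than silently truncated, which would bias the series.

## Known misses in the reproduction report

Three reference values are not reproduced, for reasons the package
documents rather than tunes away:

- the 0.5 °C contralateral difference of the four-combination study is
  evaluated (as specified) under `as_printed`, where the perfusion clamp
  makes the gland isothermal at ≈ 37.0 °C and the computed difference is
  ≈ 0.003 °C. The study's actual claim — that the four combinations are
  mutually indistinguishable (< 0.1 °C) — does hold and is asserted;
- the 0.6 °C maximum nodule-size effect: with diameter-read nodules the
  computed effect is ≈ 0.27 °C. The printed figure is consistent with
  4×-area nodules (the semi-axes reading), which the geometry proof above
  rules out;
- the zero-fat transient case (end of cooling 32.3 °C): computed
  ≈ 31.6 °C. The reference study itself flags its 0 cm-fat transient curve
  as a possible numerical inconsistency; the package's zero-fat case is
  self-consistent with its own steady state (start 35.1 °C vs reported
  35.5 °C, inside tolerance).

Also note the reference's steady numbers are mutually constrained: a front
skin temperature of 34.3 °C under h = 10, Tair = 25 fixes the surface flux
at ≈ 93 W/m², which across 0.6 cm of fat (k = 0.21) implies a drop of
≈ 2.6 °C, not the 2.0 °C quoted alongside it; the computed pair here
(34.03 °C, 1.83 °C drop) is flux-consistent and lands within tolerance of
both quoted values.

## Limitations

2D cross-section only (no axial conduction, no patient-specific anatomy);
no inverse fitting of tissue parameters to measured series; no radiometric
decoding of proprietary camera formats; nodule position fixed concentric
in the left lobe; single uniform arterial temperature. These match the
scope of the computational study being reproduced.
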