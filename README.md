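# lingerlab

Analysis of red blood cell (RBC) **lingering** at a diverging microvascular
bifurcation, and of its consequences for hematocrit partitioning.

At a Y-shaped capillary bifurcation, some RBCs do not flow directly from the
parent vessel into a daughter branch: they approach the flow divider along the
separation streamline, fold around the apex with near-zero velocity, and pause
there before committing to a branch. These lingering cells (LRBCs) afterwards
marginate against the distal wall of the daughter vessel, skewing its
hematocrit profile — a mechanism that can flip the classical Zweifach–Fung
partitioning at the next bifurcation downstream.

`lingerlab` post-processes particle-tracking-velocimetry (PTV) cell tracks
through such a bifurcation. It is aimed at microfluidics / biofluid-dynamics
groups who track individual cells through junction geometries and need a
tested, scriptable version of this analysis chain:

- **geometry** — Y-bifurcation coordinate frame, regions of interest (ROIs),
  apex location, normalized lateral coordinate y* = y/W ∈ [−0.5, 0.5],
  separation-axis crossing detection;
- **classification** — per-cell lingering metrics and labels under four
  criteria: relative residence time τ, minimum intersection speed, minimum
  apex distance, and their conjunction;
- **hemodynamics** — tube hematocrit, the Pries–Secomb prediction, blood flow
  rates and RBC fluxes with a mass-conservation correction, partitioning
  fractions Φᵢ/Ψᵢ, capillary number;
- **distribution** — lateral distribution functions (LDFs), skewness index,
  composite-LDF mixture fitting of the lingering frequency, two-sample K–S
  and Mann–Whitney tests;
- **synthetic** — a trajectory generator with ground-truth labels so the whole
  chain is testable without microscopy data.

## The statistics at the core

**Relative residence time.** For each cell, τ = t_r / t_ref, where t_r is the
time its centroid spends inside the intersection region and
t_ref = L / ū_out,0 is a convective reference time (L: path length from the
parent-ROI exit over the apex to a daughter-ROI entry; ū_out,0: mean cell
speed at the parent outlet). A cell lingers iff τ > 2.0 (strict; the
threshold is configurable and a sensitivity table over {1.7, 2.0, 2.3} is
reported).

**Skewness index.** For a normalized lateral profile LDF(y*),
Sk = |∫₋₀.₅⁰ LDF dy* − 0.5|: 0 for a symmetric profile, 0.5 when all cells
sit on one side of the centerline.

**Composite-LDF fit.** With lingerer/non-lingerer profiles measured at the
daughter outlets, LDF_C(y*, γ) = γ·LDF_LRBC + (1−γ)·LDF_NLRBC. The lingering
frequency γ̂ that best explains a target profile minimizes
E(γ) = ∫₀⁰·⁵ [LDF(y*) − LDF_C(y*, γ)]² dy*; E is exactly quadratic in γ, so
γ̂ is closed-form (clipped to [0, 1]).

**Flux partitioning.** Q_blood,i = χ·ū_i·W·H and Q_RBC,i = ū_i·H̄_t,i·W·H per
ROI; measured fluxes are corrected to satisfy Q₀ = Q₁ + Q₂ by minimizing the
summed squared *relative* adjustments (closed-form Lagrange solution), then
Φᵢ = Q̂_blood,i/Q̂_blood,0 and Ψᵢ = Q̂_RBC,i/Q̂_RBC,0.

## Worked example

```python
import lingerlab as ll

cfg = ll.SyntheticConfig(n_rbc=378, gamma_true=0.11, seed=1)
table, truth = ll.generate_experiment(cfg)
geom = cfg.geometry

scale = ll.reference_time(table, geom)
records = ll.compute_records(table, geom, scale)
ll.classify(records, "tau", tau_threshold=2.0)
print(f"t_ref = {scale.t_ref*1e3:.1f} ms, lingering frequency = "
      f"{ll.lingering_frequency(records):.3f} (truth {truth.lingering_fraction():.3f})")

fx = ll.flux_summary(table, geom)
print(f"Phi1 = {fx.phi[1]:.3f}, Ca = {fx.capillary_number:.3f}")
```

prints

```
t_ref = 24.8 ms, lingering frequency = 0.122 (truth 0.122)
Phi1 = 0.503, Ca = 0.519
```

The 378 tracked cells yield a reference time of ≈25 ms; the τ criterion
recovers the generated lingering fraction exactly on this draw, and the
symmetric bifurcation splits the blood flow evenly (Φ₁ ≈ 0.5). Building the
daughter-outlet LDFs split by label gives Sk = 0.50 for lingerers (all cells
against the distal wall) versus Sk ≈ 0.32 for non-lingerers, and fitting a
composite profile mixed at γ = 0.25 returns γ̂ = 0.250.

The same chain is available from the shell:

```bash
lingerlab simulate --seed 5 --out tracks.csv --truth truth.csv
lingerlab classify --tracks tracks.csv --criterion tau --out records.json
lingerlab fluxes   --tracks tracks.csv --out fluxes.json
lingerlab ldf      --tracks tracks.csv --roi daughter1 --station outlet --out ldf.csv
lingerlab analyze  --config run.yaml   # full pipeline -> JSON report
```

Track tables are plain CSV with columns
`rbc_id, frame, x_um, y_um, u_mm_s[, circularity, orientation_deg]`.

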