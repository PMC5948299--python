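# femload

Micro-finite-element based inverse-remodelling prediction of hip joint
loads from voxel images of the proximal femur.

## The problem

Joint loads are among the largest forces a bone experiences, but they are
hard to measure: instrumented prostheses exist for a handful of subjects,
and musculoskeletal models carry large uncertainties. Bone itself,
however, records its loading history — trabecular architecture adapts
until the local mechanical stimulus is near a remodelling equilibrium.
Inverse remodelling exploits this: given an observed architecture, find
the combination of candidate joint loads that would put the tissue
closest to that equilibrium.

`femload` implements this load-estimation pipeline for the femoral head,
end to end and at desk scale, together with a parameter-sensitivity
harness and a plausibility comparison against instrumented-prosthesis
style load recordings. It is aimed at researchers studying bone
adaptation, joint loading, and the robustness of architecture-based load
estimation.

## The method

1. **Image processing** — a grayscale CT-like volume is Gaussian-filtered
   (support 2 voxels, σ = 1.6), resampled by two (block mean), and
   segmented at a fixed threshold (grey value 3000). An implant-style
   anatomical frame is built from the best-fitting femoral head sphere,
   the shaft axis (line fit to distal slice centroids over a 40 mm
   section), and the neck axis through the smallest neck cross-section.
   The volume is rotated into this frame, cropped to 1.5 head radii
   lateral and distal, and capped with a 2.2 mm spherical cartilage layer.
2. **Unit load cases** — n = 4 loads, inclined −20°, 20°, 60° and 100°
   from the vertical axis in the frontal plane, each applied through the
   intersection of the articular sphere with a 40° cone (uniform nodal
   forces along the inward surface normals) and scaled to a 1000 N
   resultant **F**ᵢ.
3. **Voxel FE** — one trilinear hexahedral element per labelled voxel
   (E = 10 GPa bone, 10 MPa cartilage, ν = 0.3; lateral and distal faces
   fully constrained), solved by matrix-cached, Jacobi-preconditioned
   conjugate gradients; per-element strain energy density (SED) Uᵢ(x).
4. **Inverse remodelling** — the combined stimulus is
   U(x) = Σᵢ sᵢ·Uᵢ(x), and the non-negative least-squares problem

       min_{s ≥ 0}  Σ_{x∈X} [ Ũ − Σᵢ sᵢ Uᵢ(x) ]²

   with equilibrium stimulus Ũ = 0.02 MPa yields load magnitudes
   αᵢ = √(n·sᵢ), the scaled vectors αᵢ·**F**ᵢ, the peak and mean joint
   load vectors, and the coefficient of variation (CoV) of the stimulus
   before and after optimisation.
5. **Sensitivity & plausibility** — a one-at-a-time design varies nine
   parameters (threshold, load area, force distribution, bone/cartilage
   moduli, number and location of unit loads, ROI, equilibrium stimulus)
   with two levels each; the plausibility stage extracts per-subject peak
   vectors and frontal-plane inclination ranges from load traces and
   compares them with predictions (incl. a Wilcoxon signed-rank test on
   CoV pairs).

Because real micro-CT scans and the in-vivo force database are not
shipped, the `synthetic_data` module generates every input: mini-joint
structures forward-remodelled to a *known* load history (so recovery can
be tested), grayscale renderings, and activity-resolved load traces; the
published per-specimen scaling-factor/CoV table is packaged as a text
fixture.

## Worked example

```python
import numpy as np
from femload import PipelineConfig, run_pipeline
from femload.synthetic_data import RemodellingParams, generate_adapted_structure

# structure adapted to a single 1000 N load at 20 degrees
spec = generate_adapted_structure(load_mix=[(20.0, 1000.0)],
                                  params=RemodellingParams(seed=1))
cfg = PipelineConfig(threshold=0.5, filter_sigma=0.0, shaft_section_mm=10.0)
res = run_pipeline(spec.binary_structure, cfg, frame=spec.frame)
p = res.prediction
print("alpha:", np.round(p.alpha, 3), "at", res.inclinations_deg, "deg")
print(f"peak {np.linalg.norm(p.peak_vector):.0f} N at {p.peak_inclination:.1f} deg; "
      f"CoV {p.cov_init:.0f}% -> {p.cov_opt:.0f}%")
```

prints

```
alpha: [0.102 1.041 0.21  0.   ] at [-20.  20.  60. 100.] deg
peak 1041 N at 20.0 deg; CoV 166% -> 71%
```

i.e. the inverse pipeline assigns the dominant magnitude to the load case
the structure was actually adapted to (20°), recovers the generating
magnitude within ~4 %, and the optimised scaling more than halves the
tissue-loading inhomogeneity.

The same machinery is exposed on the command line:

```bash
femload simulate --out demo --seed 1
femload predict --image demo/specimen_grey.mhd --frame demo/specimen_frame.txt --out demo/pred.txt
femload sensitivity --image demo/specimen_grey.mhd --out demo/sensitivity.csv
femload compare --traces demo/traces.csv --predictions demo/peaks.csv
```

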