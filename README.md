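# osteovasc

Simultaneous 3D quantification of bone and blood-vessel microstructure
from contrast-enhanced micro-CT volumes of small-animal long bones.

After perfusion with a radio-opaque contrast agent, a micro-CT scan of a
mouse tibia contains three phases in one volume: bright vasculature,
intermediate mineralized bone, and dark marrow/background. `osteovasc`
turns such a volume into standard bone- and vessel-morphometry numbers
and runs the group statistics of a treatment study:

* **Segmentation** — hysteresis-threshold seeds and a marker-controlled
  watershed flooding the *phase asymmetry of the monogenic signal*, a
  contrast-invariant edge measure that keeps the weak bone/vessel
  interface as strong a barrier as the bone/background one.
* **Vascular cleaning** — multi-scale Hessian "tubeness" (per scale
  σ²·√(λ2·λ3) on the negative Hessian eigenvalue pair) removes blob-like
  contrast leaks while preserving connected vessel runs, and the vessel
  tree is partitioned by local thickness into capillaries, sinusoids and
  arteries/veins.
* **Compartments** — the total volume TV as slice-wise convex hulls of
  the cortex with signed-distance shape interpolation, the marrow cavity
  by inward erosion past the cortical shell, and the exact trabecular /
  cortical split by mask algebra.
* **Morphometry** — BV/TV, VV/TV, Tb.BV/Mar.V by voxel counting; Tb.Th
  and V.Th by the maximal-inscribed-sphere method; box-counting fractal
  dimension from log N(λ) = −FD·log λ + log α; the structure model index
  SMI = 12·V·M/S² (0 ideal plate, 3 ideal rod, 4 sphere) from a
  triangulated iso-surface with M the integral of mean curvature; and
  connectivity density Conn.D = β1/TV from the Euler characteristic by
  octant counting.
* **Statistics** — per group Lilliefors (Monte-Carlo p-values) and
  Grubbs; across groups Bartlett, one-way ANOVA with η² effect sizes
  (Cohen's 0.01/0.06/0.14 benchmarks) and Tukey HSD when significant.

Because raw synchrotron acquisitions are rarely shareable, the package
ships a first-class phantom generator: synthetic tibiae with a cortical
shell, plate/rod trabecular lattice, branching vascular tree, contrast
leaks, blur and noise — with exact per-voxel ground truth — plus a
grouped study design (2 time points × 4 treatments, 73 animals) for
end-to-end rehearsal of the whole pipeline.

## Worked example

```python
from osteovasc import PhantomSpec, RunConfig, generate_phantom, process_sample

spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0, seed=3)
vol, truth = generate_phantom(spec)
rec = process_sample(vol, RunConfig(), sample_id="demo", group="T1P")
print(f"BV/TV      {rec.bvtv:.3f}   (truth {truth.true_bvtv:.3f})")
print(f"VV/TV      {rec.vvtv:.3f}   (truth {truth.true_vvtv:.3f})")
print(f"Tb.Th      {rec.tb_th_um:.1f} um   V.Th {rec.v_th_um:.1f} um")
print(f"SMI        {rec.smi:.2f}   FD(bone) {rec.fd_bone:.2f}   "
      f"Conn.D {rec.conn_d:.0f} /mm^3")
```

prints

```
BV/TV      0.462   (truth 0.467)
VV/TV      0.032   (truth 0.029)
Tb.Th      14.5 um   V.Th 40.7 um
SMI        2.70   FD(bone) 1.81   Conn.D 19688 /mm^3
```

The bone and vessel volume fractions land within half a percentage
point of the phantom's exact truth despite the added blur and noise;
the mean trabecular thickness (~14 µm ≈ 4 voxels) and vessel caliber
(~41 µm) reflect the generated plate/rod lattice and vessel tree; SMI
2.7 says the half-plate/half-rod lattice reads rod-dominated once rods
intersect. Conn.D counts handles per mm³ of total volume and is the
parameter most sensitive to segmentation noise — speckle bridges in a
noisy mask add handles, so it is best compared between groups processed
identically rather than against the clean-mask value.

A full study runs the same way:

```python
from osteovasc import RunConfig, generate_study, run_pipeline

samples = generate_study(master_seed=0)      # 73 phantoms, 8 groups
result = run_pipeline(RunConfig(), samples)  # records + StatsReport
print(result.records.groupby("group")["tb_bv_marv"].mean())
```

There is also a CLI (`osteovasc phantom|segment|enhance|partition|
compartments|run-all|stats`) mirroring the library stages, reading and
writing TIFF stacks with YAML sidecars and CSV tables.

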