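# memdyn

Quantification stack for the membrane dynamics and nanoscale clustering of
neuronal transmembrane proteins — built for experiments that combine
quantum-dot single-particle tracking (QD-SPT), STORM super-resolution
imaging, and widefield immunofluorescence, as used to study how chloride
cotransporters such as NKCC1 are confined and clustered at the neuronal
surface.

It is aimed at lab analysts who have localization tables and images and need
the standard readouts of such a study, reproducibly and scriptably:

* **SPT** — trajectory linking and crossing-track removal; per-trajectory
  mean squared displacement MSD(nτ) = (1/(N−n))·Σᵢ[(x₍ᵢ₊ₙ₎−xᵢ)² +
  (y₍ᵢ₊ₙ₎−yᵢ)²]; diffusion coefficient D from the 4-point fit
  MSD(nτ) = 4Dnτ + b (b ≈ 4σ_loc²); explored area EA = MSD at 0.42/0.45 s;
  synaptic/extrasynaptic classification against marker masks (190 nm camera
  pixels, 760 nm inclusion radius); dwell time per synaptic exit with the
  five-frame discard rule.
* **STORM** — sliding-window (2000-frame) center-of-mass drift correction;
  merging of repeated detections of one blinking fluorophore (2σ in space,
  15 s in time); 20 nm-pixel rendering; density-threshold nanocluster
  segmentation with per-cluster area, detection count, and density.
* **Widefield** — 3×3 median background flattening, threshold-based cluster
  number/area/intensity inside a dendritic ROI, surface/total membrane
  ratio, and background-subtracted ratiometric (chloride-probe) traces.
* **Statistics** — log-normalization by the control median; Welch t vs
  Mann-Whitney selection via Shapiro-Wilk; and a balanced Monte-Carlo
  Mann-Whitney test for clustered super-resolution data (equal per-neuron
  draws, per-culture control-median normalization, 1000 repetitions, p-value
  from the resampled U distribution).
* **Synthetic data** — seeded simulators for all three streams (trajectories
  with free/confined motion and blinking, STORM bursts with drift, punctate
  widefield images, clustered log-normal samples) with ground truth, so the
  whole stack is testable without microscope data.

See `docs/methods.md` for the models, conventions, and calibration caveats.

## Worked example

Simulate a two-condition SPT experiment in which the treated condition has
half the diffusion coefficient and half the confinement radius of control
(the signature of increased confinement), then quantify it:

```python
from memdyn.pipeline import run_scenario_confinement

res = run_scenario_confinement(n_per_group=300, seed=7, test_method="mw")
for name in ("D", "EA"):
    b = res[name]
    print(f"{name}: control {b['median_control']:.4g}, treated "
          f"{b['median_treated']:.4g}, {b['test']} p = {b['p_value']:.3g}")
```

prints

```
D: control 0.08291, treated 0.03467, mann_whitney p = 1.05e-99
EA: control 0.1053, treated 0.03802, mann_whitney p = 1.05e-99
```

i.e. the median fitted diffusion coefficient drops from 0.083 to
0.035 µm²/s (2.4-fold) and the median explored area at 0.42 s from 0.105 to
0.038 µm² (2.8-fold), both overwhelmingly significant by the rank test on
log-normalized values — the treated population is slower and more confined,
as simulated.

The numbered scripts under `analysis/` run the same machinery step by step —
simulation (`01`), tracking and trajectory metrics (`02`), STORM nanocluster
analysis (`03`), widefield quantification (`04`), statistics calibration
(`05`), and the confinement scenario (`06`) — writing their tables under
`results/`. A command-line interface is available as `memdyn`
(`memdyn metrics`, `memdyn storm`, `memdyn stats`, `memdyn run`).

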