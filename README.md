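# golgiscreen

Quantification of organelle morphology and membrane-carrier dynamics
for image-based RNAi screens, with a synthetic-microscopy generator
that provides exact ground truth for every stage.

## What it is for

High-content screens that knock down genes one by one and image a
fluorescent organelle marker need unbiased per-cell readouts of what
the organelle looks like and how its transport intermediates move.
This package implements that analytic surface for a Golgi/endosome
screen in HeLa-like cells:

- **Cell segmentation** — nuclei by thresholding with
  distance-transform watershed declumping, cells by seeded watershed
  propagation, intracellular fragments/puncta by per-cell robust
  thresholding (background median + k·MAD).
- **Golgi polar distribution score (PDS)** — a circular statistic for
  how anisotropically the Golgi sits around the cell centre. Fragment
  centroids are converted to polar angles about the cell centroid,
  rotated to a zero circular mean, and binned into 8 equal sectors:

  PDS = Σₖ | fₖ − 1/8 |

  where fₖ is the fraction of fragments in sector k. PDS = 0 for a
  perfectly even ring, 1.75 (= 2·(1 − 1/8)) when every fragment falls
  in one sector. Treatment means are reported relative to the
  non-silencing control (NEG): < 1 reads as "dispersed", > 1 as
  "compacted".
- **Organelle features** — per-cell structure counts, integrated and
  mean marker intensity, occupied area (µm²), normalised to control.
- **Carrier kinematics** — time-lapse preprocessing (−10 constant
  subtraction, σ = 1 px Gaussian blur, ×3 rescale), detection,
  greedy nearest-neighbour linking, per-track mean speed and net
  displacement, a strict > 2 µm displacement filter, and
  tubular (length ≥ 2 µm) vs vesicular classification.
- **Screen statistics** — Mann–Whitney U or ANOVA vs the NEG control
  with Bonferroni correction, Pearson correlation of screen readouts,
  and qPCR knockdown efficiency by the ΔΔCt method
  (relative expression = 2^−ΔΔCt, knockdown % = (1 − 2^−ΔΔCt)·100).
- **Synthetic scenes** — perturbed-ellipse cells with one nucleus,
  fragments placed with a von Mises angular law (concentration κ is
  the single dispersion knob), puncta of controlled count/intensity,
  and moving point/tubular carriers with programmed speeds — all with
  exact truth records, so every estimator can be validated.

## Worked example

```python
import golgiscreen as gs

scene = gs.generate_cell_scene(3, seed=5)          # render a clean field
cells, frags = gs.segment_scene(scene)             # nuclei -> cells -> fragments
for cell, fs in zip(cells, frags):
    print(cell.cell_id, len(fs), round(gs.pds_for_cell(cell, fs).pds, 3))
```

prints

```
1 12 1.083
2 12 0.917
3 12 1.0
```

— each segmented cell recovers exactly the 12 rendered fragments, and
the per-cell PDS near 1.0 reflects the moderately juxtanuclear
placement (κ = 4) the generator used. The `examples/` directory has
one short script per capability (scene simulation, polar scoring,
segmentation, carrier tracking, screen statistics), each printing the
numbers it computes and what they mean. A thin CLI wraps the same
functions for shell pipelines:

```sh
golgiscreen simulate --out scene --n-cells 3 --seed 1
golgiscreen score-golgi --manifest manifest.csv --out-dir results
```

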