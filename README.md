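# epiwave

Vertex-model simulation and quantification of epithelial expansion waves.

Epithelial cells in a growing organ pass through three mechanical phases —
membrane **ruffling** (random protrusive pulses, low cortical tension),
rapid basal-**area increasing**, and collective posterior-to-anterior
**spreading** driven by substrate extension. `epiwave` implements:

- a modified vertex model with many boundary vertices per cell (discrete
  adhesion clusters) moving by overdamped force balance under six force
  terms: cortical tension, area elasticity, pulsatile protrusion, Hill-gated
  substrate adhesion, one-sided dorso-ventral stress fibers, and thermal
  noise (`epiwave.model`);
- phase programs with a posterior-to-anterior onset wave, genotype presets
  (`WT`, `Rac1DN_weak/strong`, `Rho1DN`, `PaxOE`, `TalinRNAi`,
  `DumpingInhibited`) and single- vs combined-factor protocols;
- shape and signal metrics: circularity (4πA/P²), cell volume and flatten
  ratio, curvature-based de-novo ruffle detection with 12-bin rose
  diagrams, migration kinematics, autocorrelation periods, photobleaching
  correction, and Gabor-bank fiber polarity (`epiwave.metrics`);
- spatial/temporal correlation tools: masked Pearson coefficient, the
  cross-correlation-vs-shift curve, min-max coefficient normalization and
  peak-lag estimation for pulsatile cascades (`epiwave.correlation`);
- seeded synthetic-data generators with ground-truth sidecars for every
  estimator (`epiwave.synthetic`).

## CLI

```sh
# simulate one genotype (writes trajectory.jsonl, per_frame.csv, tissue.csv, manifest.json)
epiwave simulate --genotype WT --mode combined_factor --seed 7 --out runs/wt

# quantify any boundary trajectory (simulated or synthetic)
epiwave quantify --trajectory runs/wt/trajectory.jsonl --out runs/wt_metrics

# correlation analyses on TIFF pairs and/or multichannel trace CSVs
epiwave correlate --image1 c1.tif --image2 c2.tif --traces cascade.csv --out runs/corr

# synthetic fixtures with ground truth
epiwave synth --kind cascade --seed 3 --out fixtures/cascade

# genotype comparison table (migration distance, area fold-change)
epiwave report --genotypes WT,Rho1DN,DumpingInhibited --seeds 0,1,2 --out runs/report
```

Model and schedule parameters can be overridden per run with a YAML config
(`--config`) holding `params:` and `program:` sections; unknown keys are
rejected. Every output directory contains a `manifest.json` echoing the
configuration, seed and package version; identical seeds give byte-identical
outputs.

## Conventions

Coordinates are planar micrometres with the anterior–posterior axis along
+x (posterior at larger x) and dorso-ventral along +y; cell outlines are
counter-clockwise closed polygons. Trajectories are exchanged as JSON-lines
(one record per cell per frame) or tidy CSV; traces as CSV; images as TIFF.
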