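# mpasl — bias-corrected perfusion quantification from multi-phase PCASL

Multi-phase pseudo-continuous arterial spin labelling (MP-PCASL) acquires
perfusion-weighted images at several RF phase offsets θ so that cerebral
blood flow can be quantified robustly to off-resonance in the labelling
plane.  The signal in a voxel follows, to a good approximation, a modified
Fermi line shape

```
f(θ) = Ms − ΔM · [ 2 / (1 + exp((|θ − ϕ| − α)/β)) − 1 ]
```

with static tissue magnitude `Ms`, perfusion amplitude `ΔM`, the feeding
artery's off-resonance phase offset `ϕ`, and line-shape constants
`(α, β)` — (54°, 13°) for human 3T and (70°, 19°) for rat 9.4T
acquisitions.  Fitting all three parameters voxel-wise systematically
*overestimates* `ΔM` at realistic SNR, and therefore CBF.  Because `ϕ` is a
property of the artery, not the voxel, the bias can be removed by a
multi-stage analysis: a free voxel-wise fit, supervoxel clustering of the
(biased) phase map into K = 4 vascular territories, averaging of the data in
each cluster, a high-SNR fit of each cluster's series, and a final
voxel-wise refit with `ϕ` pinned to the cluster value.  Optionally, the
final stage replaces the Fermi line shape with Bloch-simulated
velocity-dependent inversion profiles, which also yields an estimate of
arterial blood flow velocity.

The package is aimed at ASL methods researchers: it provides the signal
models, the MAP fitting machinery, the clustering, the full pipeline with
NIfTI I/O and CBF calibration, a ground-truthed synthetic data generator,
and the Monte-Carlo studies that characterise the estimation bias.

## Worked example

Simulate a 32×32×10 four-territory volume at SNR 40 with ΔM/Ms = 2% and
territory phases {0°, 15°, 30°, 45°}, then run the multi-stage analysis:

```python
import numpy as np
from mpasl import (SyntheticSpec, generate_volume, PipelineConfig,
                   HUMAN_SHAPE, run_multistage, phase_consistency)

spec = SyntheticSpec(shape=(32, 32, 10), snr=40.0, dm_fraction=0.02,
                     territory_phis=(0.0, 15.0, 30.0, 45.0), seed=4)
ds = generate_volume(spec)
maps = run_multistage(ds.data, ds.mask, PipelineConfig(shape=HUMAN_SHAPE, seed=0))

dm_true = spec.m_s * spec.dm_fraction
phis = [maps.cluster_phis[k] for k in sorted(maps.cluster_phis)]
print("regional phase offsets (deg):",
      ", ".join(f"{p:.1f}" for p in sorted(phis)))
print(f"phase consistency (mean pairwise distance): "
      f"{phase_consistency(phis):.1f} deg")
print(f"free-fit amplitude bias (stage 1): "
      f"{100*(np.nanmean(maps.stage1_delta_m)/dm_true - 1):+.1f}%")
print(f"fixed-phase amplitude bias (stage 5): "
      f"{100*(np.nanmean(maps.delta_m)/dm_true - 1):+.1f}%")
```

which prints

```
regional phase offsets (deg): 0.3, 14.6, 29.1, 45.4
phase consistency (mean pairwise distance): 24.9 deg
free-fit amplitude bias (stage 1): +21.8%
fixed-phase amplitude bias (stage 5): +0.9%
```

The four regional phases land within ~1° of the generating territory
offsets; the free three-parameter fit overestimates the amplitude by ~22%
at this SNR, while the fixed-phase refit is essentially unbiased — the
core point of the multi-stage correction.  `maps.delta_m` can be converted
to CBF in mL/100g/min with `calibrate_cbf` given the usual single-PLD
calibration constants.

A command-line interface mirrors the library:

```sh
mpasl synth --out data/ds --snr 40 --dm-fraction 0.02
mpasl fit --data data/ds_data.nii.gz --mask data/ds_mask.nii.gz --out maps/
mpasl lookup --preset rat --out rat_lookup.json
mpasl simulate --study bias --snrs 20,40,60,100 --out bias.csv
```

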