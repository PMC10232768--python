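# painmap

Percept-related fMRI analysis of spontaneous pain, built as a tested,
reusable pipeline. The setting is a trigeminal-neuralgia (TN) style
experiment: patients continuously rate their momentary pain on a 0–100
visual-analog scale (VAS) while BOLD fMRI is acquired (a *pain tracking*
session), rest quietly in a second session, and — for a control — re-track
a replay of their own earlier rating cursor (*motion tracking*). Three
independent analyses each produce a ranked set of pain-related brain
regions, and regions found by at least two analyses form the cross-method
consensus ("signature centres"):

1. **Correlation mapping** — the rating trace `r(t)` is convolved with a
   canonical double-gamma hemodynamic response function `h`, giving the
   predicted response `x(t) = (r * h)(t)`; each voxel's Pearson correlation
   with `x` is Fisher-transformed, `z = atanh(ρ)`, and a voxelwise
   one-sample t test over subjects is thresholded at `p < 0.05`
   (uncorrected) with a 10-voxel cluster-extent minimum, separately for
   positive and negative correlations.
2. **Volumetric CNN decoding** — each 3-D volume is labelled *low pain*
   (rating ≤ 15) or *high pain* (rating > 15) and classified by a grouped
   ("cardinalized") residual 3-D convolutional network trained with
   class-weighted cross-entropy and SGD (momentum 0.9, weight decay 5e-4)
   under subject-grouped 8-fold cross-validation.
3. **Sliding-window graph decoding** — BOLD is averaged within each atlas
   region; 30 s moving windows give per-window connectivity matrices that
   are binarized into graphs; a two-layer Graph Isomorphism Network
   (`h'_v = MLP((1+ε) h_v + Σ_{u∈N(v)} h_u)`) classifies each window by the
   rating at its centre.

Region importance for both decoders comes from **occlusion sensitivity**:
zero a region's voxels (CNN) or its node features and incident edges
(GCNN), re-measure each fold model's held-out accuracy, and rank regions by
the mean accuracy drop.

Because the underlying patient fMRI is not public, the package ships a
first-class **synthetic cohort generator**: rating traces with paroxysmal
dynamics on the 0–100 scale, BOLD with an HRF-convolved copy of the trace
planted in designated atlas regions plus AR(1) noise, slow drift and
motion-course leakage, a resting session driven by a latent ongoing-pain
level correlated with the tracking mean, and a motion-tracking session whose
BOLD is uncoupled from the replayed cursor. Every stage of the pipeline is
exercised end to end on this cohort.

## Worked example

```python
from painmap.cohort import CohortConfig
from painmap.pipeline import run_pipeline

result = run_pipeline(CohortConfig(seed=1))
print("label threshold:", result.threshold)
print("correlation regions:", sorted(result.corr_regions))
print("CNN mean fold accuracy: %.3f" % result.cnn.metrics_.mean_accuracy)
print("GCNN mean fold accuracy: %.3f" % result.gcnn.metrics_.mean_accuracy)
print("top-5 CNN occlusion regions:", result.cnn_heatmap.ranking()[:5])
print("top-5 GCNN occlusion regions:", result.gcnn_heatmap.ranking()[:5])
print("motion-control accuracy: %.3f" % result.motion_control.motion_accuracy)
```

On the default 12-subject desk-scale cohort (three planted regions, codes
3, 8 and 13 — superior_temporal, thalamus and parahippocampal) this prints:

```
label threshold: 13
correlation regions: ['parahippocampal', 'superior_temporal', 'thalamus']
CNN mean fold accuracy: 0.561
GCNN mean fold accuracy: 0.782
top-5 CNN occlusion regions: [3, 12, 14, 10, 13]
top-5 GCNN occlusion regions: [8, 13, 3, 9, 7]
motion-control accuracy: 0.526
```

Reading this: the correlation branch flags exactly the three planted
regions and nothing else; both decoders are above the 50% chance level
(the window-based GCNN decisively so); the GCNN occlusion ranking puts all
three planted regions in its top 5, while the single-volume CNN's
occlusion map — whose per-region accuracy drops are only a little larger
than their fold-to-fold noise at this cohort size — catches two of the
three on this seed (see the known-limitations section of
`docs/methods.md`); and the motion-tracking control sits at chance
(subject-level t test p > 0.05) because its BOLD is uncoupled from the
replayed cursor by construction.

The `painmap` command exposes the same steps from a shell:
`painmap generate`, `painmap correlate`, `painmap decode`, `painmap report`.

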