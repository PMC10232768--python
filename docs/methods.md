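# Methods

This note documents the models implemented in `painmap`, the assumptions of
the synthetic cohort, the numerical choices, and what the tests do and do
not establish about real data.

## The analysis pipeline

**Preprocessing.** Each functional run is cleaned in two steps, in this
order: (1) voxelwise ordinary-least-squares removal of an intercept and six
head-motion time courses (three translations, three rotations); residuals
are exactly orthogonal to the regressors, and a rank-deficient design falls
back to the pseudoinverse with a warning. (2) A zero-phase (forward–
backward) 4th-order Butterworth bandpass, default [0.01, 0.1] Hz. The
filter family and order are our choice — only the band is prescribed by the
protocol we follow — and forward–backward application is the field-standard
way to avoid phase distortion. Runs shorter than three times the filter's
settling length (3 × `padlen` of `scipy.signal.filtfilt`) are rejected
rather than silently padded.

**Correlation branch.** The canonical HRF is the double-gamma kernel
(peak delay 6 s, undershoot delay 16 s, undershoot ratio 1/6, 32 s
support), sampled at the TR. The rating trace is resampled at volume
acquisition mid-times `(i + 1/2)·TR` by linear interpolation, causally
convolved, truncated to the run length, and correlated with every voxel.
Zero-variance voxels get r = 0 and a flag. Per-subject maps are Fisher
transformed (|r| = 1 clamped to atanh(1 − 1e-7)), and a voxelwise
one-sample t test across subjects is thresholded at p < 0.05 uncorrected,
both signs, with connected-component labelling (26-connectivity by
default; 6 and 18 available) and a 10-voxel extent minimum. Clusters are
reported at their max-|t| voxel, mapped to mm through the atlas affine and
named by the atlas code at the peak (scan-order tie-break). No multiple-
comparison correction is applied by default, matching the protocol;
Benjamini–Hochberg FDR is available behind a flag. Voxels with zero
between-subject variance in z are treated as overwhelming evidence when
their common z is nonzero (t = ±inf, p = 0) and as no evidence when it is
zero (p = 1); this degenerate case only arises in noise-free constructions.

**Labels and folds.** Ratings are dichotomized at a threshold (default
15 VAS; label 1 strictly above). `choose_threshold` recomputes the
class-balancing integer cut for any cohort — the rationale behind the
original choice of 15 — and the pipeline uses it for synthetic cohorts,
whose rating scale is not calibrated to the clinical one. Folds partition
subjects, never samples: 8 groups of near-equal size, each fold training
on 7 groups and testing on the held-out one. An optional fixed
hemodynamic-lag shift for the label lookup exists (default 0 s).

**CNN decoder.** A parametric grouped-convolution residual network:
strided 3×3×3 stem, `n_stages` residual stages whose two 3×3×3
convolutions are split into `cardinality` independent grouped paths with a
1×1 projected shortcut, batch normalization throughout, global average
pooling, 2-unit linear head. The desk-scale default is 2 stages,
cardinality 4, base width 16 (≈15k parameters; narrower widths make the
redundant planted regions compete for too few filters and destabilize the
occlusion ranking); a deep 4-stage, 32-path configuration is expressible
through the same parameters but is not the tested surface. Training is class-weighted cross-entropy (inverse class
frequency on the training split) with SGD, momentum 0.9, weight decay
5e-4. Early stopping monitors held-out accuracy and the weights of the
best epoch are kept.

**GCNN decoder.** BOLD is averaged within each atlas region; Pearson
correlation in 30 s moving windows (15 volumes at TR 1.98 s) gives
per-window connectivity; entries strictly greater than a threshold
(default 0.3; the protocol leaves the value open) become edges, diagonal
forced to zero. Each window is a graph whose node features are the
regions' windowed BOLD segments; two GIN layers
(`h' = MLP((1+ε)h + Σ_neighbours h)`, ε fixed at 0 by default, learnable on
request) with mean readout and a 2-unit head classify the window by the
rating at its centre time. "Cross-correlation" is implemented at lag zero;
window stride is 1 volume at the operation level (the desk-scale pipeline
uses stride 2 for run time).

**Occlusion importance.** For each region and each fold model, the
held-out samples are re-scored with the region zeroed (voxels for the CNN;
node feature row plus incident adjacency row/column for the GIN). The drop
in accuracy relative to the unoccluded inputs, averaged over the 8 folds,
is the region's importance; regions are ranked by mean drop with ties
broken by region code. A drop can be negative (occlusion can remove
noise). The conversion of a heatmap into an "identified" region set is not
prescribed anywhere; the default rule requires the 8 fold drops to be
positive at a one-sided one-sample t test (p < 0.05), with a top-K
alternative; the rule used is recorded by the caller.

**Decision calibration.** Class-weighted losses bias raw decisions toward
the training minority class, so each fold model's decision threshold is
set, after training, to the score-margin quantile that makes its
prediction rate on its own training split equal the training label
fraction. Without this, a fold model carries its training prior onto
held-out subjects, which appears as spurious above-chance accuracy on
label-uncoupled data (the motion-tracking control) and as shared-model
variance that inflates the between-session prediction correlation. The
calibration uses only training data and is part of the decoder, not of the
evaluation.

**Consensus and validation.** The three branches' region-name sets are
intersected: regions found by ≥2 methods form the consensus table, with
counts of all-three / exactly-two / at-least-two. Validation analyses use
one shared Pearson routine and are computed for both decoder branches:
per-subject mean predicted pain (mean class-1 probability; mean hard label
available) against mean reported rating, and resting-session against
tracking-session predicted means (resting inputs are scored by the model
that held the subject out). At desk scale the two branches have different
power for the two analyses: the window-based GIN estimates each subject's
pain fraction better (it sees temporal context), so the
predicted-vs-reported correlation is most informative through it, while
the CNN's resting predictions recover the planted resting–tracking
coupling well. The motion-tracking control uses the CNN models, comparing
fold-respecting accuracies on pain-tracking and motion-tracking samples,
the latter labelled by the replayed cursor trace; besides pooled exact
binomial tests against 50% it reports subject-level t tests of the
per-subject accuracies, because samples within a subject are autocorrelated
and the subject is the exchangeable unit. Subgroup transfer trains a single (unfolded) model on
one subgroup and tests on the other, refusing training subgroups below a
configurable minimum size (default 4 subjects).

## The synthetic cohort

The generator emulates the statistical structure the analyses assume, at a
desk scale that keeps a full multi-seed experiment on one CPU:

* **Rating traces.** A reflected random walk (step SD 0.15 VAS per sample)
  carries a slow baseline started uniformly in [6, 9] VAS; paroxysms
  arrive as a regularized renewal process (Gamma-distributed inter-event
  intervals, shape 4) with a per-subject mean rate drawn from
  [0.015, 0.030] events/s and per-subject mean amplitude drawn from
  [25, 45] VAS (Gamma, shape 4), decaying with a 12 s time constant.
  Ratings are clipped to [0, 100]. The renewal regularity keeps each
  run's high-pain time fraction near balance; the per-subject rate and
  amplitude are the between-subject drivers of mean pain. Threshold
  crossings therefore happen on 10–100 s timescales — inside the analysis
  band — rather than through DC offsets, which the preprocessing removes
  and no single-volume decoder could recover.
* **BOLD.** Voxels outside the brain mask are exactly zero, as in
  skull-stripped normalized data. Brain voxels carry AR(1) noise
  (φ = 0.4, unit stationary SD), a sinusoidal drift below 0.01 Hz, and a
  leak of the six simulated motion courses; voxels inside the planted
  regions additionally carry the HRF-convolved rating trace in units of
  10 VAS, scaled by the coupling amplitude (noise-SD units per 10 VAS).
* **Coupling amplitude.** The default places the decoders on the steep
  part of their accuracy-vs-SNR curve, where the occlusion analysis is
  informative: a saturated decoder loses nothing when one of several
  redundant regions is removed, and an occlusion map stops ranking
  regions meaningfully. At the default, a planted voxel correlates with
  the HRF-convolved ratings at r ≈ 0.4–0.5, the strength of a clearly
  pain-correlated (not peak) voxel in published percept-fMRI maps.
* **Sessions.** Tracking 480 s, resting 300 s, motion 480 s at TR 1.98 s.
  The resting run is driven by a latent "ongoing pain" trace whose
  paroxysm rate correlates (ρ = 0.7) with the subject's tracking rate;
  the motion run replays the subject's own rating cursor while its BOLD
  carries no coupling at all. Sex and prior-surgery labels follow the
  clinical proportions (25/39 female, 20/39 surgery) at any cohort size.
* **Geometry.** 16 cubic ROI blocks on a lattice with background gaps
  wide enough that 26-connected clusters cannot merge across regions
  through a single stray suprathreshold voxel; block origins are aligned
  to the stride-2 downsampling grid so no region is systematically
  attenuated by the decoder's pooling geometry. Three regions (codes 3,
  8, 13) carry the planted signal.

**What the synthetic data does not have:** spatial autocorrelation of the
noise, scanner artefacts needing realignment or slice-timing correction,
physiological (cardiac/respiratory) structure, anatomical variability
between subjects, hemispheric structure, or any nonlinearity between
ratings and BOLD. Passing tests therefore demonstrate that the pipeline's
machinery is correct and recovers planted structure under its own
assumptions — not that the scientific conclusions transfer to real
scanner data.

## Desk-scale run sizes

The full-scale recipe (50 epochs, batch 2, learning rate 1e-3) remains the
`TrainConfig` default. The desk-scale experiments use 3 epochs, batch 16,
learning rate 1e-2, early-stop patience 3, CNN training on every 2nd
volume with occlusion/validation on the same density, and GCNN windows at
stride 2 — sizes chosen so that a multi-cohort recovery study runs in
minutes on a single CPU. The neural networks are implemented in a
compact numpy engine (`painmap._nn`) with manual backpropagation; grouped
convolution is computed as an im2col GEMM with the grouped kernel expanded
block-diagonally, which at these volume sizes is faster than per-group
contractions.

## Known limitations

* Decoding accuracies on the synthetic cohort (CNN ≈ 0.6–0.65, GCNN ≈
  0.8) are not calibrated to the clinical study's reported accuracies;
  the single-volume CNN is intrinsically limited by the removal of
  per-subject DC pain level in preprocessing.
* Occlusion drops are small relative to their fold-to-fold variance for
  decoders operating near their accuracy ceiling; the default conditions
  are chosen to avoid that regime, but for the single-volume CNN the
  per-region drop (~1–3 accuracy points) remains comparable to the
  between-fold spread of drops with only 12 held-out subjects, so
  individual cohort seeds can rank a noise region above a planted one.
  The GIN's occlusion map, whose drops are several times larger, is
  stable across seeds.
* The per-class one-vs-rest AUCs are computed from the two raw output
  unit scores; with a softmax head the two scores are nearly antisymmetric
  and the two AUCs nearly equal, so differing per-class AUCs arise only
  when calibration offsets or score scales differ.
* The consensus layer matches regions by exact (hemisphere-free) name.
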