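"""Synthetic cohort generator: trace dynamics, planted coupling, metadata."""

import numpy as np
import pytest

from painmap.cohort import (Atlas, BoldRun, CohortConfig, PainTrace,
                            generate_cohort, generate_subject, generate_trace,
                            make_block_atlas)
from painmap.correlation import canonical_hrf, convolve_trace
from painmap.preprocess import bandpass, regress_nuisance

from conftest import small_config


class TestPainTrace:
    def test_ratings_bounded_over_many_seeds(self):
        for seed in range(1000):
            t = generate_trace(60.0, 1.98, paroxysm_rate=0.05, seed=seed,
                               spike_amp_mean=60.0)
            assert t.ratings.min() >= 0.0 and t.ratings.max() <= 100.0

    def test_zero_variance_walk_is_constant(self):
        t = generate_trace(120.0, 1.98, paroxysm_rate=0.0, seed=3,
                           walk_sigma=0.0, baseline_start=12.0)
        assert np.allclose(t.ratings, 12.0)

    def test_length_and_range_contract(self):
        t = generate_trace(600.0, 1.98, seed=11)
        assert len(t.ratings) == int(np.floor(600 / 1.98)) + 1
        assert np.all((t.ratings >= 0) & (t.ratings <= 100))

    def test_same_seed_bit_identical(self):
        a = generate_trace(300.0, 1.98, seed=7)
        b = generate_trace(300.0, 1.98, seed=7)
        assert np.array_equal(a.ratings, b.ratings)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_trace(-5.0, 1.98)
        with pytest.raises(ValueError):
            generate_trace(60.0, 0.0)

    def test_trace_invariants_enforced(self):
        with pytest.raises(ValueError):
            PainTrace("s", times=[0.0, 1.0], ratings=[0.0, 101.0])
        with pytest.raises(ValueError):
            PainTrace("s", times=[1.0, 0.5], ratings=[1.0, 2.0])
        with pytest.raises(ValueError):
            PainTrace("s", times=[0.0], ratings=[5.0])


class TestAtlas:
    def test_block_atlas_regions_disjoint_and_named(self, atlas):
        assert atlas.n_regions == 16
        sizes = [atlas.mask(c).sum() for c in atlas.codes]
        assert all(s == 64 for s in sizes)
        assert len(set(atlas.names.values())) == 16

    def test_blocks_are_separated_by_background(self, atlas):
        # dilating any region by one voxel must not touch another region
        from scipy import ndimage
        struct = np.ones((3, 3, 3), bool)
        for c in atlas.codes[:4]:
            grown = ndimage.binary_dilation(atlas.mask(c), structure=struct)
            touched = set(np.unique(atlas.labels[grown])) - {0, c}
            assert not touched

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError):
            make_block_atlas(shape=(10, 10, 10), n_regions=100)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            Atlas(labels=np.array([[[1, 2]]]), names={1: "a", 2: "a"})


class TestGenerateSubject:
    def test_noise_free_planted_voxel_tracks_regressor(self):
        cfg = small_config(noise_sigma=0.0, drift_amplitude=0.0,
                           motion_amplitude=0.0, ar1=0.0, amplitude=0.5)
        subjects, atlas = generate_cohort(cfg)
        s = subjects[0]
        run = s.run("tracking")
        clean = regress_nuisance(run, np.zeros((run.n_volumes, 6)))
        filtered = bandpass(clean)
        reg = convolve_trace(s.trace, canonical_hrf(run.tr), run)
        # compare against the identically filtered regressor
        reg_run = BoldRun(data=np.tile(reg, (1, 1, 1, 1)).reshape(1, 1, 1, -1),
                          tr=run.tr, affine=run.affine, session="tracking")
        reg_f = bandpass(regress_nuisance(reg_run, np.zeros((run.n_volumes, 6))))
        vox = filtered.data[atlas.mask(cfg.planted_rois[0])][0]
        r = np.corrcoef(vox, reg_f.data[0, 0, 0])[0, 1]
        assert r > 0.999

    def test_zero_amplitude_means_no_coupling(self):
        cfg = small_config(amplitude=0.0, seed=5)
        subjects, atlas = generate_cohort(cfg)
        s = subjects[0]
        run = s.run("tracking")
        reg = convolve_trace(s.trace, canonical_hrf(run.tr), run)
        regc = (reg - reg.mean()) / reg.std()
        planted = np.isin(atlas.labels, list(cfg.planted_rois))
        flat = run.data[planted]
        flat = flat - flat.mean(axis=1, keepdims=True)
        rs = (flat @ regc) / (np.linalg.norm(flat, axis=1) * np.linalg.norm(regc))
        assert abs(rs.mean()) < 0.1

    def test_motion_run_uncoupled_from_replayed_cursor(self):
        # empirical null: mean |r| with the replayed trace is the same in
        # planted regions as in the rest of the brain, over many subjects
        cfg = small_config(include_motion=True, tracking_s=140.0,
                           motion_s=140.0)
        atlas = make_block_atlas(tuple(cfg.shape), cfg.n_regions)
        diffs = []
        for seed in range(120):
            s = generate_subject(cfg, atlas, f"m{seed}", seed)
            run = s.run("motion_tracking")
            reg = convolve_trace(s.motion_trace, canonical_hrf(run.tr), run)
            regc = (reg - reg.mean()) / (reg.std() + 1e-12)
            planted = np.isin(atlas.labels, list(cfg.planted_rois))
            other = atlas.brain_mask() & ~planted
            def mean_abs_r(mask):
                flat = run.data[mask].astype(float)
                flat = flat - flat.mean(axis=1, keepdims=True)
                rs = (flat @ regc) / (np.linalg.norm(flat, axis=1)
                                      * np.linalg.norm(regc) + 1e-12)
                return np.abs(rs).mean()
            diffs.append(mean_abs_r(planted) - mean_abs_r(other))
        # mean difference indistinguishable from zero
        diffs = np.array(diffs)
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert abs(t) < 4.0

    def test_unknown_planted_code_rejected(self):
        cfg = small_config(planted_rois=(99,))
        with pytest.raises(ValueError, match="planted"):
            generate_cohort(cfg)


class TestGenerateCohort:
    def test_default_proportions_at_n39(self):
        cfg = small_config(n_subjects=39, tracking_s=170.0, resting_s=170.0)
        subjects, _ = generate_cohort(cfg)
        assert sum(s.sex == "female" for s in subjects) == 25
        assert sum(s.sex == "male" for s in subjects) == 14
        assert sum(s.surgery for s in subjects) == 20
        assert sum(not s.surgery for s in subjects) == 19

    def test_reproducible_under_seed(self):
        cfg = small_config(seed=9, n_subjects=8)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        for sa, sb in zip(a, b):
            assert sa.sex == sb.sex and sa.surgery == sb.surgery
            assert np.array_equal(sa.trace.ratings, sb.trace.ratings)
            assert np.array_equal(sa.run("tracking").data, sb.run("tracking").data)

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError, match="n_subjects"):
            CohortConfig(n_subjects=5).validate()

    def test_run_structure(self, small_cohort):
        _, subjects, _ = small_cohort
        for s in subjects:
            assert s.has_run("tracking") and s.has_run("resting")
            assert s.run("tracking").tr == pytest.approx(1.98)
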