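"""Generator contracts: planted truth, noise structure, dataset round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cghdiv import (
    ConfigurationError,
    DISTANT_PROFILE,
    GeneratorConfig,
    SpeciesProfile,
    generate_feature_annotations,
    quality_filter,
    read_array_scan,
    simulate_scans,
    write_dataset,
)
from cghdiv.preprocess import background_correct_minimum
from cghdiv.synthetic import NO_HIT_FLOOR_ID, read_annotations

ZERO = lambda x: np.zeros_like(np.asarray(x, dtype=float))


def quiet_config(**kw):
    """Config with every noise and artifact source switched off."""
    base = dict(
        seed=3, n_features=400, n_arrays=2, conserved_n=40,
        sd_kinetic=ZERO, sd_technical=ZERO, dye_bias=0.0,
        intensity_trend_amplitude=0.0, frac_lowquality=0.0,
        beta_gc=0.0, beta_align=0.0, beta_id_gc=0.0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


def oriented_m(scan):
    corr = background_correct_minimum(scan)
    m = np.log2(corr["R"].to_numpy() / corr["G"].to_numpy())
    return -m if scan.dye_swapped else m


class TestProfilesAndConfig:
    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SpeciesProfile("bad", ((0.5, 95.0, 1.0), (0.4, 90.0, 1.0)))

    def test_component_mean_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SpeciesProfile("bad", ((1.0, 55.0, 1.0),))

    def test_odd_array_count_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_arrays=3)

    def test_conserved_n_bounded_by_features(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_features=100, conserved_n=101)


class TestAnnotations:
    def test_conserved_features_flagged_and_above_95(self):
        cfg = GeneratorConfig(n_features=1000, conserved_n=50, seed=7)
        ann, _ = generate_feature_annotations(cfg, DISTANT_PROFILE)
        cons = ann[ann["conserved"] == 1]
        assert len(cons) == 50
        assert (cons["true_pct_id"] >= 95.0).all()

    def test_mixture_mean_matches_truncated_normal(self):
        # single-component profile: sample mean within 3 SE of the analytic
        # truncated-normal mean on [60, 100]
        prof = SpeciesProfile("one", ((1.0, 95.5, 2.0),))
        cfg = GeneratorConfig(n_features=10000, conserved_n=0, seed=11)
        ann, _ = generate_feature_annotations(cfg, prof)
        a, b = (60 - 95.5) / 2.0, (100 - 95.5) / 2.0
        expected = stats.truncnorm.mean(a, b, loc=95.5, scale=2.0)
        sd = stats.truncnorm.std(a, b, loc=95.5, scale=2.0)
        assert abs(ann["true_pct_id"].mean() - expected) < 3 * sd / np.sqrt(10000)

    def test_probe_lengths_center_on_500bp(self):
        cfg = GeneratorConfig(n_features=5000, conserved_n=0, seed=1)
        ann, _ = generate_feature_annotations(cfg, DISTANT_PROFILE)
        assert 480 <= ann["probe_length_bp"].median() <= 520

    def test_alignment_can_exceed_100_and_tracks_identity(self):
        cfg = GeneratorConfig(n_features=5000, conserved_n=0, seed=2)
        ann, _ = generate_feature_annotations(cfg, DISTANT_PROFILE)
        hit = ann[~ann["no_hit"]]
        assert (hit["pct_align"] > 100).any()
        assert np.corrcoef(hit["true_pct_id"], hit["pct_align"])[0, 1] > 0.5

    def test_missing_orthologs_carry_sentinel_and_floor(self):
        prof = SpeciesProfile("gappy", ((1.0, 95.0, 2.0),), frac_missing_ortholog=0.2)
        cfg = GeneratorConfig(n_features=2000, conserved_n=100, seed=5)
        ann, truth = generate_feature_annotations(cfg, prof)
        nh = ann["no_hit"]
        assert 0.15 < nh.mean() < 0.25
        assert ann.loc[nh, "true_pct_id"].isna().all()
        assert (truth.loc[nh.to_numpy(), "true_pct_id"] == NO_HIT_FLOOR_ID).all()

    def test_truth_mean_at_full_identity_is_exact(self):
        cfg = quiet_config()
        prof = SpeciesProfile("top", ((1.0, 99.9, 0.05),))
        _, truth = generate_feature_annotations(cfg, prof)
        # zero kinetic deviation => mu = beta0 + beta_id * pct_id exactly
        expect = cfg.beta0 + cfg.beta_id * truth["true_pct_id"]
        assert np.allclose(truth["true_mean_m"], expect, atol=0, rtol=0)

    def test_planted_mean_monotone_in_identity(self):
        cfg = GeneratorConfig(n_features=8000, conserved_n=0, seed=9)
        _, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
        binned = truth.groupby(pd.cut(truth["true_pct_id"], np.arange(60, 101, 5)), observed=True)[
            "true_mean_m"
        ].mean()
        diffs = np.diff(binned.dropna().to_numpy())
        assert (diffs > -0.05).all()  # non-decreasing up to binning noise


class TestScans:
    def test_noise_free_scans_recover_planted_means_exactly(self):
        cfg = quiet_config()
        ann, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
        scans = simulate_scans(ann, truth, cfg)
        for scan in scans:
            assert np.allclose(oriented_m(scan), truth["true_mean_m"], atol=1e-9)

    def test_dye_bias_shifts_orientations_apart(self):
        cfg = quiet_config(dye_bias=0.5)
        ann, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
        scans = simulate_scans(ann, truth, cfg)
        m = {s.dye_swapped: oriented_m(s).mean() for s in scans}
        # oriented M keeps +bias on normal and -bias on swapped arrays
        assert m[False] - m[True] == pytest.approx(1.0, abs=1e-6)

    def test_low_quality_fraction_fails_filter(self):
        cfg = GeneratorConfig(seed=4, n_features=4000, n_arrays=2, conserved_n=100,
                              frac_lowquality=0.2)
        ann, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
        scans = simulate_scans(ann, truth, cfg)
        rate = np.mean([1.0 - quality_filter(s).mean() for s in scans])
        assert abs(rate - 0.2) < 0.02

    def test_replicate_noise_matches_planted_technical_sd(self):
        # oversized replication so per-feature SDs are stable
        cfg = GeneratorConfig(seed=6, n_features=500, n_arrays=64, conserved_n=50,
                              dye_bias=0.0, intensity_trend_amplitude=0.0,
                              frac_lowquality=0.0)
        ann, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
        scans = simulate_scans(ann, truth, cfg)
        m = np.column_stack([oriented_m(s) for s in scans])
        sd = m.std(axis=1, ddof=1)
        ratio = sd / np.asarray(cfg.sd_technical(truth["true_pct_id"]))
        assert abs(np.median(ratio) - 1.0) < 0.1


class TestDatasetIO:
    def test_round_trip_preserves_values_bit_exactly(self, tmp_path, small_dataset):
        cfg, ann, truth, scans = small_dataset
        write_dataset(scans, ann, truth, tmp_path, cfg=cfg)
        for scan in scans:
            back = read_array_scan(tmp_path / f"{scan.array_id}.tsv")
            assert back.dye_swapped == scan.dye_swapped
            pd.testing.assert_frame_equal(back.data, scan.data, check_exact=True)
        ann_back = read_annotations(tmp_path / "annotations.tsv")
        assert np.array_equal(
            ann_back["true_pct_id"].to_numpy(), ann["true_pct_id"].to_numpy(), equal_nan=True
        )

    def test_same_seed_regenerates_identical_files(self, tmp_path):
        cfg = GeneratorConfig(seed=12, n_features=300, n_arrays=2, conserved_n=40)
        out = []
        for sub in ("a", "b"):
            ann, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
            scans = simulate_scans(ann, truth, cfg)
            manifest = write_dataset(scans, ann, truth, tmp_path / sub, cfg=cfg)
            out.append(manifest)
        assert out[0] == out[1]
        assert out[0]["seed"] == 12
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_eight_array_design_writes_eight_scan_files(self, tmp_path, small_dataset):
        cfg, ann, truth, scans = small_dataset
        manifest = write_dataset(scans, ann, truth, tmp_path, cfg=cfg)
        assert len(manifest["scan_files"]) == 8
        assert all((tmp_path / f).exists() for f in manifest["scan_files"])
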