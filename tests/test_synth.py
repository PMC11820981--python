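"""Ground-truth fidelity of the synthetic map generator."""

import numpy as np
import pytest

import imsnose as ims
from imsnose.errors import ParameterError
from imsnose.synth import (PeakSpec, SynthConfig, default_peaks, equalized,
                           generate_dataset, generate_sample)


def clean_config(**kwargs):
    """Deterministic construction: no noise, baseline, jitter or depletion."""
    # n_drift chosen so every catalogue drift centre (multiples of 0.05 ms)
    # sits exactly on the grid
    base = dict(n_ret=241, n_drift=201, ret_span=(0.0, 240.0),
                drift_span=(4.0, 14.0), noise_sd=0.0, baseline_amp=0.0,
                rip_jitter_sd=0.0, ret_offset_sd=0.0, depletion_coef=0.0,
                n_per_class=(1, 1, 1), seed=0)
    base.update(kwargs)
    return SynthConfig(**base)


class FixedJitterRng:
    """Generator stand-in that returns a fixed normal draw (to pin the
    drift-axis factor) and zeros elsewhere."""

    def __init__(self, z):
        self.z = z

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is None:
            return loc + scale * self.z
        return np.zeros(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        mid = (low + high) / 2.0
        return mid if size is None else np.full(size, mid)


class TestGenerateSample:
    def test_noiseless_map_is_exact_sum_of_gaussians(self):
        # three well-separated peaks: each apex must equal its amplitude
        classes = ("EVOO", "VOO", "LVOO")
        peaks = tuple(
            PeakSpec(r, 4.0, d, 0.1, {c: a for c in classes})
            for r, d, a in [(30.0, 7.0, 1.5), (100.0, 10.0, 2.5),
                            (180.0, 12.5, 0.7)]
        )
        cfg = clean_config(peaks=peaks, rip_amplitude=0.0)
        m, gt = generate_sample(cfg, "EVOO", np.random.default_rng(0))
        drift, ret = cfg.drift_axis(), cfg.retention_axis()
        for p in peaks:
            r = int(np.argmin(np.abs(ret - (cfg.injection_s + p.ret_center))))
            c = int(np.argmin(np.abs(drift - p.drift_center)))
            assert m.intensity[r, c] == pytest.approx(
                p.amplitude_by_class["EVOO"], abs=1e-10)
        # catalogue apexes are still dominated by their own amplitude
        cfg_full = clean_config()
        m2, _ = generate_sample(cfg_full, "EVOO", np.random.default_rng(0))
        for p in cfg_full.resolved_peaks():
            r = int(np.argmin(np.abs(ret - (cfg_full.injection_s
                                            + p.ret_center))))
            c = int(np.argmin(np.abs(drift - p.drift_center)))
            assert m2.intensity[r, c] == pytest.approx(
                p.amplitude_by_class["EVOO"], rel=1e-2)

    def test_fixed_jitter_moves_rip_apex_multiplicatively(self):
        cfg = clean_config(rip_jitter_sd=0.03)
        sd = cfg.rip_jitter_sd
        m, gt = generate_sample(cfg, "VOO", FixedJitterRng(0.02 / sd))
        assert gt.true_axis_factor == pytest.approx(1.02)
        row = np.argmin(np.abs(m.retention_time - 100.0))
        loc = ims.detect_rip(m.intensity[row], m.drift_time, (4.0, 9.0))
        step = m.drift_time[1] - m.drift_time[0]
        assert abs(loc.t_rip - 1.02 * 6.488) < step

    def test_peak_integral_matches_closed_form(self):
        peak = PeakSpec(100.0, 8.0, 9.0, 0.2, {c: 2.5 for c in
                                               ("EVOO", "VOO", "LVOO")})
        cfg = clean_config(peaks=(peak,), rip_amplitude=0.0)
        m, _ = generate_sample(cfg, "EVOO", np.random.default_rng(0))
        dret = np.diff(cfg.retention_axis()).mean()
        ddrift = np.diff(cfg.drift_axis()).mean()
        expected = 2.5 * 2 * np.pi * 8.0 * 0.2 / (dret * ddrift)
        assert m.intensity.sum() == pytest.approx(expected, rel=0.02)

    def test_rip_gated_by_injection_and_depleted_by_analytes(self):
        cfg = clean_config(depletion_coef=0.5)
        m, _ = generate_sample(cfg, "EVOO", np.random.default_rng(0))
        drift = cfg.drift_axis()
        rip_col = int(np.argmin(np.abs(drift - cfg.rip_t)))
        pre = m.retention_time < cfg.injection_s
        # only far analyte tails remain before injection — no RIP signal
        assert np.all(m.intensity[pre, rip_col] < 1e-6)
        post = m.intensity[~pre, rip_col]
        col_gain = np.exp(-((drift[rip_col] - cfg.rip_t) ** 2)
                          / (2 * cfg.rip_sigma**2))
        assert post.max() > 0.9 * cfg.rip_amplitude * col_gain
        # at the strongest-eluting row the normalised analyte signal is 1,
        # so the RIP is depleted by exactly the depletion coefficient
        assert post.min() == pytest.approx(
            (1 - cfg.depletion_coef) * cfg.rip_amplitude * col_gain, abs=1e-9)

    def test_unknown_class_rejected(self):
        with pytest.raises(ParameterError):
            generate_sample(clean_config(), "OLIVE", np.random.default_rng(0))

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ParameterError):
            clean_config(rip_jitter_sd=0.2).validate()


class TestGenerateDataset:
    def test_class_counts_honoured(self):
        cfg = clean_config(n_per_class=(3, 2, 1))
        ds, gts = generate_dataset(cfg)
        assert len(ds) == 6
        labels = [m.label for m in ds.maps]
        assert labels.count("EVOO") == 3
        assert labels.count("VOO") == 2
        assert labels.count("LVOO") == 1
        assert len(gts) == 6

    def test_seed_reproducibility(self):
        cfg = SynthConfig(n_ret=12, n_drift=100, n_per_class=(2, 2, 2),
                          seed=99)
        ds1, gt1 = generate_dataset(cfg)
        ds2, gt2 = generate_dataset(cfg)
        for a, b in zip(ds1.maps, ds2.maps):
            np.testing.assert_array_equal(a.intensity, b.intensity)
            np.testing.assert_array_equal(a.drift_time, b.drift_time)
        assert [g.true_axis_factor for g in gt1] == \
            [g.true_axis_factor for g in gt2]


class TestGroundTruth:
    def test_informative_mask_nonempty_iff_class_effects(self):
        cfg = clean_config()
        _, gt = generate_sample(cfg, "EVOO", np.random.default_rng(0))
        assert gt.informative_mask.any()
        assert gt.informative_mask.shape == (cfg.n_ret, cfg.n_drift)
        _, gt_null = generate_sample(equalized(cfg), "EVOO",
                                     np.random.default_rng(0))
        assert not gt_null.informative_mask.any()

    def test_default_catalogue_has_three_informative_peaks(self):
        peaks = default_peaks()
        assert sum(p.is_informative() for p in peaks) == 3
        assert len(peaks) == 12

    def test_baseline_truth_matches_generated_surface(self):
        cfg = clean_config(baseline_amp=2.0, rip_amplitude=0.0,
                           peaks=tuple())
        m, gt = generate_sample(cfg, "EVOO", np.random.default_rng(4))
        np.testing.assert_allclose(m.intensity, gt.true_baseline, atol=1e-12)
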