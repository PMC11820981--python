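"""Synthetic MCC-IMS e-nose maps with ground truth.

The generator emulates the structure of positive-mode MCC-IMS measurements
so every pipeline stage can be exercised against a known truth:

* a dominant reactant-ion peak (RIP) column near 6.488 ms drift time that
  switches on at the injection point and is depleted in rows where analytes
  elute (charge transfer from the reactant ions to the analytes);
* class-dependent 2D Gaussian analyte peaks placed at fixed positions in
  nominal (instrument-reference) coordinates, with amplitudes that may
  differ between sample classes;
* a smooth per-sample background surface — a RIP-tail-like decay plus broad
  humps along drift, slowly modulated along retention — with random
  coefficients, mimicking slow baseline fluctuations;
* additive white Gaussian noise;
* a per-sample multiplicative drift-axis factor ``g ~ N(1, rip_jitter_sd)``
  (the exact distortion the RIP-anchored correction ``k_c = t_ref/t_rip``
  inverts, so alignment recovery is sharply identifiable) and a per-sample
  injection-time offset that shifts all elution in retention.

Each sample carries a :class:`GroundTruth` record with the drift factor,
the retention offset, the exact baseline surface and the boolean footprint
of class-informative peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .io import IMSDataset, IMSMap

__all__ = [
    "PeakSpec",
    "SynthConfig",
    "GroundTruth",
    "default_peaks",
    "generate_sample",
    "generate_dataset",
]

CLASSES_DEFAULT = ("EVOO", "VOO", "LVOO")


@dataclass(frozen=True)
class PeakSpec:
    """One 2D Gaussian analyte peak.

    ``ret_center`` is relative to the injection point (s); amplitudes are
    keyed by class name — unequal amplitudes make the peak class-informative.
    """

    ret_center: float
    ret_sigma: float
    drift_center: float
    drift_sigma: float
    amplitude_by_class: dict

    def is_informative(self) -> bool:
        amps = list(self.amplitude_by_class.values())
        return len(set(amps)) > 1


def default_peaks(classes=CLASSES_DEFAULT) -> list[PeakSpec]:
    """Default catalogue: 12 analyte peaks, 3 of them class-informative.

    Positions span the usable map (retention 15–190 s after injection,
    drift 7.1–12.6 ms, clear of the RIP); widths follow typical MCC-IMS
    peak extents (a few seconds by ~0.1 ms).  The three informative peaks
    have amplitudes that rank the classes differently, so no single feature
    separates all three on its own.
    """
    c0, c1, c2 = classes
    flat = [
        # (ret_center, ret_sigma, drift_center, drift_sigma, amplitude)
        (15.0, 5.0, 7.10, 0.10, 1.8),
        (28.0, 6.0, 8.45, 0.12, 1.2),
        (45.0, 7.0, 7.80, 0.10, 2.2),
        (60.0, 6.0, 10.30, 0.14, 0.9),
        (80.0, 8.0, 9.10, 0.12, 1.5),
        (95.0, 7.0, 11.40, 0.15, 1.1),
        (120.0, 9.0, 8.10, 0.11, 1.7),
        (150.0, 10.0, 9.80, 0.13, 1.0),
        (190.0, 12.0, 12.60, 0.16, 0.8),
    ]
    peaks = [
        PeakSpec(r, rs, d, ds, {c0: a, c1: a, c2: a})
        for (r, rs, d, ds, a) in flat
    ]
    peaks += [
        PeakSpec(35.0, 6.0, 9.60, 0.12,
                 {c0: 1.5, c1: 1.15, c2: 0.85}),
        PeakSpec(70.0, 7.0, 7.45, 0.10,
                 {c0: 0.8, c1: 1.25, c2: 1.0}),
        PeakSpec(105.0, 8.0, 10.90, 0.14,
                 {c0: 1.0, c1: 0.8, c2: 1.25}),
    ]
    return peaks


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings (defaults emulate the study design at desk scale).

    The grid defaults to 200 retention rows by 600 drift points — a reduced
    version of the instrument's 1300 x 3000 raster with the same axis spans
    — and three balanced classes of 60 samples each.  ``rip_jitter_sd`` is
    the relative s.d. of the multiplicative drift-axis factor;
    ``ret_offset_sd`` the s.d. (s) of the injection-time offset;
    ``depletion_coef`` scales how strongly eluting analytes deplete the RIP.
    """

    n_ret: int = 200
    n_drift: int = 600
    drift_span: tuple[float, float] = (4.0, 14.0)
    ret_span: tuple[float, float] = (0.0, 240.0)
    rip_t: float = 6.488
    rip_sigma: float = 0.08
    rip_amplitude: float = 10.0
    rip_jitter_sd: float = 0.01
    injection_s: float = 20.0
    ret_offset_sd: float = 2.0
    peaks: tuple[PeakSpec, ...] | None = None
    baseline_amp: float = 2.0
    baseline_smoothness: float = 0.25
    noise_sd: float = 0.08
    depletion_coef: float = 0.3
    classes: tuple[str, ...] = CLASSES_DEFAULT
    n_per_class: tuple[int, ...] = (60, 60, 60)
    seed: int = 0

    def validate(self) -> None:
        if self.n_ret < 2 or self.n_drift < 4:
            raise ParameterError("grid too small")
        if self.rip_amplitude < 0 or self.noise_sd < 0 or self.baseline_amp < 0:
            raise ParameterError("amplitudes must be non-negative")
        if not 0.0 <= self.depletion_coef <= 1.0:
            raise ParameterError("depletion_coef must lie in [0, 1]")
        if self.rip_jitter_sd >= 0.05:
            raise ParameterError(
                "rip_jitter_sd must stay below 0.05 to keep the RIP inside "
                "the detection window"
            )
        if len(self.classes) != len(self.n_per_class):
            raise ParameterError("classes and n_per_class lengths differ")
        for p in self.resolved_peaks():
            if p.ret_sigma <= 0 or p.drift_sigma <= 0:
                raise ParameterError("peak sigmas must be positive")

    def resolved_peaks(self) -> list[PeakSpec]:
        if self.peaks is None:
            return default_peaks(self.classes)
        return list(self.peaks)

    def drift_axis(self) -> np.ndarray:
        return np.linspace(*self.drift_span, self.n_drift)

    def retention_axis(self) -> np.ndarray:
        return np.linspace(*self.ret_span, self.n_ret)


@dataclass
class GroundTruth:
    """Per-sample truth channel for recovery tests."""

    true_axis_factor: float
    true_ret_offset: float
    true_baseline: np.ndarray
    informative_mask: np.ndarray
    class_label: str


def _informative_mask(config: SynthConfig, n_sigma: float = 2.0) -> np.ndarray:
    """Footprint of class-informative peaks on the aligned grid (retention
    measured from the injection point)."""
    drift = config.drift_axis()
    ret = config.retention_axis() - config.injection_s
    mask = np.zeros((config.n_ret, config.n_drift), dtype=bool)
    for p in config.resolved_peaks():
        if not p.is_informative():
            continue
        in_ret = np.abs(ret - p.ret_center) <= n_sigma * p.ret_sigma
        in_drift = np.abs(drift - p.drift_center) <= n_sigma * p.drift_sigma
        mask |= np.outer(in_ret, in_drift)
    return mask


def _baseline_surface(config: SynthConfig, rng: np.random.Generator,
                      drift: np.ndarray, ret: np.ndarray) -> np.ndarray:
    """Smooth random background: RIP-tail-like decay plus a broad hump in
    drift, slowly modulated along retention.  Coefficients are drawn per
    sample so the baseline is a nuisance that varies between measurements.
    """
    if config.baseline_amp == 0.0:
        return np.zeros((ret.size, drift.size))
    u = (drift - drift[0]) / (drift[-1] - drift[0])
    v = (ret - ret[0]) / max(ret[-1] - ret[0], 1.0)
    tau = config.baseline_smoothness
    c = rng.uniform(0.3, 1.0, size=2)
    base = c[0] * 0.4 + c[1] * np.exp(-u / tau)
    a = rng.uniform(-1.0, 1.0, size=2)
    modulation = 1.0 + 0.4 * (a[0] * (v - 0.5) + a[1] * (v - 0.5) ** 2)
    surface = np.outer(modulation, base)
    # broad humps at random drift positions with their own slow retention
    # modulation: each sample's background points in a fresh direction of
    # feature space, so it cannot be spanned by a small latent basis
    for _ in range(3):
        center = rng.uniform(0.0, 1.0)
        width = rng.uniform(1.0, 2.0) * tau
        amp = rng.uniform(0.2, 0.8)
        bump = np.exp(-((u - center) ** 2) / (2 * width**2))
        b = rng.uniform(-1.0, 1.0, size=2)
        mod = 1.0 + 0.5 * (b[0] * (v - 0.5) + b[1] * (v - 0.5) ** 2)
        surface += amp * np.outer(mod, bump)
    return config.baseline_amp * surface


def generate_sample(config: SynthConfig, class_label: str,
                    rng: np.random.Generator) -> tuple[IMSMap, GroundTruth]:
    """Draw one synthetic sample of the given class.

    The intensity model (in nominal coordinates) is
    ``analyte peaks + gated/depleted RIP column + baseline + noise``; the
    returned map carries the jittered drift axis ``g * nominal`` while the
    retention axis is the shared instrument clock, with the injection time
    (and hence all elution) shifted by the sample's retention offset.
    """
    config.validate()
    if class_label not in config.classes:
        raise ParameterError(
            f"unknown class {class_label!r}; expected one of {config.classes}"
        )
    drift = config.drift_axis()
    ret = config.retention_axis()
    g = 1.0 + (rng.normal(0.0, config.rip_jitter_sd)
               if config.rip_jitter_sd > 0 else 0.0)
    offset = (rng.normal(0.0, config.ret_offset_sd)
              if config.ret_offset_sd > 0 else 0.0)
    t_inj = config.injection_s + offset

    analyte = np.zeros((config.n_ret, config.n_drift))
    for p in config.resolved_peaks():
        amp = p.amplitude_by_class.get(class_label, 0.0)
        if amp == 0.0:
            continue
        rp = np.exp(-((ret - (t_inj + p.ret_center)) ** 2)
                    / (2 * p.ret_sigma**2))
        dp = np.exp(-((drift - p.drift_center) ** 2) / (2 * p.drift_sigma**2))
        analyte += amp * np.outer(rp, dp)

    row_signal = analyte.sum(axis=1)
    peak = row_signal.max()
    s_r = row_signal / peak if peak > 0 else row_signal
    rip_row_amp = config.rip_amplitude * np.clip(
        1.0 - config.depletion_coef * s_r, 0.0, None)
    rip_row_amp[ret < t_inj] = 0.0  # no reactant ions before injection
    rip_col = np.exp(-((drift - config.rip_t) ** 2) / (2 * config.rip_sigma**2))
    rip = np.outer(rip_row_amp, rip_col)

    baseline = _baseline_surface(config, rng, drift, ret)
    noise = (rng.normal(0.0, config.noise_sd, size=analyte.shape)
             if config.noise_sd > 0 else 0.0)

    m = IMSMap(
        intensity=analyte + rip + baseline + noise,
        drift_time=g * drift,
        retention_time=ret,
        label=class_label,
    )
    gt = GroundTruth(
        true_axis_factor=g,
        true_ret_offset=offset,
        true_baseline=baseline,
        informative_mask=_informative_mask(config),
        class_label=class_label,
    )
    return m, gt


def generate_dataset(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[IMSDataset, list[GroundTruth]]:
    """Draw a full dataset with the configured per-class sample counts.

    Reproducible from ``config.seed`` when no generator is passed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    maps, truths = [], []
    i = 0
    for cls, n in zip(config.classes, config.n_per_class):
        for _ in range(n):
            m, gt = generate_sample(config, cls, rng)
            maps.append(m.replace(sample_id=f"{cls}_{i:04d}"))
            truths.append(gt)
            i += 1
    ds = IMSDataset(maps=maps, class_names=list(config.classes))
    return ds, truths


def equalized(config: SynthConfig) -> SynthConfig:
    """A copy of the configuration with all class differences removed
    (every peak amplitude set to its across-class mean) — a null dataset
    whose classification accuracy should sit at chance level."""
    peaks = []
    for p in config.resolved_peaks():
        mean_amp = float(np.mean(list(p.amplitude_by_class.values())))
        peaks.append(replace(p, amplitude_by_class={
            c: mean_amp for c in config.classes}))
    return replace(config, peaks=tuple(peaks))
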