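"""RIP-anchored drift-time alignment and retention-time alignment.

Temperature and pressure variations inside the drift tube rescale every
drift spectrum multiplicatively.  Because the reactant-ion peak (RIP) of a
positive-mode IMS always corresponds to the same ion species, its apparent
drift time tracks this rescaling, so each spectrum can be corrected by the
factor

    k_c = t_ref / t_RIP

computed per spectrum, where ``t_RIP`` is the detected RIP apex and
``t_ref`` a fixed reference position (default 6.488 ms).  Multiplying the
drift axis by ``k_c`` and linearly re-interpolating onto the reference grid
brings all analyte peaks of the same species to the same column.  Retention
alignment is a translation of the retention axis to the injection point,
followed by re-gridding at the dataset level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InjectionDetectionError, ParameterError, RIPDetectionError
from .io import IMSDataset, IMSMap

__all__ = [
    "RIPLocation",
    "AlignParams",
    "detect_rip",
    "drift_correction_factor",
    "estimate_drift_factors",
    "align_drift",
    "detect_injection",
    "align_retention",
    "resample_retention",
    "align_dataset",
]

T_REF_DEFAULT = 6.488  # ms


@dataclass
class RIPLocation:
    """Detected reactant-ion peak: integer apex index, sub-sample refined
    drift time (ms) and the apex intensity."""

    index: int
    t_rip: float
    apex_intensity: float


@dataclass
class AlignParams:
    """Alignment settings.

    ``search_window`` bounds the RIP search on the drift axis (ms);
    ``out_of_range_fill`` is the value assigned to grid points that fall
    outside the rescaled axis (zero = post-baseline background);
    ``fallback_median`` applies the sample-median correction factor to
    spectra whose RIP cannot be detected (heavily depleted or pre-injection
    rows); ``rip_min_frac`` routes spectra whose apex falls below this
    fraction of the map's median apex to the fallback as well;
    ``reference_grid`` fixes a common output drift grid (defaults to the
    map's own axis).
    """

    t_ref: float = T_REF_DEFAULT
    search_window: tuple[float, float] = (4.0, 9.0)
    interp: str = "linear"
    out_of_range_fill: float = 0.0
    fallback_median: bool = True
    rip_min_frac: float = 0.1
    reference_grid: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        lo, hi = self.search_window
        if not lo < hi:
            raise ParameterError("search_window must be an increasing interval")
        if not lo <= self.t_ref <= hi:
            raise ParameterError("t_ref must lie inside the search window")
        if self.interp != "linear":
            raise ParameterError(f"unsupported interpolation {self.interp!r}")


def detect_rip(spectrum: np.ndarray, drift_time: np.ndarray,
               window: tuple[float, float] = (4.0, 9.0)) -> RIPLocation:
    """Locate the RIP apex inside a drift-time window.

    The apex is the intensity argmax in the window, refined by a three-point
    parabolic fit when it is not on the window edge.  A flat or non-positive
    window raises :class:`RIPDetectionError`.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    drift_time = np.asarray(drift_time, dtype=float)
    lo, hi = window
    sel = np.flatnonzero((drift_time >= lo) & (drift_time <= hi))
    if sel.size < 3:
        raise RIPDetectionError("search window contains fewer than 3 samples")
    seg = spectrum[sel]
    if np.ptp(seg) == 0.0 or np.max(seg) <= 0.0:
        raise RIPDetectionError("no peak in search window (flat or non-positive)")
    k = int(np.argmax(seg))
    idx = int(sel[k])
    apex = float(seg[k])
    t_rip = float(drift_time[idx])
    if 0 < k < seg.size - 1:
        y0, y1, y2 = seg[k - 1], seg[k], seg[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0.0:  # strict local maximum
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step = 0.5 * (drift_time[idx + 1] - drift_time[idx - 1])
            t_rip += delta * step
    else:
        warnings.warn("RIP apex on window edge; skipping parabolic refinement",
                      stacklevel=2)
    return RIPLocation(index=idx, t_rip=t_rip, apex_intensity=apex)


def drift_correction_factor(t_rip: float, t_ref: float = T_REF_DEFAULT) -> float:
    """Multiplicative drift correction ``k_c = t_ref / t_rip``."""
    if t_rip <= 0:
        raise ParameterError("t_rip must be positive")
    return t_ref / t_rip


def estimate_drift_factors(m: IMSMap,
                           params: AlignParams = AlignParams()) -> np.ndarray:
    """Per-spectrum correction factors for a map.

    Spectra with no detectable RIP (or an apex weaker than ``rip_min_frac``
    of the map's median apex) receive the median factor of the remaining
    spectra when ``fallback_median`` is set, else an error naming the
    retention row is raised.
    """
    params.validate()
    n = m.n_ret
    kc = np.full(n, np.nan)
    apex = np.full(n, np.nan)
    with warnings.catch_warnings():
        # weak/edge apexes are routed to the median fallback below
        warnings.simplefilter("ignore", category=UserWarning)
        for r in range(n):
            try:
                loc = detect_rip(m.intensity[r], m.drift_time,
                                 params.search_window)
            except RIPDetectionError:
                continue
            kc[r] = drift_correction_factor(loc.t_rip, params.t_ref)
            apex[r] = loc.apex_intensity
    ok = np.isfinite(kc)
    if ok.any():
        med_apex = np.median(apex[ok])
        weak = ok & (apex < params.rip_min_frac * med_apex)
        kc[weak] = np.nan
        ok = np.isfinite(kc)
    if not ok.any():
        raise RIPDetectionError("RIP detection failed on every spectrum")
    if not ok.all():
        if not params.fallback_median:
            bad = int(np.flatnonzero(~ok)[0])
            raise RIPDetectionError(
                f"RIP detection failed at retention row {bad} "
                f"(t = {m.retention_time[bad]:g} s)"
            )
        kc[~ok] = np.median(kc[ok])
    return kc


def align_drift(m: IMSMap, params: AlignParams = AlignParams()) -> IMSMap:
    """Align every drift spectrum of a map to the reference RIP position.

    Each spectrum's axis is rescaled by its own ``k_c`` and the intensities
    are linearly re-interpolated onto the output grid
    (``params.reference_grid`` or the map's own axis); points outside the
    rescaled span get ``out_of_range_fill``.
    """
    kc = estimate_drift_factors(m, params)
    target = (np.asarray(params.reference_grid, dtype=float)
              if params.reference_grid is not None else m.drift_time)
    out = np.empty((m.n_ret, target.size))
    for r in range(m.n_ret):
        corrected = kc[r] * m.drift_time
        out[r] = np.interp(target, corrected, m.intensity[r],
                           left=params.out_of_range_fill,
                           right=params.out_of_range_fill)
    return m.replace(intensity=out, drift_time=target.copy())


def detect_injection(m: IMSMap,
                     params: AlignParams = AlignParams()) -> float:
    """Injection time: earliest retention row whose RIP apex reaches 50% of
    the map's median RIP apex (before injection the drift tube carries no
    reactant-ion signal)."""
    apex = np.zeros(m.n_ret)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        for r in range(m.n_ret):
            try:
                loc = detect_rip(m.intensity[r], m.drift_time,
                                 params.search_window)
            except RIPDetectionError:
                continue
            apex[r] = loc.apex_intensity
    med = np.median(apex)
    if med <= 0:
        raise InjectionDetectionError(
            "no RIP signal found; pass an explicit injection_time"
        )
    hits = np.flatnonzero(apex >= 0.5 * med)
    if hits.size == 0:
        raise InjectionDetectionError(
            "no retention row reaches half the median RIP apex; "
            "pass an explicit injection_time"
        )
    return float(m.retention_time[hits[0]])


def align_retention(m: IMSMap, injection_time: float | str = "auto",
                    params: AlignParams = AlignParams()) -> IMSMap:
    """Translate the retention axis so the injection point sits at 0 s.

    ``injection_time`` may be an explicit time in seconds or ``"auto"`` to
    detect the point where the RIP first appears.  Intensities are untouched.
    """
    if injection_time == "auto":
        injection_time = detect_injection(m, params)
    t0 = float(injection_time)
    return m.replace(retention_time=m.retention_time - t0)


def resample_retention(m: IMSMap, ref_axis: np.ndarray,
                       fill: float = 0.0) -> IMSMap:
    """Linearly re-grid a map onto a common retention axis (per column)."""
    ref_axis = np.asarray(ref_axis, dtype=float)
    if np.array_equal(ref_axis, m.retention_time):
        return m.replace()
    from scipy.interpolate import interp1d

    f = interp1d(m.retention_time, m.intensity, axis=0, kind="linear",
                 bounds_error=False, fill_value=fill, assume_sorted=True)
    return m.replace(intensity=f(ref_axis), retention_time=ref_axis.copy())


def align_dataset(ds: IMSDataset, params: AlignParams = AlignParams(),
                  injection: float | str = "auto",
                  drift: bool = True, retention: bool = True) -> IMSDataset:
    """Align a whole dataset onto common drift and retention grids.

    Drift: the common grid is the first map's median-``k_c``-corrected axis
    (unless ``params.reference_grid`` is given); every spectrum is aligned
    onto it.  Retention: each map is shifted to its injection point, then
    re-gridded onto the first map's shifted axis.
    """
    maps = list(ds.maps)
    if drift:
        if params.reference_grid is None:
            kc0 = estimate_drift_factors(maps[0], params)
            ref_grid = float(np.median(kc0)) * maps[0].drift_time
        else:
            ref_grid = np.asarray(params.reference_grid, dtype=float)
        p = AlignParams(**{**params.__dict__, "reference_grid": ref_grid})
        maps = [align_drift(m, p) for m in maps]
    if retention:
        maps = [align_retention(m, injection, params) for m in maps]
        ref_axis = maps[0].retention_time
        maps = [resample_retention(m, ref_axis, fill=params.out_of_range_fill)
                for m in maps]
    return IMSDataset(maps=maps, class_names=list(ds.class_names))
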