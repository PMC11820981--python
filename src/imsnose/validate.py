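"""Double cross-validation and the preprocessing-ablation experiment.

Model complexity (the number of PLS latent variables, LV) must be chosen
without ever looking at the samples used to report accuracy.  The double
(nested) scheme implemented here repeats, for a configurable number of
rounds: (i) a stratified random split into a training portion and an
untouched test portion; (ii) stratified k-fold cross-validation *within
the training portion* to score every candidate LV count; (iii) selection
of the LV maximising mean internal accuracy (ties break to the smallest
LV, favouring parsimony); (iv) a refit on the full training portion at the
chosen LV and a single evaluation on the test portion.  Centring is always
computed from the data a model is fitted on, so the test samples never
influence fitting or selection.  Defaults follow a 180-sample, three-class
design: 126 training / 54 test, 5 folds, 10 repeats.

The ablation experiment reruns the whole pipeline with one preprocessing
stage removed at a time and reports the internal-accuracy-versus-LV curve
for each variant, plus the "plateau LV" — the smallest LV whose accuracy
comes within one accuracy point of the curve maximum — which measures how
parsimonious a model the data quality permits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, align_dataset
from .errors import ParameterError
from .io import FeatureMatrix, IMSDataset, flatten_dataset
from .plsda import PLSModel, _yhat_from_scores, encode_labels, fit_pls, transform
from .preprocess import AsLSParams, SGParams, correct_map

__all__ = [
    "CVConfig",
    "CVResult",
    "AblationSpec",
    "AblationResult",
    "STAGES",
    "split_train_test",
    "kfold_indices",
    "double_cv",
    "run_pipeline",
    "ablation_curves",
    "plateau_lv",
]

STAGES = ("denoise", "baseline", "drift_align", "retention_align")


@dataclass(frozen=True)
class CVConfig:
    """Double cross-validation settings."""

    test_fraction: float = 54 / 180
    k_folds: int = 5
    repeats: int = 10
    lv_grid: tuple[int, ...] = tuple(range(1, 21))
    seed: int = 0
    stratified: bool = True

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ParameterError("test_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ParameterError("k_folds must be at least 2")
        if not self.lv_grid:
            raise ParameterError("lv_grid must be non-empty")
        if any(a < 1 for a in self.lv_grid):
            raise ParameterError("lv_grid entries must be positive")


@dataclass
class CVResult:
    """Outcome of one double-CV run.

    ``internal_acc`` is repeats x |lv_grid| (mean fold accuracy; NaN where
    an LV exceeded the attainable rank); ``models`` holds the per-repeat
    refit models used for external validation (and VIP averaging).
    """

    internal_acc: np.ndarray
    chosen_lv: np.ndarray
    external_acc: np.ndarray
    summary: dict
    lv_grid: tuple[int, ...]
    models: list[PLSModel] = field(default_factory=list, repr=False)


@dataclass(frozen=True)
class AblationSpec:
    """One pipeline variant: the set of preprocessing stages to omit."""

    omit: frozenset = frozenset()
    label: str = "full"

    def __post_init__(self) -> None:
        unknown = set(self.omit) - set(STAGES)
        if unknown:
            raise ParameterError(f"unknown stages {sorted(unknown)}")


@dataclass
class AblationResult:
    """Per-variant internal accuracy curves and plateau statistics."""

    spec: AblationSpec
    lv_grid: tuple[int, ...]
    internal_acc: np.ndarray          # repeats x |lv_grid|
    plateau_lv: np.ndarray            # per repeat
    plateau_acc: np.ndarray           # per repeat (curve maximum)


def _class_indices(labels) -> dict:
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return groups


def split_train_test(labels, config: CVConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random (optionally stratified) train/test split.

    Stratified mode draws ``round(test_fraction * n_c)`` test samples per
    class, which for the default 3 x 60 design gives exactly 126 training
    and 54 test samples with 18 test samples per class.
    """
    config.validate()
    labels = list(labels)
    n = len(labels)
    if not config.stratified:
        perm = rng.permutation(n)
        n_test = int(round(config.test_fraction * n))
        if not 1 <= n_test < n:
            raise ParameterError("test_fraction leaves an empty partition")
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    train, test = [], []
    for lab, idx in _class_indices(labels).items():
        idx = np.asarray(idx)
        n_test = int(round(config.test_fraction * idx.size))
        if n_test < 1 or n_test >= idx.size:
            raise ParameterError(
                f"class {lab!r} too small to stratify at "
                f"test_fraction={config.test_fraction}"
            )
        perm = rng.permutation(idx.size)
        test.extend(idx[perm[:n_test]])
        train.extend(idx[perm[n_test:]])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def kfold_indices(n: int, k: int, labels=None,
                  rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Partition ``range(n)`` into ``k`` folds of near-equal size.

    With labels given, folds are stratified: each class's shuffled indices
    are dealt round-robin with a running fold counter, so both overall and
    per-class fold sizes differ by at most one.
    """
    if k > n:
        raise ParameterError(f"k = {k} exceeds n = {n}")
    if rng is None:
        rng = np.random.default_rng()
    folds: list[list[int]] = [[] for _ in range(k)]
    if labels is None:
        order = rng.permutation(n)
    else:
        labels = list(labels)
        if len(labels) != n:
            raise ParameterError("labels length must equal n")
        order = []
        for idx in _class_indices(labels).values():
            idx = np.asarray(idx)
            order.extend(idx[rng.permutation(idx.size)])
        order = np.asarray(order)
    for j, sample in enumerate(order):
        folds[j % k].append(int(sample))
    return [np.sort(np.asarray(f)) for f in folds]


def _accuracy(true_labels, pred_labels) -> float:
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    return float(np.mean(true_labels == pred_labels))


def _internal_curve(X, y, class_names, train_idx, config: CVConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Mean fold accuracy per LV-grid entry from k-fold CV on ``train_idx``."""
    lv_grid = config.lv_grid
    folds = kfold_indices(train_idx.size, config.k_folds,
                          labels=[y[i] for i in train_idx]
                          if config.stratified else None,
                          rng=rng)
    acc = np.zeros((config.k_folds, len(lv_grid)))
    acc[:] = np.nan
    warned = False
    for f, fold in enumerate(folds):
        val_idx = train_idx[fold]
        fit_mask = np.ones(train_idx.size, dtype=bool)
        fit_mask[fold] = False
        fit_idx = train_idx[fit_mask]
        a_cap = min(max(lv_grid), fit_idx.size - 1, X.shape[1])
        if a_cap < max(lv_grid) and not warned:
            warnings.warn(
                f"LV grid truncated to {a_cap} (training-fold rank limit)",
                stacklevel=2,
            )
            warned = True
        enc = encode_labels([y[i] for i in fit_idx], class_names)
        model = fit_pls(X[fit_idx], enc.Y, a_cap, class_names=class_names)
        T_val = transform(model, X[val_idx])
        y_val = np.asarray([y[i] for i in val_idx], dtype=object)
        for j, a in enumerate(lv_grid):
            if a > model.A:
                continue
            yhat = _yhat_from_scores(model, T_val, a)
            pred = np.array([class_names[c] for c in np.argmax(yhat, axis=1)],
                            dtype=object)
            acc[f, j] = _accuracy(y_val, pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(acc, axis=0)


def _choose_lv(curve: np.ndarray, lv_grid) -> int:
    """LV maximising internal accuracy; ties break to the smallest LV
    (``argmax`` returns the first maximum and the grid is increasing)."""
    valid = np.isfinite(curve)
    if not valid.any():
        raise ParameterError("no LV in the grid was attainable")
    masked = np.where(valid, curve, -np.inf)
    return int(lv_grid[int(np.argmax(masked))])


def double_cv(X: np.ndarray, y, config: CVConfig = CVConfig(),
              class_names=None, keep_models: bool = True) -> CVResult:
    """Run the repeated nested train/test + k-fold LV-selection scheme.

    Returns per-repeat internal accuracy curves, the chosen LV, the
    external (test-set) accuracy and a mean +/- s.d. summary.  All
    randomness derives from ``config.seed`` via per-repeat substreams, so
    identical configurations reproduce identical results.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ParameterError("X contains non-finite values")
    y = np.asarray(y, dtype=object)
    if class_names is None:
        class_names = sorted(set(y))
    class_names = list(class_names)

    repeats = config.repeats
    internal = np.full((repeats, len(config.lv_grid)), np.nan)
    chosen = np.zeros(repeats, dtype=int)
    external = np.zeros(repeats)
    models: list[PLSModel] = []
    streams = np.random.SeedSequence(config.seed).spawn(repeats)
    for r in range(repeats):
        rng = np.random.default_rng(streams[r])
        train_idx, test_idx = split_train_test(y, config, rng)
        internal[r] = _internal_curve(X, y, class_names, train_idx, config, rng)
        chosen[r] = _choose_lv(internal[r], config.lv_grid)
        enc = encode_labels([y[i] for i in train_idx], class_names)
        model = fit_pls(X[train_idx], enc.Y, chosen[r],
                        class_names=class_names)
        T_test = transform(model, X[test_idx])
        yhat = _yhat_from_scores(model, T_test, model.A)
        pred = np.array([class_names[c] for c in np.argmax(yhat, axis=1)],
                        dtype=object)
        external[r] = _accuracy([y[i] for i in test_idx], pred)
        if keep_models:
            models.append(model)
    summary = {
        "external_mean": float(np.mean(external)),
        "external_sd": float(np.std(external, ddof=1)) if repeats > 1 else 0.0,
        "chosen_lv": [int(a) for a in chosen],
    }
    return CVResult(internal_acc=internal, chosen_lv=chosen,
                    external_acc=external, summary=summary,
                    lv_grid=config.lv_grid, models=models)


def run_pipeline(ds: IMSDataset, omit=frozenset(),
                 sg: SGParams = SGParams(),
                 asls: AsLSParams = AsLSParams(),
                 align_params: AlignParams = AlignParams(),
                 injection="auto") -> IMSDataset:
    """Apply the preprocessing workflow, optionally omitting stages.

    Order: Savitzky–Golay denoising, AsLS baseline subtraction, RIP drift
    alignment, retention alignment.  When an alignment stage is omitted the
    maps are stacked by grid index (axes relabelled to the first map's), as
    an uncorrected analysis would do.
    """
    omit = frozenset(omit)
    unknown = omit - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages {sorted(unknown)}")
    maps = [
        correct_map(m,
                    sg if "denoise" not in omit else None,
                    asls if "baseline" not in omit else None)
        for m in ds.maps
    ]
    out = IMSDataset(maps=maps, class_names=list(ds.class_names))
    do_drift = "drift_align" not in omit
    do_ret = "retention_align" not in omit
    if do_drift or do_ret:
        out = align_dataset(out, align_params, injection=injection,
                            drift=do_drift, retention=do_ret)
    if not out.is_aligned():
        ref_d = out.maps[0].drift_time
        ref_r = out.maps[0].retention_time
        out = IMSDataset(
            maps=[m.replace(drift_time=ref_d.copy(),
                            retention_time=ref_r.copy()) for m in out.maps],
            class_names=list(out.class_names),
        )
    return out


def plateau_lv(curve: np.ndarray, lv_grid, tol: float = 0.01) -> int:
    """Smallest LV whose accuracy is within ``tol`` (one accuracy point by
    default) of the curve maximum."""
    curve = np.asarray(curve, dtype=float)
    valid = np.isfinite(curve)
    if not valid.any():
        raise ParameterError("empty accuracy curve")
    peak = np.nanmax(curve)
    ok = np.flatnonzero(valid & (curve >= peak - tol))
    return int(np.asarray(lv_grid)[ok[0]])


def ablation_curves(ds_raw: IMSDataset, specs, config: CVConfig = CVConfig(),
                    sg: SGParams = SGParams(),
                    asls: AsLSParams = AsLSParams(),
                    align_params: AlignParams = AlignParams(),
                    plateau_tol: float = 0.01) -> dict:
    """Internal accuracy-vs-LV curves for a set of pipeline variants.

    Each variant preprocesses the *raw* dataset with its stages omitted,
    then runs the repeated stratified split + internal k-fold scoring with
    the same seed, so splits are identical across variants and comparisons
    are paired.  Returns ``{spec.label: AblationResult}``.
    """
    config.validate()
    results: dict = {}
    for spec in specs:
        ds_p = run_pipeline(ds_raw, omit=spec.omit, sg=sg, asls=asls,
                            align_params=align_params)
        fm: FeatureMatrix = flatten_dataset(ds_p)
        y = fm.y
        class_names = list(ds_raw.class_names)
        internal = np.full((config.repeats, len(config.lv_grid)), np.nan)
        streams = np.random.SeedSequence(config.seed).spawn(config.repeats)
        for r in range(config.repeats):
            rng = np.random.default_rng(streams[r])
            train_idx, _ = split_train_test(y, config, rng)
            internal[r] = _internal_curve(fm.X, y, class_names, train_idx,
                                          config, rng)
        plat = np.array([plateau_lv(internal[r], config.lv_grid, plateau_tol)
                         for r in range(config.repeats)])
        peak = np.nanmax(internal, axis=1)
        results[spec.label] = AblationResult(
            spec=spec, lv_grid=config.lv_grid, internal_acc=internal,
            plateau_lv=plat, plateau_acc=peak,
        )
    return results
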