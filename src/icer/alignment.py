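"""Cross-sample alignment: global windows and per-sample correction models.

The RT alignment window is 1.5x the inter-quartile range of pooled
absolute RT deviations of shared peptide identities from their
cross-sample median; the m/z window is 1.0x the corresponding IQR of
absolute m/z deviations.  Quantiles use linear interpolation (type 7)
so the windows are reproducible.

Per sample, a random-forest regressor (100 trees, 4 candidate variables
per split, minimum terminal node size 100) maps (rt, mz, charge,
resolution) to the deviation of uncalibrated from calibrated m/z, and a
smoothing spline maps reference RT to the sample's expected RT
deviation.  Both fall back to constant medians when too few rows are
available.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error

from .io_formats import DetectedFeature

__all__ = [
    "AlignmentWindows",
    "MzCorrectionModel",
    "RtDeviationModel",
    "SampleCorrectionModels",
    "estimate_alignment_windows",
    "fit_mz_correction",
    "fit_rt_deviation",
    "predict_feature_windows",
]

MIN_FOREST_ROWS = 200  # below this, fall back to a median correction
MIN_RT_PAIRS = 10


@dataclass
class AlignmentWindows:
    rt_window: float | None = None
    mz_window: float | None = None
    user_min_rt: float | None = None
    user_min_mz: float | None = None
    user_fixed_rt: float | None = None
    user_fixed_mz: float | None = None

    DEFAULT_MIN_RT = 0.2  # minutes
    DEFAULT_MIN_MZ = 0.001  # Th

    def resolved(self) -> "AlignmentWindows":
        if self.rt_window is None or self.mz_window is None:
            raise ValueError("windows not yet estimated")
        if self.rt_window <= 0 or self.mz_window <= 0:
            raise ValueError("resolved windows must be positive")
        return self


class IdentityKeyError(ValueError):
    """No peptide identity is shared between samples."""


def _pooled_abs_deviations(
    features: dict[str, list[DetectedFeature]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-key absolute RT / calibrated-m/z deviations from the
    key's cross-sample median."""
    by_key: dict[tuple, list[tuple[float, float]]] = defaultdict(list)
    for feats in features.values():
        for f in feats:
            if f.identity_key is not None:
                by_key[f.identity_key].append((f.rt, f.mz_calibrated))
    rt_devs: list[float] = []
    mz_devs: list[float] = []
    for vals in by_key.values():
        if len(vals) < 2:
            continue
        rts = np.array([v[0] for v in vals])
        mzs = np.array([v[1] for v in vals])
        rt_devs.extend(np.abs(rts - np.median(rts)))
        mz_devs.extend(np.abs(mzs - np.median(mzs)))
    return np.asarray(rt_devs), np.asarray(mz_devs)


def _iqr(values: np.ndarray) -> float:
    # linear-interpolation (type-7) quantiles
    q75, q25 = np.percentile(values, [75.0, 25.0])
    return float(q75 - q25)


def estimate_alignment_windows(
    features: dict[str, list[DetectedFeature]],
    windows: AlignmentWindows | None = None,
) -> AlignmentWindows:
    """Resolve the RT and m/z alignment windows from cross-sample deviations.

    ``rt_window = 1.5 * IQR(|RT deviation|)``;
    ``mz_window = 1.0 * IQR(|m/z deviation|)``.  User floors raise windows
    that come out smaller; user fixed values short-circuit estimation.
    """
    w = windows or AlignmentWindows()
    min_rt = w.user_min_rt if w.user_min_rt is not None else AlignmentWindows.DEFAULT_MIN_RT
    min_mz = w.user_min_mz if w.user_min_mz is not None else AlignmentWindows.DEFAULT_MIN_MZ

    if w.user_fixed_rt is not None and w.user_fixed_mz is not None:
        return AlignmentWindows(
            rt_window=w.user_fixed_rt, mz_window=w.user_fixed_mz,
            user_min_rt=w.user_min_rt, user_min_mz=w.user_min_mz,
            user_fixed_rt=w.user_fixed_rt, user_fixed_mz=w.user_fixed_mz,
        )

    rt_devs, mz_devs = _pooled_abs_deviations(features)
    if rt_devs.size == 0 and (w.user_fixed_rt is None or w.user_fixed_mz is None):
        raise IdentityKeyError(
            "no peptide identity observed in >= 2 samples; "
            "set fixed RT and m/z windows explicitly"
        )

    rt_window = (w.user_fixed_rt if w.user_fixed_rt is not None
                 else max(1.5 * _iqr(rt_devs), min_rt))
    mz_window = (w.user_fixed_mz if w.user_fixed_mz is not None
                 else max(1.0 * _iqr(mz_devs), min_mz))
    return AlignmentWindows(
        rt_window=float(rt_window), mz_window=float(mz_window),
        user_min_rt=w.user_min_rt, user_min_mz=w.user_min_mz,
        user_fixed_rt=w.user_fixed_rt, user_fixed_mz=w.user_fixed_mz,
    )


# --------------------------------------------------------------------------
# m/z correction (random forest)
# --------------------------------------------------------------------------

@dataclass
class MzCorrectionModel:
    """Predicts (uncalibrated - calibrated) m/z for one sample.

    Adding the prediction to a reference (calibrated-scale) m/z gives the
    expected raw-scale location of the ion cloud in this sample.  The
    small-data fallback is a median relative (ppm-scale) correction, since
    mass errors scale with m/z.
    """

    forest: RandomForestRegressor | None
    fallback_ppm: float
    holdout_rmse: float
    is_fallback: bool
    n_train: int
    ppm_spline: object | None = None  # RT-dependent ppm term of the fallback
    rt_min: float = 0.0
    rt_max: float = 0.0

    def _fallback_ppm_at(self, rt: np.ndarray) -> np.ndarray:
        if self.ppm_spline is None:
            return np.full(rt.shape, self.fallback_ppm)
        return np.asarray(
            self.ppm_spline(np.clip(rt, self.rt_min, self.rt_max)), dtype=float
        )

    def predict(self, rt, mz, charge, resolution) -> np.ndarray:
        rt = np.atleast_1d(np.asarray(rt, dtype=float))
        mz = np.atleast_1d(np.asarray(mz, dtype=float))
        charge = np.broadcast_to(np.atleast_1d(np.asarray(charge, dtype=float)), rt.shape)
        resolution = np.broadcast_to(
            np.atleast_1d(np.asarray(resolution, dtype=float)), rt.shape
        )
        if self.forest is None:
            return self._fallback_ppm_at(rt) * 1e-6 * mz
        X = np.column_stack([rt, mz, charge, resolution])
        X = np.nan_to_num(X, nan=0.0)
        return self.forest.predict(X)


def _ppm_spline(rt: np.ndarray, ppm: np.ndarray):
    """GCV smoothing spline of the relative mass error against RT."""
    ok = np.isfinite(rt) & np.isfinite(ppm)
    rt, ppm = rt[ok], ppm[ok]
    if rt.size < MIN_RT_PAIRS:
        return None, 0.0, 0.0
    order = np.argsort(rt)
    x, y = rt[order], ppm[order]
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    if ux.size < 4:
        return None, 0.0, 0.0
    return make_smoothing_spline(ux, uy), float(ux[0]), float(ux[-1])


def fit_mz_correction(
    features: list[DetectedFeature], seed: int = 0
) -> MzCorrectionModel:
    """Fit the per-sample random-forest m/z correction with an 80/20 split."""
    rows = [f for f in features
            if np.isfinite(f.mz_uncalibrated) and np.isfinite(f.mz_calibrated)]
    y = np.array([f.mz_uncalibrated - f.mz_calibrated for f in rows])
    ppm = np.array([(f.mz_uncalibrated - f.mz_calibrated) / f.mz_calibrated * 1e6
                    for f in rows])
    if len(rows) < MIN_FOREST_ROWS:
        med_ppm = float(np.median(ppm)) if ppm.size else 0.0
        warnings.warn(
            f"only {len(rows)} features available; "
            "falling back to an RT-dependent ppm m/z correction"
        )
        spline, lo, hi = _ppm_spline(np.array([f.rt for f in rows]), ppm)
        return MzCorrectionModel(None, med_ppm, float("nan"), True, len(rows),
                                 ppm_spline=spline, rt_min=lo, rt_max=hi)

    X = np.column_stack([
        [f.rt for f in rows],
        [f.mz_calibrated for f in rows],
        [float(f.charge) for f in rows],
        [f.resolution for f in rows],
    ])
    X = np.nan_to_num(X, nan=0.0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    n_train = int(round(0.8 * len(rows)))
    train, test = order[:n_train], order[n_train:]

    forest = RandomForestRegressor(
        n_estimators=100,
        max_features=4,
        min_samples_leaf=100,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X[train], y[train])
    rmse = float(np.sqrt(mean_squared_error(y[test], forest.predict(X[test]))))
    return MzCorrectionModel(forest, float(np.median(ppm)), rmse, False, n_train)


# --------------------------------------------------------------------------
# RT deviation (smoothing spline with automatic smoothness)
# --------------------------------------------------------------------------

@dataclass
class RtDeviationModel:
    """Smooth map from reference RT to this sample's expected RT deviation.

    Evaluation outside the training range is clamped to the boundary value.
    """

    _spline: object | None
    rt_min: float
    rt_max: float
    fallback_median: float
    is_fallback: bool

    def predict(self, rt) -> np.ndarray:
        rt = np.atleast_1d(np.asarray(rt, dtype=float))
        if self._spline is None:
            return np.full(rt.shape, self.fallback_median)
        clamped = np.clip(rt, self.rt_min, self.rt_max)
        return np.asarray(self._spline(clamped), dtype=float)


def fit_rt_deviation(
    reference_rt: np.ndarray, observed_rt: np.ndarray
) -> RtDeviationModel:
    """Fit deviation = observed - reference as a smooth function of reference RT."""
    reference_rt = np.asarray(reference_rt, dtype=float)
    observed_rt = np.asarray(observed_rt, dtype=float)
    dev = observed_rt - reference_rt
    ok = np.isfinite(reference_rt) & np.isfinite(dev)
    reference_rt, dev = reference_rt[ok], dev[ok]

    if reference_rt.size < MIN_RT_PAIRS:
        med = float(np.median(dev)) if dev.size else 0.0
        return RtDeviationModel(None, 0.0, 0.0, med, True)

    # smoothing splines need strictly increasing x: average duplicates
    order = np.argsort(reference_rt)
    x, y = reference_rt[order], dev[order]
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    if ux.size < 4:
        med = float(np.median(dev))
        return RtDeviationModel(None, 0.0, 0.0, med, True)

    spline = make_smoothing_spline(ux, uy)  # GCV-selected smoothness
    return RtDeviationModel(
        spline, float(ux[0]), float(ux[-1]), float(np.median(dev)), False
    )


@dataclass
class SampleCorrectionModels:
    sample_id: str
    mz_model: MzCorrectionModel
    rt_model: RtDeviationModel

    @property
    def mz_holdout_rmse(self) -> float:
        return self.mz_model.holdout_rmse


def predict_feature_windows(
    rt_ref: float,
    mz_ref: float,
    charge: int,
    resolution: float,
    rt_peak_width: float,
    models: SampleCorrectionModels,
    windows: AlignmentWindows,
) -> tuple[float, float, float, float]:
    """Expected DICE window for one consensus feature in one sample.

    Returns ``(rt_center, mz_center, rt_half_width, mz_half_width)`` where
    half-widths are the feature-specific ``rt_peak_width / 2`` and the
    global m/z alignment window.
    """
    windows.resolved()
    rt_center = rt_ref + float(models.rt_model.predict(rt_ref)[0])
    mz_center = mz_ref + float(
        models.mz_model.predict(rt_ref, mz_ref, charge, resolution)[0]
    )
    return rt_center, mz_center, rt_peak_width / 2.0, float(windows.mz_window)
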