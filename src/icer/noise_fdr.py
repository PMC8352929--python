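"""Decoy-derived noise models, significance scoring, masking FDR, imputation.

Background noise is learned from decoy windows: an RT-dependent smoother
of decoy intensities, a robust dispersion, and the empirical decoy ion
count distribution whose median sets the minimum-ion threshold for peak
detection.  Observed ion counts are scored against that distribution with
a one-sided empirical p-value.  Peak-selection accuracy is estimated by
masking sequenced features (treating them as undetected) and counting how
often the re-selection lands on a wrong peak with deviating intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "QuantEvent",
    "NoiseModel",
    "fit_noise_model",
    "score_significance",
    "estimate_fdr",
    "impute_missing",
]

MIN_DECOY_EVENTS = 20


@dataclass
class QuantEvent:
    """One DICE quantification of one consensus feature in one sample."""

    consensus_id: int
    sample_id: str
    ion_count: int
    total_intensity: float
    signal_intensity: float
    background_intensity: float
    rt_center: float = float("nan")
    mz_center: float = float("nan")
    origin: str = "expected_fallback"
    p_value: float = float("nan")
    missing: bool = False
    imputed: bool = False
    removed_reason: str = ""

    @property
    def signal_to_background(self) -> float:
        if self.background_intensity <= 0:
            return float("inf") if self.signal_intensity > 0 else 0.0
        return self.signal_intensity / self.background_intensity


class NoiseModel:
    """Per-sample RT-dependent background model fitted on decoy windows."""

    def __init__(
        self,
        sample_id: str,
        spline,
        rt_min: float,
        rt_max: float,
        mean_fallback: float,
        sd_intensity: float,
        count_distribution: np.ndarray,
        residuals: np.ndarray,
    ) -> None:
        self.sample_id = sample_id
        self._spline = spline
        self.rt_min = rt_min
        self.rt_max = rt_max
        self._mean_fallback = mean_fallback
        self.sd_intensity = sd_intensity
        self.count_distribution = np.sort(np.asarray(count_distribution))
        self.residuals = np.asarray(residuals, dtype=float)
        self.median_decoy_count = (
            int(np.median(self.count_distribution))
            if self.count_distribution.size else 0
        )

    def mean_intensity(self, rt) -> np.ndarray | float:
        rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
        if self._spline is None:
            out = np.full(rt_arr.shape, self._mean_fallback)
        else:
            out = np.asarray(
                self._spline(np.clip(rt_arr, self.rt_min, self.rt_max)),
                dtype=float,
            )
        out = np.maximum(out, 0.0)
        return float(out[0]) if np.isscalar(rt) or np.ndim(rt) == 0 else out


def fit_noise_model(
    decoy_events: list[QuantEvent],
    sample_id: str,
    sd_estimator: str = "mad",
) -> NoiseModel:
    """Fit the RT-dependent decoy intensity smoother and count distribution."""
    counts = np.array([e.ion_count for e in decoy_events], dtype=float)
    intensities = np.array([e.total_intensity for e in decoy_events])
    rts = np.array([e.rt_center for e in decoy_events])

    if len(decoy_events) < MIN_DECOY_EVENTS:
        warnings.warn(
            f"{sample_id}: only {len(decoy_events)} decoy events; "
            "using a constant-median noise model"
        )
        med = float(np.median(intensities)) if intensities.size else 0.0
        resid = intensities - med if intensities.size else np.zeros(0)
        sd = _dispersion(resid, sd_estimator)
        return NoiseModel(sample_id, None, 0.0, 0.0, med, sd, counts, resid)

    order = np.argsort(rts)
    x, y = rts[order], intensities[order]
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    if ux.size < 4 or np.all(y == y[0]):
        med = float(np.median(intensities))
        resid = intensities - med
        sd = _dispersion(resid, sd_estimator)
        return NoiseModel(sample_id, None, 0.0, 0.0, med, sd, counts, resid)

    spline = make_smoothing_spline(ux, uy)
    fitted = np.asarray(spline(np.clip(rts, ux[0], ux[-1])), dtype=float)
    resid = intensities - fitted
    sd = _dispersion(resid, sd_estimator)
    return NoiseModel(
        sample_id, spline, float(ux[0]), float(ux[-1]),
        float(np.median(intensities)), sd, counts, resid,
    )


def _dispersion(residuals: np.ndarray, estimator: str) -> float:
    if residuals.size == 0:
        return 0.0
    if estimator == "sd":
        return float(np.std(residuals))
    if estimator == "mad":
        return float(1.4826 * np.median(np.abs(residuals - np.median(residuals))))
    raise ValueError(f"unknown sd estimator {estimator!r}; use 'mad' or 'sd'")


def score_significance(
    event: QuantEvent, noise: NoiseModel, alpha: float = 0.05
) -> float:
    """One-sided empirical p-value of the observed ion count against the
    decoy count distribution, with an add-one pseudocount."""
    counts = noise.count_distribution
    n = counts.size
    if event.ion_count <= 0:
        p = 1.0
    else:
        n_ge = n - int(np.searchsorted(counts, event.ion_count, side="left"))
        p = (1.0 + n_ge) / (1.0 + n)
    event.p_value = p
    return p


def estimate_fdr(
    context,
    n_mask: int = 500,
    seed: int = 0,
    intensity_tolerance: float = 0.2,
) -> pd.DataFrame:
    """Masking-based estimate of peak-selection FDR.

    ``context`` must provide:

    * ``sequenced_cells() -> list[(feature_id, sample_id)]`` — cells whose
      sample contributed a sequenced detected feature,
    * ``original_result(fid, sid) -> (DiceWindow, QuantEvent)``,
    * ``reselect_masked(fid, sid) -> (DiceWindow, QuantEvent)`` — re-run
      selection with the sample treated as if no feature was detected.

    A masked re-selection is wrong when the new intensity deviates from the
    original by more than ``intensity_tolerance`` (relative) or its center
    leaves the original window.  Returns a per-sample report with a pooled
    "all" row.
    """
    rng = np.random.default_rng(seed)
    cells = context.sequenced_cells()
    by_sample: dict[str, list] = {}
    for fid, sid in cells:
        by_sample.setdefault(sid, []).append(fid)

    rows = []
    total_masked = 0
    total_wrong = 0
    for sid in sorted(by_sample):
        fids = sorted(by_sample[sid])
        k = min(n_mask, len(fids))
        chosen = rng.choice(len(fids), size=k, replace=False)
        n_wrong = 0
        for ci in chosen:
            fid = fids[int(ci)]
            orig_win, orig_ev = context.original_result(fid, sid)
            new_win, new_ev = context.reselect_masked(fid, sid)
            wrong = not orig_win.contains(new_win.rt_center, new_win.mz_center)
            if not wrong:
                base = max(orig_ev.total_intensity, 1e-12)
                wrong = (abs(new_ev.total_intensity - orig_ev.total_intensity)
                         / base > intensity_tolerance)
            n_wrong += int(wrong)
        rows.append({"sample_id": sid, "n_masked": k, "n_wrong": n_wrong,
                     "fdr": n_wrong / k if k else float("nan")})
        total_masked += k
        total_wrong += n_wrong

    rows.append({
        "sample_id": "all", "n_masked": total_masked, "n_wrong": total_wrong,
        "fdr": total_wrong / total_masked if total_masked else float("nan"),
    })
    return pd.DataFrame(rows)


def impute_missing(
    events: list[QuantEvent],
    noise_models: dict[str, NoiseModel],
    seed: int = 0,
    enabled: bool = True,
) -> list[QuantEvent]:
    """Impute missing quantifications from the sample's noise model.

    Missing events (zero ions) receive ``mean_intensity(rt)`` plus a
    resampled residual, are flagged ``imputed`` and carry ``p_value = 1``
    (an imputed value never claims significance).  The input list is
    returned with imputed copies substituted; non-missing events are
    untouched.
    """
    if not enabled:
        return events
    sample_ids = sorted({e.sample_id for e in events})
    rngs = {sid: np.random.default_rng((seed, i))
            for i, sid in enumerate(sample_ids)}
    out: list[QuantEvent] = []
    for e in events:
        if not e.missing or e.removed_reason:
            out.append(e)
            continue
        noise = noise_models.get(e.sample_id)
        if noise is None:
            out.append(e)
            continue
        rng = rngs[e.sample_id]
        mean = float(np.atleast_1d(noise.mean_intensity(e.rt_center))[0])
        if noise.residuals.size:
            resid = float(rng.choice(noise.residuals))
        else:
            resid = float(rng.normal(0.0, noise.sd_intensity))
        value = max(mean + resid, 0.0)
        out.append(QuantEvent(
            consensus_id=e.consensus_id,
            sample_id=e.sample_id,
            ion_count=0,
            total_intensity=value,
            signal_intensity=0.0,
            background_intensity=value,
            rt_center=e.rt_center,
            mz_center=e.mz_center,
            origin=e.origin,
            p_value=1.0,
            missing=True,
            imputed=True,
        ))
    return out
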