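"""Local KDE ion-accumulation maps, peak selection and ion extraction.

For each consensus feature and sample, ions are gathered from an extended
search region around the expected window, coordinates are standardized by
the alignment windows (the raw RT and m/z scales differ by ~1e5), a
bivariate normal-kernel density is evaluated on a 50x50 grid, and local
maxima become peak candidates.  One extraction window per sample is then
chosen: samples with a contributing detected feature take the candidate
nearest the expected center (``known``), other samples take the candidate
nearest the known peaks' consensus location within the transfer limits
(``transferred``), and the expected window itself otherwise
(``expected_fallback``).  Ion counts and intensity sums inside the chosen
window form the quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .alignment import AlignmentWindows
from .io_formats import SampleIonMap
from .noise_fdr import NoiseModel, QuantEvent

__all__ = [
    "KdeMap",
    "PeakCandidate",
    "DiceWindow",
    "compute_kde_map",
    "detect_peaks",
    "select_window",
    "extract_quant",
    "filter_outlier_peaks",
]

KDE_RESOLUTION = 50
SEARCH_MULTIPLE = 3  # extended region = expected center +- 3 windows
TRANSFER_MAX_MZ_MULTIPLE = 3
MAX_CANDIDATES = 5


@dataclass
class KdeMap:
    density: np.ndarray  # (resolution, resolution), rt x mz
    rt_grid: np.ndarray  # minutes
    mz_grid: np.ndarray  # Th
    ion_idx: np.ndarray  # indices into the sample ion map

    @property
    def resolution(self) -> int:
        return self.density.shape[0]


@dataclass
class PeakCandidate:
    rt: float
    mz: float
    ion_count: int
    distance: float  # standardized distance from expected center
    rank: int = 0
    in_expected_window: bool = False


@dataclass
class DiceWindow:
    sample_id: str
    consensus_id: int
    rt_center: float
    rt_half_width: float
    mz_center: float
    mz_half_width: float
    origin: str  # known | transferred | expected_fallback

    def contains(self, rt: float, mz: float) -> bool:
        return (abs(rt - self.rt_center) <= self.rt_half_width
                and abs(mz - self.mz_center) <= self.mz_half_width)


def _bandwidth(x: np.ndarray) -> float:
    """Normal reference rule on standardized coordinates, floored so the
    kernel spans at least a couple of grid cells."""
    n = x.size
    if n < 2:
        return 0.2
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.2
    return max(0.9 * spread * n ** (-0.2), 0.12)


def compute_kde_map(
    ion_map: SampleIonMap,
    expected_rt: float,
    expected_mz: float,
    windows: AlignmentWindows,
    rt_half_width: float,
    resolution: int = KDE_RESOLUTION,
    im_center: float | None = None,
    im_window: float | None = None,
) -> KdeMap:
    """Unweighted bivariate normal KDE of ions around the expected window."""
    windows.resolved()
    rt_w, mz_w = windows.rt_window, windows.mz_window
    rt_half_region = max(SEARCH_MULTIPLE * rt_w, rt_half_width + rt_w)
    mz_half_region = SEARCH_MULTIPLE * mz_w

    idx = ion_map.query(
        expected_rt - rt_half_region, expected_rt + rt_half_region,
        expected_mz - mz_half_region, expected_mz + mz_half_region,
        im_lo=None if im_center is None or im_window is None else im_center - im_window,
        im_hi=None if im_center is None or im_window is None else im_center + im_window,
    )
    rt_grid = np.linspace(expected_rt - rt_half_region,
                          expected_rt + rt_half_region, resolution)
    mz_grid = np.linspace(expected_mz - mz_half_region,
                          expected_mz + mz_half_region, resolution)
    if idx.size == 0:
        return KdeMap(np.zeros((resolution, resolution)), rt_grid, mz_grid, idx)

    # standardize each dimension by its alignment window before the KDE
    u = (ion_map.rt[idx] - expected_rt) / rt_w
    v = (ion_map.mz[idx] - expected_mz) / mz_w
    gu = (rt_grid - expected_rt) / rt_w
    gv = (mz_grid - expected_mz) / mz_w
    hu, hv = _bandwidth(u), _bandwidth(v)
    # separable normal kernels: density = Ku @ Kv^T / (n * hu * hv * 2pi)
    ku = np.exp(-0.5 * ((gu[:, None] - u[None, :]) / hu) ** 2)
    kv = np.exp(-0.5 * ((gv[:, None] - v[None, :]) / hv) ** 2)
    density = ku @ kv.T / (idx.size * hu * hv * 2.0 * np.pi)
    return KdeMap(density, rt_grid, mz_grid, idx)


def detect_peaks(
    kde_map: KdeMap,
    ion_map: SampleIonMap,
    expected_rt: float,
    expected_mz: float,
    rt_half_width: float,
    mz_half_width: float,
    windows: AlignmentWindows,
    min_ions: int,
) -> list[PeakCandidate]:
    """Local maxima (8-neighborhood) of the density grid as peak candidates.

    A candidate is kept when it gathers at least ``min_ions`` ions inside a
    window of the feature's half-widths, or when it lies inside the
    expected window.  Grid locations are refined to the intensity-weighted
    centroid of the ions inside the candidate window: elution clusters put
    roughly one ion per scan, so the density along RT is near-flat and the
    raw argmax alone would wander along the ridge.  At most
    :data:`MAX_CANDIDATES` are returned, sorted by ascending standardized
    distance from the expected center.
    """
    dens = kde_map.density
    if not np.any(dens > 0):
        return []
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (dens == ndimage.maximum_filter(dens, footprint=footprint,
                                                mode="constant")) & (dens > 0)
    # plateau handling: of connected equal-valued maxima keep the cell
    # nearest the expected center
    labels, n_lab = ndimage.label(local_max)
    rt_w, mz_w = windows.rt_window, windows.mz_window
    candidates: list[PeakCandidate] = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        du = (kde_map.rt_grid[rows] - expected_rt) / rt_w
        dv = (kde_map.mz_grid[cols] - expected_mz) / mz_w
        pick = int(np.argmin(np.hypot(du, dv)))
        rt = float(kde_map.rt_grid[rows[pick]])
        mz = float(kde_map.mz_grid[cols[pick]])
        idx = ion_map.query(rt - rt_half_width, rt + rt_half_width,
                            mz - mz_half_width, mz + mz_half_width)
        if idx.size:
            weights = ion_map.intensity[idx]
            if weights.sum() > 0:
                rt = float(np.average(ion_map.rt[idx], weights=weights))
                mz = float(np.average(ion_map.mz[idx], weights=weights))
            idx = ion_map.query(rt - rt_half_width, rt + rt_half_width,
                                mz - mz_half_width, mz + mz_half_width)
        count = int(idx.size)
        in_window = (abs(rt - expected_rt) <= rt_half_width
                     and abs(mz - expected_mz) <= mz_half_width)
        if count >= min_ions or in_window:
            d_rt = (rt - expected_rt) / rt_w
            d_mz = (mz - expected_mz) / mz_w
            candidates.append(PeakCandidate(
                rt=rt, mz=mz, ion_count=count,
                distance=float(np.hypot(d_rt, d_mz)),
                in_expected_window=in_window,
            ))
    candidates.sort(key=lambda c: c.distance)
    # centroid refinement can collapse neighbouring grid maxima onto the
    # same location; keep only the first of near-identical candidates
    deduped: list[PeakCandidate] = []
    for c in candidates:
        if any(abs(c.rt - d.rt) <= 0.25 * rt_half_width
               and abs(c.mz - d.mz) <= 0.25 * mz_half_width for d in deduped):
            continue
        deduped.append(c)
    candidates = deduped[:MAX_CANDIDATES]
    for rank, c in enumerate(candidates):
        c.rank = rank
    return candidates


def select_window(
    candidates: dict[str, list[PeakCandidate]],
    expected: dict[str, tuple[float, float]],
    known_samples: set[str],
    consensus_id: int,
    rt_half_width: float,
    mz_half_width: float,
    windows: AlignmentWindows,
    min_ions: dict[str, int],
    max_mz_multiple: float = TRANSFER_MAX_MZ_MULTIPLE,
) -> dict[str, DiceWindow]:
    """Choose one extraction window per sample for one consensus feature.

    Selection happens in deviation space (peak minus the sample's expected
    center) so that known-peak locations are comparable across samples.
    """
    windows.resolved()
    rt_w, mz_w = windows.rt_window, windows.mz_window

    selected: dict[str, DiceWindow] = {}
    known_deltas: list[tuple[float, float]] = []
    rejected_known_deltas: list[tuple[float, float]] = []

    for sid in sorted(known_samples):
        cands = candidates.get(sid, [])
        exp_rt, exp_mz = expected[sid]
        chosen: PeakCandidate | None = None
        for c in cands:  # already sorted by distance
            if c.ion_count >= min_ions.get(sid, 0) and c.in_expected_window:
                chosen = c
                break
        if chosen is not None:
            selected[sid] = DiceWindow(sid, consensus_id, chosen.rt,
                                       rt_half_width, chosen.mz,
                                       mz_half_width, "known")
            known_deltas.append((chosen.rt - exp_rt, chosen.mz - exp_mz))
            # only genuinely distinct peaks block transfer; near-duplicates
            # of the chosen peak are the same analyte
            rejected_known_deltas.extend(
                (c.rt - exp_rt, c.mz - exp_mz) for c in cands
                if c is not chosen
                and (abs(c.rt - chosen.rt) > rt_half_width
                     or abs(c.mz - chosen.mz) > mz_half_width)
            )
        else:
            selected[sid] = DiceWindow(sid, consensus_id, exp_rt,
                                       rt_half_width, exp_mz,
                                       mz_half_width, "expected_fallback")

    if known_deltas:
        target_delta = (float(np.median([d[0] for d in known_deltas])),
                        float(np.median([d[1] for d in known_deltas])))
    else:
        target_delta = (0.0, 0.0)

    for sid in sorted(set(candidates) | set(expected)):
        if sid in known_samples:
            continue
        exp_rt, exp_mz = expected[sid]
        best: PeakCandidate | None = None
        best_d = np.inf
        for c in candidates.get(sid, []):
            d_rt = c.rt - exp_rt
            d_mz = c.mz - exp_mz
            if abs(d_rt) > rt_w or abs(d_mz) > max_mz_multiple * mz_w:
                continue
            # skip candidates overlapping a distinct (rejected) known peak
            if any(abs(d_rt - rr) <= rt_half_width and abs(d_mz - rm) <= mz_half_width
                   for rr, rm in rejected_known_deltas):
                continue
            d = np.hypot((d_rt - target_delta[0]) / rt_w,
                         (d_mz - target_delta[1]) / mz_w)
            if d < best_d:
                best, best_d = c, d
        if best is not None and known_deltas:
            selected[sid] = DiceWindow(sid, consensus_id, best.rt,
                                       rt_half_width, best.mz,
                                       mz_half_width, "transferred")
        else:
            selected[sid] = DiceWindow(sid, consensus_id, exp_rt,
                                       rt_half_width, exp_mz,
                                       mz_half_width, "expected_fallback")
    return selected


def extract_quant(
    ion_map: SampleIonMap,
    window: DiceWindow,
    noise_model: NoiseModel | None = None,
    sd_multiple: float = 2.0,
) -> QuantEvent:
    """Count and sum ions inside the selected window; split signal from
    background using the decoy noise model when available."""
    idx = ion_map.query(
        window.rt_center - window.rt_half_width,
        window.rt_center + window.rt_half_width,
        window.mz_center - window.mz_half_width,
        window.mz_center + window.mz_half_width,
    )
    intensities = ion_map.intensity[idx]
    total = float(intensities.sum())
    if noise_model is not None and idx.size:
        threshold = (noise_model.mean_intensity(window.rt_center)
                     + sd_multiple * noise_model.sd_intensity)
        signal = float(intensities[intensities > threshold].sum())
    else:
        signal = 0.0
    return QuantEvent(
        consensus_id=window.consensus_id,
        sample_id=window.sample_id,
        ion_count=int(idx.size),
        total_intensity=total,
        signal_intensity=signal,
        background_intensity=total - signal,
        rt_center=window.rt_center,
        mz_center=window.mz_center,
        origin=window.origin,
        missing=idx.size == 0,
    )


# --------------------------------------------------------------------------
# Peak-selection outlier filters
# --------------------------------------------------------------------------

def _upper_fence(values: np.ndarray, multiplier: float) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + multiplier * (q3 - q1))


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale <= 0:
        return np.zeros_like(values, dtype=float)
    return (values - med) / scale


def filter_outlier_peaks(
    selections: dict[int, dict[str, DiceWindow]],
    expected: dict[int, dict[str, tuple[float, float]]],
    isotope_selections: dict[int, dict[str, DiceWindow]] | None,
    charges: dict[int, int],
    windows: AlignmentWindows,
    z_threshold: float = 3.0,
    isotope_delta: float = 1.002,
) -> tuple[set[int], set[tuple[int, str]], pd.DataFrame]:
    """Remove unreliable peak selections.

    Deviations are measured in alignment-corrected space (selected peak
    minus the sample's expected center) so that genuine cross-sample drift
    does not register as an outlier.

    1. Whole features whose cross-sample IQR of peak-RT or peak-m/z
       deviation is an upper outlier of the feature population (log-IQR
       above a Tukey fence of ``z_threshold`` population IQRs over Q3).
    2. Individual samples whose deviation sits more than ``z_threshold``
       pooled robust standard deviations from the feature's median
       deviation (scale floored at a third of the alignment window so
       honest transfer error cannot dominate).
    3. Samples where the monoisotopic and +1-isotope selected peaks
       disagree (|d rt| > rt_window or |d mz - delta/charge| > mz_window).

    Returns (removed feature ids, excluded (feature, sample) cells, log).
    """
    windows.resolved()
    log_rows: list[dict] = []
    removed_features: set[int] = set()
    excluded_cells: set[tuple[int, str]] = set()

    fids = sorted(selections)
    rt_iqr = np.empty(len(fids))
    mz_iqr = np.empty(len(fids))
    rt_dev_pool: list[np.ndarray] = []
    mz_dev_pool: list[np.ndarray] = []
    per_feature_devs: dict[int, tuple[list[str], np.ndarray, np.ndarray]] = {}
    for k, fid in enumerate(fids):
        wins = selections[fid]
        sids = sorted(wins)
        rts = np.array([wins[s].rt_center - expected[fid][s][0] for s in sids])
        mzs = np.array([wins[s].mz_center - expected[fid][s][1] for s in sids])
        rt_iqr[k] = np.subtract(*np.percentile(rts, [75, 25]))
        mz_iqr[k] = np.subtract(*np.percentile(mzs, [75, 25]))
        rt_dev = rts - np.median(rts)
        mz_dev = mzs - np.median(mzs)
        per_feature_devs[fid] = (sids, rt_dev, mz_dev)
        rt_dev_pool.append(rt_dev)
        mz_dev_pool.append(mz_dev)

    if fids:
        # upper outliers of the log-IQR population via a Tukey far-out
        # fence (Q3 + z_threshold * IQR): the population is right-skewed,
        # so an MAD-based z over-flags moderate transfers.  An outlying
        # IQR must also be large on the window scale.
        fence_rt = _upper_fence(np.log(rt_iqr + 1e-12), z_threshold)
        fence_mz = _upper_fence(np.log(mz_iqr + 1e-12), z_threshold)
        big_rt = rt_iqr > 0.2 * windows.rt_window
        big_mz = mz_iqr > 0.2 * windows.mz_window
        for k, fid in enumerate(fids):
            if (np.log(rt_iqr[k] + 1e-12) > fence_rt and big_rt[k]) or (
                    np.log(mz_iqr[k] + 1e-12) > fence_mz and big_mz[k]):
                removed_features.add(fid)
                log_rows.append({"feature_id": fid, "sample_id": "",
                                 "reason": "feature_iqr_outlier"})

        pooled_rt = np.concatenate(rt_dev_pool)
        pooled_mz = np.concatenate(mz_dev_pool)
        # floor the pooled scale at a third of the alignment window so the
        # z > 3 rule only fires for deviations beyond a full window;
        # smaller offsets are within honest model error for transfers
        rt_scale = max(1.4826 * np.median(np.abs(pooled_rt)),
                       windows.rt_window / 3.0)
        mz_scale = max(1.4826 * np.median(np.abs(pooled_mz)),
                       windows.mz_window / 3.0)
        for fid in fids:
            if fid in removed_features:
                continue
            sids, rt_dev, mz_dev = per_feature_devs[fid]
            for s, dr, dm in zip(sids, rt_dev, mz_dev):
                if abs(dr) / rt_scale > z_threshold or abs(dm) / mz_scale > z_threshold:
                    excluded_cells.add((fid, s))
                    log_rows.append({"feature_id": fid, "sample_id": s,
                                     "reason": "sample_peak_outlier"})

    if isotope_selections:
        for fid, iso_wins in isotope_selections.items():
            if fid not in selections or fid in removed_features:
                continue
            charge = charges.get(fid, 1)
            for sid, iso_win in iso_wins.items():
                win = selections[fid].get(sid)
                if win is None or (fid, sid) in excluded_cells:
                    continue
                if iso_win.origin == "expected_fallback":
                    continue  # no isotope evidence to compare against
                d_rt = abs(iso_win.rt_center - win.rt_center)
                d_mz = abs((iso_win.mz_center - win.mz_center)
                           - isotope_delta / charge)
                if d_rt > windows.rt_window or d_mz > windows.mz_window:
                    excluded_cells.add((fid, sid))
                    log_rows.append({"feature_id": fid, "sample_id": sid,
                                     "reason": "isotope_disagreement"})

    log = pd.DataFrame(log_rows, columns=["feature_id", "sample_id", "reason"])
    return removed_features, excluded_cells, log
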