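"""End-to-end orchestration of the re-quantification workflow.

Stage order: alignment windows -> consensus assembly (merge, decoys,
isotopes, identity propagation) -> per-sample correction models -> decoy
extraction and noise models -> per-feature KDE peak selection and DICE
extraction -> significance scoring -> outlier filters -> masking FDR ->
imputation -> peptide/protein tables.

A single global seed fans out deterministically to every stage; identical
config and seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, dice_quant, feature_assembly, noise_fdr, rollup
from .alignment import AlignmentWindows, SampleCorrectionModels
from .feature_assembly import ConsensusFeature, SEQUENCED_HERE
from .io_formats import (
    DetectedFeature,
    SampleIonMap,
    read_feature_table,
    read_ms1_map,
    write_table,
)
from .noise_fdr import NoiseModel, QuantEvent

__all__ = ["PipelineConfig", "PipelineResult", "Quantifier",
           "run_on_data", "run_pipeline"]


@dataclass
class PipelineConfig:
    # inputs (unused when running on in-memory data)
    ion_map_paths: dict[str, str] = field(default_factory=dict)
    feature_table_paths: dict[str, str] = field(default_factory=dict)
    feature_dialect: str = "generic"
    output_dir: str = "icer_out"
    # alignment windows
    rt_window: float | None = None  # fixed override
    mz_window: float | None = None
    min_rt_window: float | None = None
    min_mz_window: float | None = None
    # stage constants (defaults are the published ones)
    kde_resolution: int = 50
    merge_delta_mass: float = 0.002
    decoy_offset_multiplier: float = 5.0
    isotope_enabled: bool = True
    isotope_delta: float = 1.002
    transfer_max_mz_multiple: float = 3.0
    signal_sd_multiple: float = 2.0
    significance_alpha: float = 0.05
    fdr_n_mask: int = 500
    fdr_tolerance: float = 0.2
    impute_enabled: bool = True
    noise_sd_estimator: str = "mad"
    outlier_z: float = 3.0
    aggregate_unknown: bool = False
    rollup_method: str = "top3"
    min_peptides: int = 2
    run_fdr: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    windows: AlignmentWindows
    consensus: list[ConsensusFeature]
    decoys: list[ConsensusFeature]
    isotopes: list[ConsensusFeature]
    models: dict[str, SampleCorrectionModels]
    noise_models: dict[str, NoiseModel]
    quantifier: "Quantifier"
    events: pd.DataFrame
    peptide_table: pd.DataFrame
    peptide_table_nonimputed: pd.DataFrame
    protein_table: pd.DataFrame
    normalization_factors: pd.Series
    fdr_report: pd.DataFrame
    removal_log: pd.DataFrame
    alignment_diagnostics: pd.DataFrame
    manifest: dict
    sample_ids: list[str]


class Quantifier:
    """Runs KDE peak selection and DICE extraction per consensus feature.

    Candidates are cached per (feature, sample) so the masking FDR can
    re-run the selection pathway cheaply.  Tasks are independent across
    (feature, sample); iteration order never influences any output.
    """

    def __init__(
        self,
        targets: list[ConsensusFeature],
        ion_maps: dict[str, SampleIonMap],
        models: dict[str, SampleCorrectionModels],
        windows: AlignmentWindows,
        noise_models: dict[str, NoiseModel],
        config: PipelineConfig,
        rt_ref_corrected: dict[int, float] | None = None,
    ) -> None:
        self.targets = {c.id: c for c in targets}
        self.rt_ref_corrected = rt_ref_corrected or {}
        self.ion_maps = ion_maps
        self.models = models
        self.windows = windows
        self.noise_models = noise_models
        self.config = config
        self.sample_ids = sorted(ion_maps)
        self.min_ions = {sid: noise_models[sid].median_decoy_count
                         for sid in self.sample_ids}
        self._expected: dict[int, dict[str, tuple[float, float]]] = {}
        self._model_expected: dict[int, dict[str, tuple[float, float]]] = {}
        self._candidates: dict[int, dict[str, list]] = {}
        self._known: dict[int, set[str]] = {}
        self.selections: dict[int, dict[str, dice_quant.DiceWindow]] = {}
        self.events: dict[int, dict[str, QuantEvent]] = {}

    # -- expected centers ---------------------------------------------------

    def _model_center(self, c: ConsensusFeature, sid: str) -> tuple[float, float]:
        m = self.models[sid]
        base_rt = self.rt_ref_corrected.get(c.id, c.rt_ref)
        rt_c = base_rt + float(m.rt_model.predict(base_rt)[0])
        mz_c = c.mz_ref + float(m.mz_model.predict(
            base_rt, c.mz_ref, c.charge, _typical_resolution(c))[0])
        return rt_c, mz_c

    def _observed_center(self, c: ConsensusFeature, sid: str) -> tuple[float, float]:
        feats = c.contributors.get(sid, [])
        rts = np.array([f.rt for f in feats])
        mzs = np.array([f.mz_uncalibrated for f in feats])
        return float(np.median(rts)), float(np.median(mzs))

    def expected_centers(self, fid: int) -> dict[str, tuple[float, float]]:
        if fid not in self._expected:
            c = self.targets[fid]
            exp, mexp = {}, {}
            for sid in self.sample_ids:
                mexp[sid] = self._model_center(c, sid)
                exp[sid] = (self._observed_center(c, sid)
                            if c.contributors.get(sid) else mexp[sid])
            self._expected[fid] = exp
            self._model_expected[fid] = mexp
        return self._expected[fid]

    # -- candidates ---------------------------------------------------------

    def _candidates_at(self, c: ConsensusFeature, sid: str,
                       center: tuple[float, float]) -> list:
        rt_c, mz_c = center
        rt_half = c.rt_peak_width / 2.0
        mz_half = self.windows.mz_window
        kde = dice_quant.compute_kde_map(
            self.ion_maps[sid], rt_c, mz_c, self.windows, rt_half,
            resolution=self.config.kde_resolution,
        )
        return dice_quant.detect_peaks(
            kde, self.ion_maps[sid], rt_c, mz_c, rt_half, mz_half,
            self.windows, self.min_ions[sid],
        )

    def candidates(self, fid: int) -> dict[str, list]:
        if fid not in self._candidates:
            c = self.targets[fid]
            exp = self.expected_centers(fid)
            self._candidates[fid] = {
                sid: self._candidates_at(c, sid, exp[sid])
                for sid in self.sample_ids
            }
        return self._candidates[fid]

    # -- selection and extraction ------------------------------------------

    def quantify(self, fid: int) -> dict[str, QuantEvent]:
        c = self.targets[fid]
        exp = self.expected_centers(fid)
        known = {sid for sid in self.sample_ids if c.contributors.get(sid)}
        self._known[fid] = known
        sel = dice_quant.select_window(
            self.candidates(fid), exp, known, fid,
            c.rt_peak_width / 2.0, self.windows.mz_window,
            self.windows, self.min_ions,
            max_mz_multiple=self.config.transfer_max_mz_multiple,
        )
        self.selections[fid] = sel
        evs = {
            sid: dice_quant.extract_quant(
                self.ion_maps[sid], sel[sid], self.noise_models[sid],
                self.config.signal_sd_multiple,
            )
            for sid in self.sample_ids
        }
        self.events[fid] = evs
        return evs

    def quantify_all(self) -> None:
        for fid in sorted(self.targets):
            self.quantify(fid)

    # -- masking FDR interface ---------------------------------------------

    def sequenced_cells(self) -> list[tuple[int, str]]:
        cells = []
        for fid in sorted(self.targets):
            c = self.targets[fid]
            for sid in self.sample_ids:
                if c.sample_status.get(sid) == SEQUENCED_HERE:
                    cells.append((fid, sid))
        return cells

    def original_result(self, fid: int, sid: str):
        return self.selections[fid][sid], self.events[fid][sid]

    def reselect_masked(self, fid: int, sid: str):
        """Re-run selection for one cell as if its sample had no feature."""
        c = self.targets[fid]
        exp = dict(self.expected_centers(fid))
        exp[sid] = self._model_expected[fid][sid]
        cands = dict(self.candidates(fid))
        cands[sid] = self._candidates_at(c, sid, exp[sid])
        known = self._known[fid] - {sid}
        sel = dice_quant.select_window(
            cands, exp, known, fid, c.rt_peak_width / 2.0,
            self.windows.mz_window, self.windows, self.min_ions,
            max_mz_multiple=self.config.transfer_max_mz_multiple,
        )
        ev = dice_quant.extract_quant(
            self.ion_maps[sid], sel[sid], self.noise_models[sid],
            self.config.signal_sd_multiple,
        )
        return sel[sid], ev


def _fit_rt_models(
    obs_rt: dict[int, dict[str, float]],
    rt_ref_init: dict[int, float],
    sample_ids: list[str],
    n_iter: int = 3,
) -> tuple[dict[str, alignment.RtDeviationModel], dict[int, float]]:
    """Alternating fit of per-sample RT-deviation smoothers and
    drift-corrected consensus RTs.

    The raw per-feature median RT depends on which samples happened to
    contribute, so deviations against it carry subset noise of the order
    of the inter-sample drift spread.  Iterating between (a) smoothing
    each sample's deviation against the current consensus RT and (b)
    re-estimating the consensus RT from drift-corrected observations
    removes most of that noise.
    """
    ref = dict(rt_ref_init)
    rt_models: dict[str, alignment.RtDeviationModel] = {}
    for _ in range(n_iter):
        for sid in sample_ids:
            pairs = [(ref[fid], rts[sid]) for fid, rts in obs_rt.items()
                     if sid in rts]
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            rt_models[sid] = alignment.fit_rt_deviation(x, y)
        for fid, rts in obs_rt.items():
            corrected = [rt - float(rt_models[sid].predict(ref[fid])[0])
                         for sid, rt in rts.items()]
            ref[fid] = float(np.median(corrected))
    return rt_models, ref


def _typical_resolution(c: ConsensusFeature) -> float:
    vals = [f.resolution for feats in c.contributors.values() for f in feats
            if np.isfinite(f.resolution)]
    return float(np.median(vals)) if vals else 60000.0


def _quantify_isotopes(
    isotopes: list[ConsensusFeature],
    quantifier: Quantifier,
    config: PipelineConfig,
) -> dict[int, dict[str, dice_quant.DiceWindow]]:
    """Select peaks for +1-isotope companions relative to the parent's
    selected monoisotopic peak."""
    windows = quantifier.windows
    out: dict[int, dict[str, dice_quant.DiceWindow]] = {}
    for iso in sorted(isotopes, key=lambda c: c.id):
        parent_sel = quantifier.selections.get(iso.parent_id)
        if parent_sel is None:
            continue
        shift = config.isotope_delta / iso.charge
        sel: dict[str, dice_quant.DiceWindow] = {}
        for sid in quantifier.sample_ids:
            pwin = parent_sel[sid]
            rt_c, mz_c = pwin.rt_center, pwin.mz_center + shift
            cands = quantifier._candidates_at(iso, sid, (rt_c, mz_c))
            best = None
            best_d = np.inf
            for c in cands:
                d_rt = abs(c.rt - rt_c)
                d_mz = abs(c.mz - mz_c)
                if d_rt > windows.rt_window or d_mz > windows.mz_window:
                    continue
                d = np.hypot(d_rt / windows.rt_window, d_mz / windows.mz_window)
                if d < best_d:
                    best, best_d = c, d
            if best is not None:
                sel[sid] = dice_quant.DiceWindow(
                    sid, iso.parent_id, best.rt, pwin.rt_half_width,
                    best.mz, pwin.mz_half_width, "transferred",
                )
            else:
                sel[sid] = dice_quant.DiceWindow(
                    sid, iso.parent_id, rt_c, pwin.rt_half_width,
                    mz_c, pwin.mz_half_width, "expected_fallback",
                )
        out[iso.parent_id] = sel
    return out


def run_on_data(
    ion_maps: dict[str, SampleIonMap],
    features: dict[str, list[DetectedFeature]],
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full workflow on in-memory inputs."""
    sample_ids = sorted(ion_maps)
    counts: dict[str, int] = {}

    # 1. alignment windows
    windows = alignment.estimate_alignment_windows(
        features,
        AlignmentWindows(
            user_min_rt=config.min_rt_window, user_min_mz=config.min_mz_window,
            user_fixed_rt=config.rt_window, user_fixed_mz=config.mz_window,
        ),
    )

    # 2. consensus assembly
    consensus = feature_assembly.aggregate_features(
        features, windows, aggregate_unknown=config.aggregate_unknown
    )
    consensus = feature_assembly.merge_overlapping(
        consensus, config.merge_delta_mass
    )
    counts["consensus_features"] = len(consensus)

    # 3. decoys and isotopes
    decoys = feature_assembly.generate_decoys(
        consensus, windows, config.decoy_offset_multiplier
    )
    isotopes = (feature_assembly.generate_isotope_features(
        consensus, config.isotope_delta
    ) if config.isotope_enabled else [])
    counts["decoys"] = len(decoys)
    counts["isotopes"] = len(isotopes)

    # 4. correction models per sample
    models: dict[str, SampleCorrectionModels] = {}
    seq_consensus = [c for c in consensus if c.is_sequenced]
    obs_rt = {
        c.id: {sid: float(np.median([f.rt for f in fl]))
               for sid, fl in c.contributors.items() if fl}
        for c in seq_consensus
    }
    rt_models, rt_ref_corrected = _fit_rt_models(
        obs_rt, {c.id: c.rt_ref for c in seq_consensus}, sample_ids
    )
    for i, sid in enumerate(sample_ids):
        mz_model = alignment.fit_mz_correction(
            features.get(sid, []), seed=config.seed + 17 * i
        )
        models[sid] = SampleCorrectionModels(sid, mz_model, rt_models[sid])

    # 5. feature-based identity propagation
    feature_assembly.propagate_identities(consensus, sample_ids)

    # 6. decoy extraction and noise models
    noise_models: dict[str, NoiseModel] = {}
    decoy_events_all: list[QuantEvent] = []
    for sid in sample_ids:
        decoy_events = []
        for d in sorted(decoys, key=lambda c: c.id):
            rt_c, mz_c, rt_half, mz_half = alignment.predict_feature_windows(
                d.rt_ref, d.mz_ref, d.charge, _typical_resolution(d),
                d.rt_peak_width, models[sid], windows,
            )
            win = dice_quant.DiceWindow(sid, d.id, rt_c, rt_half,
                                        mz_c, mz_half, "decoy")
            decoy_events.append(dice_quant.extract_quant(ion_maps[sid], win))
        noise_models[sid] = noise_fdr.fit_noise_model(
            decoy_events, sid, config.noise_sd_estimator
        )
        decoy_events_all.extend(decoy_events)

    # 7-8. KDE peak selection + DICE extraction
    targets = [c for c in consensus if c.is_sequenced]
    counts["sequenced_targets"] = len(targets)
    quantifier = Quantifier(targets, ion_maps, models, windows,
                            noise_models, config, rt_ref_corrected)
    quantifier.quantify_all()
    iso_selections = _quantify_isotopes(isotopes, quantifier, config)

    # 9. significance
    for fid in sorted(quantifier.events):
        for sid, ev in quantifier.events[fid].items():
            noise_fdr.score_significance(ev, noise_models[sid],
                                         config.significance_alpha)
    for ev in decoy_events_all:
        noise_fdr.score_significance(ev, noise_models[ev.sample_id],
                                     config.significance_alpha)

    # 10. outlier filters
    charges = {c.id: c.charge for c in targets}
    removed_features, excluded_cells, removal_log = dice_quant.filter_outlier_peaks(
        quantifier.selections, quantifier._expected, iso_selections, charges, windows,
        z_threshold=config.outlier_z, isotope_delta=config.isotope_delta,
    )
    for fid in removed_features:
        for ev in quantifier.events[fid].values():
            ev.removed_reason = "feature_iqr_outlier"
    for fid, sid in excluded_cells:
        quantifier.events[fid][sid].removed_reason = \
            quantifier.events[fid][sid].removed_reason or "sample_peak_outlier"
    counts["features_removed"] = len(removed_features)
    counts["cells_excluded"] = len(excluded_cells)

    # 11. masking FDR
    if config.run_fdr:
        fdr_report = noise_fdr.estimate_fdr(
            quantifier, n_mask=config.fdr_n_mask,
            seed=config.seed + 101, intensity_tolerance=config.fdr_tolerance,
        )
    else:
        fdr_report = pd.DataFrame(
            columns=["sample_id", "n_masked", "n_wrong", "fdr"]
        )

    # 12. imputation (imputed and non-imputed tables in parallel)
    flat_events = [ev for fid in sorted(quantifier.events)
                   for ev in quantifier.events[fid].values()]
    imputed_events = noise_fdr.impute_missing(
        flat_events, noise_models, seed=config.seed + 211,
        enabled=config.impute_enabled,
    )
    imputed_by_cell = {(e.consensus_id, e.sample_id): e for e in imputed_events}

    events_df = _events_table(quantifier, imputed_by_cell, targets)
    peptide_table = _peptide_table(targets, quantifier, imputed_by_cell,
                                   sample_ids, use_imputed=True)
    peptide_nonimp = _peptide_table(targets, quantifier, imputed_by_cell,
                                    sample_ids, use_imputed=False)

    # 13. filtering, normalization, protein rollup
    filtered = rollup.filter_tables(peptide_table, sample_ids,
                                    config.min_peptides)
    if len(filtered):
        normalized, factors = rollup.normalize_median(filtered, sample_ids)
        protein_table = rollup.aggregate_protein(
            normalized, sample_ids, config.rollup_method, config.min_peptides
        )
    else:
        factors = pd.Series(dtype=float)
        protein_table = pd.DataFrame(columns=["protein", "n_peptides",
                                              *sample_ids])
    counts["proteins"] = len(protein_table)
    counts["peptides_quantified"] = int(
        (events_df["removed_reason"] == "").sum()
    ) if len(events_df) else 0

    diag_rows = []
    for sid in sample_ids:
        m = models[sid]
        diag_rows.append({
            "sample_id": sid,
            "rt_window": windows.rt_window,
            "mz_window": windows.mz_window,
            "mz_holdout_rmse": m.mz_holdout_rmse,
            "mz_model_fallback": m.mz_model.is_fallback,
            "rt_model_fallback": m.rt_model.is_fallback,
            "median_decoy_count": noise_models[sid].median_decoy_count,
        })
    diagnostics = pd.DataFrame(diag_rows)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_samples": len(sample_ids),
        "rt_window": windows.rt_window,
        "mz_window": windows.mz_window,
        "counts": counts,
    }

    return PipelineResult(
        windows=windows, consensus=consensus, decoys=decoys,
        isotopes=isotopes, models=models, noise_models=noise_models,
        quantifier=quantifier, events=events_df,
        peptide_table=peptide_table, peptide_table_nonimputed=peptide_nonimp,
        protein_table=protein_table, normalization_factors=factors,
        fdr_report=fdr_report, removal_log=removal_log,
        alignment_diagnostics=diagnostics, manifest=manifest,
        sample_ids=sample_ids,
    )


def _events_table(quantifier: Quantifier, imputed_by_cell, targets) -> pd.DataFrame:
    meta = {c.id: c for c in targets}
    rows = []
    for fid in sorted(quantifier.events):
        c = meta[fid]
        for sid in quantifier.sample_ids:
            ev = quantifier.events[fid][sid]
            imp = imputed_by_cell.get((fid, sid), ev)
            rows.append({
                "feature_id": fid,
                "sequence": c.sequence or "",
                "charge": c.charge,
                "protein": c.protein or "",
                "sample_id": sid,
                "status": c.sample_status.get(sid, ""),
                "origin": ev.origin,
                "peak_rt": ev.rt_center,
                "peak_mz": ev.mz_center,
                "ion_count": ev.ion_count,
                "total_intensity": ev.total_intensity,
                "signal_intensity": ev.signal_intensity,
                "background_intensity": ev.background_intensity,
                "p_value": ev.p_value,
                "signal_to_background": ev.signal_to_background,
                "missing": ev.missing,
                "imputed": imp.imputed,
                "imputed_intensity": imp.total_intensity if imp.imputed else np.nan,
                "removed_reason": ev.removed_reason,
            })
    return pd.DataFrame(rows)


def _peptide_table(
    targets: list[ConsensusFeature],
    quantifier: Quantifier,
    imputed_by_cell: dict,
    sample_ids: list[str],
    use_imputed: bool,
) -> pd.DataFrame:
    rows = []
    for c in sorted(targets, key=lambda c: c.id):
        evs = quantifier.events.get(c.id)
        if evs is None:
            continue
        contributors = [f for feats in c.contributors.values() for f in feats]
        row = {
            "feature_id": c.id,
            "sequence": c.sequence,
            "modifications": c.modifications,
            "charge": c.charge,
            "mz_ref": c.mz_ref,
            "rt_ref": c.rt_ref,
            "protein": c.protein or "",
            "is_contaminant": any(f.is_contaminant for f in contributors),
            "is_reverse": any(f.is_reverse for f in contributors),
        }
        for sid in sample_ids:
            ev = evs[sid]
            cell = imputed_by_cell.get((c.id, sid), ev) if use_imputed else ev
            value = cell.total_intensity
            if ev.removed_reason or (cell.missing and not cell.imputed):
                value = np.nan
            row[sid] = value
            row[f"p_value_{sid}"] = cell.p_value
            row[f"s2b_{sid}"] = cell.signal_to_background
            row[f"imputed_{sid}"] = bool(cell.imputed) if use_imputed else False
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run from files on disk and persist all result tables."""
    if not config.ion_map_paths or not config.feature_table_paths:
        raise ValueError("config must list ion_map_paths and feature_table_paths")
    ion_maps = {sid: read_ms1_map(path, sid)
                for sid, path in sorted(config.ion_map_paths.items())}
    features = {
        sid: list(read_feature_table(path, sid, config.feature_dialect))
        for sid, path in sorted(config.feature_table_paths.items())
    }
    result = run_on_data(ion_maps, features, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(feature_assembly.consensus_table(
        result.consensus + result.decoys + result.isotopes), out / "consensus.tsv")
    write_table(result.events, out / "events.tsv")
    write_table(result.peptide_table, out / "peptides.tsv")
    write_table(result.peptide_table_nonimputed, out / "peptides_nonimputed.tsv")
    write_table(result.protein_table, out / "proteins.tsv")
    write_table(result.fdr_report, out / "fdr_report.tsv")
    write_table(result.removal_log, out / "removal_log.tsv")
    write_table(result.alignment_diagnostics, out / "alignment_diagnostics.tsv")
    factors = result.normalization_factors.rename_axis("sample_id").reset_index()
    write_table(factors, out / "normalization_factors.tsv")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result
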