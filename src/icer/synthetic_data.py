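"""Synthetic multi-sample DDA experiments with known ground truth.

Generates, per sample, a centroided MS1 ion map plus a detected-feature
table that mimic the statistical structure the pipeline assumes:

* Gaussian elution profiles sampled on a regular scan grid,
* optional +1 isotope clusters at ``+1.002/charge`` Th,
* smooth per-sample RT drift (linear + sinusoid) and ppm-scale m/z error
  (constant + slow RT-dependent term),
* stochastic MS2-identification dropout (a species missing its
  identification in a sample may still leave a sequence-less feature),
* uniform background ions,
* group-wise spike-in abundance ratios.

Everything is driven by a single seed; equal configs and seeds produce
bit-identical outputs.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .io_formats import DetectedFeature, SampleIonMap, read_feature_table, write_table

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "detected_features",
    "evaluate_against_truth",
    "write_dataset",
    "write_mzxml",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 6
    n_species: int = 200
    groups: tuple[str, ...] | None = None  # default: half "A", half "B"
    spike_fraction: float = 0.0  # fraction of species with group ratio
    spike_ratio: float = 1.0  # group-B/group-A abundance ratio for spiked species
    rt_range: tuple[float, float] = (10.0, 30.0)
    mz_range: tuple[float, float] = (400.0, 900.0)
    rt_drift_amplitude: float = 0.3  # minutes
    mz_error_ppm: float = 3.0
    id_dropout_rate: float = 0.0
    absent_fraction: float = 0.0  # species/sample cells with no ions at all
    unknown_feature_rate: float = 0.5  # unidentified species leaving a feature row
    noise_ion_density: float = 0.0  # ions per minute per Th
    elution_sigma_rt: float = 0.05  # minutes
    mz_sigma: float = 2e-4  # Th centroid jitter
    scan_interval: float = 0.01  # minutes between MS1 scans
    intensity_log_mean: float = 11.0  # natural-log scale
    intensity_log_sd: float = 1.0
    isotope_enabled: bool = True
    isotope_relative_intensity: float = 0.5
    peptides_per_protein: int = 4
    contaminant_fraction: float = 0.0
    interference_fraction: float = 0.0  # species with a nearby decoy peak
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spike_fraction", "id_dropout_rate", "absent_fraction",
                     "unknown_feature_rate", "contaminant_fraction",
                     "interference_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("rt_drift_amplitude", "mz_error_ppm", "noise_ion_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 1 or self.n_species < 1:
            raise ValueError("need at least one sample and one species")

    def resolved_groups(self) -> tuple[str, ...]:
        if self.groups is not None:
            if len(self.groups) != self.n_samples:
                raise ValueError("groups length must equal n_samples")
            return tuple(self.groups)
        half = self.n_samples // 2
        return tuple(["A"] * (self.n_samples - half) + ["B"] * half)


@dataclass
class GroundTruth:
    """Per-species/per-sample truth plus the injected per-sample functions."""

    species: pd.DataFrame  # species_id, sequence, charge, mz_true, rt_true, ...
    cells: pd.DataFrame  # species_id x sample: rt/mz/abundance/identified/...
    drift_functions: dict[str, Callable[[np.ndarray], np.ndarray]]
    ppm_functions: dict[str, Callable[[np.ndarray], np.ndarray]]
    ion_counts: pd.DataFrame  # per sample: species/isotope/background/interference

    def identified_fraction(self) -> float:
        return float(self.cells["identified"].mean())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def _make_drift(rng: np.random.Generator, amplitude: float,
                rt_range: tuple[float, float]) -> Callable[[np.ndarray], np.ndarray]:
    """Linear + sinusoid drift with max amplitude ~``amplitude`` minutes."""
    span = rt_range[1] - rt_range[0]
    mid = 0.5 * (rt_range[0] + rt_range[1])
    a_lin = amplitude * rng.uniform(-0.5, 0.5)
    a_sin = amplitude * rng.uniform(0.25, 0.5)
    period = span * rng.uniform(0.8, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    offset = amplitude * rng.uniform(-0.5, 0.5)

    def drift(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (offset + a_lin * (t - mid) / (0.5 * span)
                + a_sin * np.sin(2 * np.pi * t / period + phase))

    return drift


def _make_ppm_error(rng: np.random.Generator, amplitude: float,
                    rt_range: tuple[float, float]) -> Callable[[np.ndarray], np.ndarray]:
    """Constant ppm offset plus a slow RT-dependent ppm term."""
    span = rt_range[1] - rt_range[0]
    const = amplitude * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
    slow = amplitude * rng.uniform(0.1, 0.3)
    period = span * rng.uniform(1.5, 3.0)
    phase = rng.uniform(0, 2 * np.pi)

    def ppm(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return const + slow * np.sin(2 * np.pi * t / period + phase)

    return ppm


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[dict[str, SampleIonMap], dict[str, pd.DataFrame], GroundTruth]:
    """Generate ion maps, feature tables (generic dialect) and ground truth."""
    rng = np.random.default_rng(config.seed)
    groups = config.resolved_groups()
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    rt_lo, rt_hi = config.rt_range
    mz_lo, mz_hi = config.mz_range
    scan_times = np.arange(rt_lo, rt_hi + 1e-9, config.scan_interval)

    # --- species catalogue -------------------------------------------------
    n = config.n_species
    lengths = rng.integers(8, 15, size=n)
    sequences: list[str] = []
    seen: set[str] = set()
    for L in lengths:
        while True:
            s = _random_sequence(rng, int(L))
            if s not in seen:
                seen.add(s)
                sequences.append(s)
                break
    charges = rng.choice([2, 3], size=n, p=[0.7, 0.3])
    # keep apexes and m/z inside the map with margins
    rt_margin = 10 * config.elution_sigma_rt + config.rt_drift_amplitude + 0.5
    rt_true = rng.uniform(rt_lo + rt_margin, rt_hi - rt_margin, size=n)
    mz_true = rng.uniform(mz_lo + 2.0, mz_hi - 2.0, size=n)
    base_abundance = np.exp(rng.normal(config.intensity_log_mean,
                                       config.intensity_log_sd, size=n))
    spiked = rng.random(n) < config.spike_fraction
    contaminant = rng.random(n) < config.contaminant_fraction
    interfered = rng.random(n) < config.interference_fraction
    protein_ids = np.array(
        [f"PROT{(i // config.peptides_per_protein) + 1:04d}" for i in range(n)]
    )
    # spiked status must be uniform within a protein so ratios are coherent
    for pid in np.unique(protein_ids):
        members = protein_ids == pid
        spiked[members] = spiked[np.argmax(members)]
        contaminant[members] = contaminant[np.argmax(members)]

    species = pd.DataFrame({
        "species_id": np.arange(n),
        "sequence": sequences,
        "charge": charges,
        "mz_true": mz_true,
        "rt_true": rt_true,
        "base_abundance": base_abundance,
        "protein": protein_ids,
        "spiked": spiked,
        "contaminant": contaminant,
        "interfered": interfered,
    })

    drift_fns: dict[str, Callable] = {}
    ppm_fns: dict[str, Callable] = {}
    ion_maps: dict[str, SampleIonMap] = {}
    tables: dict[str, pd.DataFrame] = {}
    cell_rows: list[dict] = []
    count_rows: list[dict] = []

    absent = rng.random((n, config.n_samples)) < config.absent_fraction
    identified = (rng.random((n, config.n_samples)) >= config.id_dropout_rate) \
        & ~absent
    leaves_unknown = rng.random((n, config.n_samples)) < config.unknown_feature_rate
    abundance_noise = np.exp(rng.normal(0.0, 0.05, size=(n, config.n_samples)))

    for j, sid in enumerate(sample_ids):
        s_rng = np.random.default_rng((config.seed, 1000 + j))
        drift = _make_drift(s_rng, config.rt_drift_amplitude, config.rt_range)
        ppm = _make_ppm_error(s_rng, config.mz_error_ppm, config.rt_range)
        drift_fns[sid] = drift
        ppm_fns[sid] = ppm
        group = groups[j]

        rt_parts: list[np.ndarray] = []
        mz_parts: list[np.ndarray] = []
        int_parts: list[np.ndarray] = []
        n_species_ions = 0
        n_isotope_ions = 0
        n_interference_ions = 0
        feat_rows: list[dict] = []

        for i in range(n):
            ratio = config.spike_ratio if (spiked[i] and group == "B") else 1.0
            abundance = base_abundance[i] * ratio * abundance_noise[i, j]
            apex = rt_true[i] + float(drift(rt_true[i]))
            if absent[i, j]:
                cell_rows.append({
                    "species_id": i, "sample_id": sid,
                    "rt_drifted": apex,
                    "mz_drifted": float(mz_true[i] * (1.0 + ppm(apex) * 1e-6)),
                    "abundance": 0.0, "present": False,
                    "identified": False, "has_feature_row": False,
                })
                continue
            sigma = config.elution_sigma_rt
            sel = np.abs(scan_times - apex) <= 3.5 * sigma
            t = scan_times[sel]
            if t.size == 0:
                continue
            profile = abundance * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
            profile = profile * np.exp(s_rng.normal(0.0, 0.05, size=t.size))
            mz_obs = (mz_true[i] * (1.0 + ppm(t) * 1e-6)
                      + s_rng.normal(0.0, config.mz_sigma, size=t.size))
            rt_parts.append(t)
            mz_parts.append(mz_obs)
            int_parts.append(profile)
            n_species_ions += t.size

            if config.isotope_enabled:
                iso_mz = (
                    (mz_true[i] + 1.002 / charges[i]) * (1.0 + ppm(t) * 1e-6)
                    + s_rng.normal(0.0, config.mz_sigma, size=t.size)
                )
                iso_int = profile * config.isotope_relative_intensity
                rt_parts.append(t.copy())
                mz_parts.append(iso_mz)
                int_parts.append(iso_int)
                n_isotope_ions += t.size

            if interfered[i]:
                # distinct interference cluster 5 sigma away in RT, close
                # enough in m/z to compete during peak selection
                i_apex = apex + 5.0 * sigma
                i_sel = np.abs(scan_times - i_apex) <= 3.5 * sigma
                ti = scan_times[i_sel]
                if ti.size:
                    prof_i = (abundance * 1.5
                              * np.exp(-0.5 * ((ti - i_apex) / sigma) ** 2))
                    mz_i = (mz_true[i] * (1.0 + ppm(ti) * 1e-6)
                            + s_rng.normal(0.0, config.mz_sigma, size=ti.size))
                    rt_parts.append(ti)
                    mz_parts.append(mz_i)
                    int_parts.append(prof_i)
                    n_interference_ions += ti.size

            mz_drifted_apex = float(mz_true[i] * (1.0 + ppm(apex) * 1e-6))
            cell_rows.append({
                "species_id": i,
                "sample_id": sid,
                "rt_drifted": apex,
                "mz_drifted": mz_drifted_apex,
                "abundance": abundance,
                "present": True,
                "identified": bool(identified[i, j]),
                "has_feature_row": bool(identified[i, j] or leaves_unknown[i, j]),
            })

            if identified[i, j] or leaves_unknown[i, j]:
                feat_rows.append({
                    "sequence": sequences[i] if identified[i, j] else "",
                    "modifications": "",
                    "charge": int(charges[i]),
                    "mz_calibrated": mz_true[i]
                    + float(s_rng.normal(0.0, config.mz_sigma / 4)),
                    "mz_uncalibrated": mz_drifted_apex,
                    "rt": apex + float(s_rng.normal(0.0, 0.02 * sigma)),
                    "rt_peak_width": 4.0 * sigma * float(s_rng.uniform(0.9, 1.2)),
                    "intensity": abundance,
                    "resolution": 60000.0 * np.sqrt(400.0 / mz_true[i]),
                    "protein": protein_ids[i] if identified[i, j] else "",
                    "is_contaminant": bool(contaminant[i]) if identified[i, j] else False,
                    "is_reverse": False,
                })

        # --- background ions ---------------------------------------------
        area = (rt_hi - rt_lo) * (mz_hi - mz_lo)
        n_bg = int(s_rng.poisson(config.noise_ion_density * area))
        if n_bg:
            bg_rt = scan_times[s_rng.integers(0, scan_times.size, size=n_bg)]
            bg_mz = s_rng.uniform(mz_lo, mz_hi, size=n_bg)
            bg_int = np.exp(s_rng.normal(config.intensity_log_mean - 4.0,
                                         0.7, size=n_bg))
            rt_parts.append(bg_rt)
            mz_parts.append(bg_mz)
            int_parts.append(bg_int)

        if rt_parts:
            ion_maps[sid] = SampleIonMap(
                sid,
                np.concatenate(rt_parts),
                np.concatenate(mz_parts),
                np.concatenate(int_parts),
            )
        else:
            ion_maps[sid] = SampleIonMap(sid, [], [], [])
        tables[sid] = pd.DataFrame(
            feat_rows,
            columns=["sequence", "modifications", "charge", "mz_calibrated",
                     "mz_uncalibrated", "rt", "rt_peak_width", "intensity",
                     "resolution", "protein", "is_contaminant", "is_reverse"],
        )
        count_rows.append({
            "sample_id": sid,
            "n_species_ions": n_species_ions,
            "n_isotope_ions": n_isotope_ions,
            "n_background_ions": n_bg,
            "n_interference_ions": n_interference_ions,
            "n_total": n_species_ions + n_isotope_ions + n_bg
            + n_interference_ions,
        })

    truth = GroundTruth(
        species=species,
        cells=pd.DataFrame(cell_rows),
        drift_functions=drift_fns,
        ppm_functions=ppm_fns,
        ion_counts=pd.DataFrame(count_rows),
    )
    return ion_maps, tables, truth


def detected_features(
    tables: dict[str, pd.DataFrame],
) -> dict[str, list[DetectedFeature]]:
    """Parse generated feature tables through the generic-dialect reader."""
    import io as _io

    out: dict[str, list[DetectedFeature]] = {}
    for sid, df in tables.items():
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        out[sid] = list(read_feature_table(buf, sid, "generic"))
    return out


# --------------------------------------------------------------------------
# Evaluation against truth
# --------------------------------------------------------------------------

def evaluate_against_truth(
    peptide_table: pd.DataFrame,
    truth: GroundTruth,
    sample_ids: list[str],
    peak_positions: pd.DataFrame | None = None,
    rt_tolerance: float = 0.15,
    mz_tolerance_ppm: float = 10.0,
) -> dict[str, float]:
    """Compare pipeline output against ground truth.

    ``peptide_table`` must carry ``sequence`` and ``charge`` columns plus
    one intensity column per sample.  ``peak_positions`` (optional) is a
    long table with columns feature sequence/charge/sample_id/peak_rt/peak_mz
    used for the wrong-window rate.

    Returns missing-value rate, median per-species absolute log2-ratio
    error between groups (where spike ratios exist), and wrong-window rate.
    """
    key = truth.species.set_index(["sequence", "charge"])
    matched = peptide_table[
        peptide_table.set_index(["sequence", "charge"]).index.isin(key.index)
    ]
    if matched.empty:
        raise ValueError("no species of the truth set found in the peptide table")

    quant = matched[sample_ids].to_numpy(dtype=float)
    missing_rate = float(np.mean(~np.isfinite(quant) | (quant <= 0)))

    metrics = {"missing_value_rate": missing_rate,
               "n_matched_species": int(len(matched))}

    if peak_positions is not None and len(peak_positions):
        cells = truth.cells.merge(
            truth.species[["species_id", "sequence", "charge"]], on="species_id"
        )
        merged = peak_positions.merge(
            cells, on=["sequence", "charge", "sample_id"], how="inner"
        )
        if len(merged):
            d_rt = np.abs(merged["peak_rt"] - merged["rt_drifted"])
            d_ppm = (np.abs(merged["peak_mz"] - merged["mz_drifted"])
                     / merged["mz_drifted"] * 1e6)
            wrong = (d_rt > rt_tolerance) | (d_ppm > mz_tolerance_ppm)
            metrics["wrong_window_rate"] = float(np.mean(wrong))
            metrics["n_windows_checked"] = int(len(merged))

    return metrics


# --------------------------------------------------------------------------
# File emission (same dialects io_formats reads)
# --------------------------------------------------------------------------

def write_mzxml(ion_map: SampleIonMap, path: str | Path) -> Path:
    """Write a minimal centroided mzXML file (MS1 scans only, 32-bit peaks)."""
    path = Path(path)
    rts, inverse = np.unique(ion_map.rt, return_inverse=True)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{rts.size}">',
    ]
    for s, rt in enumerate(rts):
        idx = np.nonzero(inverse == s)[0]
        order = idx[np.argsort(ion_map.mz[idx])]
        interleaved = np.empty(2 * order.size, dtype=">f4")
        interleaved[0::2] = ion_map.mz[order]
        interleaved[1::2] = ion_map.intensity[order]
        payload = base64.b64encode(interleaved.tobytes()).decode("ascii")
        lines.append(
            f'  <scan num="{s + 1}" msLevel="1" centroided="1" '
            f'peaksCount="{order.size}" retentionTime="PT{rt * 60.0:.6f}S">'
        )
        lines.append(
            '   <peaks precision="32" byteOrder="network" '
            f'contentType="m/z-int">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines.append(" </msRun>")
    lines.append("</mzXML>")
    path.write_text("\n".join(lines) + "\n", encoding="ascii")
    return path


def write_dataset(
    ion_maps: dict[str, SampleIonMap],
    tables: dict[str, pd.DataFrame],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Persist a synthetic dataset as mzXML + tab-delimited tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, ion_map in ion_maps.items():
        paths[f"mzxml:{sid}"] = write_mzxml(ion_map, out_dir / f"{sid}.mzXML")
    for sid, table in tables.items():
        paths[f"features:{sid}"] = write_table(
            table, out_dir / f"{sid}.features.tsv"
        )
    paths["truth:species"] = write_table(truth.species, out_dir / "truth_species.tsv")
    paths["truth:cells"] = write_table(truth.cells, out_dir / "truth_cells.tsv")
    return paths
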