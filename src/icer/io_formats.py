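"""Readers and writers for MS1 ion maps and feature tables.

Supported external formats:

* centroided mzXML (read only, MS1 scans only),
* MaxQuant-dialect tab-delimited feature tables (``allpeptides``,
  ``evidence`` or a ``generic`` dialect),
* tab-delimited result tables (``"\\t"`` separator, ``"."`` decimal,
  one header row).

Retention times are minutes everywhere; mzXML times recorded in seconds
are converted at parse time.  All extraction windows are closed on both
ends, so boundary ties are included.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd

__all__ = [
    "IonObservation",
    "SampleIonMap",
    "DetectedFeature",
    "MzXmlParseError",
    "read_ms1_map",
    "read_feature_table",
    "write_quant_tables",
    "read_table",
    "write_table",
]


class MzXmlParseError(ValueError):
    """Raised for malformed mzXML input; carries the byte offset if known."""


@dataclass(frozen=True)
class IonObservation:
    """A single centroided MS1 ion."""

    sample_id: str
    rt: float  # minutes
    mz: float  # Th
    intensity: float
    im: float | None = None  # inverse reduced mobility (1/K0), optional

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"rt must be >= 0, got {self.rt}")
        if self.mz <= 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


class SampleIonMap:
    """Centroided MS1 ion cloud of one sample, queryable by RT x m/z window.

    Ions are stored as parallel numpy arrays sorted by retention time so
    that window queries run in O(log n + k).
    """

    def __init__(
        self,
        sample_id: str,
        rt: np.ndarray | Sequence[float],
        mz: np.ndarray | Sequence[float],
        intensity: np.ndarray | Sequence[float],
        im: np.ndarray | Sequence[float] | None = None,
    ) -> None:
        rt = np.asarray(rt, dtype=float)
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if not (rt.shape == mz.shape == intensity.shape):
            raise ValueError("rt, mz and intensity must have equal length")
        if im is not None:
            im = np.asarray(im, dtype=float)
            if im.shape != rt.shape:
                raise ValueError("im must match rt length")
        order = np.argsort(rt, kind="stable")
        self.sample_id = sample_id
        self.rt = rt[order]
        self.mz = mz[order]
        self.intensity = intensity[order]
        self.im = im[order] if im is not None else None

    def __len__(self) -> int:
        return self.rt.size

    @property
    def rt_range(self) -> tuple[float, float]:
        if len(self) == 0:
            return (0.0, 0.0)
        return (float(self.rt[0]), float(self.rt[-1]))

    @property
    def mz_range(self) -> tuple[float, float]:
        if len(self) == 0:
            return (0.0, 0.0)
        return (float(self.mz.min()), float(self.mz.max()))

    def query(
        self,
        rt_lo: float,
        rt_hi: float,
        mz_lo: float,
        mz_hi: float,
        im_lo: float | None = None,
        im_hi: float | None = None,
    ) -> np.ndarray:
        """Indices of ions inside the closed window [rt_lo, rt_hi] x [mz_lo, mz_hi].

        When the map carries ion mobility and ``im_lo``/``im_hi`` are given,
        the closed IM interval is applied as an extra filter.
        """
        lo = int(np.searchsorted(self.rt, rt_lo, side="left"))
        hi = int(np.searchsorted(self.rt, rt_hi, side="right"))
        idx = np.arange(lo, hi)
        mask = (self.mz[idx] >= mz_lo) & (self.mz[idx] <= mz_hi)
        if im_lo is not None and im_hi is not None and self.im is not None:
            mask &= (self.im[idx] >= im_lo) & (self.im[idx] <= im_hi)
        return idx[mask]

    def iter_ions(self) -> Iterator[IonObservation]:
        for i in range(len(self)):
            yield IonObservation(
                self.sample_id,
                float(self.rt[i]),
                float(self.mz[i]),
                float(self.intensity[i]),
                float(self.im[i]) if self.im is not None else None,
            )


@dataclass
class DetectedFeature:
    """One per-sample feature from upstream feature detection.

    ``sequence`` is ``None`` for unknown (unsequenced) features.  The
    identity key when the sequence is present is
    ``(sequence, modifications, charge)``.
    """

    sample_id: str
    sequence: str | None
    modifications: str
    charge: int
    mz_calibrated: float
    mz_uncalibrated: float
    rt: float
    rt_peak_width: float
    intensity: float
    resolution: float
    is_contaminant: bool = False
    is_reverse: bool = False
    protein: str | None = None
    im: float | None = None

    @property
    def identity_key(self) -> tuple[str, str, int] | None:
        if self.sequence is None:
            return None
        return (self.sequence, self.modifications, self.charge)


# --------------------------------------------------------------------------
# mzXML reading
# --------------------------------------------------------------------------

def _parse_retention_time(value: str) -> float:
    """Parse an mzXML retentionTime attribute into minutes.

    Accepts xs:duration ('PT123.4S', 'PT2.5M') or a bare number of seconds.
    """
    v = value.strip()
    if v.startswith("PT"):
        body = v[2:]
        if body.endswith("S"):
            return float(body[:-1]) / 60.0
        if body.endswith("M"):
            return float(body[:-1])
        raise MzXmlParseError(f"unsupported duration {value!r}")
    return float(v) / 60.0


def _decode_peaks(
    text: str, precision: int, compression: str | None, byte_order: str
) -> tuple[np.ndarray, np.ndarray]:
    raw = base64.b64decode(text.strip().encode("ascii"))
    if compression and compression.lower() == "zlib":
        raw = zlib.decompress(raw)
    fmt = {32: "f", 64: "d"}.get(precision)
    if fmt is None:
        raise MzXmlParseError(f"unsupported peak precision {precision}")
    endian = "<" if byte_order.lower() in ("little", "lsb") else ">"
    width = precision // 8
    n = len(raw) // width
    values = np.array(struct.unpack(f"{endian}{n}{fmt}", raw[: n * width]))
    return values[0::2], values[1::2]  # m/z, intensity interleaved


def _local_name(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_ms1_map(path: str | Path, sample_id: str) -> SampleIonMap:
    """Read MS1 scans of a centroided mzXML file into a :class:`SampleIonMap`.

    Only scans with ``msLevel="1"`` contribute ions.  Each centroid peak
    becomes one ion with the RT of its scan, converted to minutes.  Files
    declaring profile-mode scans (``centroided="0"``) are rejected.
    """
    path = Path(path)
    rts: list[float] = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []

    try:
        context = ElementTree.iterparse(str(path), events=("start", "end"))
        scan_stack: list[dict] = []
        for event, elem in context:
            name = _local_name(elem.tag)
            if event == "start" and name == "scan":
                scan_stack.append(dict(elem.attrib))
            elif event == "end":
                if name == "peaks" and scan_stack:
                    attrs = scan_stack[-1]
                    if attrs.get("msLevel", "1") != "1":
                        continue
                    if attrs.get("centroided", "1") == "0":
                        raise MzXmlParseError(
                            f"{path}: non-centroided (profile) scans are not supported"
                        )
                    rt = _parse_retention_time(attrs.get("retentionTime", "PT0S"))
                    precision = int(elem.get("precision", "32"))
                    compression = elem.get("compressionType")
                    byte_order = elem.get("byteOrder", "network")
                    if byte_order == "network":
                        byte_order = "big"
                    mz, inten = _decode_peaks(
                        elem.text or "", precision, compression, byte_order
                    )
                    rts.append(rt)
                    mzs.append(mz)
                    intens.append(inten)
                    elem.clear()
                elif name == "scan":
                    if scan_stack:
                        scan_stack.pop()
                    elem.clear()
    except ElementTree.ParseError as exc:
        # exc.position is (line, column); report the file byte offset too
        offset = _byte_offset(path, exc.position)
        raise MzXmlParseError(
            f"{path}: malformed XML at byte offset {offset} "
            f"(line {exc.position[0]}, column {exc.position[1]}): {exc}"
        ) from exc

    if not rts:
        warnings.warn(f"{path}: no MS1 scans found; returning empty ion map")
        return SampleIonMap(sample_id, [], [], [])

    rt_arr = np.concatenate([np.full(m.size, t) for t, m in zip(rts, mzs)])
    return SampleIonMap(
        sample_id, rt_arr, np.concatenate(mzs), np.concatenate(intens)
    )


def _byte_offset(path: Path, position: tuple[int, int]) -> int:
    line_no, col = position
    offset = 0
    try:
        with open(path, "rb") as fh:
            for i, line in enumerate(fh, start=1):
                if i == line_no:
                    return offset + col
                offset += len(line)
    except OSError:
        pass
    return offset


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------

# Column mapping per dialect: internal field -> accepted column names.
_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "allpeptides": {
        "sequence": ("Sequence",),
        "modifications": ("Modifications",),
        "charge": ("Charge",),
        "mz_calibrated": ("m/z", "Calibrated m/z"),
        "mz_uncalibrated": ("Uncalibrated m/z",),
        "rt": ("Retention time",),
        "rt_peak_width": ("Retention length",),
        "intensity": ("Intensity",),
        "resolution": ("Resolution",),
        "protein": ("Proteins",),
        "is_contaminant": ("Potential contaminant",),
        "is_reverse": ("Reverse",),
        "im": ("1/K0",),
    },
    "evidence": {
        "sequence": ("Sequence",),
        "modifications": ("Modifications",),
        "charge": ("Charge",),
        "mz_calibrated": ("m/z",),
        "mz_uncalibrated": ("Uncalibrated m/z", "m/z"),
        "rt": ("Retention time",),
        "rt_peak_width": ("Retention length",),
        "intensity": ("Intensity",),
        "resolution": ("Resolution",),
        "protein": ("Leading razor protein", "Proteins"),
        "is_contaminant": ("Potential contaminant",),
        "is_reverse": ("Reverse",),
        "im": ("1/K0",),
    },
    "generic": {
        "sequence": ("sequence",),
        "modifications": ("modifications",),
        "charge": ("charge",),
        "mz_calibrated": ("mz_calibrated",),
        "mz_uncalibrated": ("mz_uncalibrated",),
        "rt": ("rt",),
        "rt_peak_width": ("rt_peak_width",),
        "intensity": ("intensity",),
        "resolution": ("resolution",),
        "protein": ("protein",),
        "is_contaminant": ("is_contaminant",),
        "is_reverse": ("is_reverse",),
        "im": ("im",),
    },
}

_REQUIRED = ("charge", "mz_calibrated", "rt", "rt_peak_width", "intensity")
_OPTIONAL_DEFAULTS = {
    "sequence": None,
    "modifications": "",
    "mz_uncalibrated": None,
    "resolution": float("nan"),
    "protein": None,
    "is_contaminant": False,
    "is_reverse": False,
    "im": None,
}


class FeatureTableError(ValueError):
    """Configuration error for feature-table parsing (e.g. missing column)."""


@dataclass
class FeatureTableResult:
    features: list[DetectedFeature]
    n_dropped: int = 0

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


def _resolve_columns(header: Sequence[str], dialect: str) -> dict[str, str]:
    try:
        mapping = _DIALECTS[dialect]
    except KeyError:
        raise FeatureTableError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        ) from None
    resolved: dict[str, str] = {}
    for fieldname, candidates in mapping.items():
        for cand in candidates:
            if cand in header:
                resolved[fieldname] = cand
                break
    missing = [f for f in _REQUIRED if f not in resolved]
    if missing:
        names = ", ".join(
            f"{f} (expected column {mapping[f][0]!r})" for f in missing
        )
        raise FeatureTableError(f"missing required column(s): {names}")
    return resolved


def _flag(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip() in ("+", "1", "True", "true", "yes")


def read_feature_table(
    path: str | Path, sample_id: str, dialect: str = "generic"
) -> FeatureTableResult:
    """Parse a tab-delimited feature table into :class:`DetectedFeature` rows.

    Rows whose required numeric fields do not parse are dropped and counted
    in ``n_dropped``.  Sequence-absent rows are retained as unknown features.
    ``path`` may be a filesystem path or any readable text buffer.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), dialect)

    features: list[DetectedFeature] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            charge = int(float(row[cols["charge"]]))
            mz_cal = float(row[cols["mz_calibrated"]])
            rt = float(row[cols["rt"]])
            width = float(row[cols["rt_peak_width"]])
            intensity = float(row[cols["intensity"]])
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        if not all(np.isfinite([mz_cal, rt, width, intensity])):
            n_dropped += 1
            continue

        def opt(fieldname: str):
            col = cols.get(fieldname)
            if col is None:
                return _OPTIONAL_DEFAULTS[fieldname]
            return row[col]

        seq_raw = opt("sequence")
        sequence = None
        if seq_raw is not None:
            s = str(seq_raw).strip()
            if s and s not in ("NA", "nan", " "):
                sequence = s
        mz_uncal_raw = opt("mz_uncalibrated")
        try:
            mz_uncal = float(mz_uncal_raw)
            if not np.isfinite(mz_uncal):
                mz_uncal = mz_cal
        except (ValueError, TypeError):
            mz_uncal = mz_cal
        try:
            resolution = float(opt("resolution"))
        except (ValueError, TypeError):
            resolution = float("nan")
        im_raw = opt("im")
        try:
            im = float(im_raw) if im_raw not in (None, "") else None
        except (ValueError, TypeError):
            im = None
        protein_raw = opt("protein")
        protein = str(protein_raw).strip() or None if protein_raw is not None else None

        features.append(
            DetectedFeature(
                sample_id=sample_id,
                sequence=sequence,
                modifications=str(opt("modifications") or ""),
                charge=charge,
                mz_calibrated=mz_cal,
                mz_uncalibrated=mz_uncal,
                rt=rt,
                rt_peak_width=width,
                intensity=intensity,
                resolution=resolution,
                is_contaminant=_flag(opt("is_contaminant")),
                is_reverse=_flag(opt("is_reverse")),
                protein=protein,
                im=im,
            )
        )
    return FeatureTableResult(features, n_dropped)


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as tab-delimited UTF-8 text with '.' decimals."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_quant_tables(
    peptide_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the peptide and protein quantification tables.

    Returns the two file paths.  Tables round-trip through
    :func:`read_table` with at least 6 significant digits.
    """
    if peptide_table is None or protein_table is None:
        raise ValueError("tables must be non-null")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pep_path = write_table(peptide_table, out_dir / "peptides.tsv")
    prot_path = write_table(protein_table, out_dir / "proteins.tsv")
    return pep_path, prot_path
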