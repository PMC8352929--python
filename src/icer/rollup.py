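"""Peptide-to-protein rollup: filtering, median normalization, aggregation.

Contaminant and reverse rows are dropped before anything else; proteins
need at least ``min_peptides`` distinct peptides overall, and a protein
cell is reported for a sample only when at least that many peptide
quantifications contribute there.  Rollup methods: ``top3`` (mean of the
up-to-3 most intense peptides), ``sum``, and ``maxlfq`` (least-squares
reconstruction from median pairwise peptide log-ratios, minimum ratio
count 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_tables",
    "normalize_median",
    "aggregate_protein",
]


def filter_tables(
    peptide_table: pd.DataFrame,
    sample_ids: list[str],
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Drop contaminant/reverse peptides and under-supported proteins."""
    if "protein" not in peptide_table.columns:
        raise ValueError("peptide table needs a 'protein' column for rollup")
    df = peptide_table.copy()
    for col in ("is_contaminant", "is_reverse"):
        if col in df.columns:
            flags = np.array([bool(v) if pd.notna(v) else False
                              for v in df[col]])
            df = df[~flags]
    df = df[df["protein"].notna() & (df["protein"] != "")]

    counts = df.groupby("protein")["sequence"].nunique()
    keep = counts[counts >= min_peptides].index
    return df[df["protein"].isin(keep)].reset_index(drop=True)


def normalize_median(
    table: pd.DataFrame,
    sample_ids: list[str],
    reference_rows: pd.Series | np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample so that reference-row medians agree across samples.

    ``reference_rows`` is a boolean mask selecting the rows used to compute
    the factors (e.g. constant background peptides in spike-in designs);
    default is all rows.  Returns the normalized table and the factors.
    """
    ref = table if reference_rows is None else table[np.asarray(reference_rows)]
    medians = {}
    for sid in sample_ids:
        vals = pd.to_numeric(ref[sid], errors="coerce")
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.empty:
            raise ValueError(f"sample {sid}: no reference values to normalize on")
        medians[sid] = float(np.median(vals))
    target = float(np.median(list(medians.values())))
    factors = pd.Series({sid: target / m for sid, m in medians.items()},
                        name="factor")
    out = table.copy()
    for sid in sample_ids:
        out[sid] = pd.to_numeric(out[sid], errors="coerce") * factors[sid]
    return out, factors


def _top3(values: np.ndarray) -> float:
    vals = values[np.isfinite(values) & (values > 0)]
    if vals.size == 0:
        return float("nan")
    top = np.sort(vals)[::-1][:3]
    return float(np.mean(top))


def _sum(values: np.ndarray) -> float:
    vals = values[np.isfinite(values) & (values > 0)]
    if vals.size == 0:
        return float("nan")
    return float(vals.sum())


def _maxlfq(matrix: np.ndarray, min_ratio_count: int = 2) -> np.ndarray:
    """Least-squares abundance profile from median pairwise log-ratios.

    ``matrix`` is peptides x samples (raw intensities, NaN = missing).
    Anchored per connected component so the mean log-abundance equals the
    mean log of the per-sample peptide sums.
    """
    n_pep, n_s = matrix.shape
    log_m = np.where(np.isfinite(matrix) & (matrix > 0), np.log(matrix), np.nan)

    ratios: dict[tuple[int, int], float] = {}
    for a in range(n_s):
        for b in range(a + 1, n_s):
            both = np.isfinite(log_m[:, a]) & np.isfinite(log_m[:, b])
            if both.sum() >= min_ratio_count:
                ratios[(a, b)] = float(np.median(log_m[both, a] - log_m[both, b]))

    result = np.full(n_s, np.nan)
    has_data = np.isfinite(log_m).any(axis=0)

    # connected components of the ratio graph
    parent = list(range(n_s))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (a, b) in ratios:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    comps: dict[int, list[int]] = {}
    for s in range(n_s):
        if has_data[s]:
            comps.setdefault(find(s), []).append(s)

    for members in comps.values():
        members = sorted(members)
        idx = {s: k for k, s in enumerate(members)}
        m = len(members)
        sums = np.array([np.nansum(np.where(np.isfinite(log_m[:, s]),
                                            np.exp(log_m[:, s]), 0.0))
                         for s in members])
        anchor = float(np.mean(np.log(np.maximum(sums, 1e-300))))
        if m == 1:
            result[members[0]] = np.exp(anchor)
            continue
        rows = []
        rhs = []
        for (a, b), r in ratios.items():
            if a in idx and b in idx:
                row = np.zeros(m)
                row[idx[a]], row[idx[b]] = 1.0, -1.0
                rows.append(row)
                rhs.append(r)
        # anchor equation ties the mean to the summed input
        rows.append(np.full(m, 1.0 / m) * np.sqrt(m))
        rhs.append(anchor * np.sqrt(m))
        A = np.vstack(rows)
        y = np.asarray(rhs)
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        for s in members:
            result[s] = np.exp(sol[idx[s]])
    return result


def aggregate_protein(
    peptide_table: pd.DataFrame,
    sample_ids: list[str],
    method: str = "top3",
    min_peptides: int = 2,
    min_ratio_count: int = 2,
) -> pd.DataFrame:
    """Aggregate peptide rows to one row per protein.

    Cells with fewer than ``min_peptides`` contributing peptide
    quantifications are reported missing.  Also emits per-cell
    ``n_peptides_<sample>`` columns.
    """
    if method not in ("top3", "sum", "maxlfq"):
        raise ValueError(
            f"unknown rollup method {method!r}; expected top3, sum or maxlfq"
        )
    rows = []
    for protein, grp in peptide_table.groupby("protein", sort=True):
        matrix = grp[sample_ids].apply(pd.to_numeric, errors="coerce").to_numpy()
        matrix = np.where(matrix > 0, matrix, np.nan)
        n_contrib = np.isfinite(matrix).sum(axis=0)
        if method == "maxlfq":
            values = _maxlfq(matrix, min_ratio_count)
        else:
            agg = _top3 if method == "top3" else _sum
            values = np.array([agg(matrix[:, k]) for k in range(len(sample_ids))])
        values = np.where(n_contrib >= min_peptides, values, np.nan)
        row = {"protein": protein, "n_peptides": int(grp["sequence"].nunique())}
        for k, sid in enumerate(sample_ids):
            row[sid] = values[k]
            row[f"n_peptides_{sid}"] = int(n_contrib[k])
        rows.append(row)
    return pd.DataFrame(rows)
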