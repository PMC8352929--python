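"""Consensus feature assembly and feature-based identity propagation.

Per-sample detected features sharing (sequence, modifications, charge)
are aggregated into consensus features at their cross-sample median RT
and calibrated m/z.  Contributors deviating from those medians by more
than the alignment windows are excluded and the medians recomputed once.
Sequence-less features inside a consensus window are attached.  Each
target gets a decoy companion (windows x 5 offset) and, by default, a
+1-isotope companion at ``+1.002/charge`` Th.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentWindows
from .io_formats import DetectedFeature

__all__ = [
    "ConsensusFeature",
    "aggregate_features",
    "merge_overlapping",
    "generate_decoys",
    "generate_isotope_features",
    "propagate_identities",
    "consensus_table",
]

SEQUENCED_HERE = "sequenced_here"
FEATURE_PROPAGATED = "feature_propagated"
TO_RECOVER = "to_recover_by_ion_PIP"

ISOTOPE_DELTA = 1.002  # Th per charge
DECOY_OFFSET_MULTIPLIER = 5
MAX_DECOY_SHIFTS = 10


def normalize_modifications(mods: str) -> str:
    """Canonical PTM string: individual entries sorted."""
    parts = [p.strip() for p in str(mods or "").split(";") if p.strip()]
    return ";".join(sorted(parts))


@dataclass
class ConsensusFeature:
    id: int
    sequence: str | None
    modifications: str
    charge: int
    mz_ref: float
    rt_ref: float
    rt_peak_width: float
    contributors: dict[str, list[DetectedFeature]] = field(default_factory=dict)
    kind: str = "target"  # target | decoy | isotope_plus1
    parent_id: int | None = None
    protein: str | None = None
    sample_status: dict[str, str] = field(default_factory=dict)

    @property
    def is_sequenced(self) -> bool:
        return self.sequence is not None

    def contributing_samples(self) -> set[str]:
        return set(self.contributors)

    def rt_extent(self) -> tuple[float, float]:
        half = self.rt_peak_width / 2.0
        return (self.rt_ref - half, self.rt_ref + half)


def _consensus_from_members(
    cid: int, key: tuple[str, str, int] | None, members: list[DetectedFeature]
) -> ConsensusFeature:
    rts = np.array([f.rt for f in members])
    mzs = np.array([f.mz_calibrated for f in members])
    contributors: dict[str, list[DetectedFeature]] = defaultdict(list)
    for f in members:
        contributors[f.sample_id].append(f)
    proteins = [f.protein for f in members if f.protein]
    return ConsensusFeature(
        id=cid,
        sequence=key[0] if key else None,
        modifications=key[1] if key else "",
        charge=key[2] if key else members[0].charge,
        mz_ref=float(np.median(mzs)),
        rt_ref=float(np.median(rts)),
        rt_peak_width=float(max(f.rt_peak_width for f in members)),
        contributors=dict(contributors),
        protein=proteins[0] if proteins else None,
    )


def aggregate_features(
    features: dict[str, list[DetectedFeature]],
    windows: AlignmentWindows,
    aggregate_unknown: bool = False,
) -> list[ConsensusFeature]:
    """Build consensus features from per-sample detected features.

    Median exclusion runs exactly once: after dropping contributors outside
    ``median +- window`` the medians are recomputed, and unknown-feature
    attachment uses those final medians.
    """
    windows.resolved()
    rt_w, mz_w = windows.rt_window, windows.mz_window

    by_key: dict[tuple[str, str, int], list[DetectedFeature]] = defaultdict(list)
    unknown: list[DetectedFeature] = []
    for feats in features.values():
        for f in feats:
            if f.sequence is not None:
                key = (f.sequence, normalize_modifications(f.modifications), f.charge)
                by_key[key].append(f)
            else:
                unknown.append(f)

    consensus: list[ConsensusFeature] = []
    next_id = itertools.count()
    for key, members in sorted(by_key.items()):
        rts = np.array([f.rt for f in members])
        mzs = np.array([f.mz_calibrated for f in members])
        rt_med, mz_med = np.median(rts), np.median(mzs)
        keep = [
            f for f, r, m in zip(members, rts, mzs)
            if abs(r - rt_med) <= rt_w and abs(m - mz_med) <= mz_w
        ]
        if not keep:
            continue
        consensus.append(_consensus_from_members(next(next_id), key, keep))

    # attach unknown features that fall inside a consensus window (final medians)
    claimed: set[int] = set()
    if unknown and consensus:
        mz_refs = np.array([c.mz_ref for c in consensus])
        order = np.argsort(mz_refs)
        mz_sorted = mz_refs[order]
        for ui, f in enumerate(unknown):
            lo = np.searchsorted(mz_sorted, f.mz_calibrated - mz_w, side="left")
            hi = np.searchsorted(mz_sorted, f.mz_calibrated + mz_w, side="right")
            best: ConsensusFeature | None = None
            best_d = np.inf
            for oi in range(lo, hi):
                c = consensus[order[oi]]
                if c.charge != f.charge:
                    continue
                if abs(f.rt - c.rt_ref) > rt_w:
                    continue
                d = abs(f.mz_calibrated - c.mz_ref) / mz_w + abs(f.rt - c.rt_ref) / rt_w
                if d < best_d:
                    best, best_d = c, d
            if best is not None:
                best.contributors.setdefault(f.sample_id, []).append(f)
                best.rt_peak_width = max(best.rt_peak_width, f.rt_peak_width)
                claimed.add(ui)

    if aggregate_unknown and unknown:
        leftovers = [f for ui, f in enumerate(unknown) if ui not in claimed]
        consensus.extend(_aggregate_unknown(leftovers, rt_w, mz_w, next_id))

    return consensus


def _aggregate_unknown(
    leftovers: list[DetectedFeature], rt_w: float, mz_w: float, next_id
) -> list[ConsensusFeature]:
    """Greedy clustering of leftover unknown features by charge and windows."""
    out: list[ConsensusFeature] = []
    by_charge: dict[int, list[DetectedFeature]] = defaultdict(list)
    for f in leftovers:
        by_charge[f.charge].append(f)
    for charge, feats in sorted(by_charge.items()):
        feats = sorted(feats, key=lambda f: (f.mz_calibrated, f.rt))
        cluster: list[DetectedFeature] = []
        for f in feats:
            if cluster and (
                abs(f.mz_calibrated - cluster[0].mz_calibrated) > mz_w
                or abs(f.rt - cluster[0].rt) > rt_w
            ):
                out.append(_consensus_from_members(next(next_id), None, cluster))
                cluster = []
            cluster.append(f)
        if cluster:
            out.append(_consensus_from_members(next(next_id), None, cluster))
    return out


def merge_overlapping(
    consensus: list[ConsensusFeature], delta_mass: float = 0.002
) -> list[ConsensusFeature]:
    """Transitively merge same-charge features with close m/z and
    overlapping RT extents.

    Features with conflicting sequences are left unmerged (conflict logged
    as a warning).
    """
    n = len(consensus)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: consensus[i].mz_ref)
    conflicts = 0
    for a_pos in range(n):
        i = order[a_pos]
        ci = consensus[i]
        for b_pos in range(a_pos + 1, n):
            j = order[b_pos]
            cj = consensus[j]
            if cj.mz_ref - ci.mz_ref >= delta_mass:
                break
            if ci.charge != cj.charge:
                continue
            lo_i, hi_i = ci.rt_extent()
            lo_j, hi_j = cj.rt_extent()
            if hi_i < lo_j or hi_j < lo_i:
                continue
            if (ci.sequence is not None and cj.sequence is not None
                    and (ci.sequence, ci.modifications) != (cj.sequence, cj.modifications)):
                conflicts += 1
                continue
            union(i, j)
    if conflicts:
        warnings.warn(f"{conflicts} overlapping feature pairs with conflicting "
                      "sequences left unmerged")

    groups: dict[int, list[ConsensusFeature]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(consensus[i])

    merged: list[ConsensusFeature] = []
    for root in sorted(groups):
        members = groups[root]
        if len(members) == 1:
            merged.append(members[0])
            continue
        sequenced = [m for m in members if m.sequence is not None]
        head = sequenced[0] if sequenced else members[0]
        contributors: dict[str, list[DetectedFeature]] = defaultdict(list)
        for m in members:
            for sid, feats in m.contributors.items():
                contributors[sid].extend(feats)
        all_feats = [f for feats in contributors.values() for f in feats]
        merged.append(ConsensusFeature(
            id=head.id,
            sequence=head.sequence,
            modifications=head.modifications,
            charge=head.charge,
            mz_ref=float(np.median([f.mz_calibrated for f in all_feats])),
            rt_ref=float(np.median([f.rt for f in all_feats])),
            rt_peak_width=float(max(f.rt_peak_width for f in all_feats)),
            contributors=dict(contributors),
            protein=head.protein,
        ))
    return merged


def _window_collision(
    rt: float, mz: float, targets: list[ConsensusFeature],
    rt_w: float, mz_w: float,
) -> bool:
    for t in targets:
        if (abs(rt - t.rt_ref) <= t.rt_peak_width / 2.0 + rt_w
                and abs(mz - t.mz_ref) <= 2.0 * mz_w):
            return True
    return False


def generate_decoys(
    consensus: list[ConsensusFeature],
    windows: AlignmentWindows,
    offset_multiplier: float = DECOY_OFFSET_MULTIPLIER,
    id_offset: int = 1_000_000,
) -> list[ConsensusFeature]:
    """One decoy per target, offset by ``offset_multiplier`` windows in both
    RT and m/z; decoys colliding with a target window are pushed further in
    m/z (up to :data:`MAX_DECOY_SHIFTS` extra windows, else dropped)."""
    windows.resolved()
    rt_w, mz_w = windows.rt_window, windows.mz_window
    decoys: list[ConsensusFeature] = []
    dropped = 0
    for c in consensus:
        rt = c.rt_ref + offset_multiplier * rt_w
        mz = c.mz_ref + offset_multiplier * mz_w
        for _ in range(MAX_DECOY_SHIFTS + 1):
            if not _window_collision(rt, mz, consensus, rt_w, mz_w):
                break
            mz += mz_w
        else:
            dropped += 1
            continue
        decoys.append(ConsensusFeature(
            id=c.id + id_offset,
            sequence=c.sequence,
            modifications=c.modifications,
            charge=c.charge,
            mz_ref=mz,
            rt_ref=rt,
            rt_peak_width=c.rt_peak_width,
            contributors={sid: [] for sid in c.contributors},
            kind="decoy",
            parent_id=c.id,
        ))
    if dropped:
        warnings.warn(f"{dropped} decoy features dropped: no collision-free slot")
    return decoys


def generate_isotope_features(
    consensus: list[ConsensusFeature],
    delta: float = ISOTOPE_DELTA,
    id_offset: int = 2_000_000,
) -> list[ConsensusFeature]:
    """+1-isotope companion per target at ``mz_ref + delta/charge``."""
    isotopes: list[ConsensusFeature] = []
    skipped = 0
    for c in consensus:
        if not c.charge or c.charge < 1:
            skipped += 1
            continue
        isotopes.append(ConsensusFeature(
            id=c.id + id_offset,
            sequence=c.sequence,
            modifications=c.modifications,
            charge=c.charge,
            mz_ref=c.mz_ref + delta / c.charge,
            rt_ref=c.rt_ref,
            rt_peak_width=c.rt_peak_width,
            contributors={sid: list(v) for sid, v in c.contributors.items()},
            kind="isotope_plus1",
            parent_id=c.id,
        ))
    if skipped:
        warnings.warn(f"{skipped} features without charge skipped for isotopes")
    return isotopes


def propagate_identities(
    consensus: list[ConsensusFeature], sample_ids: list[str]
) -> list[ConsensusFeature]:
    """Label every sample of each sequenced consensus feature.

    ``sequenced_here`` when the sample contributed a sequenced feature,
    ``feature_propagated`` when it contributed only unknown features, and
    ``to_recover_by_ion_PIP`` otherwise.
    """
    for c in consensus:
        if not c.is_sequenced:
            c.sample_status = {
                sid: (FEATURE_PROPAGATED if sid in c.contributors else TO_RECOVER)
                for sid in sample_ids
            }
            continue
        status: dict[str, str] = {}
        for sid in sample_ids:
            feats = c.contributors.get(sid, [])
            if any(f.sequence is not None for f in feats):
                status[sid] = SEQUENCED_HERE
            elif feats:
                status[sid] = FEATURE_PROPAGATED
            else:
                status[sid] = TO_RECOVER
        c.sample_status = status
    return consensus


def consensus_table(consensus: list[ConsensusFeature]) -> pd.DataFrame:
    rows = []
    for c in consensus:
        n_seq = sum(1 for s in c.sample_status.values() if s == SEQUENCED_HERE)
        n_prop = sum(1 for s in c.sample_status.values() if s == FEATURE_PROPAGATED)
        rows.append({
            "id": c.id,
            "kind": c.kind,
            "sequence": c.sequence or "",
            "modifications": c.modifications,
            "charge": c.charge,
            "mz_ref": c.mz_ref,
            "rt_ref": c.rt_ref,
            "rt_peak_width": c.rt_peak_width,
            "protein": c.protein or "",
            "n_samples_sequenced": n_seq,
            "n_samples_propagated": n_prop,
        })
    return pd.DataFrame(rows)
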