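import itertools

import numpy as np
import pytest

from icer.alignment import AlignmentWindows
from icer.feature_assembly import (
    FEATURE_PROPAGATED,
    SEQUENCED_HERE,
    TO_RECOVER,
    aggregate_features,
    consensus_table,
    generate_decoys,
    generate_isotope_features,
    merge_overlapping,
    normalize_modifications,
    propagate_identities,
)
from icer.io_formats import DetectedFeature

WINDOWS = AlignmentWindows(rt_window=0.6, mz_window=0.001)


def _feature(sample_id, sequence, rt, mz, charge=2, width=0.3, mods=""):
    return DetectedFeature(
        sample_id=sample_id, sequence=sequence, modifications=mods,
        charge=charge, mz_calibrated=mz, mz_uncalibrated=mz, rt=rt,
        rt_peak_width=width, intensity=1e5, resolution=60000.0,
    )


class TestNormalizeModifications:
    def test_sorted_and_stripped(self):
        assert normalize_modifications("b; a") == "a;b"
        assert normalize_modifications("") == ""
        assert normalize_modifications(None) == ""


class TestAggregateFeatures:
    def test_median_reference(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0)],
            "B": [_feature("B", "PEPK", 50.1, 500.0)],
            "C": [_feature("C", "PEPK", 50.2, 500.0)],
        }
        (c,) = aggregate_features(features, WINDOWS)
        assert c.rt_ref == pytest.approx(50.1)
        assert c.mz_ref == pytest.approx(500.0)

    def test_out_of_window_contributor_excluded(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0)],
            "B": [_feature("B", "PEPK", 50.1, 500.0)],
            "C": [_feature("C", "PEPK", 52.0, 500.0)],  # 1.9 min off median
        }
        (c,) = aggregate_features(features, WINDOWS)
        assert "C" not in c.contributors
        assert len(c.contributors) == 2

    def test_unknown_feature_attached_in_window(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0)],
            "B": [_feature("B", "PEPK", 50.1, 500.0)],
            "C": [_feature("C", None, 50.05, 500.0003)],
        }
        (c,) = aggregate_features(features, WINDOWS)
        assert "C" in c.contributors
        assert c.contributors["C"][0].sequence is None

    def test_unknown_feature_outside_window_not_attached(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0)],
            "B": [_feature("B", "PEPK", 50.1, 500.0)],
            "C": [_feature("C", None, 50.05, 500.01)],  # 10 mz windows away
        }
        (c,) = aggregate_features(features, WINDOWS)
        assert "C" not in c.contributors

    def test_peak_width_is_max_of_contributors(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0, width=0.2)],
            "B": [_feature("B", "PEPK", 50.0, 500.0, width=0.5)],
        }
        (c,) = aggregate_features(features, WINDOWS)
        assert c.rt_peak_width == pytest.approx(0.5)

    def test_each_feature_in_at_most_one_consensus(self):
        features = {
            "A": [_feature("A", "AAK", 10.0, 500.0),
                  _feature("A", "CCK", 20.0, 600.0),
                  _feature("A", None, 10.01, 500.0002)],
            "B": [_feature("B", "AAK", 10.0, 500.0),
                  _feature("B", "CCK", 20.0, 600.0)],
        }
        consensus = aggregate_features(features, WINDOWS)
        seen = set()
        for c in consensus:
            for feats in c.contributors.values():
                for f in feats:
                    assert id(f) not in seen
                    seen.add(id(f))

    def test_permutation_invariance(self, rng):
        feats = []
        for i in range(20):
            for sid in ("A", "B", "C"):
                feats.append(_feature(sid, f"SEQ{i}K", 10.0 + i,
                                      450.0 + 3 * i))
        by_sample = {sid: [f for f in feats if f.sample_id == sid]
                     for sid in "ABC"}
        c1 = aggregate_features(by_sample, WINDOWS)
        shuffled = {sid: list(rng.permutation(v)) for sid, v in by_sample.items()}
        c2 = aggregate_features(shuffled, WINDOWS)
        k1 = sorted((c.sequence, c.rt_ref, c.mz_ref) for c in c1)
        k2 = sorted((c.sequence, c.rt_ref, c.mz_ref) for c in c2)
        assert k1 == k2

    def test_optional_unknown_aggregation(self):
        features = {
            "A": [_feature("A", None, 33.0, 700.0)],
            "B": [_feature("B", None, 33.1, 700.0002),
                  _feature("B", "PEPK", 10.0, 500.0)],
            "C": [_feature("C", "PEPK", 10.0, 500.0)],
        }
        default = aggregate_features(features, WINDOWS)
        assert len(default) == 1  # unknowns dropped by default
        with_unknown = aggregate_features(features, WINDOWS,
                                          aggregate_unknown=True)
        kinds = sorted((c.sequence is None, len(c.contributors))
                       for c in with_unknown)
        assert (True, 2) in kinds


class TestMergeOverlapping:
    def test_close_mz_overlapping_rt_merged(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0000)],
            "B": [_feature("B", None, 50.05, 500.0015)],
        }
        # force two consensus features, then merge
        consensus = aggregate_features(
            {"A": features["A"]}, WINDOWS
        ) + aggregate_features({"B": features["B"]}, WINDOWS,
                               aggregate_unknown=True)
        consensus[1].id = 1
        merged = merge_overlapping(consensus, delta_mass=0.002)
        assert len(merged) == 1
        assert merged[0].sequence == "PEPK"

    def test_distant_mz_not_merged(self):
        c1 = aggregate_features({"A": [_feature("A", "AAK", 50.0, 500.000)]},
                                WINDOWS)
        c2 = aggregate_features({"B": [_feature("B", "CCK", 50.0, 500.010)]},
                                WINDOWS)
        c2[0].id = 1
        assert len(merge_overlapping(c1 + c2)) == 2

    def test_conflicting_sequences_kept_separate(self):
        c1 = aggregate_features({"A": [_feature("A", "AAK", 50.0, 500.0000)]},
                                WINDOWS)
        c2 = aggregate_features({"B": [_feature("B", "CCK", 50.0, 500.0005)]},
                                WINDOWS)
        c2[0].id = 1
        with pytest.warns(UserWarning, match="conflicting"):
            merged = merge_overlapping(c1 + c2)
        assert len(merged) == 2

    def test_transitive_chain_matches_union_find_oracle(self):
        # A~B and B~C but A!~C by delta mass; closure must merge all three
        mzs = [500.0000, 500.0015, 500.0030]
        consensus = []
        for i, mz in enumerate(mzs):
            (c,) = aggregate_features(
                {"S": [_feature("S", None, 50.0, mz)]}, WINDOWS,
                aggregate_unknown=True)
            c.id = i
            consensus.append(c)

        def predicate(a, b):
            return (abs(a.mz_ref - b.mz_ref) < 0.002
                    and a.rt_extent()[0] <= b.rt_extent()[1]
                    and b.rt_extent()[0] <= a.rt_extent()[1])

        # oracle: brute-force transitive closure over the pairwise predicate
        groups = [{i} for i in range(3)]
        for i, j in itertools.combinations(range(3), 2):
            if predicate(consensus[i], consensus[j]):
                gi = next(g for g in groups if i in g)
                gj = next(g for g in groups if j in g)
                if gi is not gj:
                    gi |= gj
                    groups.remove(gj)
        assert len(groups) == 1
        assert not predicate(consensus[0], consensus[2])
        merged = merge_overlapping(consensus)
        assert len(merged) == len(groups) == 1


def _simple_consensus(n=3):
    features = {}
    for i in range(n):
        for sid in ("A", "B"):
            features.setdefault(sid, []).append(
                _feature(sid, f"SEQ{i}K", 20.0 + 5 * i, 500.0 + 10 * i,
                         width=0.4)
            )
    return aggregate_features(features, WINDOWS)


class TestGenerateDecoys:
    def test_offset_is_five_windows(self):
        consensus = aggregate_features(
            {"A": [_feature("A", "PEPK", 50.0, 500.0, width=0.4)]},
            AlignmentWindows(rt_window=0.5, mz_window=0.005),
        )
        (d,) = generate_decoys(consensus,
                               AlignmentWindows(rt_window=0.5, mz_window=0.005))
        assert d.rt_ref == pytest.approx(52.5)
        assert d.mz_ref == pytest.approx(500.025)
        assert d.kind == "decoy" and d.parent_id == consensus[0].id

    def test_decoy_inherits_width_and_samples(self):
        consensus = _simple_consensus()
        decoys = generate_decoys(consensus, WINDOWS)
        for c, d in zip(consensus, decoys):
            assert d.rt_peak_width == c.rt_peak_width
            assert set(d.contributors) == set(c.contributors)

    def test_collision_shifts_in_mz(self):
        w = AlignmentWindows(rt_window=0.5, mz_window=0.005)
        features = {
            "A": [_feature("A", "AAK", 50.0, 500.0, width=0.4),
                  # a target sitting exactly where AAK's decoy would land
                  _feature("A", "CCK", 52.5, 500.025, width=0.4)],
        }
        consensus = aggregate_features(features, w)
        decoys = generate_decoys(consensus, w)
        aak_decoy = next(d for d in decoys
                         if d.parent_id == next(c.id for c in consensus
                                                if c.sequence == "AAK"))
        assert aak_decoy.mz_ref > 500.025 + 0.005  # shifted clear

    def test_bookkeeping_counts(self):
        consensus = _simple_consensus(5)
        decoys = generate_decoys(consensus, WINDOWS)
        assert len(decoys) == len(consensus)


class TestGenerateIsotopeFeatures:
    def test_mz_shift_per_charge(self):
        consensus = aggregate_features(
            {"A": [_feature("A", "PEPK", 50.0, 500.0, charge=2)]}, WINDOWS)
        (iso,) = generate_isotope_features(consensus)
        assert iso.mz_ref == pytest.approx(500.0 + 1.002 / 2)
        assert iso.rt_ref == pytest.approx(50.0)
        assert iso.kind == "isotope_plus1"

    def test_charge_one_full_shift(self):
        consensus = aggregate_features(
            {"A": [_feature("A", "PEPK", 50.0, 500.0, charge=1)]}, WINDOWS)
        (iso,) = generate_isotope_features(consensus)
        assert iso.mz_ref == pytest.approx(501.002)

    def test_counts_match_targets(self):
        consensus = _simple_consensus(4)
        assert len(generate_isotope_features(consensus)) == 4


class TestPropagateIdentities:
    def test_all_sequenced(self):
        consensus = _simple_consensus(1)
        propagate_identities(consensus, ["A", "B"])
        assert set(consensus[0].sample_status.values()) == {SEQUENCED_HERE}

    def test_three_way_labels(self):
        features = {
            "A": [_feature("A", "PEPK", 50.0, 500.0)],
            "B": [_feature("B", None, 50.05, 500.0002)],
        }
        consensus = aggregate_features(features, WINDOWS)
        propagate_identities(consensus, ["A", "B", "C"])
        status = consensus[0].sample_status
        assert status == {"A": SEQUENCED_HERE, "B": FEATURE_PROPAGATED,
                          "C": TO_RECOVER}


class TestConsensusTable:
    def test_columns_and_counts(self):
        consensus = _simple_consensus(2)
        propagate_identities(consensus, ["A", "B"])
        df = consensus_table(consensus)
        assert list(df["n_samples_sequenced"]) == [2, 2]
        assert {"id", "kind", "sequence", "charge", "mz_ref", "rt_ref",
                "rt_peak_width"} <= set(df.columns)
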