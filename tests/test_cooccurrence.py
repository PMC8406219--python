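"""Alignment identity, species-group clustering, and co-occurrence analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cprhab.cooccurrence import (UNDEFINED, CooccurrenceError,
                                 classify_exclusive_cooccurrence,
                                 cluster_species_groups,
                                 correlate_coverage_profiles, global_identity,
                                 relative_abundance, richness_ratio,
                                 scaled_coverage_profile)
from cprhab.synthetic import SimConfig, simulate_marker_sequences

AA = "ACDEFGHIKLMNPQRSTVWY"


def _nw_oracle(a, b):
    """Plain dynamic-programming score oracle (match +1, mismatch/gap -1,
    free terminal gaps)."""
    la, lb = len(a), len(b)
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] - 1,
                          H[i][j - 1] - 1)
    return max(max(H[la]), max(row[lb] for row in H))


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("PEPTIDE", "PEPTIDE") == 1.0

    def test_single_mismatch(self):
        assert global_identity("ACDEF", "ACDFF") == pytest.approx(0.8)

    def test_disjoint_alphabets_zero(self):
        # no-overlap (all-terminal-gap) alignment scores 0, beating any
        # mismatch-laden overlap; identity is 0 by convention
        assert global_identity("AAAA", "TTTT") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(CooccurrenceError):
            global_identity("", "PEPTIDE")

    @given(st.text(AA, min_size=1, max_size=12),
           st.text(AA, min_size=1, max_size=12))
    @settings(max_examples=150, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        ab = global_identity(a, b)
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(global_identity(b, a))

    def test_internal_gap_in_denominator(self):
        # best alignment of ACDEFG vs ACDFG deletes E: 5 matches over 6 cols
        assert global_identity("ACDEFG", "ACDFG") == pytest.approx(5 / 6)


class TestClusterSpeciesGroups:
    def test_identical_sequences_one_group(self):
        groups = cluster_species_groups(
            {"s1": "PEPTIDE" * 10, "s2": "PEPTIDE" * 10,
             "s3": "PEPTIDE" * 10})
        assert len(groups) == 1 and len(groups[0].members) == 3

    def test_threshold_is_inclusive(self):
        seq = "A" * 99 + "C"
        var = "A" * 100  # identity exactly 0.99
        groups = cluster_species_groups({"s1": seq, "s2": var},
                                        threshold=0.99)
        assert len(groups) == 1

    def test_planted_groups_recovered(self):
        cfg = SimConfig(seed=5, n_species_groups=2, members_per_group=10)
        records, truth = simulate_marker_sequences(cfg)
        groups = cluster_species_groups(dict(records), threshold=0.99)
        assert len(groups) == 2
        for grp in groups:
            labels = {truth.marker_groups[m] for m in grp.members}
            assert len(labels) == 1

    def test_partition_and_member_identity_invariant(self):
        cfg = SimConfig(seed=9, n_species_groups=3, members_per_group=4)
        records, _ = simulate_marker_sequences(cfg)
        seqs = dict(records)
        groups = cluster_species_groups(seqs, threshold=0.99)
        members = sorted(m for g in groups for m in g.members)
        assert members == sorted(seqs)
        for g in groups:
            for m in g.members:
                assert global_identity(seqs[m], g.centroid_sequence) >= 0.99
        # permuting input order leaves the partition unchanged
        shuffled = dict(reversed(list(seqs.items())))
        regrouped = cluster_species_groups(shuffled, threshold=0.99)
        assert [sorted(g.members) for g in groups] == \
            [sorted(g.members) for g in regrouped]


def _sample(detections):
    """detections: list of (group_id, lineage, order)."""
    return pd.DataFrame(
        [{"sample_id": "s1", "group_id": g, "lineage": lin, "order": o,
          "mean_coverage": 1.0, "covered_fraction": 0.5}
         for g, lin, o in detections])


class TestRichnessRatio:
    def test_eleven_to_one(self):
        det = [(f"sac{i}", "Saccharibacteria", "unknown") for i in range(11)]
        det += [("act0", "Actinobacteria", "Actinomycetales")]
        assert richness_ratio(_sample(det), "Saccharibacteria",
                              "Actinobacteria") == pytest.approx(11.0)

    def test_equal_richness(self):
        det = [(f"sac{i}", "Saccharibacteria", "unknown") for i in range(3)]
        det += [(f"act{i}", "Actinobacteria", "Actinomycetales")
                for i in range(3)]
        assert richness_ratio(_sample(det), "Saccharibacteria",
                              "Actinobacteria") == pytest.approx(1.0)

    def test_undefined_when_denominator_absent(self):
        det = [("sac0", "Saccharibacteria", "unknown"),
               ("sac1", "Saccharibacteria", "unknown")]
        assert richness_ratio(_sample(det), "Saccharibacteria",
                              "Actinobacteria") == UNDEFINED


class TestExclusiveCooccurrence:
    def test_species_level(self):
        det = [("sac0", "Saccharibacteria", "unknown"),
               ("act0", "Actinobacteria", "Actinomycetales")]
        labels, pairs = classify_exclusive_cooccurrence(
            _sample(det), "Saccharibacteria", "Actinobacteria")
        assert labels.iloc[0]["label"] == "exclusive-species"
        assert len(pairs) == 1

    def test_order_level(self):
        det = [("sac0", "Saccharibacteria", "unknown")]
        det += [(f"act{i}", "Actinobacteria", "Coriobacteriales")
                for i in range(3)]
        labels, pairs = classify_exclusive_cooccurrence(
            _sample(det), "Saccharibacteria", "Actinobacteria")
        assert labels.iloc[0]["label"] == "exclusive-order"
        assert len(pairs) == 3

    def test_mixed_orders_none(self):
        det = [("sac0", "Saccharibacteria", "unknown"),
               ("act0", "Actinobacteria", "Coriobacteriales"),
               ("act1", "Actinobacteria", "Actinomycetales")]
        labels, _ = classify_exclusive_cooccurrence(
            _sample(det), "Saccharibacteria", "Actinobacteria")
        assert labels.iloc[0]["label"] == "none"

    def test_matches_manual_enumeration_on_planted_communities(self):
        from cprhab.synthetic import simulate_communities
        cfg = SimConfig(seed=21, n_samples=10, coupling_prob=1.0,
                        leak_prob=0.0)
        samples, truth = simulate_communities(cfg)
        labels, pairs = classify_exclusive_cooccurrence(
            samples, "Saccharibacteria", "Actinobacteria")
        for sid, sub in samples.groupby("sample_id"):
            a = set(sub.loc[sub["lineage"] == "Saccharibacteria", "group_id"])
            b_rows = sub.loc[sub["lineage"] == "Actinobacteria"]
            b = set(b_rows["group_id"])
            expected = "none"
            if len(a) == 1 and len(b) == 1:
                expected = "exclusive-species"
            elif len(a) == 1 and len(b) >= 2 and \
                    b_rows["order"].nunique() == 1:
                expected = "exclusive-order"
            got = labels.set_index("sample_id").loc[sid, "label"]
            assert got == expected
            got_pairs = pairs[pairs["sample_id"] == sid]
            assert len(got_pairs) == len(a) * len(b)


class TestScaledCoverage:
    def _samples(self):
        rows = [
            ("s1", "act0", "Actinobacteria", "Actinomycetales", 2.0, 0.5),
            ("s1", "act1", "Actinobacteria", "Actinomycetales", 3.0, 0.6),
            ("s2", "act0", "Actinobacteria", "Actinomycetales", 50.0, 0.9),
            ("s2", "sac0", "Saccharibacteria", "unknown", 0.5, 0.05),
        ]
        return pd.DataFrame(rows, columns=[
            "sample_id", "group_id", "lineage", "order", "mean_coverage",
            "covered_fraction"])

    def test_minimum_cell_maps_to_zero_and_log_scale(self):
        mat = scaled_coverage_profile(self._samples())
        # coverages after floor: Actinomycetales s1 = 5.0, s2 = 50.0
        assert mat.at["Actinomycetales", "s1"] == pytest.approx(0.0)
        assert mat.at["Actinomycetales", "s2"] == pytest.approx(1.0)

    def test_low_covered_fraction_dropped(self):
        mat = scaled_coverage_profile(self._samples())
        # sac0 at covered_fraction 0.05 is excluded before summation
        assert "Saccharibacteria (unresolved order)" not in mat.index

    def test_all_below_floor_rejected(self):
        df = self._samples()
        df["covered_fraction"] = 0.01
        with pytest.raises(CooccurrenceError):
            scaled_coverage_profile(df)

    def test_values_nonnegative_one_zero_when_min_unique(self):
        mat = scaled_coverage_profile(self._samples())
        vals = mat.values[np.isfinite(mat.values)]
        assert (vals >= 0).all()
        assert (vals == 0).sum() == 1


class TestCorrelateCoverage:
    def _matrix(self):
        return pd.DataFrame(
            {"s1": [1.0, 1.0, 3.0, 2.0], "s2": [2.0, 2.0, 2.0, 2.0],
             "s3": [3.0, 3.0, 1.0, 2.0]},
            index=["focal", "same", "opposite", "flat"])

    def test_identical_profile_rank_one(self):
        out = correlate_coverage_profiles(self._matrix(), "focal")
        assert out.iloc[0]["taxon"] == "same"
        assert out.iloc[0]["pearson_r"] == pytest.approx(1.0)

    def test_opposite_profile_minus_one(self):
        out = correlate_coverage_profiles(self._matrix(), "focal")
        r = out.set_index("taxon").at["opposite", "pearson_r"]
        assert r == pytest.approx(-1.0)

    def test_constant_profile_excluded(self):
        out = correlate_coverage_profiles(self._matrix(), "focal")
        flat = out.set_index("taxon").loc["flat"]
        assert flat["excluded_constant"]
        assert np.isnan(flat["pearson_r"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(CooccurrenceError):
            correlate_coverage_profiles(self._matrix()[["s1", "s2"]], "focal")


class TestRelativeAbundance:
    def _mapping(self):
        return pd.DataFrame([
            {"genome_id": "g1", "sample_id": "s1", "strict_mapped": 1000,
             "total_reads": 100_000, "covered_fraction": 0.5,
             "read_pairs": 50_000},
            {"genome_id": "g1", "sample_id": "s2", "strict_mapped": 5000,
             "total_reads": 100_000, "covered_fraction": 0.08,
             "read_pairs": 120_000_000},
            {"genome_id": "g2", "sample_id": "s1", "strict_mapped": 0,
             "total_reads": 100_000, "covered_fraction": 0.2,
             "read_pairs": 50_000},
        ])

    def test_abundance_is_strict_fraction(self):
        out, _ = relative_abundance(self._mapping())
        row = out[(out["genome_id"] == "g1") & (out["sample_id"] == "s1")]
        assert row.iloc[0]["relative_abundance"] == pytest.approx(0.01)

    def test_low_covered_fraction_absent(self):
        out, reps = relative_abundance(self._mapping())
        row = out[(out["genome_id"] == "g1") & (out["sample_id"] == "s2")]
        assert not row.iloc[0]["present"]
        assert pd.isna(row.iloc[0]["relative_abundance"])
        # representative is therefore s1 despite s2's higher mapped count
        assert reps.set_index("genome_id").at["g1",
                                              "representative_sample"] == "s1"

    def test_subsample_flag(self):
        out, _ = relative_abundance(self._mapping())
        flagged = out[out["read_pairs"] > 100_000_000]
        assert flagged["subsample"].all()
        assert (flagged["subsample_target"] == 36_000_000).all()

    def test_zero_total_reads_rejected(self):
        bad = self._mapping()
        bad.loc[0, "total_reads"] = 0
        with pytest.raises(CooccurrenceError):
            relative_abundance(bad)
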