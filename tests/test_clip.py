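"""Peak merging, condition overlap, annotation and metagene profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ncrbp import clip
from conftest import make_peaks, make_sites


# --- independent oracles ----------------------------------------------------


def brute_force_site_clusters(positions, merge_gap):
    """All-pairs single-linkage clustering of 1D positions (O(n^2))."""
    positions = sorted(set(positions))
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= merge_gap:
                ri, rj = find(i), find(j)
                parent[ri] = rj
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted(tuple(sorted(g)) for g in groups.values())


def brute_force_interval_clusters(intervals):
    """All-pairs single-linkage clustering on >=1 bp overlap (O(n^2))."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 < e2 and s2 < e1:
                ri, rj = find(i), find(j)
                parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


# --- merge_sites ------------------------------------------------------------


class TestMergeSites:
    def test_solo_site_is_extended_symmetrically(self):
        peaks = clip.merge_sites(make_sites([("chr1", 100, "+")]))
        row = peaks.iloc[0]
        assert (row["start"], row["end"]) == (75, 125)
        assert row["end"] - row["start"] == 50

    def test_nearby_sites_merge_into_one_span(self):
        peaks = clip.merge_sites(make_sites([("chr1", 100, "+"), ("chr1", 120, "+")]))
        assert len(peaks) == 1
        row = peaks.iloc[0]
        assert (row["start"], row["end"], row["n_sites"]) == (100, 121, 2)

    def test_opposite_strands_never_merge(self):
        peaks = clip.merge_sites(make_sites([("chr1", 100, "+"), ("chr1", 100, "-")]))
        assert len(peaks) == 2
        assert set(peaks["strand"]) == {"+", "-"}

    def test_solo_extension_clipped_at_chromosome_start(self):
        peaks = clip.merge_sites(make_sites([("chr1", 5, "+")]))
        assert peaks.iloc[0]["start"] == 0

    def test_negative_coordinate_errors(self):
        with pytest.raises(ValueError, match="negative"):
            clip.merge_sites(make_sites([("chr1", -3, "+")]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=60),
           st.integers(1, 120))
    def test_matches_brute_force_clustering_oracle(self, positions, gap):
        sites = make_sites([("chr1", p, "+") for p in positions])
        peaks = clip.merge_sites(sites, merge_gap=gap, solo_width=50)
        expected = brute_force_site_clusters(positions, gap)
        spans = [(r.start, r.end, r.n_sites) for r in peaks.itertuples()]
        assert len(peaks) == len(expected)
        assert peaks["n_sites"].sum() == len(set(positions))
        for cluster in expected:
            if len(cluster) == 1:
                assert any(n == 1 and s <= cluster[0] < e for s, e, n in spans)
            else:
                assert (cluster[0], cluster[-1] + 1, len(cluster)) in spans

    def test_every_site_lies_in_exactly_one_peak(self, rng):
        positions = rng.integers(0, 5000, size=200)
        sites = make_sites([("chr1", int(p), "+") for p in positions])
        peaks = clip.merge_sites(sites)
        for p in positions:
            hits = ((peaks["start"] <= p) & (p < peaks["end"])).sum()
            assert hits == 1

    def test_output_disjoint_per_strand_and_condition(self, rng):
        positions = rng.integers(0, 3000, size=150)
        rows = [("chr1", int(p), rng.choice(["+", "-"]), rng.choice(["norm", "low"]))
                for p in positions]
        peaks = clip.merge_sites(make_sites(rows))
        for _, sub in peaks.groupby(["chrom", "strand", "condition"]):
            s = sub.sort_values("start")
            assert (s["start"].values[1:] >= s["end"].values[:-1]).all()


# --- condition_overlap ------------------------------------------------------


class TestConditionOverlap:
    def test_identical_peaksets_all_in_three(self):
        base = make_peaks([("chr1", 0, 50, "+"), ("chr1", 100, 150, "+")])
        counts = clip.condition_overlap({c: base for c in ("norm", "low", "gal")})
        assert counts["three"] == 2
        assert counts["exactly_two"] == 0 and counts["exactly_one"] == 0

    def test_enumerated_three_condition_example(self):
        peaksets = {
            "A": make_peaks([("chr1", 0, 50, "+")]),
            "B": make_peaks([("chr1", 40, 90, "+")]),
            "C": make_peaks([("chr1", 200, 250, "+")]),
        }
        counts = clip.condition_overlap(peaksets)
        assert counts == {"three": 0, "exactly_two": 1, "exactly_one": 1,
                          "n_clusters": 2, "n_peaks_total": 3}

    def test_empty_inputs_are_all_zero(self):
        empty = make_peaks([]).reindex(columns=["chrom", "start", "end", "strand",
                                                "condition", "n_sites", "score"])
        counts = clip.condition_overlap({"A": empty, "B": empty, "C": empty})
        assert counts["three"] == counts["exactly_two"] == counts["exactly_one"] == 0

    def test_counts_invariant_to_condition_relabeling(self, rng):
        peaksets = {}
        for cond in ("A", "B", "C"):
            starts = np.sort(rng.choice(np.arange(0, 3000, 60), size=20, replace=False))
            peaksets[cond] = make_peaks([("chr1", int(s), int(s) + 50, "+") for s in starts])
        counts = clip.condition_overlap(peaksets)
        relabeled = {"C": peaksets["A"], "A": peaksets["B"], "B": peaksets["C"]}
        assert clip.condition_overlap(relabeled) == counts
        assert counts["n_clusters"] == counts["three"] + counts["exactly_two"] + counts["exactly_one"]

    def test_matches_brute_force_interval_oracle(self, rng):
        intervals, frames = [], {}
        for cond in ("A", "B", "C"):
            rows = []
            for _ in range(40):
                s = int(rng.integers(0, 4000))
                e = s + int(rng.integers(1, 120))
                rows.append(("chr1", s, e, "+", cond))
                intervals.append((s, e))
            frames[cond] = make_peaks(rows)
        counts = clip.condition_overlap(frames)
        oracle = brute_force_interval_clusters(intervals)
        assert counts["n_clusters"] == len(oracle)

    def test_too_many_conditions_error(self):
        base = make_peaks([("chr1", 0, 50, "+")])
        with pytest.raises(ValueError):
            clip.condition_overlap({c: base for c in "ABCD"})
        clip.condition_overlap({c: base for c in "ABCD"}, strict=False)


# --- annotate_peaks ---------------------------------------------------------


class TestAnnotatePeaks:
    def test_category_assignment(self, toy_annotation):
        peaks = make_peaks([
            ("chr1", 120, 160, "+"),    # inside 5'UTR
            ("chr1", 180, 260, "+"),    # spans 5'UTR and CDS -> 5UTR by precedence
            ("chr1", 300, 360, "+"),    # CDS
            ("chr1", 5000, 5050, "+"),  # nothing
            ("chr1", 4100, 4150, "+"),  # lncRNA
            ("chr1", 2100, 2150, "-"),  # minus-strand 3'UTR
            ("chr1", 120, 160, "-"),    # right coords, wrong strand -> intergenic
        ])
        labelled, dist = clip.annotate_peaks(peaks, toy_annotation)
        assert labelled["category"].tolist() == [
            "5UTR", "5UTR", "CDS", "intergenic", "lncRNA", "3UTR", "intergenic"
        ]
        assert dist["fraction"].sum() == pytest.approx(1.0)

    def test_unknown_strand_errors(self, toy_annotation):
        bad = toy_annotation.copy()
        bad.loc[0, "strand"] = "."
        with pytest.raises(ValueError, match="strand"):
            clip.annotate_peaks(make_peaks([("chr1", 120, 160, "+")]), bad)


# --- metagene_profile -------------------------------------------------------


class TestMetageneProfile:
    def test_full_coverage_gives_all_ones(self, toy_annotation):
        peaks = make_peaks([("chr1", 0, 1200, "+"), ("chr1", 1500, 3100, "-")])
        profile = clip.metagene_profile(peaks, toy_annotation, n_bins=10)
        np.testing.assert_allclose(profile, 1.0)

    def test_half_covered_utr_fills_first_half_of_profile(self):
        annot = pd.DataFrame(
            [("chr1", 0, 100, "+", "five_prime_utr", "G1", "T1", "protein_coding")],
            columns=["chrom", "start", "end", "strand", "feature", "gene_id",
                     "transcript_id", "biotype"],
        )
        peaks = make_peaks([("chr1", 0, 50, "+")])
        profile = clip.metagene_profile(peaks, annot, n_bins=10)
        np.testing.assert_allclose(profile, [1] * 5 + [0] * 5)

    def test_no_peaks_gives_zero_profile(self, toy_annotation):
        empty = make_peaks([]).reindex(columns=["chrom", "start", "end", "strand",
                                                "condition", "n_sites", "score"])
        profile = clip.metagene_profile(empty, toy_annotation, n_bins=8)
        np.testing.assert_allclose(profile, 0.0)

    def test_minus_strand_profile_mirrors_plus_strand(self):
        # same geometry mirrored around the UTR midline on the other strand
        annot = pd.DataFrame(
            [
                ("chr1", 0, 100, "+", "five_prime_utr", "G1", "T1", "protein_coding"),
                ("chr2", 0, 100, "-", "five_prime_utr", "G2", "T2", "protein_coding"),
            ],
            columns=["chrom", "start", "end", "strand", "feature", "gene_id",
                     "transcript_id", "biotype"],
        )
        plus = clip.metagene_profile(make_peaks([("chr1", 0, 30, "+")]),
                                     annot[annot.strand == "+"], n_bins=10)
        minus = clip.metagene_profile(make_peaks([("chr2", 70, 100, "-")]),
                                      annot[annot.strand == "-"], n_bins=10)
        np.testing.assert_allclose(plus, minus)

    def test_zero_length_utr_is_skipped_with_warning(self, toy_annotation):
        annot = pd.concat([
            toy_annotation,
            pd.DataFrame([("chr1", 50, 50, "+", "five_prime_utr", "GZ", "TZ",
                           "protein_coding")], columns=toy_annotation.columns),
        ], ignore_index=True)
        peaks = make_peaks([("chr1", 0, 1200, "+"), ("chr1", 1500, 3100, "-")])
        with pytest.warns(UserWarning, match="zero-length"):
            profile = clip.metagene_profile(peaks, annot, n_bins=5)
        np.testing.assert_allclose(profile, 1.0)
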