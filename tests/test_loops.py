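"""Loop filtering/merging, RPS, covariation, activity and expression."""

import numpy as np
import pandas as pd
import pytest

from chromarch import (
    classify_differential_rps, classify_enhancer_activity, compute_rps,
    covariation_genes, filter_expressed_genes, filter_loops, filter_peis,
    merge_loops,
)
from chromarch.loops import LOOP_COLUMNS


def make_loops(rows):
    return pd.DataFrame(rows, columns=LOOP_COLUMNS)


MOTIFS = pd.DataFrame({"chrom": ["chr1"] * 2,
                       "start": [10_000, 500_000],
                       "end": [12_000, 502_000]})


class TestFilterLoops:
    def base_loop(self, q=0.005, start2=500_000):
        return ("chr1", 10_000, 15_000, start2, start2 + 5_000, q)

    def test_weak_q_rejected(self):
        out = filter_loops(make_loops([self.base_loop(q=0.02)]), MOTIFS)
        assert len(out) == 0

    def test_short_span_rejected(self):
        loops = make_loops([("chr1", 10_000, 15_000, 35_000, 40_000, 0.001)])
        assert len(filter_loops(loops, MOTIFS)) == 0  # span 25 kb < 30 kb

    def test_all_filters_pass(self):
        out = filter_loops(make_loops([self.base_loop()]), MOTIFS)
        assert len(out) == 1  # q=0.005, span ~490 kb, both anchors on motifs

    def test_anchor_off_motif_rejected(self):
        loops = make_loops([("chr1", 100_000, 105_000, 500_000, 505_000, 0.001)])
        assert len(filter_loops(loops, MOTIFS)) == 0

    def test_span_above_two_mb_rejected(self):
        motifs = pd.DataFrame({"chrom": ["chr1"] * 2,
                               "start": [10_000, 2_500_000],
                               "end": [12_000, 2_502_000]})
        loops = make_loops([("chr1", 10_000, 15_000, 2_500_000, 2_505_000,
                             0.001)])
        assert len(filter_loops(loops, motifs)) == 0


def _gap(s1, e1, s2, e2):
    return max(0, max(s1, s2) - min(e1, e2))


def _adj(a, b, adjacency):
    return (a[0] == b[0]
            and _gap(a[1], a[2], b[1], b[2]) <= adjacency
            and _gap(a[3], a[4], b[3], b[4]) <= adjacency)


def closure_oracle(records, adjacency):
    """Naive fixed-point merger: one adjacent pair at a time, until none.

    Independent of the odd/even-rank machinery: repeatedly scans the current
    loop list for any adjacent pair, replaces it with the union-anchor loop,
    and restarts, so the result is the transitive closure of the merge
    relation as iterated on union anchors.
    """
    loops = list(records)
    changed = True
    while changed:
        changed = False
        for i in range(len(loops)):
            for j in range(i + 1, len(loops)):
                if _adj(loops[i], loops[j], adjacency):
                    a, b = loops[i], loops[j]
                    merged = (a[0], min(a[1], b[1]), max(a[2], b[2]),
                              min(a[3], b[3]), max(a[4], b[4]),
                              min(a[5], b[5]))
                    loops = [l for k, l in enumerate(loops) if k not in (i, j)]
                    loops.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(loops)


def pairwise_closure_clusters(records, adjacency):
    """Connected components of the adjacency relation on the input loops."""
    n = len(records)
    comp = list(range(n))

    def find(i):
        while comp[i] != i:
            i = comp[i]
        return i

    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                if _adj(records[i], records[j], adjacency) \
                        and find(i) != find(j):
                    comp[find(i)] = find(j)
                    changed = True
    groups = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec)
    return list(groups.values())


class TestMergeLoops:
    def test_two_near_loops_merge_to_union(self):
        loops = make_loops([
            ("chr1", 0, 5_000, 100_000, 105_000, 0.001),
            ("chr1", 8_000, 13_000, 108_000, 113_000, 0.002),  # 3 kb gaps
        ])
        out = merge_loops(loops)
        assert len(out) == 1
        assert tuple(out.iloc[0][["start1", "end1", "start2", "end2"]]) == \
            (0, 13_000, 100_000, 113_000)

    def test_distant_loops_untouched_and_fixed_point(self):
        loops = make_loops([
            ("chr1", 0, 5_000, 100_000, 105_000, 0.001),
            ("chr1", 50_000, 55_000, 300_000, 305_000, 0.002),
        ])
        out = merge_loops(loops)
        assert len(out) == 2
        again = merge_loops(out)
        pd.testing.assert_frame_equal(out, again)

    def test_chain_merges_transitively(self):
        # 1~2 and 2~3 but 1 and 3 are 12 kb apart (not directly adjacent)
        loops = make_loops([
            ("chr1", 0, 5_000, 100_000, 105_000, 0.001),
            ("chr1", 6_000, 11_000, 106_000, 111_000, 0.002),
            ("chr1", 12_000, 17_000, 112_000, 117_000, 0.003),
        ])
        out = merge_loops(loops)
        assert len(out) == 1
        assert tuple(out.iloc[0][["start1", "end1", "start2", "end2"]]) == \
            (0, 17_000, 100_000, 117_000)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_transitive_closure_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        recs = []
        for _ in range(n):
            s1 = int(rng.integers(0, 40)) * 2_000
            s2 = s1 + 100_000 + int(rng.integers(0, 40)) * 2_000
            recs.append(("chr1", s1, s1 + 5_000, s2, s2 + 5_000,
                         float(rng.uniform(0, 0.01))))
        out = merge_loops(make_loops(recs))
        got = sorted(map(tuple, out[LOOP_COLUMNS].itertuples(index=False,
                                                             name=None)))
        assert got == closure_oracle(recs, 5_000)
        # every connected component of the input adjacency relation ends up
        # inside a single output loop
        for members in pairwise_closure_clusters(recs, 5_000):
            homes = set()
            for m in members:
                for k, o in enumerate(got):
                    if o[1] <= m[1] and o[2] >= m[2] \
                            and o[3] <= m[3] and o[4] >= m[4]:
                        homes.add(k)
                        break
            assert len(homes) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_closure_properties(self, seed):
        rng = np.random.default_rng(100 + seed)
        recs = []
        for _ in range(10):
            s1 = int(rng.integers(0, 30)) * 3_000
            s2 = s1 + 80_000 + int(rng.integers(0, 30)) * 3_000
            recs.append(("chr1", s1, s1 + 5_000, s2, s2 + 5_000, 0.001))
        loops = make_loops(recs)
        out = merge_loops(loops)
        assert len(out) <= len(loops)
        pd.testing.assert_frame_equal(merge_loops(out), out)  # idempotent
        # extensive: every input anchor is contained in some output anchor
        for rec in recs:
            contained = ((out["start1"] <= rec[1]) & (out["end1"] >= rec[2])
                         & (out["start2"] <= rec[3]) & (out["end2"] >= rec[4]))
            assert contained.any()
        # monotone in the adjacency radius
        wider = merge_loops(loops, adjacency=20_000)
        assert len(wider) <= len(out)


class TestRPS:
    def peis(self, ln_values, gene="G1"):
        return pd.DataFrame({"gene": gene, "l_n": ln_values})

    def test_worked_example(self):
        out = compute_rps(self.peis([10.0, 100.0]))
        assert out.loc["G1", "rps"] == pytest.approx(3.0)
        assert out.loc["G1", "enhancer_class"] == "multi"

    def test_no_enhancers_scores_zero(self):
        out = compute_rps(pd.DataFrame({"gene": [], "l_n": []}),
                          genes=["G1"])
        assert out.loc["G1", "rps"] == 0.0
        assert out.loc["G1", "enhancer_class"] == "none"

    def test_reciprocal_values_cancel(self):
        out = compute_rps(self.peis([2.0, 0.5]))
        assert out.loc["G1", "rps"] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_ln_excluded(self):
        out = compute_rps(self.peis([10.0, -1.0, 0.0]))
        assert out.loc["G1", "n"] == 1
        assert out.loc["G1", "rps"] == pytest.approx(1.0)

    def test_single_enhancer_class(self):
        out = compute_rps(self.peis([10.0]))
        assert out.loc["G1", "enhancer_class"] == "single"

    def test_additive_and_order_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1.1, 50, 12)
        a = compute_rps(self.peis(vals))
        b = compute_rps(self.peis(vals[::-1]))
        assert a.loc["G1", "rps"] == pytest.approx(b.loc["G1", "rps"])
        half = compute_rps(self.peis(vals[:6])).loc["G1", "rps"] + \
            compute_rps(self.peis(vals[6:])).loc["G1", "rps"]
        assert a.loc["G1", "rps"] == pytest.approx(half)

    def test_adding_strong_enhancer_increases_score(self):
        base = compute_rps(self.peis([5.0, 7.0])).loc["G1", "rps"]
        more = compute_rps(self.peis([5.0, 7.0, 2.0])).loc["G1", "rps"]
        assert more > base


class TestPEIFilter:
    def test_retention_rules(self):
        peis = pd.DataFrame({
            "gene": ["G1"] * 3,
            "l_n": [5.0, 5.0, 5.0],
            "fdr": [0.0005, 0.01, 0.0005],
            "distance": [50_000, 50_000, 30_000],
        })
        out = filter_peis(peis)
        assert len(out) == 1  # FDR < 0.001 and distance >= 40 kb


class TestDifferentialRPS:
    def test_worked_differential(self):
        a = pd.Series({"G1": 4.0})
        b = pd.Series({"G1": 1.0})
        out = classify_differential_rps(a, b)  # FC 4 > 1.5 and delta 3 > 2
        assert bool(out.loc["G1", "differential"])

    def test_small_changes_not_differential(self):
        out = classify_differential_rps(pd.Series({"G1": 3.0}),
                                        pd.Series({"G1": 2.5}))
        assert not bool(out.loc["G1", "differential"])

    def test_equal_scores_not_differential(self):
        out = classify_differential_rps(pd.Series({"G1": 2.0}),
                                        pd.Series({"G1": 2.0}))
        assert not bool(out.loc["G1", "differential"])

    def test_nonpositive_rps_uses_delta_only(self):
        out = classify_differential_rps(pd.Series({"G1": 0.0}),
                                        pd.Series({"G1": 2.5}))
        assert bool(out.loc["G1", "differential"])

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_under_condition_swap(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{k}" for k in range(30)]
        a = pd.Series(rng.uniform(0, 8, 30), index=genes)
        b = pd.Series(rng.uniform(0, 8, 30), index=genes)
        ab = classify_differential_rps(a, b)
        ba = classify_differential_rps(b, a)
        assert (ab["differential"] == ba["differential"]).all()
        assert (ab["direction"] == -ba["direction"]).all()


class TestCovariation:
    def test_concordant_gene_included(self):
        diff = pd.DataFrame({"differential": [True], "direction": [1]},
                            index=["G1"])
        deg = pd.DataFrame({"gene": ["G1"], "log2fc": [2.1], "fdr": [0.01]})
        assert covariation_genes(diff, deg) == ["G1"]

    def test_opposite_direction_excluded(self):
        diff = pd.DataFrame({"differential": [True], "direction": [1]},
                            index=["G1"])
        deg = pd.DataFrame({"gene": ["G1"], "log2fc": [-2.0], "fdr": [0.01]})
        assert covariation_genes(diff, deg) == []

    def test_matches_row_by_row_oracle_on_toy_table(self):
        rng = np.random.default_rng(7)
        genes = [f"G{k}" for k in range(20)]
        diff = pd.DataFrame({
            "differential": rng.random(20) < 0.5,
            "direction": rng.choice([-1, 1], 20),
        }, index=genes)
        deg = pd.DataFrame({"gene": genes,
                            "log2fc": rng.uniform(-3, 3, 20),
                            "fdr": rng.uniform(0, 0.2, 20)})
        expected = [g for g in genes
                    if diff.loc[g, "differential"]
                    and abs(deg.set_index("gene").loc[g, "log2fc"]) > 1.0
                    and deg.set_index("gene").loc[g, "fdr"] < 0.05
                    and np.sign(deg.set_index("gene").loc[g, "log2fc"])
                    == diff.loc[g, "direction"]]
        assert covariation_genes(diff, deg) == expected


class TestEnhancerActivity:
    def test_classes_from_peak_overlap(self):
        enh = pd.DataFrame({"chrom": ["chr1"] * 3,
                            "start": [0, 10_000, 20_000],
                            "end": [5_000, 15_000, 25_000]})
        high = pd.DataFrame({"chrom": ["chr1"], "start": [1_000],
                             "end": [2_000]})
        moderate = pd.DataFrame({"chrom": ["chr1"], "start": [11_000],
                                 "end": [12_000]})
        out = classify_enhancer_activity(enh, high, moderate)
        assert list(out) == ["highly-active", "moderately-active",
                             "low-active"]

    def test_matches_naive_intersection_on_toy(self):
        rng = np.random.default_rng(3)
        enh = pd.DataFrame({"chrom": "chr1",
                            "start": rng.integers(0, 100, 5) * 1_000})
        enh["end"] = enh["start"] + 5_000
        peaks = pd.DataFrame({"chrom": "chr1",
                              "start": rng.integers(0, 100, 3) * 1_000})
        peaks["end"] = peaks["start"] + 4_000
        out = classify_enhancer_activity(enh, peaks,
                                         pd.DataFrame(columns=["chrom",
                                                               "start", "end"]))
        for k, row in enh.iterrows():
            hit = any(p["start"] < row["end"] and p["end"] > row["start"]
                      for _, p in peaks.iterrows())
            assert (out[k] == "highly-active") == hit


class TestExpressionFilter:
    BIOTYPE = pd.Series({"P1": "PCG", "P2": "PCG", "L1": "lncRNA"})

    def test_pcg_cutoff(self):
        tpm = pd.DataFrame({"s1": [0.0, 0.4], "s2": [0.6, 0.4]},
                           index=["P1", "P2"])
        out = filter_expressed_genes(tpm, self.BIOTYPE)
        assert out == ["P1"]  # P2 never exceeds 0.5 TPM

    def test_lncrna_lower_cutoff(self):
        tpm = pd.DataFrame({"s1": [0.2]}, index=["L1"])
        assert filter_expressed_genes(tpm, self.BIOTYPE) == ["L1"]

    def test_unknown_biotype_rejected(self):
        tpm = pd.DataFrame({"s1": [1.0]}, index=["X1"])
        with pytest.raises(ValueError, match="biotype"):
            filter_expressed_genes(tpm, pd.Series({"X1": "rRNA"}))
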