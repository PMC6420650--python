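"""Peak-set algebra: oracle equivalence, partition identities, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_overlaps_any, make_peaks, overlaps
from neurodyn import atac
from neurodyn.errors import ComputationError, SchemaError


def peaks_from_tuples(tuples, chrom="chr1"):
    df = pd.DataFrame(tuples, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["name"] = [f"p{i}" for i in range(len(df))]
    df["summit"] = (df["end"] - df["start"]) // 2
    return df


class TestMerge:
    def test_textbook_merge(self):
        merged = atac.merge_peak_sets([peaks_from_tuples([(0, 10), (5, 20), (30, 40)])])
        assert list(zip(merged["start"], merged["end"])) == [(0, 20), (30, 40)]

    def test_single_nonoverlapping_set_is_identity(self):
        p = peaks_from_tuples([(0, 10), (20, 30)])
        merged = atac.merge_peak_sets([p])
        assert list(zip(merged["start"], merged["end"])) == [(0, 10), (20, 30)]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1, max_size=40))
    def test_merge_equals_covered_bp_oracle(self, raw):
        """Merged intervals cover exactly the union of covered base pairs."""
        p = peaks_from_tuples([(s, s + w) for s, w in raw])
        merged = atac.merge_peak_sets([p])
        covered = np.zeros(700, dtype=bool)
        for s, w in raw:
            covered[s : s + w] = True
        merged_cov = np.zeros(700, dtype=bool)
        for _, r in merged.iterrows():
            assert not merged_cov[r["start"] : r["end"]].any()  # non-overlapping
            merged_cov[r["start"] : r["end"]] = True
        assert np.array_equal(covered, merged_cov)


class TestOverlapOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_overlaps_any_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = make_peaks(rng, 120)
        s = make_peaks(rng, 120)
        assert np.array_equal(atac.overlaps_any(q, s), brute_overlaps_any(q, s))


class TestReproducible:
    def test_identical_replicates_return_same_intervals(self):
        p = peaks_from_tuples([(0, 10), (50, 80)])
        rp = atac.reproducible_peaks(p, p)
        assert list(zip(rp["start"], rp["end"])) == [(0, 10), (50, 80)]

    def test_disjoint_replicates_empty(self):
        r1 = peaks_from_tuples([(0, 10)])
        r2 = peaks_from_tuples([(100, 120)])
        assert len(atac.reproducible_peaks(r1, r2)) == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pairwise_union_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        r1, r2 = make_peaks(rng, 100), make_peaks(rng, 100)
        got = atac.reproducible_peaks(r1, r2)
        # oracle: union interval of each rep1 peak with its partners, merged
        unions = []
        for _, p in r1.iterrows():
            partners = [q for _, q in r2.iterrows() if overlaps(p, q)]
            if partners:
                unions.append(
                    (
                        p["chrom"],
                        min([p["start"]] + [q["start"] for q in partners]),
                        max([p["end"]] + [q["end"] for q in partners]),
                    )
                )
        expected = atac.merge_peak_sets(
            [pd.DataFrame(unions, columns=["chrom", "start", "end"])]
        )
        assert got[["chrom", "start", "end"]].equals(expected[["chrom", "start", "end"]])


class TestDynamics:
    def test_first_stage_all_novel(self):
        rng = np.random.default_rng(0)
        labels = atac.classify_novel_peaks(["s1"], {"s1": make_peaks(rng, 30)})
        assert (labels["label"] == "novel").all()

    def test_identical_stages_zero_novel_after_first(self):
        rng = np.random.default_rng(1)
        p = make_peaks(rng, 30)
        labels = atac.classify_novel_peaks(["a", "b", "c"], {"a": p, "b": p, "c": p})
        later = labels[labels["stage"] != "a"]
        assert (later["label"] == "conserved").all()

    def test_unknown_stage_errors(self):
        with pytest.raises(SchemaError):
            atac.classify_novel_peaks(["a", "b"], {"a": peaks_from_tuples([(0, 5)])})

    @pytest.mark.parametrize("seed", range(3))
    def test_novel_matches_cumulative_union_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        stages = {f"s{t}": make_peaks(rng, 80) for t in range(4)}
        order = list(stages)
        labels = atac.classify_novel_peaks(order, stages)
        for t, stage in enumerate(order):
            sub = labels[labels["stage"] == stage]
            if t == 0:
                assert (sub["label"] == "novel").all()
                continue
            prior = pd.concat([stages[s] for s in order[:t]], ignore_index=True)
            expect = np.where(brute_overlaps_any(stages[stage], prior), "conserved", "novel")
            assert list(sub["label"]) == list(expect)

    def test_novel_conserved_partition(self):
        rng = np.random.default_rng(3)
        stages = {f"s{t}": make_peaks(rng, 50) for t in range(3)}
        labels = atac.classify_novel_peaks(list(stages), stages)
        for stage, peaks in stages.items():
            sub = labels[labels["stage"] == stage]
            assert len(sub) == len(peaks)
            assert set(sub["label"]) <= {"novel", "conserved"}

    def test_adding_earlier_peak_never_increases_novel(self):
        rng = np.random.default_rng(4)
        a, b = make_peaks(rng, 50), make_peaks(rng, 50)
        base = atac.classify_novel_peaks(["a", "b"], {"a": a, "b": b})
        extra = pd.concat([a, b.iloc[:1]], ignore_index=True)
        more = atac.classify_novel_peaks(["a", "b"], {"a": extra, "b": b})
        n0 = (base.query("stage == 'b'")["label"] == "novel").sum()
        n1 = (more.query("stage == 'b'")["label"] == "novel").sum()
        assert n1 <= n0


class TestGainedLost:
    def test_identical_stages_nothing_gained_or_lost(self):
        p = peaks_from_tuples([(0, 10), (50, 60)])
        gained, lost = atac.classify_gained_lost(p, p)
        assert len(gained) == 0 and len(lost) == 0

    def test_disjoint_stages_everything_gained_and_lost(self):
        a = peaks_from_tuples([(0, 10)])
        b = peaks_from_tuples([(100, 110)])
        gained, lost = atac.classify_gained_lost(b, a)
        assert len(gained) == 1 and len(lost) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_and_partitions(self, seed):
        rng = np.random.default_rng(300 + seed)
        prev, cur = make_peaks(rng, 150), make_peaks(rng, 150)
        gained, lost = atac.classify_gained_lost(cur, prev)
        assert set(gained["name"]) == set(cur["name"][~brute_overlaps_any(cur, prev)])
        assert set(lost["name"]) == set(prev["name"][~brute_overlaps_any(prev, cur)])
        # gained + retained partition the current stage
        assert len(gained) + brute_overlaps_any(cur, prev).sum() == len(cur)


class TestStageSpecific:
    def test_all_identical_stages_no_specific_peaks(self):
        p = peaks_from_tuples([(0, 10), (50, 60)])
        spec = atac.find_stage_specific_peaks({"a": p, "b": p.copy(), "c": p.copy()})
        assert all(len(v) == 0 for v in spec.values())

    def test_disjoint_stage_fully_specific(self):
        a = peaks_from_tuples([(0, 10)])
        b = peaks_from_tuples([(100, 110)])
        spec = atac.find_stage_specific_peaks({"a": a, "b": b})
        assert len(spec["a"]) == 1 and len(spec["b"]) == 1

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        stages = {f"s{t}": make_peaks(rng, 60) for t in range(4)}
        spec = atac.find_stage_specific_peaks(stages)
        for stage, peaks in stages.items():
            other = pd.concat(
                [p for s, p in stages.items() if s != stage], ignore_index=True
            )
            expect = set(peaks["name"][~brute_overlaps_any(peaks, other)])
            assert set(spec[stage]["name"]) == expect


class TestAnnotation:
    @staticmethod
    def genes():
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10000, 50000],
                "end": [18000, 58000],
                "gene_id": ["GA", "GB"],
                "length": [8000, 8000],
                "strand": ["+", "-"],
                "tss": [10000, 57999],
            }
        )

    def test_center_on_tss_is_promoter_distance_zero(self):
        p = peaks_from_tuples([(9950, 10050)])  # center 10000 == TSS of GA
        ann = atac.annotate_peak_location(p, self.genes())
        assert ann.iloc[0]["category"] == "promoter"
        assert ann.iloc[0]["distance"] == 0

    def test_far_from_everything_is_distal(self):
        p = peaks_from_tuples([(30000, 30100)])
        ann = atac.annotate_peak_location(p, self.genes())
        assert ann.iloc[0]["category"] == "distal_intergenic"

    def test_minus_strand_distance_sign(self):
        # center 57949 is 50 bp downstream of the minus-strand TSS at 57999
        p = peaks_from_tuples([(57899, 57999)])
        ann = atac.annotate_peak_location(p, self.genes())
        assert ann.iloc[0]["gene_id"] == "GB"
        assert ann.iloc[0]["distance"] == 50

    def test_precedence_promoter_over_exon_over_intron(self):
        genes = self.genes()
        exons = pd.DataFrame(
            {"chrom": ["chr1"], "start": [13000], "end": [14000], "gene_id": ["GA"]}
        )
        in_promoter = peaks_from_tuples([(10950, 11050)])  # 1 kb downstream of TSS
        in_exon = peaks_from_tuples([(13400, 13600)])
        in_intron = peaks_from_tuples([(15000, 15100)])  # gene body, not exon
        assert (
            atac.annotate_peak_location(in_promoter, genes, exons).iloc[0]["category"]
            == "promoter"
        )
        assert atac.annotate_peak_location(in_exon, genes, exons).iloc[0]["category"] == "exon"
        assert (
            atac.annotate_peak_location(in_intron, genes, exons).iloc[0]["category"]
            == "intron"
        )

    def test_missing_chromosome_errors(self):
        p = peaks_from_tuples([(0, 100)], chrom="chrZ")
        with pytest.raises(ComputationError):
            atac.annotate_peak_location(p, self.genes())

    def test_nearest_tss_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        n_genes = 40
        tss = np.sort(rng.choice(200000, size=n_genes, replace=False))
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": tss,
                "end": tss + 1000,
                "gene_id": [f"g{i:03d}" for i in range(n_genes)],
                "length": 1000,
                "strand": rng.choice(["+", "-"], n_genes),
            }
        )
        genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
        peaks = make_peaks(rng, 100, chroms=("chr1",), max_pos=200000)
        got = atac.nearest_tss(peaks, genes)
        for (_, p), (_, hit) in zip(peaks.iterrows(), got.iterrows()):
            center = p["start"] + p["summit"]
            d = np.abs(genes["tss"] - center)
            best = genes.loc[d == d.min(), "gene_id"].min()
            assert hit["gene_id"] == best


class TestTssProfile:
    def test_all_peaks_at_tss_in_central_bin(self):
        genes = TestAnnotation.genes()
        p = peaks_from_tuples([(9950, 10050)] * 5)
        prof = atac.tss_proximity_profile(p, genes, window=2000, bin=500)
        central = prof[(prof["bin_left"] == 0)]
        assert central["count"].iloc[0] == 5
        assert prof["count"].sum() == 5

    def test_peaks_outside_window_not_counted(self):
        genes = TestAnnotation.genes()
        p = peaks_from_tuples([(30000, 30100)])  # 12 kb from nearest TSS
        prof = atac.tss_proximity_profile(p, genes, window=2000, bin=500)
        assert prof["count"].sum() == 0


class TestSignalCorrelation:
    def test_scaled_signal_gives_r_one(self):
        x = np.array([1.0, 5.0, 3.0, 8.0])
        assert atac.replicate_signal_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_negated_signal_gives_minus_one(self):
        x = np.array([1.0, 5.0, 3.0, 8.0])
        assert atac.replicate_signal_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(50), rng.random(50)
        xc, yc = x - x.mean(), y - y.mean()
        direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert atac.replicate_signal_correlation(x, y) == pytest.approx(direct, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ComputationError):
            atac.replicate_signal_correlation([1, 1, 1], [1, 2, 3])
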