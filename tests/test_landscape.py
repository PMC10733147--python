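"""Sharedness/geography labels, reciprocal overlap, novelty, merging,
benchmarking, discovery curves, telomere density and CNV regions."""

import itertools

import numpy as np
import pytest
from scipy import stats

from svscape.core import CNVCall, GeneModel, GenomicInterval, GenotypeMatrix, Sample, VariantRecord
from svscape.landscape import (
    AnnotationIndex,
    benchmark_callset,
    community_spread,
    discovery_curve,
    fit_log_model,
    geographic_label,
    merge_callsets,
    merge_cnv_regions,
    novelty_label,
    reciprocal_overlap,
    sharedness,
    telomere_density,
)
from svscape.synthetic import make_annotation_set


def _v(vid, svtype="DEL", pos=1000, svlen=100, chrom="chr1", qual=30.0):
    return VariantRecord(vid, chrom, pos, svtype, svlen, "A" * svlen if svtype == "INS" else "", qual)


# --- independent caption-rule oracles -------------------------------------

def _sharedness_oracle(c, n):
    if c == 1:
        return "PRIVATE"
    if c == n:
        return "SHARED"
    if c / n < 0.5:
        return "POLYMORPHIC"
    return "MAJOR"


def _geo_oracle(carriers):
    focal = {s.sample_id for s in carriers if s.in_focal_set}
    non = {s.sample_id for s in carriers if not s.in_focal_set}
    if focal and not non:
        return "FOCAL_ONLY"
    if non and not focal:
        return "FOCAL_ABSENT"
    return "GLOBAL"


def _spread_oracle(carriers, k):
    if len(carriers) == 1:
        return "PRIVATE"
    comms = {s.community for s in carriers}
    if len(comms) == 1:
        return "COMMUNITY_SPECIFIC"
    return "SHARED_ALL" if len(comms) == k else "WIDESPREAD"


class TestLabels:
    def test_sharedness_examples(self):
        assert sharedness(1, 141) == "PRIVATE"
        assert sharedness(141, 141) == "SHARED"
        assert sharedness(70, 141) == "POLYMORPHIC"  # 70/141 < 0.5
        assert sharedness(71, 141) == "MAJOR"

    def test_sharedness_exhaustive_small_n(self):
        for n in range(1, 9):
            for c in range(1, n + 1):
                assert sharedness(c, n) == _sharedness_oracle(c, n), (c, n)

    def test_sharedness_errors(self):
        with pytest.raises(ValueError):
            sharedness(0, 10)

    def test_geo_and_spread_examples(self):
        p1 = [Sample(f"a{i}", "P1", True) for i in range(3)]
        out = [Sample("o1", "OUTGROUP", False)]
        assert geographic_label(p1) == "FOCAL_ONLY"
        assert community_spread(p1, 4) == "COMMUNITY_SPECIFIC"
        assert geographic_label(out) == "FOCAL_ABSENT"
        assert geographic_label(p1 + out) == "GLOBAL"
        all4 = [Sample(f"s{i}{j}", f"P{j}", True) for j in range(1, 5) for i in range(2)]
        assert community_spread(all4, 4) == "SHARED_ALL"
        assert community_spread(all4[:4], 4) == "WIDESPREAD"

    def test_geo_spread_exhaustive_n8(self):
        """All carrier subsets of an 8-sample cohort match the caption rules."""
        samples = [
            Sample("a1", "P1", True), Sample("a2", "P1", True),
            Sample("b1", "P2", True), Sample("b2", "P2", True),
            Sample("c1", "P3", True), Sample("d1", "P4", True),
            Sample("o1", "OUTGROUP", False), Sample("o2", "OUTGROUP", False),
        ]
        for r in range(1, 9):
            for combo in itertools.combinations(samples, r):
                carriers = list(combo)
                assert geographic_label(carriers) == _geo_oracle(carriers)
                if _geo_oracle(carriers) == "FOCAL_ONLY":
                    assert community_spread(carriers, 4) == _spread_oracle(carriers, 4)

    def test_empty_carriers_error(self):
        with pytest.raises(ValueError):
            geographic_label([])


class TestReciprocalOverlap:
    def test_identical_dels(self):
        assert reciprocal_overlap(_v("a"), _v("b")) == 1.0

    def test_half_overlap(self):
        a = _v("a", pos=0, svlen=100)
        b = _v("b", pos=50, svlen=100)
        assert reciprocal_overlap(a, b) == pytest.approx(0.5)

    def test_ins_size_ratio_with_window(self):
        a = _v("a", "INS", pos=1000, svlen=60)
        b = _v("b", "INS", pos=1100, svlen=100)
        assert reciprocal_overlap(a, b) == pytest.approx(0.6)
        far = _v("c", "INS", pos=1300, svlen=60)
        assert reciprocal_overlap(a, far) == 0.0

    def test_mixed_type_zero(self):
        assert reciprocal_overlap(_v("a", "DEL"), _v("b", "INS", svlen=100)) == 0.0

    def test_brute_force_pairs(self, rng):
        for _ in range(1000):
            svtype = "DEL" if rng.random() < 0.5 else "INS"
            a = _v("a", svtype, int(rng.integers(1, 5000)), int(rng.integers(20, 400)))
            b = _v("b", svtype, int(rng.integers(1, 5000)), int(rng.integers(20, 400)))
            got = reciprocal_overlap(a, b)
            if svtype == "INS":
                exp = (min(a.svlen, b.svlen) / max(a.svlen, b.svlen)) if abs(a.pos - b.pos) <= 200 else 0.0
            else:
                shared = max(0, min(a.pos + a.svlen, b.pos + b.svlen) - max(a.pos, b.pos))
                exp = min(shared / a.svlen, shared / b.svlen)
            assert got == pytest.approx(exp)


class TestNovelty:
    def test_perfect_copy_high(self):
        v = _v("v")
        idx = AnnotationIndex([_v("ann")])
        n = novelty_label(v, idx)
        assert n.label == "HIGH" and n.best_overlap == 1.0 and n.annotated

    def test_moderate_band(self):
        v = _v("v", "INS", pos=1000, svlen=100)
        idx = AnnotationIndex([_v("ann", "INS", pos=1000, svlen=60)])
        assert novelty_label(v, idx).label == "MODERATE"

    def test_unmapped(self):
        v = _v("v")
        idx = AnnotationIndex([_v("ann")])
        assert novelty_label(v, idx, mapping={"other": True}).label == "UNMAPPED"

    def test_none_band(self):
        v = _v("v", chrom="chr2")
        idx = AnnotationIndex([_v("ann")])
        assert novelty_label(v, idx).label == "NONE"

    def test_fixture_matches_brute_force(self, bundle):
        """Novelty labels on the jittered annotation fixture equal the
        brute-force best-single-annotation computation exactly."""
        ann, kept = make_annotation_set(bundle.records, 0.6, jitter_bp=30, size_noise=0.3, seed=5)
        idx = AnnotationIndex(ann)
        for v in bundle.records:
            got = novelty_label(v, idx)
            best = max((reciprocal_overlap(v, a) for a in ann), default=0.0)
            if best > 0.80:
                exp = "HIGH"
            elif best >= 0.50:
                exp = "MODERATE"
            elif best > 0:
                exp = "LOW"
            else:
                exp = "NONE"
            assert got.label == exp and got.best_overlap == pytest.approx(best)

    def test_keep_all_and_keep_none(self, bundle):
        sub = bundle.records[:50]
        ann_all, _ = make_annotation_set(sub, 1.0, jitter_bp=0, size_noise=0.0, seed=1)
        idx = AnnotationIndex(ann_all)
        assert all(novelty_label(v, idx).label == "HIGH" for v in sub)
        ann_none, _ = make_annotation_set(sub, 0.0, seed=1)
        idx0 = AnnotationIndex(ann_none)
        assert all(novelty_label(v, idx0).label == "NONE" for v in sub)


class TestMergeAndBenchmark:
    def test_identical_callsets_collapse(self):
        calls = [_v(f"v{i}", pos=1000 * (i + 1)) for i in range(5)]
        merged = merge_callsets({"s1": calls, "s2": calls})
        assert len(merged) == 5
        assert all(set(m.carriers()) == {"s1", "s2"} for m in merged)

    def test_disjoint_callsets_sum(self):
        a = [_v(f"a{i}", pos=1000 * (i + 1)) for i in range(3)]
        b = [_v(f"b{i}", pos=100_000 + 1000 * (i + 1)) for i in range(4)]
        assert len(merge_callsets({"s1": a, "s2": b})) == 7

    def test_jittered_duplicates_collapse_to_truth(self, rng):
        truth = [_v(f"t{i}", pos=int(p), svlen=400) for i, p in enumerate(rng.integers(5000, 500_000, 30))]
        callsets = {}
        for s in ("s1", "s2", "s3"):
            calls = []
            for t in truth:
                j = int(rng.integers(-50, 51))
                calls.append(_v(f"{s}_{t.id}", pos=t.pos + j, svlen=t.svlen, qual=float(rng.uniform(10, 60))))
            callsets[s] = calls
        merged = merge_callsets(callsets)
        assert len(merged) == len(truth)

    def test_benchmark_self_is_perfect(self, rng):
        calls = [_v(f"v{i}", pos=int(p), svlen=int(l))
                 for i, (p, l) in enumerate(zip(rng.integers(1000, 90_000, 20), rng.integers(20, 500, 20)))]
        res = benchmark_callset(calls, calls)
        assert (res.tp, res.fp, res.fn) == (20, 0, 0)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_missing_truth_entries(self):
        truth = [_v(f"t{i}", pos=5000 * (i + 1)) for i in range(10)]
        calls = truth[:8]
        res = benchmark_callset(calls, truth)
        assert res.precision == 1.0 and res.recall == pytest.approx(0.8)

    def test_breakpoint_window_boundary(self):
        t = [_v("t", "INS", pos=10_000, svlen=100)]
        near = [_v("c", "INS", pos=10_180, svlen=100)]
        far = [_v("c", "INS", pos=10_250, svlen=100)]
        assert benchmark_callset(near, t).tp == 1
        assert benchmark_callset(far, t).tp == 0

    def test_empty_truth_recall_na(self):
        res = benchmark_callset([_v("c")], [])
        assert res.recall is None and res.precision == 0.0


class TestDiscoveryCurve:
    def _matrix(self, presence):
        presence = np.asarray(presence, dtype=np.int8)
        samples = [Sample(f"s{j}", "P1", True) for j in range(presence.shape[1])]
        return GenotypeMatrix([f"v{i}" for i in range(presence.shape[0])], samples, presence)

    def test_identical_samples_flat(self):
        m = self._matrix(np.ones((30, 6)))
        c = discovery_curve(m, seed=1)
        assert np.all(c.cumulative_counts == 30)

    def test_all_private_cumulative(self):
        pres = np.eye(8, dtype=np.int8)
        c = discovery_curve(self._matrix(pres), seed=1)
        assert np.allclose(c.cumulative_counts, np.arange(1, 9))

    def test_monotone_and_permutation_invariant_final(self, bundle, rng):
        from svscape.core import build_genotype_matrix

        m = build_genotype_matrix(bundle.records, bundle.samples)
        c1 = discovery_curve(m, seed=1)
        c2 = discovery_curve(m, seed=99)
        assert np.all(np.diff(c1.cumulative_counts) >= 0)
        assert c1.cumulative_counts[-1] == c2.cumulative_counts[-1]

    def test_log_fit_recovery(self):
        n = np.arange(1, 51)
        counts = 120.0 + 35.0 * np.log(n)
        a, b = fit_log_model(counts)
        assert abs(a - 120.0) / 120.0 < 0.05 and abs(b - 35.0) / 35.0 < 0.05


class TestTelomereDensity:
    def test_bin_zero(self):
        d = telomere_density([_v("v", pos=0)], {"chr1": 2_000_000})
        assert d["all"][0] > 0

    def test_uniform_flat(self, rng):
        """Uniformly placed variants give a flat profile (chi-square, a=0.01)."""
        L = 10_000_000
        variants = [_v(f"v{i}", pos=int(p)) for i, p in enumerate(rng.integers(0, L, 4000))]
        d = telomere_density(variants, {"chr1": L})["all"]
        counts = d * 2  # undo the per-arm averaging: raw counts per bin
        chi2, p = stats.chisquare(counts)
        assert p > 0.01

    def test_enriched_tr_near_telomere(self):
        """The generator's telomere-enriched TR class exceeds the genome-wide
        mean in end bins, while other classes stay flat."""
        from svscape.classify import classify_records
        from svscape.synthetic import SimulationConfig, simulate_bundle

        cfg = SimulationConfig(seed=11, telomere_enrichment=True)
        b = simulate_bundle(cfg)
        labels = dict(zip(b.truth.variant_id, b.truth.true_label))
        scale = 50_000  # 10% end region of a 500 kb chromosome
        d = telomere_density(b.records, b.reference.chrom_lengths, bin_size=scale, labels=labels)
        tr = d["TR"]
        assert tr[0] > tr[1:].mean()


class TestCnvRegions:
    def _call(self, sid, start, end, p=1e-5, t="deletion", chrom="chr1"):
        return CNVCall(sid, GenomicInterval(chrom, start, end), t, p)

    def test_p_value_filter(self):
        calls = [self._call("s1", 0, 100_000, p=2e-4)]
        assert merge_cnv_regions(calls, n_samples=10) == []

    def test_short_calls_dropped(self):
        calls = [self._call("s1", 0, 40_000)]
        assert merge_cnv_regions(calls, n_samples=10) == []

    def test_reciprocal_overlap_merge(self):
        calls = [self._call("s1", 0, 100_000), self._call("s2", 30_000, 120_000)]
        (region,) = merge_cnv_regions(calls, n_samples=10)
        assert (region.interval.start, region.interval.end) == (0, 120_000)
        assert region.n_carriers == 2 and region.sharedness == "polymorphic"

    def test_gene_containment_strict(self):
        calls = [self._call("s1", 10_000, 100_000)]
        inside = GeneModel("gin", GenomicInterval("chr1", 20_000, 30_000), [], 5)
        straddle = GeneModel("gout", GenomicInterval("chr1", 95_000, 105_000), [], 5)
        (region,) = merge_cnv_regions(calls, n_samples=10, genes=[inside, straddle])
        assert [g.gene_id for g in region.contained_genes] == ["gin"]
        assert region.sharedness == "singleton"
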