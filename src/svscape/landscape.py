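"""Cohort-level characterization of the non-redundant callset.

Sharedness, geographic and community-spread labels; graded reciprocal
overlap against external annotation sets (novelty); simplified overlap-based
callset merging and benchmarking; discovery curves with a logarithmic fit;
telomere-distance density profiles; and merged large-CNV regions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import CNVCall, GeneModel, GenomicInterval, Sample, VariantRecord, GenotypeMatrix

log = logging.getLogger("svscape")

SHAREDNESS_LABELS = ("PRIVATE", "POLYMORPHIC", "MAJOR", "SHARED")
GEO_LABELS = ("FOCAL_ONLY", "FOCAL_ABSENT", "GLOBAL")
SPREAD_LABELS = ("PRIVATE", "COMMUNITY_SPECIFIC", "WIDESPREAD", "SHARED_ALL")


def sharedness(carrier_count: int, n_samples: int) -> str:
    """Carrier-count class: private (1 individual), polymorphic (>1 and
    <50% of individuals), major (>=50% but not all), shared (all)."""
    c, n = carrier_count, n_samples
    if not 1 <= c <= n:
        raise ValueError(f"carrier count {c} outside [1, {n}]")
    if c == 1:
        return "PRIVATE"
    if c == n:
        return "SHARED"
    return "POLYMORPHIC" if c / n < 0.5 else "MAJOR"


def geographic_label(carriers: Sequence[Sample]) -> str:
    """FOCAL_ONLY / FOCAL_ABSENT / GLOBAL from the carriers' focal flags."""
    if not carriers:
        raise ValueError("empty carrier set")
    focal = [s.in_focal_set for s in carriers]
    if all(focal):
        return "FOCAL_ONLY"
    if not any(focal):
        return "FOCAL_ABSENT"
    return "GLOBAL"


def community_spread(carriers: Sequence[Sample], n_communities: int) -> str:
    """Spread of a focal-only variant over the community partition."""
    if not carriers:
        raise ValueError("empty carrier set")
    if len(carriers) == 1:
        return "PRIVATE"
    comms = {s.community for s in carriers}
    if len(comms) == 1:
        return "COMMUNITY_SPECIFIC"
    if len(comms) == n_communities:
        return "SHARED_ALL"
    return "WIDESPREAD"


def reciprocal_overlap(a: VariantRecord, b: VariantRecord, ins_window: int = 200) -> float:
    """Mutual overlap fraction between two variants of the same type.

    DEL/DEL: shared bp divided by the longer interval (equivalently the
    minimum of the two shared/length ratios).  INS/INS are point events:
    when anchors lie within ``ins_window`` bp the overlap is the size ratio
    min(svlen)/max(svlen), else 0.  Mixed types or chromosomes give 0.
    """
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return 0.0
    if a.svtype == "INS":
        if abs(a.pos - b.pos) > ins_window:
            return 0.0
        return min(a.svlen, b.svlen) / max(a.svlen, b.svlen)
    shared = a.interval.overlap(b.interval)
    if shared <= 0:
        return 0.0
    return min(shared / a.svlen, shared / b.svlen)


def breakpoints_within(a: VariantRecord, b: VariantRecord, window: int = 200) -> bool:
    if a.svtype == "INS":
        return abs(a.pos - b.pos) <= window
    return abs(a.pos - b.pos) <= window and abs((a.pos + a.svlen) - (b.pos + b.svlen)) <= window


def is_match(a: VariantRecord, b: VariantRecord, min_ro: float = 0.5, window: int = 200) -> bool:
    """Type match + reciprocal overlap >= 50% + breakpoints within 200 bp."""
    return (
        a.svtype == b.svtype
        and a.chrom == b.chrom
        and reciprocal_overlap(a, b, ins_window=window) >= min_ro
        and breakpoints_within(a, b, window)
    )


@dataclass
class NoveltyLabel:
    label: str  # HIGH | MODERATE | LOW | NONE | UNMAPPED
    best_overlap: float = 0.0
    best_annotation: str | None = None

    @property
    def annotated(self) -> bool:
        return self.label in ("HIGH", "MODERATE")


def _overlap_band(best: float) -> str:
    if best > 0.80:
        return "HIGH"
    if best >= 0.50:
        return "MODERATE"
    if best > 0.0:
        return "LOW"
    return "NONE"


class AnnotationIndex:
    """Chromosome/position-indexed annotation set for best-overlap queries."""

    def __init__(self, annotations: Sequence[VariantRecord]):
        self._by_chrom: dict = defaultdict(list)
        for a in annotations:
            self._by_chrom[(a.chrom, a.svtype)].append(a)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda r: r.pos)

    def candidates(self, v: VariantRecord, window: int = 200) -> list:
        lst = self._by_chrom.get((v.chrom, v.svtype), [])
        lo = v.pos - window - (v.svlen if v.svtype == "DEL" else 0)
        out = []
        for a in lst:
            if a.pos + (a.svlen if a.svtype == "DEL" else 0) + window < v.pos - (v.svlen if v.svtype == "DEL" else 0):
                continue
            if a.pos > v.pos + v.svlen + window:
                break
            out.append(a)
        return out


def novelty_label(
    variant: VariantRecord,
    annotations: AnnotationIndex,
    mapping: Mapping[str, bool] | None = None,
) -> NoveltyLabel:
    """Graded best single-annotation reciprocal overlap.

    Bands: high (>80%), moderate (50-80%), low (<50%), none (0%); high and
    moderate count as "annotated".  With an explicit coordinate-mapping
    table (the lift-over surrogate), variants absent from it are UNMAPPED.
    """
    if mapping is not None and variant.id not in mapping:
        return NoveltyLabel("UNMAPPED")
    best, best_id = 0.0, None
    for a in annotations.candidates(variant):
        ro = reciprocal_overlap(variant, a)
        if ro > best:
            best, best_id = ro, a.id
    return NoveltyLabel(_overlap_band(best), best, best_id)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_callsets(
    per_sample_callsets: Mapping[str, Sequence[VariantRecord]],
    min_ro: float = 0.5,
    window: int = 200,
) -> list:
    """Merge per-sample callsets into a non-redundant joint callset.

    Single-linkage clustering of records matching on type, reciprocal
    overlap >= 0.5 and breakpoints within 200 bp.  The representative of
    each cluster is its highest-qual member; presence is recorded per
    sample in the representative's genotypes.
    """
    flat, owner = [], []
    for sample_id, calls in per_sample_callsets.items():
        for r in calls:
            flat.append(r)
            owner.append(sample_id)
    order = sorted(range(len(flat)), key=lambda i: (flat[i].chrom, flat[i].pos))
    uf = _UnionFind(len(flat))
    for oi, i in enumerate(order):
        vi = flat[i]
        reach = vi.pos + vi.svlen + window
        for j in order[oi + 1 :]:
            vj = flat[j]
            if vj.chrom != vi.chrom or vj.pos > reach:
                break
            if is_match(vi, vj, min_ro, window):
                uf.union(i, j)
    clusters: dict = defaultdict(list)
    for i in range(len(flat)):
        clusters[uf.find(i)].append(i)
    merged = []
    all_samples = list(per_sample_callsets)
    for members in clusters.values():
        rep_i = max(members, key=lambda i: flat[i].qual)
        rep = flat[rep_i]
        carriers = {owner[i] for i in members}
        genotypes = {s: ("0/1" if s in carriers else "0/0") for s in all_samples}
        merged.append(
            VariantRecord(
                id=rep.id, chrom=rep.chrom, pos=rep.pos, svtype=rep.svtype,
                svlen=rep.svlen, seq=rep.seq, qual=rep.qual,
                support_fraction=rep.support_fraction, genotypes=genotypes,
            )
        )
    merged.sort(key=lambda r: (r.chrom, r.pos, r.id))
    return merged


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float | None
    matches: list = field(default_factory=list)  # (call_id, truth_id, ro)


def benchmark_callset(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    min_ro: float = 0.5,
    window: int = 200,
) -> BenchmarkResult:
    """Precision/recall against a truth set.

    True positives match in type with >= 50% reciprocal overlap and
    breakpoints within 200 bp; matching is greedy one-to-one by descending
    overlap.  precision = TP/(TP+FP), recall = TP/(TP+FN); recall is None
    for an empty truth set.
    """
    pairs = []
    truth_idx = AnnotationIndex(truth)
    truth_pos = {id(t): k for k, t in enumerate(truth)}
    for ci, c in enumerate(calls):
        for t in truth_idx.candidates(c, window):
            if is_match(c, t, min_ro, window):
                pairs.append((reciprocal_overlap(c, t), ci, truth_pos[id(t)], t.id))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_c, used_t, matches = set(), set(), []
    for ro, ci, ti, tid in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append((calls[ci].id, tid, ro))
    tp = len(matches)
    fp = len(calls) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if truth else None
    return BenchmarkResult(tp, fp, fn, precision, recall, matches)


@dataclass
class DiscoveryCurve:
    cumulative_counts: np.ndarray  # mean over permutations, length n_samples
    intercept: float  # a in count = a + b*ln(n)
    slope: float  # b
    n_permutations: int
    seed: int


def discovery_curve(matrix: GenotypeMatrix, seed: int = 0, n_permutations: int = 10) -> DiscoveryCurve:
    """Cumulative non-redundant variant count as individuals are added.

    The addition order is randomized; the mean curve over permutations is
    reported together with the least-squares fit of count = a + b*ln(n).
    """
    pres = matrix.presence.astype(bool)
    n_var, n_samp = pres.shape
    if n_samp < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, n_samp))
    for k in range(n_permutations):
        order = rng.permutation(n_samp)
        seen = np.zeros(n_var, dtype=bool)
        for j, s in enumerate(order):
            seen |= pres[:, s]
            curves[k, j] = seen.sum()
    mean_curve = curves.mean(axis=0)
    return DiscoveryCurve(mean_curve, *fit_log_model(mean_curve), n_permutations, seed)


def fit_log_model(counts: Sequence[float]) -> tuple:
    """Least-squares fit of count = a + b*ln(n), n = 1..len(counts)."""
    counts = np.asarray(counts, dtype=float)
    n = np.arange(1, counts.size + 1)
    X = np.column_stack([np.ones_like(n, dtype=float), np.log(n)])
    (a, b), *_ = np.linalg.lstsq(X, counts, rcond=None)
    return float(a), float(b)


def telomere_density(
    variants: Sequence[VariantRecord],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 500_000,
    labels: Mapping[str, str] | None = None,
) -> dict:
    """Mean per-bin variant counts by distance to the nearest telomere.

    Distance = min(pos, chrom_length - pos); variants fall into fixed
    ``bin_size`` windows and counts are averaged across chromosomes (each
    chromosome contributes to the bins its arms reach).  Returns
    {type_label: mean counts per bin}; with no ``labels`` a single "all"
    profile is produced.
    """
    chrom_reach = {
        c: max(1, -(-int(L / 2) // bin_size)) for c, L in chrom_lengths.items()
    }
    max_bins = max(chrom_reach.values())
    # bins covered by k chromosomes each
    coverage = np.zeros(max_bins)
    for c, reach in chrom_reach.items():
        coverage[:reach] += 2  # two arms per chromosome
    counts: dict = defaultdict(lambda: np.zeros(max_bins))
    for v in variants:
        L = chrom_lengths[v.chrom]
        dist = min(v.start, L - v.start)
        b = min(int(dist // bin_size), chrom_reach[v.chrom] - 1)
        lbl = labels.get(v.id, "all") if labels is not None else "all"
        counts[lbl][b] += 1
    return {lbl: arr / np.maximum(coverage, 1) for lbl, arr in counts.items()}


def smooth_log_counts(counts: np.ndarray, frac: float = 0.75) -> np.ndarray:
    """LOESS smoothing of log(count + 1), returned on the count scale."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.arange(counts.size, dtype=float)
    sm = lowess(np.log(counts + 1.0), x, frac=frac, return_sorted=False)
    return np.exp(sm) - 1.0


@dataclass
class CNVRegion:
    interval: GenomicInterval
    members: list
    n_carriers: int
    sharedness: str  # singleton | polymorphic | major
    geo: str | None
    contained_genes: list


def _cnv_ro(a: CNVCall, b: CNVCall) -> float:
    shared = a.interval.overlap(b.interval)
    if shared <= 0:
        return 0.0
    return min(shared / a.interval.length, shared / b.interval.length)


def merge_cnv_regions(
    calls: Sequence[CNVCall],
    n_samples: int,
    genes: Sequence[GeneModel] = (),
    samples_by_id: Mapping[str, Sample] | None = None,
    p_threshold: float = 1e-4,
    min_ro: float = 0.5,
    min_length: int = 50_000,
) -> list:
    """Merge per-sample CNV calls into regions of variable copy number.

    Calls with p > 1e-4 or length <= 50 kb are excluded; the rest are
    single-linkage clustered on > 50% reciprocal overlap.  Regions are
    classified by carrier count (singleton: 1; polymorphic: >1 and <50% of
    individuals; major: >=50% but not all) and, when sample metadata is
    given, by geography.  Genes are reported only when fully contained in
    the region span.
    """
    kept = [c for c in calls if c.p_value <= p_threshold]
    short = [c for c in kept if c.interval.length <= min_length]
    if short:
        log.warning("dropping %d CNV calls <= %d bp", len(short), min_length)
    kept = [c for c in kept if c.interval.length > min_length]
    uf = _UnionFind(len(kept))
    order = sorted(range(len(kept)), key=lambda i: (kept[i].interval.chrom, kept[i].interval.start))
    for oi, i in enumerate(order):
        for j in order[oi + 1 :]:
            if kept[j].interval.chrom != kept[i].interval.chrom:
                break
            if kept[j].interval.start >= kept[i].interval.end:
                break
            if _cnv_ro(kept[i], kept[j]) > min_ro:
                uf.union(i, j)
    clusters: dict = defaultdict(list)
    for i in range(len(kept)):
        clusters[uf.find(i)].append(i)
    regions = []
    for members in clusters.values():
        calls_m = [kept[i] for i in members]
        chrom = calls_m[0].interval.chrom
        span = GenomicInterval(
            chrom,
            min(c.interval.start for c in calls_m),
            max(c.interval.end for c in calls_m),
        )
        carriers = {c.sample_id for c in calls_m}
        nc = len(carriers)
        if nc == 1:
            share = "singleton"
        elif nc / n_samples < 0.5:
            share = "polymorphic"
        else:
            share = "major"
        geo = None
        if samples_by_id is not None:
            geo = geographic_label([samples_by_id[s] for s in carriers])
        contained = [g for g in genes if span.contains(g.span)]
        regions.append(CNVRegion(span, calls_m, nc, share, geo, contained))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def label_cohort(matrix: GenotypeMatrix, n_communities: int | None = None) -> dict:
    """Sharedness, geographic and spread labels for every variant.

    Returns {variant_id: dict(sharedness=..., geo=..., spread=...)}; spread
    is only defined for FOCAL_ONLY variants, else None.  Variants with no
    carriers are skipped.
    """
    pres = matrix.presence.astype(bool)
    n = len(matrix.samples)
    focal_comms = sorted({s.community for s in matrix.samples if s.in_focal_set})
    k = n_communities if n_communities is not None else len(focal_comms)
    out = {}
    for i, vid in enumerate(matrix.variant_ids):
        carriers = [matrix.samples[j] for j in np.flatnonzero(pres[i])]
        if not carriers:
            continue
        geo = geographic_label(carriers)
        out[vid] = dict(
            sharedness=sharedness(len(carriers), n),
            geo=geo,
            spread=community_spread(carriers, k) if geo == "FOCAL_ONLY" else None,
        )
    return out
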