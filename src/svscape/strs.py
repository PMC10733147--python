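"""STR-specific analyses.

Canonical motif collapsing (all rotations on both strands are one redundant
motif), significant-expansion criteria, diploid allele genotyping from
haplotype-edited local sequence, and cross-community variability statistics
(one-way ANOVA on allele lengths, min-max normalized per-community SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import find_tandem_repeats, revcomp
from .core import GenomicInterval, VariantRecord

_ACGT = set("ACGT")


@dataclass(frozen=True)
class CanonicalMotif:
    canonical: str
    members: frozenset


def canonical_motif(motif: str) -> CanonicalMotif:
    """Collapse a motif to its canonical redundant representative.

    All rotations of the motif and of its reverse complement form one
    class (e.g. CAG, AGC, GCA, TGC, GCT, CTG are a single triplet); the
    canonical string is the lexicographic minimum of that class.
    """
    motif = motif.upper()
    if not motif or set(motif) - _ACGT:
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    members = set()
    for seq in (motif, revcomp(motif)):
        for i in range(len(seq)):
            members.add(seq[i:] + seq[:i])
    return CanonicalMotif(min(members), frozenset(members))


@dataclass
class STRLocus:
    site: GenomicInterval
    period: int
    motif: str
    reference_length: int


def is_significant_expansion(period: int, reference_length: int, expansion_bp: int) -> bool:
    """Expansion-discovery criteria, applied conjunctively.

    (1) period >= 3 bp; (2) expanded by >= 10 repeat units; (3) expanded by
    >= 50% of the reference element size; (4) reference element < 1 kb.
    """
    if period < 2:
        raise ValueError("period must be >= 2 for STR analyses")
    return (
        period >= 3
        and expansion_bp / period >= 10
        and expansion_bp >= 0.5 * reference_length
        and reference_length < 1000
    )


@dataclass
class STRAllelePair:
    sample_id: str
    site: GenomicInterval
    allele_a: str  # the longer allele
    allele_b: str
    period: int | None = None
    motif: str | None = None

    @property
    def lengths(self) -> tuple:
        return len(self.allele_a), len(self.allele_b)


def _apply_haplotype(local_seq: str, offset: int, variants: Sequence[VariantRecord]) -> tuple:
    """Apply phased INS/DEL edits to a local sequence slice.

    ``offset`` is the genomic coordinate of local_seq[0].  Returns the
    edited sequence and a mapping function genomic->edited coordinates.
    """
    edits = sorted(variants, key=lambda v: v.start)
    for a, b in zip(edits, edits[1:]):
        if a.start == b.start:
            raise ValueError(f"conflicting variants at {a.chrom}:{a.start} on one haplotype")
    out = []
    shift_points = []  # (genomic position, cumulative shift after it)
    cursor = offset
    shift = 0
    for v in edits:
        s = v.start - offset
        if s < 0 or s > len(local_seq):
            continue
        out.append(local_seq[cursor - offset : s])
        if v.svtype == "INS":
            out.append(v.seq)
            cursor = v.start
            shift += v.svlen
        else:
            cursor = min(v.start + v.svlen, offset + len(local_seq))
            shift -= cursor - v.start
        shift_points.append((v.start, shift))
    out.append(local_seq[cursor - offset :])
    edited = "".join(out)

    def to_edited(gpos: int) -> int:
        s = 0
        for p, sh in shift_points:
            if gpos > p:
                s = sh
            else:
                break
        return gpos - offset + s

    return edited, to_edited


def genotype_str_site(
    reference,
    site: GenomicInterval,
    hap1_variants: Sequence[VariantRecord] = (),
    hap2_variants: Sequence[VariantRecord] = (),
    sample_id: str = "",
    window: int = 50,
    context: int = 500,
) -> STRAllelePair:
    """Diploid STR genotyping from haplotype-resolved local variants.

    Each haplotype's variants are incorporated into the local reference
    sequence; the consensus allele is the edited sequence in a +-50 bp
    window centred on the STR site.  The longer allele is allele_A.  Period
    and motif come from the built-in tandem detector run on allele_A.
    """
    seq = reference[site.chrom]
    lo = max(0, site.start - window - context)
    hi = site.end + window + context
    piece = seq[lo:hi]
    local = str(getattr(piece, "seq", piece)).upper()

    alleles = []
    for hv in (hap1_variants, hap2_variants):
        edited, to_edited = _apply_haplotype(local, lo, hv)
        a = max(0, to_edited(site.start) - window)
        b = min(len(edited), to_edited(site.end) + window)
        alleles.append(edited[a:b])
    allele_a, allele_b = sorted(alleles, key=len, reverse=True)
    period = motif = None
    anns = find_tandem_repeats(allele_a)
    if anns:
        top = max(anns, key=lambda t: t.end - t.start)
        period, motif = top.period, top.motif
    return STRAllelePair(sample_id, site, allele_a, allele_b, period, motif)


@dataclass
class SiteVariability:
    community_means: dict
    community_sds: dict
    normalized_sds: dict  # min-max over communities, in [0, 1]
    f_statistic: float
    p_value: float


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple:
    """One-way fixed-effects ANOVA from sums of squares.

    F = MS_between / MS_within with df (k-1, N-k); the p-value is the upper
    tail of the F distribution.  Degenerate inputs (zero within-group
    variance, equal means) return F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([g.size for g in groups])
    N = int(ns.sum())
    if k < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return f, p


def site_variability(allele_lengths_by_community: Mapping[str, Sequence[float]]) -> SiteVariability:
    """Cross-community variability of allele lengths at one STR site.

    Both alleles of each individual enter as observations.  Per-community
    SDs are min-max normalized across communities to [0, 1]; for a constant
    row all normalized values are 0.
    """
    comms = sorted(allele_lengths_by_community)
    groups = [np.asarray(allele_lengths_by_community[c], dtype=float) for c in comms]
    f, p = anova_oneway(groups)
    means = {c: float(g.mean()) for c, g in zip(comms, groups)}
    sds = {c: float(g.std(ddof=1)) for c, g in zip(comms, groups)}
    vals = np.array([sds[c] for c in comms])
    rng_ = vals.max() - vals.min()
    if rng_ == 0:
        norm = {c: 0.0 for c in comms}
    else:
        norm = {c: float((sds[c] - vals.min()) / rng_) for c in comms}
    return SiteVariability(means, sds, norm, f, p)


def variability_matrix(sites: Mapping[str, SiteVariability], alpha: float = 0.05) -> pd.DataFrame:
    """Normalized-SD heatmap input: significant sites x communities."""
    rows = {
        sid: sv.normalized_sds for sid, sv in sites.items() if sv.p_value < alpha
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def motif_and_period_tables(
    str_records: Sequence[VariantRecord],
    periods: Mapping[str, int],
    motifs: Mapping[str, str],
    contexts: Mapping[str, str] | None = None,
) -> dict:
    """Frequency tables for classified STR variants.

    Returns per-period counts, per-period genomic-context proportions
    (CDS / NONCDS / INTERGENIC) and per-period canonical-motif counts.
    """
    period_counts: dict = {}
    context_counts: dict = {}
    motif_counts: dict = {}
    for r in str_records:
        p = periods.get(r.id)
        if p is None:
            continue
        period_counts[p] = period_counts.get(p, 0) + 1
        if contexts is not None:
            ctx = contexts.get(r.id, "INTERGENIC")
            context_counts.setdefault(p, {"CDS": 0, "NONCDS": 0, "INTERGENIC": 0})
            context_counts[p][ctx] += 1
        m = motifs.get(r.id)
        if m:
            canon = canonical_motif(m).canonical
            motif_counts.setdefault(p, {})
            motif_counts[p][canon] = motif_counts[p].get(canon, 0) + 1
    period_df = pd.DataFrame(
        sorted(period_counts.items()), columns=["period", "count"]
    ).set_index("period") if period_counts else pd.DataFrame(columns=["count"])
    context_df = (
        pd.DataFrame.from_dict(context_counts, orient="index").sort_index()
        if context_counts
        else pd.DataFrame()
    )
    if not context_df.empty:
        context_df = context_df.div(context_df.sum(axis=1), axis=0)
    return dict(period_counts=period_df, context_proportions=context_df, motif_counts=motif_counts)
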