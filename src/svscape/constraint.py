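"""Size-normalized variant density across LOEUF deciles.

Genes are binned by LOEUF decile (1 = most intolerant to loss of function).
Variant density is the count of non-redundant variants hitting CDS regions
of a decile's genes divided by the total CDS bp of that decile; non-CDS
density uses the gene span padded by 2 kb each side (introns, UTRs and
proximal regulatory sequence) minus CDS, counting only variants that do not
touch CDS.  Depletion in low deciles is the footprint of purifying
selection.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, IntervalIndex, VariantRecord, intersect, merged_length

PAD = 2000


def partition_hits(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    pad: int = PAD,
) -> dict:
    """Assign each variant to CDS, NONCDS or INTERGENIC.

    CDS wins if any CDS bp is hit; otherwise NONCDS if the variant lies
    within a +-2 kb padded gene span; else INTERGENIC.  A variant hitting
    genes in several deciles is counted once, in the lowest (most
    constrained) decile.  Returns {variant_id: (region_class, decile|None)}.
    """
    cds_index, span_index = IntervalIndex(), IntervalIndex()
    for g in genes:
        for c in g.cds:
            cds_index.add(c, data=g)
        span_index.add(g.padded_span(pad), data=g)
    out = {}
    for v in variants:
        bp, _ = intersect(v, cds_index)
        if bp > 0:
            iv = v.interval
            deciles = [d.loeuf_decile for _, d in cds_index.query(iv.chrom, iv.start, iv.end)]
            out[v.id] = ("CDS", min(deciles))
            continue
        iv = v.interval
        hits = span_index.query(iv.chrom, iv.start, iv.end)
        if hits:
            out[v.id] = ("NONCDS", min(d.loeuf_decile for _, d in hits))
        else:
            out[v.id] = ("INTERGENIC", None)
    return out


def region_sizes(genes: Sequence[GeneModel], pad: int = PAD) -> pd.DataFrame:
    """Merged (non-overlapping) CDS and non-CDS bp per decile."""
    rows = []
    for decile in range(1, 11):
        sub = [g for g in genes if g.loeuf_decile == decile]
        cds_by_chrom, span_by_chrom = defaultdict(list), defaultdict(list)
        for g in sub:
            for c in g.cds:
                cds_by_chrom[c.chrom].append((c.start, c.end))
            p = g.padded_span(pad)
            span_by_chrom[p.chrom].append((p.start, p.end))
        cds_bp = sum(merged_length(v) for v in cds_by_chrom.values())
        span_bp = sum(merged_length(v) for v in span_by_chrom.values())
        rows.append(dict(decile=decile, cds_bp=cds_bp, noncds_bp=max(0, span_bp - cds_bp)))
    return pd.DataFrame(rows).set_index("decile")


def decile_density(
    assignments: Mapping[str, tuple],
    genes: Sequence[GeneModel],
    types: Mapping[str, str] | None = None,
    pad: int = PAD,
) -> pd.DataFrame:
    """Variant density per decile x region class (x variant type).

    Density = variant count / merged region bp.  Per-type densities carry a
    ``normalized`` column: density divided by that type's decile-10 value,
    so decile 10 is 1.0 by construction.  Deciles with zero region bp get
    NA density.
    """
    sizes = region_sizes(genes, pad)
    counts: dict = defaultdict(int)
    for vid, (region, decile) in assignments.items():
        if region == "INTERGENIC" or decile is None:
            continue
        t = types.get(vid, "all") if types is not None else "all"
        counts[(decile, region, t)] += 1
        if types is not None:
            counts[(decile, region, "all")] += 1
    rows = []
    all_types = sorted({k[2] for k in counts} | {"all"})
    for decile in range(1, 11):
        for region, bp_col in (("CDS", "cds_bp"), ("NONCDS", "noncds_bp")):
            bp = int(sizes.loc[decile, bp_col])
            for t in all_types:
                cnt = counts.get((decile, region, t), 0)
                rows.append(
                    dict(
                        decile=decile, region_class=region, vtype=t,
                        variant_count=cnt, region_bp=bp,
                        density=(cnt / bp) if bp > 0 else np.nan,
                    )
                )
    df = pd.DataFrame(rows)
    norm = []
    for _, r in df.iterrows():
        ref = df[
            (df.decile == 10) & (df.region_class == r.region_class) & (df.vtype == r.vtype)
        ].density.iloc[0]
        norm.append(r.density / ref if ref and np.isfinite(ref) and ref > 0 else np.nan)
    df["normalized"] = norm
    return df


def fold_difference(density_low_decile: float, density_high_decile: float) -> float:
    """Fold reduction: density in the least constrained decile divided by
    the most constrained one.  NA (nan) on a zero denominator."""
    if density_low_decile == 0:
        return float("nan")
    return density_high_decile / density_low_decile
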