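"""Core domain types and variant-level primitives.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  ``VariantRecord.pos`` stores the
1-based VCF POS of the padding base; because VCF pads deletions with the base
*before* the event, the 0-based start of the deleted interval is numerically
equal to POS.  Insertions are treated as point events anchored at a single
base: for genomic intersections an insertion occupies ``[pos, pos + 1)``,
while size-based computations use its ``svlen``.

Size classes follow the long-read SV literature: "large indel" = 20-49 bp,
"SV" = 50 bp and above.  Records below 20 bp are never analyzed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger("svscape")

MISSING = -1  # dosage sentinel for ./. genotypes

# genotype string -> diploid alt-allele dosage
_GT_DOSAGE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class VariantRecord:
    """One INS/DEL call with consensus sequence and per-sample genotypes.

    ``seq`` is the inserted consensus (INS) or the deleted reference sequence
    (DEL; may be empty when only coordinates are known).  ``support_fraction``
    is the fraction of reads supporting the ALT allele.
    """

    id: str
    chrom: str
    pos: int  # 1-based VCF POS (padding base)
    svtype: str  # "INS" | "DEL"
    svlen: int  # always positive
    seq: str = ""
    qual: float = 0.0
    support_fraction: float = 1.0
    genotypes: dict = field(default_factory=dict)  # sample_id -> "0/0" etc.

    def __post_init__(self):
        if self.svtype not in ("INS", "DEL"):
            raise ValueError(f"unsupported svtype {self.svtype!r} for {self.id}")
        if self.svlen <= 0:
            raise ValueError(f"svlen must be positive for {self.id}")

    @property
    def start(self) -> int:
        """0-based start: first deleted base (DEL) or insertion anchor (INS)."""
        return self.pos

    @property
    def interval(self) -> GenomicInterval:
        """Footprint used for genomic intersections.

        DEL: the deleted reference interval.  INS: a single-base anchor.
        """
        if self.svtype == "DEL":
            return GenomicInterval(self.chrom, self.start, self.start + self.svlen)
        return GenomicInterval(self.chrom, self.start, self.start + 1)

    @property
    def is_sv(self) -> bool:
        return self.svlen >= 50

    @property
    def size_class(self) -> str:
        return "SV" if self.is_sv else "large_indel"

    def carriers(self) -> list:
        return [s for s, g in self.genotypes.items() if _GT_DOSAGE.get(g, 0) and _GT_DOSAGE.get(g, 0) > 0]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    community: str
    in_focal_set: bool


@dataclass
class GeneModel:
    """Protein-coding gene with CDS blocks and a LOEUF decile (1 = most constrained)."""

    gene_id: str
    span: GenomicInterval
    cds: list  # list[GenomicInterval]
    loeuf_decile: int

    def __post_init__(self):
        if not 1 <= self.loeuf_decile <= 10:
            raise ValueError(f"loeuf_decile out of range for {self.gene_id}")
        for c in self.cds:
            if not self.span.contains(c):
                raise ValueError(f"CDS outside span for {self.gene_id}")

    def padded_span(self, pad: int = 2000) -> GenomicInterval:
        return GenomicInterval(
            self.span.chrom, max(0, self.span.start - pad), self.span.end + pad
        )


@dataclass
class CNVCall:
    sample_id: str
    interval: GenomicInterval
    cnv_type: str  # "deletion" | "duplication"
    p_value: float


class GenotypeMatrix:
    """Variants x samples dosage/presence table.

    ``dosage`` holds 0/1/2 with -1 for missing.  The binary ``presence``
    matrix (dosage >= 1) is the substrate for sharedness, PCOA, Bray-Curtis
    and discovery curves; missing genotypes count as absence there but are
    excluded from allele-count statistics such as FST.
    """

    def __init__(self, variant_ids: Sequence[str], samples: Sequence[Sample], dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(variant_ids), len(samples)):
            raise ValueError("dosage shape does not match variant/sample lists")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("duplicate variant ids")
        self.variant_ids = list(variant_ids)
        self.samples = list(samples)
        self.dosage = dosage

    @property
    def presence(self) -> np.ndarray:
        return (self.dosage >= 1).astype(np.int8)

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def communities(self) -> np.ndarray:
        return np.array([s.community for s in self.samples])

    def carrier_counts(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def subset_variants(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            [self.variant_ids[i] for i in idx], self.samples, self.dosage[idx]
        )

    def to_tsv(self, path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("variant_id\t" + "\t".join(self.sample_ids) + "\n")
            for vid, row in zip(self.variant_ids, self.dosage):
                fh.write(vid + "\t" + "\t".join(str(int(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path, samples: Sequence[Sample] | None = None) -> "GenotypeMatrix":
        variant_ids, rows = [], []
        with open(path) as fh:
            header = None
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if header is None:
                    header = parts[1:]
                    continue
                variant_ids.append(parts[0])
                rows.append([int(x) for x in parts[1:]])
        if samples is None:
            samples = [Sample(s, "NA", True) for s in header]
        else:
            by_id = {s.sample_id: s for s in samples}
            samples = [by_id[s] for s in header]
        return cls(variant_ids, samples, np.array(rows, dtype=np.int8))


def filter_variants(
    records: Iterable[VariantRecord],
    min_qual: float = 5.0,
    min_del_support: float = 0.20,
    min_ins_support: float = 0.05,
    min_size: int = 20,
) -> list:
    """Apply the callset quality filters.

    Retains records with qual >= 5, svlen >= 20 bp, and type-specific read
    support: deletions need >= 20% supporting reads, insertions >= 5%.
    Idempotent by construction.
    """
    out = []
    for r in records:
        if r.qual < min_qual or r.svlen < min_size:
            continue
        min_support = min_del_support if r.svtype == "DEL" else min_ins_support
        if r.support_fraction < min_support:
            continue
        out.append(r)
    return out


def build_genotype_matrix(records: Sequence[VariantRecord], samples: Sequence[Sample]) -> GenotypeMatrix:
    """Convert per-record genotype dicts into a GenotypeMatrix.

    Rows are variants, columns individuals; 0/1 and 1/1 count as presence.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids in record list")
    dosage = np.empty((len(records), len(samples)), dtype=np.int8)
    for i, r in enumerate(records):
        for j, s in enumerate(samples):
            g = r.genotypes.get(s.sample_id, "./.")
            if g not in _GT_DOSAGE:
                raise ValueError(f"unparseable genotype {g!r} for {r.id}/{s.sample_id}")
            dosage[i, j] = _GT_DOSAGE[g]
    return GenotypeMatrix(ids, samples, dosage)


class IntervalIndex:
    """Per-chromosome interval lookup backed by interval trees."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval, data=None) -> None:
        if iv.length == 0:
            return
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, data)

    def query(self, chrom: str, start: int, end: int) -> list:
        """Return (GenomicInterval, data) pairs overlapping [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        return [
            (GenomicInterval(chrom, h.begin, h.end), h.data)
            for h in sorted(tree.overlap(start, end))
        ]


def intersect(variant: VariantRecord, index: IntervalIndex):
    """Overlap of a variant's footprint with an interval set.

    Returns ``(total_bp, hits)`` where ``total_bp`` is the union of the
    hit-restricted overlaps (no double counting of overlapping intervals)
    and ``hits`` the list of intersected intervals.
    """
    iv = variant.interval
    pairs = index.query(iv.chrom, iv.start, iv.end)
    hits = [p[0] for p in pairs]
    if not hits:
        return 0, []
    clipped = sorted(
        (max(h.start, iv.start), min(h.end, iv.end)) for h in hits
    )
    total, cur_s, cur_e = 0, clipped[0][0], clipped[0][1]
    for s, e in clipped[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total, hits


def merged_length(intervals: Iterable[tuple]) -> int:
    """Total bp of the union of (start, end) pairs."""
    ivs = sorted(intervals)
    if not ivs:
        return 0
    total, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)
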