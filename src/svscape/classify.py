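"""Variant repeat-context classification.

Each insertion or deletion is embedded in an *extended local allele*: the
variant sequence flanked on each side by reference sequence of twice the
variant size, so the allele is 5x the variant length and the variant itself
is its central 20%.  The allele is scanned for tandem repeats (built-in
detector, or Tandem Repeats Finder output via an adapter) and for
interspersed mobile elements (built-in k-mer matcher against a consensus
library, or RepeatMasker output via an adapter).  The variant is assigned
to a repeat class when >= 75% of the variant region is covered by
annotations of a single type; mobile-element variants are further labelled
"complete" when the variant contains >= 75% of a canonical element,
otherwise "fragment".

Tandem periods map to classes: 1 bp -> HOMO (homopolymer), 2-12 bp -> STR,
>12 bp -> TR.  Homopolymer calls are excluded from downstream analyses by
default because they are enriched for long-read sequencing errors.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import VariantRecord, merged_length

log = logging.getLogger("svscape")

TANDEM_LABELS = ("HOMO", "STR", "TR")
ME_FAMILIES = ("SINE", "LINE", "DNA", "LTR", "Retroposon", "Other")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ExtendedAllele:
    sequence: str
    variant_start: int
    variant_end: int
    clipped: bool = False

    @property
    def variant_region(self):
        return (self.variant_start, self.variant_end)


@dataclass
class TandemAnnotation:
    start: int
    end: int
    period: int
    motif: str
    copy_number: float
    purity: float


@dataclass
class ElementHit:
    start: int
    end: int
    family: str
    element_name: str
    consensus_fraction: float
    orientation: str  # "+" | "-"
    consensus_start: int = 0
    consensus_end: int = 0
    identity: float = 1.0


@dataclass
class RepeatClassification:
    label: str  # NONREP | HOMO | STR | TR | SINE | LINE | DNA | LTR | RETROPOSON | OTHER_ME
    me_completeness: str = "n/a"  # complete | fragment | n/a
    coverage: float = 0.0
    period: int | None = None
    motif: str | None = None
    evidence: list = field(default_factory=list)


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a dict of strings or a pyfaidx Fasta."""
    seq = reference[chrom]
    piece = seq[start:end]
    return str(getattr(piece, "seq", piece)).upper()


def build_extended_allele(variant: VariantRecord, reference, chrom_length: int | None = None) -> ExtendedAllele:
    """Construct the 5x extended local allele for a variant.

    INS: 2x-size reference flanks around the anchor with the consensus
    insertion between them.  DEL: a contiguous reference slice covering the
    deleted interval plus 2x flanks.  Flanks are clipped (and flagged) at
    contig edges.
    """
    L = variant.svlen
    flank = 2 * L
    if chrom_length is None:
        chrom_length = len(reference[variant.chrom])
    if variant.svtype == "INS":
        anchor = variant.start
        left_s = max(0, anchor - flank)
        right_e = min(chrom_length, anchor + flank)
        left = _fetch(reference, variant.chrom, left_s, anchor)
        right = _fetch(reference, variant.chrom, anchor, right_e)
        clipped = len(left) < flank or len(right) < flank
        seq = left + variant.seq.upper() + right
        return ExtendedAllele(seq, len(left), len(left) + L, clipped)
    s, e = variant.start, variant.start + L
    left_s = max(0, s - flank)
    right_e = min(chrom_length, e + flank)
    seq = _fetch(reference, variant.chrom, left_s, right_e)
    vstart = s - left_s
    clipped = (s - left_s) < flank or (right_e - e) < flank
    return ExtendedAllele(seq, vstart, vstart + L, clipped)


def find_tandem_repeats(
    sequence: str,
    max_period: int = 500,
    min_score: int = 50,
    min_purity: float = 0.8,
    match_score: int = 2,
    mismatch_penalty: int = 7,
) -> list:
    """Simplified tandem-repeat scan.

    For each candidate period p, positions i with s[i] == s[i-p] are
    "matches"; maximal regions with purity >= 0.8 and score
    (2*matches - 7*mismatches) >= 50 are reported.  Substitutions are
    tolerated, indels are not.  Harmonics are suppressed: a region at
    period p is dropped when most of it is already explained by a
    smaller-period call.  Scoring parallels the Tandem Repeats Finder
    recommended parameter set (2 7 7 80 10 50 500).
    """
    n = len(sequence)
    if n == 0:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    annotations: list[TandemAnnotation] = []
    accepted: list[tuple[int, int]] = []  # regions already explained (start, end)
    base = np.full(n, -mismatch_penalty, dtype=np.int64)
    for p in range(1, min(max_period, n - 1) + 1):
        m = arr[p:] == arr[:-p]
        # fast path: best position-level segment score via prefix sums;
        # most periods have no segment reaching min_score
        v = base[: m.size].copy()
        v[m] = match_score
        S = np.cumsum(v)
        gains = S - np.minimum.accumulate(np.concatenate(([0], S[:-1])))
        if gains.max(initial=0) < min_score:
            continue
        # run-length encode into alternating match/gap segments
        mi = m.view(np.int8)
        diffs = np.flatnonzero(np.diff(mi))
        bounds = np.concatenate(([0], diffs + 1, [m.size]))
        seg_lens = np.diff(bounds)
        first_is_match = bool(m[0])
        vals = np.where(
            (np.arange(seg_lens.size) % 2 == 0) == first_is_match,
            match_score * seg_lens,
            -mismatch_penalty * seg_lens,
        )
        # slow path: extract disjoint maximal-scoring segments over runs
        segments = _max_scoring_segments(vals, min_score)
        for i0, i1 in segments:
            cs, ce = int(bounds[i0]), int(bounds[i1 + 1])
            matches = int(seg_lens[i0 : i1 + 1][vals[i0 : i1 + 1] > 0].sum())
            purity = matches / (ce - cs)
            if purity < min_purity:
                continue
            start, end = cs, ce + p  # array spans one extra period to the right
            length = end - start
            if length < 2 * p:
                continue
            # harmonic suppression against smaller-period calls
            covered = sum(
                max(0, min(end, ae) - max(start, as_)) for as_, ae in accepted
            )
            if covered / length >= 0.5:
                continue
            motif = _modal_unit(sequence, start, end, p)
            annotations.append(
                TandemAnnotation(
                    start=start,
                    end=end,
                    period=p,
                    motif=motif,
                    copy_number=length / p,
                    purity=purity,
                )
            )
            accepted.append((start, end))
    return annotations


def _max_scoring_segments(vals: np.ndarray, min_score: int) -> list:
    """Disjoint maximal-scoring segments over run values (Kadane variant).

    Returns (first_run, last_run) index pairs; segments start and end on
    positive-valued runs.
    """
    out = []
    cur = 0.0
    cur_start = None
    best = 0.0
    best_end = None
    i = 0
    nseg = len(vals)
    while i < nseg:
        v = float(vals[i])
        if cur_start is None:
            if v > 0:
                cur_start, cur, best, best_end = i, v, v, i
        else:
            cur += v
            if cur > best:
                best, best_end = cur, i
            if cur <= 0:
                if best >= min_score:
                    out.append((cur_start, best_end))
                    i = best_end  # rescan after the emitted segment
                cur_start, cur = None, 0.0
        i += 1
    if cur_start is not None and best >= min_score:
        out.append((cur_start, best_end))
    return out


def _modal_unit(sequence: str, start: int, end: int, p: int) -> str:
    units = [sequence[i : i + p] for i in range(start, end - p + 1, p)]
    return Counter(units).most_common(1)[0][0]


def classify_period(period: int) -> str:
    """Map tandem period to HOMO (1 bp), STR (2-12 bp) or TR (>12 bp)."""
    if period < 1:
        raise ValueError("period must be >= 1")
    if period == 1:
        return "HOMO"
    if period <= 12:
        return "STR"
    return "TR"


class RepeatLibrary:
    """Named mobile-element consensus sequences plus STR/TR unit catalogues."""

    def __init__(self, elements: Sequence[tuple], str_motifs: Sequence[str] = (), tr_units: Sequence[str] = ()):
        # elements: (name, family, consensus)
        self.elements = [(n, f, s.upper()) for n, f, s in elements]
        self.str_motifs = list(str_motifs)
        self.tr_units = list(tr_units)
        self._kmer_index = None
        self._k = None

    def kmer_index(self, k: int = 15):
        if self._kmer_index is None or self._k != k:
            index: dict = defaultdict(list)
            for ei, (name, family, cons) in enumerate(self.elements):
                for orient, seq in (("+", cons), ("-", revcomp(cons))):
                    for i in range(len(seq) - k + 1):
                        index[seq[i : i + k]].append((ei, orient, i))
            self._kmer_index = dict(index)
            self._k = k
        return self._kmer_index


def find_mobile_elements(
    sequence: str,
    library: RepeatLibrary,
    k: int = 15,
    max_gap: int = 50,
    min_identity: float = 0.8,
    min_span: int = 30,
) -> list:
    """Seed-and-chain mobile-element matcher.

    Exact shared 15-mers with a consensus (either orientation) seed hits;
    seeds on the same alignment diagonal are chained when gaps are <= 50 bp
    and the chained region has >= 80% identity.  consensus_fraction is the
    fraction of the canonical element covered by the chain.  Tolerates
    substitutions, not indels.
    """
    sequence = sequence.upper()
    index = library.kmer_index(k)
    nq = len(sequence)
    # (elem, orient, diagonal) -> list of query seed positions
    groups: dict = defaultdict(list)
    for i in range(nq - k + 1):
        hits = index.get(sequence[i : i + k])
        if not hits:
            continue
        for ei, orient, cpos in hits:
            groups[(ei, orient, i - cpos)].append(i)
    out = []
    for (ei, orient, diag), qpos_list in groups.items():
        name, family, cons = library.elements[ei]
        cseq = cons if orient == "+" else revcomp(cons)
        qpos_list.sort()
        # split into chains on gaps larger than max_gap (+k for seed width)
        chains = [[qpos_list[0]]]
        for q in qpos_list[1:]:
            if q - chains[-1][-1] <= max_gap + k:
                chains[-1].append(q)
            else:
                chains.append([q])
        for chain in chains:
            qs, qe = chain[0], chain[-1] + k
            if qe - qs < min_span:
                continue
            cs, ce = qs - diag, qe - diag
            qsub, csub = sequence[qs:qe], cseq[cs:ce]
            ident = sum(a == b for a, b in zip(qsub, csub)) / max(1, len(qsub))
            if ident < min_identity:
                continue
            if orient == "+":
                cons_s, cons_e = cs, ce
            else:  # convert coordinates on the reverse strand back to consensus
                cons_s, cons_e = len(cons) - ce, len(cons) - cs
            out.append(
                ElementHit(
                    start=qs,
                    end=qe,
                    family=family,
                    element_name=name,
                    consensus_fraction=(ce - cs) / len(cons),
                    orientation=orient,
                    consensus_start=cons_s,
                    consensus_end=cons_e,
                    identity=ident,
                )
            )
    out.sort(key=lambda h: (h.start, h.end))
    return out


def coverage_fraction(variant_region: tuple, annotations: Iterable) -> float:
    """Fraction of the variant region covered by the union of annotations."""
    vs, ve = variant_region
    if ve <= vs:
        raise ValueError("zero-length variant region")
    clipped = [
        (max(a.start, vs), min(a.end, ve))
        for a in annotations
        if a.end > vs and a.start < ve
    ]
    return merged_length(clipped) / (ve - vs)


_TANDEM_ORDER = {"HOMO": 0, "STR": 1, "TR": 2}


def classify_variant(
    variant: VariantRecord,
    allele: ExtendedAllele,
    tandem_annotations: Sequence[TandemAnnotation],
    element_hits: Sequence[ElementHit],
    coverage_threshold: float = 0.75,
    complete_threshold: float = 0.75,
) -> RepeatClassification:
    """Assign the repeat-context label for one variant.

    Tandem classes are evaluated first (coverage per HOMO/STR/TR; ties break
    toward the larger period class since a p-periodic array is trivially
    np-periodic); then mobile-element families; otherwise NONREP.
    """
    region = allele.variant_region
    vs, ve = region
    # --- tandem classes
    by_class: dict = {lbl: [] for lbl in TANDEM_LABELS}
    for a in tandem_annotations:
        by_class[classify_period(a.period)].append(a)
    tandem_cov = {lbl: coverage_fraction(region, anns) if anns else 0.0 for lbl, anns in by_class.items()}
    best_lbl = max(tandem_cov, key=lambda l: (tandem_cov[l], _TANDEM_ORDER[l]))
    if tandem_cov[best_lbl] >= coverage_threshold:
        anns = by_class[best_lbl]
        top = max(anns, key=lambda a: min(a.end, ve) - max(a.start, vs))
        return RepeatClassification(
            label=best_lbl,
            me_completeness="n/a",
            coverage=tandem_cov[best_lbl],
            period=top.period,
            motif=top.motif,
            evidence=list(anns),
        )
    # --- mobile-element families
    by_family: dict = defaultdict(list)
    for h in element_hits:
        by_family[h.family].append(h)
    fam_cov = {f: coverage_fraction(region, hits) for f, hits in by_family.items()}
    if fam_cov:
        best_fam = max(fam_cov, key=fam_cov.get)
        if fam_cov[best_fam] >= coverage_threshold:
            hits = by_family[best_fam]
            completeness = "fragment"
            for h in hits:
                inside = max(0, min(h.end, ve) - max(h.start, vs))
                # ungapped chain: query bp inside the variant == consensus bp
                if h.consensus_fraction * inside / max(1, h.end - h.start) >= complete_threshold:
                    completeness = "complete"
                    break
            label = "RETROPOSON" if best_fam == "Retroposon" else (
                "OTHER_ME" if best_fam == "Other" else best_fam
            )
            return RepeatClassification(
                label=label,
                me_completeness=completeness,
                coverage=fam_cov[best_fam],
                evidence=list(hits),
            )
    best_any = max([*tandem_cov.values(), *fam_cov.values()] or [0.0])
    return RepeatClassification(label="NONREP", coverage=best_any)


def classify_records(
    records: Sequence[VariantRecord],
    reference,
    library: RepeatLibrary,
    tandem_by_id: Mapping[str, Sequence[TandemAnnotation]] | None = None,
    element_by_id: Mapping[str, Sequence[ElementHit]] | None = None,
    scan_pad: int = 600,
    **kwargs,
) -> dict:
    """Classify every record; returns id -> RepeatClassification.

    Pre-computed annotations (e.g. parsed TRF/RepeatMasker output, keyed by
    variant id) override the built-in detectors.  The built-in scans run on
    the variant region padded by ``scan_pad`` (>= the maximum tandem period,
    so every annotation overlapping the variant region is still found);
    classification only consults annotations overlapping that region, so the
    labels are unchanged while large-allele scans stay cheap.
    """
    out = {}
    for r in records:
        allele = build_extended_allele(r, reference)
        vs, ve = allele.variant_region
        a = max(0, vs - scan_pad)
        b = min(len(allele.sequence), ve + scan_pad)
        window = allele.sequence[a:b]
        if tandem_by_id is not None and r.id in tandem_by_id:
            tand = tandem_by_id[r.id]
        else:
            tand = find_tandem_repeats(window)
            for t in tand:
                t.start += a
                t.end += a
        if element_by_id is not None and r.id in element_by_id:
            elems = element_by_id[r.id]
        else:
            elems = find_mobile_elements(window, library)
            for h in elems:
                h.start += a
                h.end += a
        out[r.id] = classify_variant(r, allele, tand, elems, **kwargs)
    return out


def flag_homopolymers(classifications: Mapping[str, RepeatClassification]):
    """Split ids into (analysis set, homopolymer-flagged set)."""
    keep, flagged = [], []
    for vid, c in classifications.items():
        (flagged if c.label == "HOMO" else keep).append(vid)
    return keep, flagged


# ---------------------------------------------------------------------------
# adapters for real TRF / RepeatMasker output


def parse_trf_dat(path) -> dict:
    """Parse Tandem Repeats Finder ``.dat`` output.

    Returns {sequence_name: [TandemAnnotation, ...]}.  TRF coordinates are
    1-based inclusive; they are converted to 0-based half-open.
    """
    out: dict = defaultdict(list)
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("Sequence:"):
                current = line.split(None, 1)[1].split()[0]
                continue
            if not line or line[0].isalpha() or line.startswith("Parameters"):
                continue
            parts = line.split()
            if len(parts) < 14:
                continue
            try:
                start, end = int(parts[0]), int(parts[1])
                period = int(parts[2])
                copy_number = float(parts[3])
                pct_match = float(parts[5])
                motif = parts[13]
            except ValueError:
                log.warning("skipping malformed TRF line: %r", line)
                continue
            out[current].append(
                TandemAnnotation(
                    start=start - 1,
                    end=end,
                    period=period,
                    motif=motif,
                    copy_number=copy_number,
                    purity=pct_match / 100.0,
                )
            )
    return dict(out)


_RM_FAMILY = {
    "SINE": "SINE",
    "LINE": "LINE",
    "DNA": "DNA",
    "LTR": "LTR",
    "RETROPOSON": "Retroposon",
    "SVA": "Retroposon",
}


def map_repeatmasker_family(class_family: str) -> str:
    """Map a RepeatMasker class/family string (e.g. "SINE/Alu") to a family."""
    head = class_family.split("/")[0].upper()
    if "SVA" in class_family.upper():
        return "Retroposon"
    return _RM_FAMILY.get(head, "Other")


def parse_repeatmasker_out(path) -> dict:
    """Parse RepeatMasker ``.out`` files into {query: [ElementHit, ...]}.

    consensus_fraction is derived from the repeat begin/end/(left) columns.
    """
    out: dict = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 15 or not parts[0].lstrip("-").isdigit():
                continue
            try:
                qname = parts[4]
                qbegin, qend = int(parts[5]), int(parts[6])
                strand = "+" if parts[8] == "+" else "-"
                name = parts[9]
                family = map_repeatmasker_family(parts[10])
                if strand == "+":
                    rb, re_, rleft = parts[11], parts[12], parts[13]
                else:
                    rleft, re_, rb = parts[11], parts[12], parts[13]
                rb = int(rb.strip("()"))
                re_ = int(re_.strip("()"))
                rleft = int(rleft.strip("()"))
            except (ValueError, IndexError):
                log.warning("skipping malformed RepeatMasker line: %r", line.rstrip())
                continue
            total = re_ + rleft
            frac = (re_ - rb + 1) / total if total > 0 else 0.0
            out[qname].append(
                ElementHit(
                    start=qbegin - 1,
                    end=qend,
                    family=family,
                    element_name=name,
                    consensus_fraction=min(1.0, max(0.0, frac)),
                    orientation=strand,
                    consensus_start=rb - 1,
                    consensus_end=re_,
                )
            )
    return dict(out)
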