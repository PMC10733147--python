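"""Standard-format I/O: SV VCF, sample metadata, gene models, CNV calls.

VCF records carry SVTYPE/SVLEN/END in INFO and GT in FORMAT.  Insertions
store their consensus sequence in the ALT allele (padding-base convention);
deletions store the deleted sequence in REF.  SVLEN is written negative for
deletions, as most SV callers do, and normalized to a positive length on
read.  SUPP_FRAC (fraction of supporting reads) is an optional INFO key.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pysam

from .core import CNVCall, GeneModel, GenomicInterval, Sample, VariantRecord

log = logging.getLogger("svscape")

_GT_TUPLE = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), "./.": (None, None)}
_TUPLE_GT = {v: k for k, v in _GT_TUPLE.items()}
_TUPLE_GT[(1, 0)] = "0/1"


def read_sample_metadata(path) -> list:
    """Read sample metadata TSV: sample_id, community, in_focal_set."""
    samples = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            samples.append(
                Sample(
                    sample_id=row["sample_id"],
                    community=row["community"],
                    in_focal_set=row["in_focal_set"].lower() in ("1", "true", "yes"),
                )
            )
    return samples


def write_sample_metadata(samples: Sequence[Sample], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        fh.write("sample_id\tcommunity\tin_focal_set\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.community}\t{int(s.in_focal_set)}\n")


def read_sv_vcf(path, sample_metadata: Sequence[Sample] | None = None):
    """Read an SV/indel VCF into (records, samples).

    Records lacking SVLEN are rejected with a warning.  When metadata is
    supplied, every genotyped column must map to a known sample.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_metadata is not None:
            known = {s.sample_id: s for s in sample_metadata}
            unknown = [s for s in vcf_samples if s not in known]
            if unknown:
                raise ValueError(f"VCF samples missing from metadata: {unknown}")
            samples = [known[s] for s in vcf_samples]
        else:
            samples = [Sample(s, "NA", True) for s in vcf_samples]
        for rec in vcf:

            def info_get(key, default=None):
                try:
                    return rec.info.get(key, default)
                except ValueError:  # key not declared in header
                    return default

            svtype = info_get("SVTYPE")
            svlen = info_get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svtype not in ("INS", "DEL") or svlen is None:
                log.warning("skipping record %s: missing/unsupported SVTYPE or SVLEN", rec.id)
                continue
            svlen = abs(int(svlen))
            alt = rec.alts[0] if rec.alts else ""
            if svtype == "INS":
                if alt and not alt.startswith("<"):
                    seq = alt[1:]  # strip padding base
                else:
                    seq = info_get("SEQ", "") or ""
            else:
                seq = rec.ref[1:] if len(rec.ref) > 1 else ""
            genotypes = {}
            for s in vcf_samples:
                gt = rec.samples[s].get("GT")
                if gt is None or gt == (None,) or None in gt:
                    genotypes[s] = "./."
                else:
                    genotypes[s] = _TUPLE_GT.get(tuple(gt), "./.")
            records.append(
                VariantRecord(
                    id=rec.id or f"{rec.chrom}_{rec.pos}_{svtype}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    svtype=svtype,
                    svlen=svlen,
                    seq=seq,
                    qual=rec.qual if rec.qual is not None else 0.0,
                    support_fraction=float(info_get("SUPP_FRAC", 1.0)),
                    genotypes=genotypes,
                )
            )
    return records, samples


def write_sv_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[Sample],
    path,
    contig_lengths: Mapping[str, int],
    reference: Mapping[str, str] | None = None,
    extra_header_lines: Iterable[str] = (),
) -> None:
    """Write records to a VCF 4.2 file.

    ``reference`` (chrom -> sequence or pyfaidx-like) supplies padding bases;
    without it 'N' is used.
    """
    header = pysam.VariantHeader()
    for line in extra_header_lines:
        header.add_line(line)
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of variant (negative for DEL)")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SUPP_FRAC", 1, "Float", "Fraction of reads supporting ALT")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s.sample_id)

    def pad_base(chrom, pos0):
        if reference is None or pos0 < 0:
            return "N"
        seq = reference[chrom]
        base = seq[pos0 : pos0 + 1]
        return str(getattr(base, "seq", base)).upper() or "N"

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda x: (x.chrom, x.pos, x.id)):
            pad = pad_base(r.chrom, r.pos - 1)
            if r.svtype == "INS":
                ref, alt = pad, pad + r.seq
                end, svlen = r.pos, r.svlen
            else:
                deleted = r.seq if r.seq else "N" * r.svlen
                ref, alt = pad + deleted, pad
                end, svlen = r.pos + r.svlen, -r.svlen
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(ref, alt),
                id=r.id,
                qual=r.qual,
            )
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = svlen
            rec.stop = end  # pysam routes the reserved END key via .stop
            rec.info["SUPP_FRAC"] = r.support_fraction
            for s in samples:
                rec.samples[s.sample_id]["GT"] = _GT_TUPLE[r.genotypes.get(s.sample_id, "./.")]
            out.write(rec)


def read_gene_models(path) -> list:
    """Read gene models TSV: gene_id, chrom, start, end, cds_blocks, loeuf_decile.

    ``cds_blocks`` is comma-separated "start-end" pairs (0-based half-open).
    """
    genes = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            chrom = row["chrom"]
            cds = []
            if row["cds_blocks"]:
                for blk in row["cds_blocks"].split(","):
                    s, e = blk.split("-")
                    cds.append(GenomicInterval(chrom, int(s), int(e)))
            genes.append(
                GeneModel(
                    gene_id=row["gene_id"],
                    span=GenomicInterval(chrom, int(row["start"]), int(row["end"])),
                    cds=cds,
                    loeuf_decile=int(row["loeuf_decile"]),
                )
            )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        fh.write("gene_id\tchrom\tstart\tend\tcds_blocks\tloeuf_decile\n")
        for g in genes:
            blocks = ",".join(f"{c.start}-{c.end}" for c in g.cds)
            fh.write(
                f"{g.gene_id}\t{g.span.chrom}\t{g.span.start}\t{g.span.end}\t"
                f"{blocks}\t{g.loeuf_decile}\n"
            )


def read_cnv_calls(path) -> list:
    """Read per-sample large-CNV calls TSV: sample_id, chrom, start, end, cnv_type, p_value."""
    calls = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            calls.append(
                CNVCall(
                    sample_id=row["sample_id"],
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    cnv_type=row["cnv_type"],
                    p_value=float(row["p_value"]),
                )
            )
    return calls


def write_fasta(sequences: Mapping[str, str], path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
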