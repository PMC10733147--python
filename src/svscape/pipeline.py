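"""End-to-end pipeline driver: filter -> classify -> landscape -> novelty ->
constraint -> STR -> population structure.

All randomness flows from ``PipelineConfig.seed``; outputs carry a header
with the config hash and seed, contain no timestamps, and are byte-identical
across re-runs with the same config.  Stage failures abort with a
stage-tagged error and nothing is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import constraint as constraint_mod
from . import io as svio
from .classify import classify_records, flag_homopolymers
from .core import build_genotype_matrix, filter_variants
from .landscape import (
    AnnotationIndex,
    discovery_curve,
    label_cohort,
    merge_cnv_regions,
    novelty_label,
    telomere_density,
)
from .popstruct import bray_curtis, pcoa, subset_common_svs, wc_fst
from .strs import motif_and_period_tables, site_variability
from .synthetic import default_library

log = logging.getLogger("svscape")


@dataclass
class PipelineConfig:
    """Input paths and the analysis thresholds (defaults as used throughout)."""

    vcf: str = ""
    fasta: str = ""
    genes: str = ""
    metadata: str = ""
    annotation_vcf: str = ""
    cnv_calls: str = ""
    outdir: str = "svscape_out"
    seed: int = 0
    # thresholds
    min_qual: float = 5.0
    min_del_support: float = 0.20
    min_ins_support: float = 0.05
    min_size: int = 20
    coverage_threshold: float = 0.75
    complete_threshold: float = 0.75
    ro_match: float = 0.50
    ro_high: float = 0.80
    breakpoint_window: int = 200
    cnv_p_threshold: float = 1e-4
    telomere_bin: int = 500_000
    gene_pad: int = 2000
    fst_n_loci: int = 10_000
    fst_min_freq: float = 0.10
    drop_homopolymers: bool = True

    def config_hash(self) -> str:
        """Hash of inputs and thresholds; the output location is excluded so
        identical analyses hash identically wherever they are written."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns {"summary": dict, "master": DataFrame, paths...}.
    """

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    with stage("load"):
        samples = svio.read_sample_metadata(config.metadata)
        records, samples = svio.read_sv_vcf(config.vcf, samples)
        genes = svio.read_gene_models(config.genes) if config.genes else []
        summary["n_input_records"] = len(records)

    with stage("filter"):
        records = filter_variants(
            records,
            min_qual=config.min_qual,
            min_del_support=config.min_del_support,
            min_ins_support=config.min_ins_support,
            min_size=config.min_size,
        )
        summary["n_after_filter"] = len(records)

    with stage("classify"):
        if not config.fasta:
            raise FileNotFoundError("reference FASTA required for classification")
        p = Path(config.fasta)
        if not p.exists():
            raise FileNotFoundError(f"reference FASTA not found: {p}")
        import pyfaidx

        reference = pyfaidx.Fasta(str(p))
        library = default_library()
        classifications = classify_records(
            records,
            reference,
            library,
            coverage_threshold=config.coverage_threshold,
            complete_threshold=config.complete_threshold,
        )
        keep_ids, homo_ids = flag_homopolymers(classifications)
        summary["n_homopolymer_flagged"] = len(homo_ids)
        analysis_records = [
            r for r in records if (r.id in set(keep_ids)) or not config.drop_homopolymers
        ]
        label_counts: dict = {}
        for vid in (r.id for r in analysis_records):
            lbl = classifications[vid].label
            label_counts[lbl] = label_counts.get(lbl, 0) + 1
        summary["class_counts"] = dict(sorted(label_counts.items()))

    with stage("landscape"):
        matrix = build_genotype_matrix(analysis_records, samples)
        labels = label_cohort(matrix)
        share_counts: dict = {}
        geo_counts: dict = {}
        for lab in labels.values():
            share_counts[lab["sharedness"]] = share_counts.get(lab["sharedness"], 0) + 1
            geo_counts[lab["geo"]] = geo_counts.get(lab["geo"], 0) + 1
        summary["sharedness_counts"] = dict(sorted(share_counts.items()))
        summary["geo_counts"] = dict(sorted(geo_counts.items()))
        curve = discovery_curve(matrix, seed=config.seed)
        summary["discovery_fit"] = {
            "intercept": round(curve.intercept, 4),
            "slope": round(curve.slope, 4),
            "final_count": float(curve.cumulative_counts[-1]),
        }
        chrom_lengths = {name: len(reference[name]) for name in reference.keys()}
        type_labels = {r.id: classifications[r.id].label for r in analysis_records}
        telo = telomere_density(
            analysis_records, chrom_lengths, bin_size=config.telomere_bin, labels=type_labels
        )
        summary["telomere_bins"] = {
            lbl: [round(float(x), 4) for x in arr] for lbl, arr in sorted(telo.items())
        }

    with stage("novelty"):
        if config.annotation_vcf:
            ann_records, _ = svio.read_sv_vcf(config.annotation_vcf)
            index = AnnotationIndex(ann_records)
            nov = {r.id: novelty_label(r, index) for r in analysis_records}
            nov_counts: dict = {}
            for n in nov.values():
                nov_counts[n.label] = nov_counts.get(n.label, 0) + 1
            summary["novelty_counts"] = dict(sorted(nov_counts.items()))
            annotated = sum(1 for n in nov.values() if n.annotated)
            summary["annotated_fraction"] = round(annotated / max(1, len(nov)), 4)
        else:
            nov = {}

    with stage("constraint"):
        if genes:
            assignments = constraint_mod.partition_hits(
                analysis_records, genes, pad=config.gene_pad
            )
            density = constraint_mod.decile_density(assignments, genes, types=type_labels)
            cds_all = density[(density.region_class == "CDS") & (density.vtype == "all")]
            d1 = cds_all[cds_all.decile == 1].density.iloc[0]
            d10 = cds_all[cds_all.decile == 10].density.iloc[0]
            summary["cds_fold_decile10_vs_1"] = (
                round(constraint_mod.fold_difference(d1, d10), 4)
                if d1 and np.isfinite(d1)
                else None
            )
        else:
            assignments, density = {}, pd.DataFrame()

    with stage("str"):
        str_ids = [r.id for r in analysis_records if classifications[r.id].label == "STR"]
        periods = {vid: classifications[vid].period for vid in str_ids}
        motifs = {vid: classifications[vid].motif for vid in str_ids}
        contexts = {vid: assignments[vid][0] for vid in str_ids if vid in assignments}
        str_records = [r for r in analysis_records if r.id in set(str_ids)]
        tables = motif_and_period_tables(str_records, periods, motifs, contexts or None)
        summary["n_str_variants"] = len(str_ids)
        summary["str_period_counts"] = {
            int(p): int(c) for p, c in tables["period_counts"]["count"].items()
        }
        # cross-community variability of length deltas at STR loci
        comm_order = sorted({s.community for s in samples})
        sig_sites = 0
        pres = matrix.presence
        by_comm_idx = {
            c: [j for j, s in enumerate(samples) if s.community == c] for c in comm_order
        }
        for r in str_records:
            i = matrix.variant_ids.index(r.id)
            lengths = {}
            for c, idx in by_comm_idx.items():
                obs = []
                for j in idx:
                    d = int(matrix.dosage[i, j])
                    d = max(d, 0)
                    obs.extend([float(r.svlen)] * d + [0.0] * (2 - d))
                lengths[c] = obs
            if any(len(v) < 2 for v in lengths.values()):
                continue
            sv = site_variability(lengths)
            if sv.p_value < 0.05:
                sig_sites += 1
        summary["n_str_sites_variable_between_communities"] = sig_sites

    with stage("popstruct"):
        sv_records = [r for r in analysis_records if r.is_sv]
        sv_matrix = build_genotype_matrix(sv_records, samples)
        subset = subset_common_svs(
            sv_matrix, min_freq=config.fst_min_freq, n=config.fst_n_loci, seed=config.seed
        )
        sub_matrix = sv_matrix.subset_variants(subset) if subset.size else sv_matrix
        d = bray_curtis(sub_matrix)
        res = pcoa(d)
        summary["pcoa_percent_variance"] = [
            round(float(x), 3) for x in res.percent_variance[:4]
        ]
        fst = wc_fst(sub_matrix)
        summary["fst_pairs"] = {
            f"{r.group_a}|{r.group_b}": round(r.theta, 4) if np.isfinite(r.theta) else None
            for r in fst
        }

    with stage("cnv"):
        if config.cnv_calls:
            calls = svio.read_cnv_calls(config.cnv_calls)
            regions = merge_cnv_regions(
                calls,
                n_samples=len(samples),
                genes=genes,
                samples_by_id={s.sample_id: s for s in samples},
                p_threshold=config.cnv_p_threshold,
            )
            summary["n_cnv_regions"] = len(regions)

    with stage("write"):
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"config_hash={config.config_hash()} seed={config.seed}"
        master_rows = []
        for r in analysis_records:
            c = classifications[r.id]
            lab = labels.get(r.id, {})
            nv = nov.get(r.id)
            asg = assignments.get(r.id, (None, None))
            master_rows.append(
                dict(
                    variant_id=r.id, chrom=r.chrom, pos=r.pos, svtype=r.svtype,
                    svlen=r.svlen, size_class=r.size_class, label=c.label,
                    completeness=c.me_completeness, coverage=round(c.coverage, 4),
                    period=c.period or "", motif=c.motif or "",
                    sharedness=lab.get("sharedness", ""), geo=lab.get("geo", ""),
                    spread=lab.get("spread") or "",
                    novelty=nv.label if nv else "",
                    region_class=asg[0] or "", decile=asg[1] or "",
                )
            )
        master = pd.DataFrame(master_rows)
        with open(outdir / "variants.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            master.to_csv(fh, sep="\t", index=False)
        if not density.empty:
            with open(outdir / "constraint.tsv", "w") as fh:
                fh.write(f"# {header}\n")
                density.to_csv(fh, sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2, sort_keys=True)
            fh.write("\n")

    return {"summary": summary, "master": master, "outdir": str(outdir)}
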