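"""Synthetic reference + cohort generator with known truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage can be exercised without access-restricted human
data:

* a random-base reference with planted pure STR/TR arrays, homopolymer
  runs, mobile-element consensus copies and gene models spread uniformly
  over LOEUF deciles 1-10;
* a multi-community diploid cohort whose per-community allele frequencies
  follow the Balding-Nichols model: for ancestral frequency p and
  divergence theta, community frequencies are Beta(p(1-t)/t, (1-p)(1-t)/t),
  whose expected fixation index equals theta;
* variants planted as whole-unit STR/TR expansions and contractions,
  full-element insertions, element fragments and non-repetitive sequence,
  each with exactly one truth-table row.

Planted repeats are mismatch-free by default (an optional substitution
rate can roughen them) so that the built-in detectors act as exact oracles
for classifier testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .classify import RepeatLibrary, find_tandem_repeats, coverage_fraction
from .core import GeneModel, GenomicInterval, Sample, VariantRecord
from . import io as svio

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# element families with characteristic lengths: SINE-like ~280 bp (Alu),
# retroposon-like ~2 kb (SVA), LINE-like ~6 kb (L1)
DEFAULT_ELEMENT_SPECS = (
    ("SINE1_syn", "SINE", 280),
    ("LINE1_syn", "LINE", 6000),
    ("SVA_syn", "Retroposon", 2000),
    ("LTR1_syn", "LTR", 600),
    ("DNA1_syn", "DNA", 350),
)
DEFAULT_STR_MOTIFS = ("CAG", "AT", "AAG", "ACGG", "AATGG", "AC", "CCG", "AGAT")
_LIBRARY_SEED = 20231213  # fixed: the canonical synthetic element set


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def default_library(seed: int = _LIBRARY_SEED) -> RepeatLibrary:
    """The canonical synthetic repeat library (deterministic)."""
    rng = np.random.default_rng(seed)
    elements = [(name, fam, _random_seq(rng, ln)) for name, fam, ln in DEFAULT_ELEMENT_SPECS]
    tr_units = [_random_seq(rng, int(p)) for p in (13, 17, 21, 28, 35, 42)]
    return RepeatLibrary(elements, str_motifs=list(DEFAULT_STR_MOTIFS), tr_units=tr_units)


@dataclass
class TandemSite:
    chrom: str
    start: int
    end: int
    period: int
    motif: str
    copies: int


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    n_communities: int = 4
    samples_per_community: int = 8
    outgroup_size: int = 6
    theta: float = 0.10
    n_variants_per_class: dict = field(
        default_factory=lambda: {
            "HOMO": 15,
            "STR": 60,
            "TR": 50,
            "SINE_complete": 30,
            "SINE_fragment": 20,
            "LINE_complete": 8,
            "Retroposon_complete": 10,
            "NONREP": 40,
        }
    )
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 500_000, "chr2": 500_000})
    n_genes: int = 40
    telomere_enrichment: bool = False
    telomere_tr_fraction: float = 0.6  # fraction of TR sites placed near ends when enriched
    fraction_focal_only: float = 0.40
    fraction_outgroup_only: float = 0.10
    n_private_variants: int = 10
    substitution_rate: float = 0.0  # per-base roughening of planted repeats (<= 0.05)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.theta < 1:
            raise ValueError("theta must be in [0, 1)")
        if self.substitution_rate > 0.05:
            raise ValueError("substitution_rate capped at 5%")
        if any(v < 0 for v in self.n_variants_per_class.values()):
            raise ValueError("variant counts must be >= 0")


@dataclass
class ReferenceBundle:
    sequences: dict  # chrom -> str
    str_sites: list
    tr_sites: list
    homo_sites: list
    genes: list
    library: RepeatLibrary
    seed: int

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}


class _Placer:
    """Collision-free feature placement on random-backbone chromosomes.

    Planted arrays overwrite the backbone, so everything must avoid them.
    Gene models only annotate coordinates, so later variant placements may
    fall inside gene spans (introns/CDS get hit, as in real cohorts) while
    genes and arrays still avoid each other.
    """

    def __init__(self, rng, chrom_lengths: Mapping[str, int], margin: int = 2000):
        self.rng = rng
        self.lengths = dict(chrom_lengths)
        self.arrays = {c: IntervalTree() for c in chrom_lengths}
        self.genes = {c: IntervalTree() for c in chrom_lengths}
        self.margin = margin

    def place(
        self,
        length: int,
        end_region_frac: float | None = None,
        margin: int | None = None,
        kind: str = "array",
    ) -> tuple:
        """Pick (chrom, start) for a feature of `length`, avoiding collisions.

        With ``end_region_frac`` the position is drawn from within that
        fraction of the chromosome at either end (telomere analogue).
        ``kind``: "array" and "gene" avoid everything; "variant" avoids
        arrays and other variants but may fall inside gene spans.
        """
        margin = self.margin if margin is None else margin
        chroms = list(self.lengths)
        for _ in range(2000):
            chrom = chroms[self.rng.integers(len(chroms))]
            L = self.lengths[chrom]
            lo, hi = margin, L - margin - length
            if hi <= lo:
                continue
            if end_region_frac:
                w = int(L * end_region_frac)
                if self.rng.random() < 0.5:
                    pos = int(self.rng.integers(lo, min(hi, max(lo + 1, w))))
                else:
                    pos = int(self.rng.integers(max(lo, L - w), hi))
            else:
                pos = int(self.rng.integers(lo, hi))
            s, e = pos - 100, pos + length + 100
            if self.arrays[chrom].overlap(s, e):
                continue
            if kind != "variant" and self.genes[chrom].overlap(s, e):
                continue
            target = self.genes if kind == "gene" else self.arrays
            target[chrom].addi(s, e)
            return chrom, pos
        raise RuntimeError("could not place feature; chromosomes too small for the configured features")


def _roughen(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode("ascii")


def make_reference(
    chrom_lengths: Mapping[str, int],
    library: RepeatLibrary,
    seed: int,
    n_str_sites: int = 80,
    n_tr_sites: int = 60,
    n_homo_sites: int = 20,
    n_genes: int = 40,
    telomere_tr_fraction: float = 0.0,
) -> ReferenceBundle:
    """Build a toy reference with planted repeat arrays and gene models.

    Deterministic for a fixed seed.  Genes are spread uniformly over LOEUF
    deciles 1-10.
    """
    if len(chrom_lengths) < 2:
        raise ValueError("need >= 2 chromosomes")
    if any(l < 200_000 for l in chrom_lengths.values()):
        raise ValueError("each chromosome must be >= 200 kb")
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(_random_seq(rng, L).encode()) for c, L in chrom_lengths.items()}
    placer = _Placer(rng, chrom_lengths)

    def plant(array: str, end_frac=None) -> tuple:
        chrom, pos = placer.place(len(array), end_region_frac=end_frac)
        seqs[chrom][pos : pos + len(array)] = array.encode()
        return chrom, pos

    # genes first: the largest blocks are hardest to place once the
    # backbone is fragmented by arrays
    genes = []
    for i in range(n_genes):
        span_len = int(rng.integers(4000, 8001))
        chrom, pos = placer.place(span_len, margin=3000, kind="gene")
        n_exons = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(np.arange(200, span_len - 200), size=2 * n_exons, replace=False))
        cds = []
        for j in range(n_exons):
            s, e = int(bounds[2 * j]), int(bounds[2 * j + 1])
            if e - s < 30:
                e = s + 30
            cds.append(GenomicInterval(chrom, pos + s, pos + min(e, span_len)))
        genes.append(
            GeneModel(
                gene_id=f"gene{i:03d}",
                span=GenomicInterval(chrom, pos, pos + span_len),
                cds=cds,
                loeuf_decile=(i % 10) + 1,
            )
        )

    str_sites, tr_sites, homo_sites = [], [], []
    for _ in range(n_str_sites):
        motif = library.str_motifs[rng.integers(len(library.str_motifs))]
        p = len(motif)
        copies = int(rng.integers(math.ceil(60 / p), math.ceil(200 / p)))
        chrom, pos = plant(motif * copies)
        str_sites.append(TandemSite(chrom, pos, pos + p * copies, p, motif, copies))
    for i in range(n_tr_sites):
        unit = library.tr_units[rng.integers(len(library.tr_units))]
        p = len(unit)
        copies = int(rng.integers(3, 9))
        near_end = telomere_tr_fraction > 0 and rng.random() < telomere_tr_fraction
        chrom, pos = plant(unit * copies, end_frac=0.10 if near_end else None)
        tr_sites.append(TandemSite(chrom, pos, pos + p * copies, p, unit, copies))
    for _ in range(n_homo_sites):
        base = "ACGT"[rng.integers(4)]
        run = int(rng.integers(30, 61))
        chrom, pos = plant(base * run)
        homo_sites.append(TandemSite(chrom, pos, pos + run, 1, base, run))

    bundle = ReferenceBundle(
        sequences={c: bytes(b).decode("ascii") for c, b in seqs.items()},
        str_sites=str_sites,
        tr_sites=tr_sites,
        homo_sites=homo_sites,
        genes=genes,
        library=library,
        seed=seed,
    )
    bundle._placer = placer  # reused by simulate_cohort to avoid planted features
    return bundle


def balding_nichols_freqs(p_anc: float, theta: float, n_pops: int, rng) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model.

    theta = 0 is the no-drift limit: every population shares the ancestral
    frequency.
    """
    if theta == 0:
        return np.full(n_pops, p_anc)
    a = p_anc * (1 - theta) / theta
    b = (1 - p_anc) * (1 - theta) / theta
    return rng.beta(a, b, size=n_pops)


@dataclass
class CohortBundle:
    reference: ReferenceBundle
    records: list
    samples: list
    truth: pd.DataFrame
    config: SimulationConfig


def _nonrep_sequence(rng, length: int, library: RepeatLibrary) -> str:
    """Random sequence verified to carry no qualifying tandem array."""
    for _ in range(50):
        seq = _random_seq(rng, length)
        anns = find_tandem_repeats(seq)
        if not anns or coverage_fraction((0, length), anns) < 0.3:
            return seq
    raise RuntimeError("failed to draw a non-repetitive sequence")


def simulate_cohort(reference: ReferenceBundle, config: SimulationConfig) -> CohortBundle:
    """Plant variants on the reference and genotype a structured cohort.

    Every emitted record has exactly one truth row recording its planted
    class, motif/period or element identity, geographic stratum, ancestral
    frequency and carrier count.
    """
    rng = np.random.default_rng(config.seed + 1)
    lib = reference.library
    placer = getattr(reference, "_placer", None) or _Placer(rng, reference.chrom_lengths)
    elements = {name: (fam, seq) for name, fam, seq in lib.elements}

    samples = []
    for ci in range(config.n_communities):
        comm = f"P{ci + 1}"
        for si in range(config.samples_per_community):
            samples.append(Sample(f"{comm}_S{si:02d}", comm, True))
    for si in range(config.outgroup_size):
        samples.append(Sample(f"OUT_S{si:02d}", "OUTGROUP", False))

    str_pool = list(reference.str_sites)
    tr_pool = list(reference.tr_sites)
    homo_pool = list(reference.homo_sites)
    rng.shuffle(str_pool), rng.shuffle(tr_pool), rng.shuffle(homo_pool)

    planted = []  # (chrom, pos, svtype, svlen, seq, truth-dict)

    def plant_tandem(site: TandemSite, cls: str):
        p = site.period
        expand = rng.random() < 0.6
        site_len = site.end - site.start
        max_del_units = (site_len - 2 * p) // p
        if not expand and max_del_units * p >= 20:
            k = int(rng.integers(math.ceil(20 / p), max_del_units + 1))
            svlen = k * p
            seq = reference.sequences[site.chrom][site.start : site.start + svlen]
            return (site.chrom, site.start, "DEL", svlen, seq,
                    dict(true_label=cls, period=p, motif=site.motif))
        lo = max(math.ceil(20 / p), math.ceil((25 + p) / p), 2)
        k = int(rng.integers(lo, max(lo + 1, math.ceil(160 / p))))
        seq = _roughen(site.motif * k, config.substitution_rate, rng)
        return (site.chrom, site.start, "INS", k * p, seq,
                dict(true_label=cls, period=p, motif=site.motif))

    def plant_mobile(name: str, complete: bool):
        fam, cons = elements[name]
        if complete:
            seq = cons
        else:
            frac = rng.uniform(0.30, 0.55)
            m = max(50, int(len(cons) * frac))
            a = int(rng.integers(0, len(cons) - m))
            seq = cons[a : a + m]
        seq = _roughen(seq, config.substitution_rate, rng)
        if rng.random() < 0.5:
            from .classify import revcomp
            seq = revcomp(seq)
        L = len(seq)
        chrom, pos = placer.place(1, margin=2 * L + 500, kind="variant")
        label = "RETROPOSON" if fam == "Retroposon" else fam
        return (chrom, pos, "INS", L, seq,
                dict(true_label=label, element=name,
                     completeness="complete" if complete else "fragment"))

    def plant_nonrep():
        L = int(rng.integers(50, 301))
        if rng.random() < 0.5:
            seq = _nonrep_sequence(rng, L, lib)
            chrom, pos = placer.place(1, margin=2 * L + 500, kind="variant")
            return (chrom, pos, "INS", L, seq, dict(true_label="NONREP"))
        for _ in range(50):
            chrom, pos = placer.place(L, margin=2 * L + 500, kind="variant")
            seq = reference.sequences[chrom][pos : pos + L]
            anns = find_tandem_repeats(seq)
            if not anns or coverage_fraction((0, L), anns) < 0.3:
                return (chrom, pos, "DEL", L, seq, dict(true_label="NONREP"))
        raise RuntimeError("failed to place non-repetitive deletion")

    for cls, count in config.n_variants_per_class.items():
        for _ in range(count):
            if cls == "STR":
                if not str_pool:
                    raise ValueError("not enough planted STR sites for requested variants")
                planted.append(plant_tandem(str_pool.pop(), "STR"))
            elif cls == "TR":
                if not tr_pool:
                    raise ValueError("not enough planted TR sites for requested variants")
                planted.append(plant_tandem(tr_pool.pop(), "TR"))
            elif cls == "HOMO":
                if not homo_pool:
                    raise ValueError("not enough planted homopolymer sites")
                planted.append(plant_tandem(homo_pool.pop(), "HOMO"))
            elif cls == "NONREP":
                planted.append(plant_nonrep())
            elif cls.endswith("_complete") or cls.endswith("_fragment"):
                fam_key, _, mode = cls.rpartition("_")
                name = {
                    "SINE": "SINE1_syn", "LINE": "LINE1_syn",
                    "Retroposon": "SVA_syn", "LTR": "LTR1_syn", "DNA": "DNA1_syn",
                }[fam_key]
                planted.append(plant_mobile(name, mode == "complete"))
            else:
                raise ValueError(f"unknown variant class {cls!r}")

    # deterministic emission order
    order = sorted(range(len(planted)), key=lambda i: (planted[i][0], planted[i][1]))
    n_pops = config.n_communities + 1  # communities + outgroup
    comm_names = [f"P{i + 1}" for i in range(config.n_communities)] + ["OUTGROUP"]
    pop_of_sample = np.array([comm_names.index(s.community) for s in samples])

    records, truth_rows = [], []
    n_private_left = config.n_private_variants
    for out_idx, i in enumerate(order):
        chrom, pos, svtype, svlen, seq, info = planted[i]
        vid = f"sv{out_idx:05d}"
        u = rng.random()
        if u < config.fraction_focal_only:
            geo = "FOCAL_ONLY"
        elif u < config.fraction_focal_only + config.fraction_outgroup_only:
            geo = "FOCAL_ABSENT"
        else:
            geo = "GLOBAL"
        p_anc = rng.uniform(0.05, 0.95)
        freqs = balding_nichols_freqs(p_anc, config.theta, n_pops, rng)
        if geo == "FOCAL_ONLY":
            freqs[-1] = 0.0
        elif geo == "FOCAL_ABSENT":
            freqs[:-1] = 0.0
        private = n_private_left > 0
        if private:
            n_private_left -= 1
            dosage = np.zeros(len(samples), dtype=np.int8)
            focal_idx = [j for j, s in enumerate(samples) if s.in_focal_set]
            dosage[focal_idx[rng.integers(len(focal_idx))]] = 1
            geo = "FOCAL_ONLY"
        else:
            for _ in range(200):
                dosage = rng.binomial(2, freqs[pop_of_sample]).astype(np.int8)
                if dosage.sum() > 0:
                    break
            else:
                j = np.flatnonzero(freqs[pop_of_sample] > 0)
                dosage = np.zeros(len(samples), dtype=np.int8)
                dosage[j[rng.integers(len(j))]] = 1
        genotypes = {
            s.sample_id: {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
            for s, d in zip(samples, dosage)
        }
        records.append(
            VariantRecord(
                id=vid, chrom=chrom, pos=pos, svtype=svtype, svlen=svlen, seq=seq,
                qual=float(rng.uniform(10, 60)),
                support_fraction=float(rng.uniform(0.30, 1.0)),
                genotypes=genotypes,
            )
        )
        truth_rows.append(
            dict(
                variant_id=vid, chrom=chrom, pos=pos, svtype=svtype, svlen=svlen,
                true_label=info["true_label"],
                completeness=info.get("completeness", "n/a"),
                period=info.get("period", 0),
                motif=info.get("motif", ""),
                element=info.get("element", ""),
                geo_truth=geo,
                private=private,
                p_anc=p_anc,
                pop_freqs=json.dumps([round(float(f), 6) for f in freqs]),
                carrier_count=int((dosage > 0).sum()),
            )
        )
    truth = pd.DataFrame(truth_rows)
    return CohortBundle(reference, records, samples, truth, config)


def simulate_bundle(config: SimulationConfig) -> CohortBundle:
    """Reference + cohort in one step, sizing planted sites to the config."""
    counts = config.n_variants_per_class
    lib = default_library()
    ref = make_reference(
        config.chrom_lengths,
        lib,
        seed=config.seed,
        n_str_sites=counts.get("STR", 0) + 20,
        n_tr_sites=counts.get("TR", 0) + 10,
        n_homo_sites=counts.get("HOMO", 0) + 5,
        n_genes=config.n_genes,
        telomere_tr_fraction=config.telomere_tr_fraction if config.telomere_enrichment else 0.0,
    )
    return simulate_cohort(ref, config)


def make_annotation_set(
    records: Sequence[VariantRecord],
    keep_fraction: float,
    jitter_bp: int = 0,
    size_noise: float = 0.0,
    seed: int = 0,
):
    """Derive an external-annotation fixture from a truth callset.

    ``keep_fraction`` of the records are copied with breakpoint jitter and
    multiplicative size noise; the rest are omitted and are the expected
    "unannotated" set.  Returns (annotation_records, kept_ids).
    """
    if not 0 <= keep_fraction <= 1:
        raise ValueError("keep_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = int(round(keep_fraction * len(records)))
    kept_idx = sorted(rng.choice(len(records), size=n_keep, replace=False)) if n_keep else []
    out, kept_ids = [], set()
    for i in kept_idx:
        r = records[i]
        jitter = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
        factor = 1.0 + (rng.uniform(-size_noise, size_noise) if size_noise else 0.0)
        svlen = max(20, int(round(r.svlen * factor)))
        out.append(
            VariantRecord(
                id=f"ann_{r.id}", chrom=r.chrom, pos=max(1, r.pos + jitter),
                svtype=r.svtype, svlen=svlen, seq="", qual=50.0,
            )
        )
        kept_ids.add(r.id)
    return out, kept_ids


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write FASTA, VCF, metadata, gene models, truth tracks and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fa",
        "vcf": outdir / "cohort.vcf",
        "metadata": outdir / "samples.tsv",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.tsv",
        "str_bed": outdir / "str_sites.bed",
        "tr_bed": outdir / "tr_sites.bed",
        "config": outdir / "sim_config.json",
    }
    ref = bundle.reference
    svio.write_fasta(ref.sequences, paths["fasta"])
    svio.write_sv_vcf(
        bundle.records, bundle.samples, paths["vcf"],
        contig_lengths=ref.chrom_lengths, reference=ref.sequences,
        extra_header_lines=[f"##svscape_sim_seed={bundle.config.seed}"],
    )
    svio.write_sample_metadata(bundle.samples, paths["metadata"],
                               header_comment=f"seed={bundle.config.seed}")
    svio.write_gene_models(ref.genes, paths["genes"],
                           header_comment=f"seed={bundle.config.seed}")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    for key, sites in (("str_bed", ref.str_sites), ("tr_bed", ref.tr_sites)):
        with open(paths[key], "w") as fh:
            for s in sites:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.motif}\t{s.period}\t{s.copies}\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
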