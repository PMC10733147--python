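"""Extended alleles, tandem/element detectors and repeat classification."""

import numpy as np
import pytest

from svscape.classify import (
    ElementHit,
    TandemAnnotation,
    build_extended_allele,
    classify_period,
    classify_records,
    classify_variant,
    coverage_fraction,
    find_mobile_elements,
    find_tandem_repeats,
    flag_homopolymers,
    map_repeatmasker_family,
    parse_repeatmasker_out,
    parse_trf_dat,
    revcomp,
)
from svscape.core import VariantRecord


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestExtendedAllele:
    def test_ins_mid_chromosome(self, rng):
        ref = {"chr1": _rand_seq(rng, 2000)}
        v = VariantRecord("i", "chr1", 1000, "INS", 100, _rand_seq(rng, 100))
        a = build_extended_allele(v, ref)
        assert len(a.sequence) == 500  # 5x the variant size
        assert a.variant_region == (200, 300)  # central 20%
        assert a.sequence[200:300] == v.seq
        assert not a.clipped

    def test_del_slice(self, rng):
        ref = {"chr1": _rand_seq(rng, 2000)}
        v = VariantRecord("d", "chr1", 500, "DEL", 50)
        a = build_extended_allele(v, ref)
        assert a.sequence == ref["chr1"][400:650]
        assert a.variant_region == (100, 150)

    def test_contig_edge_clipping(self, rng):
        ref = {"chr1": _rand_seq(rng, 2000)}
        v = VariantRecord("i", "chr1", 10, "INS", 100, _rand_seq(rng, 100))
        a = build_extended_allele(v, ref)
        assert a.clipped
        assert a.variant_region == (10, 110)  # left flank clipped to 10 bp
        assert len(a.sequence) == 10 + 100 + 200


class TestTandemDetector:
    def test_homopolymer(self):
        anns = find_tandem_repeats("A" * 40)
        assert len(anns) == 1
        a = anns[0]
        assert (a.period, a.copy_number, a.motif) == (1, 40.0, "A")

    def test_triplet(self):
        (a,) = find_tandem_repeats("CAG" * 40)
        assert (a.period, a.motif, a.purity) == (3, "CAG", 1.0)

    def test_tr_range_13mer(self):
        unit = "ACGTGTACCTTGA"
        (a,) = find_tandem_repeats(unit * 10)
        assert a.period == 13
        # autocorrelation oracle: smallest shift with perfect self-match
        s = unit * 10
        best = next(p for p in range(1, len(s)) if s[p:] == s[: len(s) - p])
        assert a.period == best

    def test_empty_sequence(self):
        assert find_tandem_repeats("") == []

    def test_substitution_tolerance(self, rng):
        arr = list("TTAGGG" * 30)
        for i in rng.choice(len(arr), size=9, replace=False):  # 5% substitutions
            arr[i] = "C" if arr[i] != "C" else "A"
        anns = find_tandem_repeats("".join(arr))
        assert any(a.period == 6 and a.purity >= 0.8 for a in anns)

    def test_agrees_with_brute_force_smallest_period(self, rng):
        """Planted pure arrays <= 200 bp, period <= 20: detector period equals
        the smallest p with >= 80% positional self-match (brute force)."""
        for _ in range(60):
            p = int(rng.integers(1, 21))
            unit = _rand_seq(rng, p)
            copies = max(3, int(np.ceil((p + 30) / p)))
            s = (unit * copies)[:200]
            anns = find_tandem_repeats(s)
            matches_at = lambda q: sum(s[i] == s[i - q] for i in range(q, len(s))) / (len(s) - q)
            brute = next((q for q in range(1, len(s) // 2 + 1) if matches_at(q) >= 0.8), None)
            if brute is None:
                assert anns == []
            else:
                assert anns and min(a.period for a in anns) == brute

    def test_harmonics_suppressed(self):
        anns = find_tandem_repeats("AT" * 60)
        assert all(a.period == 2 for a in anns)


class TestClassifyPeriod:
    @pytest.mark.parametrize("period,label", [(1, "HOMO"), (2, "STR"), (12, "STR"), (13, "TR"), (300, "TR")])
    def test_boundaries(self, period, label):
        assert classify_period(period) == label

    def test_invalid(self):
        with pytest.raises(ValueError):
            classify_period(0)


class TestMobileElements:
    def test_full_copy(self, library, rng):
        name, fam, cons = library.elements[0]
        seq = _rand_seq(rng, 150) + cons + _rand_seq(rng, 150)
        hits = [h for h in find_mobile_elements(seq, library) if h.element_name == name]
        assert hits and max(h.consensus_fraction for h in hits) >= 0.99

    def test_fragment_fraction(self, library, rng):
        _, _, cons = [e for e in library.elements if e[1] == "LINE"][0]
        mid = len(cons) // 2
        frag = cons[mid - len(cons) // 5 : mid + len(cons) // 5]  # middle 40%
        seq = _rand_seq(rng, 200) + frag + _rand_seq(rng, 200)
        hits = find_mobile_elements(seq, library)
        best = max(hits, key=lambda h: h.consensus_fraction)
        assert abs(best.consensus_fraction - 0.4) < 0.05

    def test_strand_symmetry(self, library, rng):
        name, _, cons = library.elements[0]
        flank = _rand_seq(rng, 100)
        fwd = find_mobile_elements(flank + cons + flank, library)
        rev = find_mobile_elements(flank + revcomp(cons) + flank, library)
        f = max(fwd, key=lambda h: h.consensus_fraction)
        r = max(rev, key=lambda h: h.consensus_fraction)
        assert f.orientation != r.orientation
        assert abs(f.consensus_fraction - r.consensus_fraction) < 0.02


class TestCoverage:
    def test_empty(self):
        assert coverage_fraction((0, 100), []) == 0.0

    def test_union_arithmetic(self):
        anns = [TandemAnnotation(0, 30, 2, "AT", 15, 1.0), TandemAnnotation(20, 60, 2, "AT", 20, 1.0)]
        assert coverage_fraction((0, 100), anns) == pytest.approx(0.6)

    def test_spanning_annotation(self):
        anns = [TandemAnnotation(0, 500, 3, "CAG", 100, 1.0)]
        assert coverage_fraction((100, 200), anns) == 1.0

    def test_zero_length_region(self):
        with pytest.raises(ValueError):
            coverage_fraction((5, 5), [])


class TestClassifyVariant:
    def _classify_ins(self, seq, reference_seq, library, pos=3000):
        ref = {"chr1": reference_seq}
        v = VariantRecord("v", "chr1", pos, "INS", len(seq), seq)
        allele = build_extended_allele(v, ref)
        return classify_variant(
            v, allele, find_tandem_repeats(allele.sequence), find_mobile_elements(allele.sequence, library)
        )

    def test_pure_str_insertion(self, library, rng):
        c = self._classify_ins("CAG" * 50, _rand_seq(rng, 10_000), library)
        assert c.label == "STR" and c.coverage == 1.0 and c.period == 3

    def test_complete_sine_with_flanking_novel_sequence(self, library, rng):
        _, _, cons = library.elements[0]
        seq = _rand_seq(rng, 10) + cons + _rand_seq(rng, 10)
        c = self._classify_ins(seq, _rand_seq(rng, 10_000), library)
        assert c.label == "SINE" and c.me_completeness == "complete"

    def test_random_sequence_nonrep(self, library, rng):
        c = self._classify_ins(_rand_seq(rng, 200), _rand_seq(rng, 10_000), library)
        assert c.label == "NONREP"

    def test_sine_fragment(self, library, rng):
        _, _, cons = library.elements[0]
        frag = cons[50:190]  # half the element
        c = self._classify_ins(frag, _rand_seq(rng, 10_000), library)
        assert c.label == "SINE" and c.me_completeness == "fragment"

    def test_strand_symmetry_of_labels(self, library, rng):
        _, _, cons = library.elements[0]
        backbone = _rand_seq(rng, 10_000)
        for seq in ("CAG" * 40, cons, _rand_seq(rng, 150)):
            a = self._classify_ins(seq, backbone, library)
            b = self._classify_ins(revcomp(seq), backbone, library)
            assert a.label == b.label

    def test_deletion_uses_reference_context(self, library, rng):
        # deletion inside a planted STR array classifies from reference sequence
        left, right = _rand_seq(rng, 5000), _rand_seq(rng, 5000)
        array = "AATGG" * 60
        ref = {"chr1": left + array + right}
        v = VariantRecord("d", "chr1", 5010, "DEL", 50)
        allele = build_extended_allele(v, ref)
        c = classify_variant(v, allele, find_tandem_repeats(allele.sequence), [])
        assert c.label == "STR" and c.period == 5


class TestFlagHomopolymers:
    def test_split(self, library, rng):
        from svscape.classify import RepeatClassification

        cls = {
            "a": RepeatClassification("HOMO"),
            "b": RepeatClassification("STR"),
            "c": RepeatClassification("NONREP"),
        }
        keep, flagged = flag_homopolymers(cls)
        assert sorted(keep) == ["b", "c"] and flagged == ["a"]


class TestAdapters:
    def test_trf_dat(self, tmp_path):
        path = tmp_path / "x.dat"
        path.write_text(
            "Tandem Repeats Finder Program\n\n"
            "Sequence: sv00001\n\n"
            "Parameters: 2 7 7 80 10 50 500\n\n"
            "1 120 3 40.0 3 100 0 240 25 25 25 25 2.00 CAG CAGCAGCAG\n"
            "not a data line\n"
        )
        out = parse_trf_dat(path)
        (ann,) = out["sv00001"]
        assert (ann.start, ann.end, ann.period, ann.motif) == (0, 120, 3, "CAG")
        assert ann.purity == 1.0

    def test_trf_empty(self, tmp_path):
        p = tmp_path / "e.dat"
        p.write_text("")
        assert parse_trf_dat(p) == {}

    def test_repeatmasker_families(self):
        assert map_repeatmasker_family("SINE/Alu") == "SINE"
        assert map_repeatmasker_family("LINE/L1") == "LINE"
        assert map_repeatmasker_family("Retroposon/SVA") == "Retroposon"
        assert map_repeatmasker_family("Simple_repeat") == "Other"

    def test_repeatmasker_out(self, tmp_path):
        path = tmp_path / "x.out"
        path.write_text(
            "   SW   perc perc perc  query     position in query    matching  repeat         position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat    class/family   begin end (left)  ID\n"
            "\n"
            " 1500   2.0  0.0  0.0  sv00002      11   290   (10)  +  AluY     SINE/Alu         1  280   (0)   1\n"
        )
        out = parse_repeatmasker_out(path)
        (hit,) = out["sv00002"]
        assert hit.family == "SINE" and hit.start == 10 and hit.end == 290
        assert hit.consensus_fraction == 1.0

    def test_repeatmasker_empty(self, tmp_path):
        p = tmp_path / "e.out"
        p.write_text("")
        assert parse_repeatmasker_out(p) == {}


class TestCohortRecovery:
    def test_planted_classes_recovered(self, bundle):
        """On pure planted repeats the classifier reproduces truth labels."""
        cls = classify_records(bundle.records, bundle.reference.sequences, bundle.reference.library)
        truth = bundle.truth.set_index("variant_id")
        per_class = {}
        for vid, c in cls.items():
            t = truth.loc[vid]
            ok = c.label == t.true_label and (
                t.completeness == "n/a" or c.me_completeness == t.completeness
            )
            per_class.setdefault(t.true_label, []).append(ok)
        for label, oks in per_class.items():
            assert np.mean(oks) >= 0.95, f"class {label} below 95% recovery"
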