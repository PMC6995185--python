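import numpy as np
import pytest

from ervkit import annotate, simulate
from ervkit.core import CompositionError, ParameterError


def codons_for(peptide: str) -> str:
    from ervkit.simulate import _AA_CODON

    return "".join(_AA_CODON[a] for a in peptide)


class TestLocateLtrs:
    def test_age_zero_exact_coordinates(self, base_template):
        seq = base_template.sequence()
        L = len(base_template.ltr)
        ltr5, ltr3 = annotate.locate_ltrs(seq)
        assert (ltr5.start, ltr5.end) == (0, L)
        assert (ltr3.start, ltr3.end) == (len(seq) - L, len(seq))

    def test_random_sequence_yields_none(self):
        rnd = simulate.random_dna(5000, 42)
        assert annotate.locate_ltrs(rnd) is None

    def test_aged_provirus_found_with_expected_identity(self, base_template):
        seq = simulate.evolve(base_template.sequence(), 15.0, seed=7)
        hit = annotate.locate_ltrs(seq)
        assert hit is not None
        ltr5, ltr3 = hit
        # boundaries within a handful of nt of the planted LTRs
        assert abs(ltr5.start - 0) <= 10
        assert abs(ltr3.end - len(seq)) <= 10

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ParameterError):
            annotate.locate_ltrs("ACGT" * 50)


class TestFindPbs:
    def test_planted_entry_found_exactly(self, base_template, pbs_library):
        seq = base_template.sequence()
        hit = annotate.find_pbs(seq, len(base_template.ltr), pbs_library)
        assert hit.present and hit.identity == 1.0
        assert hit.best_trna == "Arg"
        assert hit.interval.start == len(base_template.ltr)

    def test_below_threshold_not_present(self, pbs_library):
        # 13/18 identity to the Arg entry: 5 mismatches planted
        arg = dict(pbs_library)["Arg"]
        window = list(arg)
        for i in range(5):
            window[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[i]]
        seq = "T" * 100 + "".join(window) + "T" * 50
        hit = annotate.find_pbs(seq, 100, pbs_library)
        assert not hit.present

    def test_best_library_entry_wins(self, pbs_library):
        """A window at 17/18 to Arg must be assigned Arg even if other
        entries also match partially (exhaustive comparison)."""
        lib = dict(pbs_library)
        window = list(lib["Arg"])
        window[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[9]]
        seq = "T" * 60 + "".join(window) + "T" * 40
        hit = annotate.find_pbs(seq, 60, pbs_library)
        assert hit.best_trna == "Arg"
        assert hit.identity == pytest.approx(17 / 18)
        for name, entry in pbs_library:
            ident = sum(a == b for a, b in zip("".join(window), entry)) / 18
            assert ident <= hit.identity

    def test_no_call_past_sequence_end(self, pbs_library):
        assert annotate.find_pbs("ACGT" * 4, 10, pbs_library) is None

    def test_bad_library_rejected(self):
        with pytest.raises(ParameterError):
            annotate.find_pbs("A" * 100, 10, [("Arg", "ACGT")])


class TestScanMotifs:
    def test_planted_patterns_detected(self):
        pad = codons_for("GGGGG")
        seq = pad + codons_for("CAACAAAAHAAAAC") + pad
        hits = annotate.scan_motifs(seq, kinds=("ZF1",))
        assert len(hits) == 1 and hits[0].intact
        assert hits[0].interval.start == 15 and hits[0].frame == 0

        seq2 = pad + codons_for("WAGPFSV") + pad
        (gpyf,) = annotate.scan_motifs(seq2, kinds=("GPYF",))
        assert gpyf.aa_sequence == "WAGPFSV"

    def test_internal_stop_flags_hit(self):
        pad = codons_for("GGGGG")
        zf = codons_for("CAACAAAAHAAAAC")
        broken = zf[:15] + "TAA" + zf[18:]  # variable residue -> stop
        hits = annotate.scan_motifs(pad + broken + pad, kinds=("ZF1",))
        assert len(hits) == 1
        assert not hits[0].intact
        assert hits[0].failure_reasons == {"internal_stop"}

    def test_anchor_substitution_means_no_hit(self):
        pad = codons_for("GGGGG")
        seq = pad + codons_for("CAACAAAAYAAAAC") + pad  # H anchor -> Y
        assert annotate.scan_motifs(seq, kinds=("ZF1",)) == []

    def test_scanning_is_pure(self, base_template):
        seq = base_template.sequence()
        a = annotate.scan_motifs(seq)
        b = annotate.scan_motifs(str(seq))
        assert [(h.kind, h.interval, h.intact) for h in a] == [
            (h.kind, h.interval, h.intact) for h in b
        ]

    def test_presence_requires_gene_region_when_known(self):
        pad = codons_for("G" * 30)
        seq = pad + codons_for("CAACAAAAHAAAAC") + pad
        hits = annotate.scan_motifs(seq, kinds=("ZF1",))
        inside = annotate.motif_presence(hits, {"gag": (0, len(seq))})
        outside = annotate.motif_presence(hits, {"gag": (0, 30)})
        assert inside["ZF1"] and not outside["ZF1"]


class TestComposition:
    def test_fraction_examples(self):
        rep = annotate.composition("AAAACCGT")
        assert (rep.a, rep.c, rep.g, rep.t) == (0.5, 0.25, 0.125, 0.125)
        rep2 = annotate.composition("ACGT")
        assert rep2.purine_bias == 0.0

    def test_all_n_rejected(self):
        with pytest.raises(CompositionError):
            annotate.composition("NNNN")

    def test_uniform_genome_near_quarter(self):
        seq = simulate.random_dna(100_000, 11)
        rep = annotate.composition(seq)
        for frac in (rep.a, rep.c, rep.g, rep.t):
            assert abs(frac - 0.25) < 0.01


class TestPregagOrf:
    def test_planted_orf_recovered(self, base_template):
        t = base_template
        orf = annotate.find_pregag_orf(t.pregag)
        assert (orf.start, orf.end) == (
            t.params.orf_start,
            t.params.orf_start + t.params.orf_len,
        )

    def test_random_sequence_has_no_long_orf(self):
        rnd = simulate.random_dna(1000, 13)
        assert annotate.find_pregag_orf(rnd, min_orf_len=300) is None

    def test_longest_orf_wins(self):
        from ervkit.simulate import _coding_dna

        rng = np.random.default_rng(3)
        orf_long = "ATG" + _coding_dna(198, rng) + "TAA"   # 600 nt
        orf_short = "ATG" + _coding_dna(148, rng) + "TAA"  # 450 nt
        seq = "TTT" + orf_short + "TAATAA" + orf_long + "TT"
        hit = annotate.find_pregag_orf(seq)
        assert hit.end - hit.start == 600


class TestIntactness:
    def test_identical_sequence_full_coverage(self, base_template):
        seq = base_template.sequence()
        cov, _segs = annotate.intactness(seq, seq)
        assert cov == 1.0

    def test_unrelated_sequence_near_zero(self, base_template):
        rnd = simulate.random_dna(9000, 21)
        cov, _ = annotate.intactness(rnd, base_template.sequence(), k=12)
        assert cov < 0.01

    def test_central_deletion_halves_coverage(self, base_template):
        ref = base_template.sequence()[:4000]
        q = ref[:1000] + ref[3000:]
        cov, _ = annotate.intactness(q, ref)
        assert abs(cov - 0.5) < 0.03

    def test_small_k_rejected(self):
        with pytest.raises(ParameterError):
            annotate.intactness("A" * 100, "A" * 100, k=4)


class TestPresenceDecay:
    def test_motif_presence_non_increasing_with_age(self, base_template):
        """Mutations only destroy planted motifs, so presence fractions
        must not increase with simulated age."""
        rng = np.random.default_rng(17)
        fracs = []
        for age in (0.0, 15.0, 40.0):
            present = 0
            n = 12
            for _ in range(n):
                seq = simulate.evolve(base_template.sequence(), age, seed=rng)
                pres = annotate.motif_presence(annotate.scan_motifs(seq))
                present += sum(pres.values())
            fracs.append(present / (3 * n))
        assert fracs[0] == 1.0
        assert fracs[0] >= fracs[1] >= fracs[2]
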