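"""Annotation: decomposition, joint typing, 12/23, frame, ledger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdjcapture._util import random_dna
from vdjcapture.annotate import (
    DecompositionError,
    PairingError,
    annotate_calls,
    check_12_23,
    classify_side,
    decompose_junction,
    ledger_reciprocal,
    locus_lineage,
)
from vdjcapture.detect import JunctionCall
from vdjcapture.locus import (
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    LocusBlueprint,
    LocusModel,
    LocusSpec,
    RSSMotif,
    build_synthetic_model,
)
from vdjcapture.simulate import (
    JunctionSide,
    recombine_deletion,
    recombine_inversion,
    recombine_v_replacement,
    translocate,
)


def calls_from_truth(truths):
    """Promote simulator truth junctions to base-pair junction calls."""
    calls = []
    for t in truths:
        for i, jt in enumerate(t.junctions):
            cls = (
                "interchromosomal"
                if jt.left.chrom != jt.right.chrom
                else ("inversion-like" if "-" in (jt.left.orient, jt.right.orient)
                      else "deletion-like")
            )
            calls.append(
                JunctionCall(
                    f"{t.event_id}_{i}", cls, jt.left, jt.right, "base-pair",
                    (jt.left.pos, jt.left.pos + 1), (jt.right.pos, jt.right.pos + 1),
                    n_pairs=5, n_splits=5, n_seq=jt.n_seq, micro=jt.micro,
                )
            )
    return calls


def oracle_decompose(consensus, left_ref, right_ref):
    """Exhaustive oracle: maximal matches over every split point."""
    a = 0
    while a < min(len(consensus), len(left_ref)) and consensus[a] == left_ref[a]:
        a += 1
    b = 0
    while (
        b < min(len(consensus), len(right_ref))
        and consensus[-(b + 1)] == right_ref[-(b + 1)]
    ):
        b += 1
    if a + b <= len(consensus):
        return a, b, 0, consensus[a : len(consensus) - b]
    return a, b, a + b - len(consensus), ""


class TestDecompose:
    def test_exact_concatenation(self, rng):
        lf, rf = random_dna(rng, 40), random_dna(rng, 40)
        # continuation bases chosen so the seam cannot slide
        cont = "A" if rf[0] != "A" else "C"
        pre = "A" if lf[-1] != "A" else "C"
        d = decompose_junction(lf + rf, lf + cont * 40, pre * 40 + rf)
        assert d.n_region == "" and d.microhomology == 0

    def test_eleven_inserted_untemplated_bases(self, rng):
        lf, rf = random_dna(rng, 40), random_dna(rng, 40)
        left_ref = lf + "T" * 40
        right_ref = "T" * 40 + rf
        n = "G" + random_dna(rng, 9) + "C"  # edges distinct from the T context
        n = "G" + n[1:-1] + "C"
        d = decompose_junction(lf + n + rf, left_ref, right_ref)
        assert d.n_len == 11
        assert d.n_region == n

    def test_three_base_seam_is_microhomology(self, rng):
        core_l = random_dna(rng, 30)
        core_r = random_dna(rng, 30)
        seam = "ACG"
        consensus = core_l + seam + core_r
        left_ref = core_l + seam + "TTTTT"
        right_ref = "TTTTT" + seam + core_r
        d = decompose_junction(consensus, left_ref, right_ref)
        assert d.microhomology == 3 and d.n_region == ""
        assert (d.left_match, d.right_match, d.microhomology, d.n_region) == oracle_decompose(
            consensus, left_ref, right_ref
        )

    def test_missing_flank_raises(self, rng):
        with pytest.raises(DecompositionError):
            decompose_junction(random_dna(rng, 60), random_dna(rng, 60), random_dna(rng, 60))

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        r = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        lf, rf = random_dna(r, 30), random_dna(r, 30)
        n = random_dna(r, int(r.integers(0, 8)))
        cons = lf + n + rf
        left_ref = lf + random_dna(r, 35)
        right_ref = random_dna(r, 35) + rf
        d = decompose_junction(cons, left_ref, right_ref, min_anchor=5)
        assert (d.left_match, d.right_match, d.microhomology, d.n_region) == oracle_decompose(
            cons, left_ref, right_ref
        )
        assert not (d.microhomology > 0 and d.n_region)

    def test_inverse_of_simulator_junctions(self, igh_model, rng):
        """Round-trip: reconstruct each truth junction's consensus from the
        derivative and decompose it against the reference flanks."""
        v, j = igh_model.segment("IGHV2"), igh_model.segment("IGHJ1")
        for n_len in (0, 3, 11, 23):
            derivs, truth = recombine_deletion(
                igh_model, v.rss_3prime, j.rss_5prime, trims=(2, 1), n_len=n_len, rng=rng
            )
            jt = truth.junctions[0]
            g = igh_model.sequences["chr_IGH"]
            seq = derivs[0].sequence(igh_model.sequences)
            cons = seq[jt.offset - 40 : jt.offset + len(jt.n_seq) + 40]
            left_ref = g[jt.left.pos - 40 : jt.left.pos + 60]
            right_ref = g[jt.right.pos - 60 : jt.right.pos + 40]
            d = decompose_junction(cons, left_ref, right_ref, min_anchor=10)
            assert d.n_region == jt.n_seq
            assert d.microhomology == jt.micro


class TestClassifyAndCheck:
    def test_inversion_signal_and_coding_joints(self, igk_inverted_model, rng):
        m = igk_inverted_model
        v, j = m.segment("IGKV1"), m.segment("IGKJ2")
        _, truth = recombine_inversion(m, v.rss_3prime, j.rss_5prime,
                                       trims=(2, 2), n_len=4, rng=rng)
        anns = annotate_calls(calls_from_truth([truth]), m, sample_lineage="B")
        by_type = {a.joint_type: a for a in anns}
        assert set(by_type) == {"signal", "coding"}
        assert by_type["signal"].n_len == 0
        assert by_type["coding"].n_len == 4
        assert by_type["signal"].twelve_23 == "compliant"

    def test_translocation_sides_signal_plus_non_rss(self, rng):
        bp = LocusBlueprint(
            loci=[LocusSpec(name="IGK", n_v=1, n_d=0, n_j=2, spacing=600),
                  LocusSpec(name="ONC", n_v=0, n_d=0, n_j=0, margin=4000)],
            seed=6,
        )
        m = build_synthetic_model(bp)
        j = m.segment("IGKJ2")
        # one side at the J RSS outer edge, the other in anonymous sequence
        _, truth = translocate(
            m, "chr_IGK", "chr_ONC", j.rss_5prime.start, j.rss_5prime.start + 40,
            2600, 2600, rng=rng,
        )
        anns = annotate_calls(calls_from_truth([truth]), m, sample_lineage="B")
        kinds = {
            (a.left.kind, a.right.kind) for a in anns
        }
        assert any("non-RSS" in k for k in kinds)
        assert all(a.category == "translocation" for a in anns)

    def test_12_23_truth_table(self):
        def rss(spacer):
            return RSSMotif("c", 0, 16 + spacer, spacer, "+",
                            HEPTAMER_CONSENSUS, NONAMER_CONSENSUS)
        assert check_12_23(rss(23), rss(12)) == "compliant"
        assert check_12_23(rss(12), rss(23)) == "compliant"
        assert check_12_23(rss(23), rss(23)) == "violation"
        assert check_12_23(rss(12), rss(12)) == "violation"
        assert check_12_23(rss(23), None) == "not-applicable"
        assert check_12_23(None, rss(12)) == "not-applicable"
        # slack: spacers one off the canonical length still classify
        assert check_12_23(rss(22), rss(13)) == "compliant"

    @settings(max_examples=50, deadline=None)
    @given(st.integers(8, 30), st.integers(8, 30))
    def test_12_23_symmetric(self, s1, s2):
        def rss(spacer):
            return RSSMotif("c", 0, 16 + spacer, spacer, "+",
                            HEPTAMER_CONSENSUS, NONAMER_CONSENSUS)
        assert check_12_23(rss(s1), rss(s2)) == check_12_23(rss(s2), rss(s1))


class TestProductivity:
    def _annotated_deletion(self, model, v_id, j_id, trims, n_len, rng, **kw):
        v, j = model.segment(v_id), model.segment(j_id)
        _, truth = recombine_deletion(
            model, v.rss_3prime, j.rss_5prime, trims=trims, n_len=n_len, rng=rng, **kw
        )
        return annotate_calls(calls_from_truth([truth]), model, sample_lineage="B")[0]

    def test_frame_preserving_join_is_productive(self, igh_model):
        # choose trims + N so (retained_left + n) % 3 == right offset % 3
        v = igh_model.segment("IGHV1")
        rng = np.random.default_rng(3)
        ann = self._annotated_deletion(igh_model, "IGHV1", "IGHJ1", (0, 0), 3, rng)
        assert ann.frame_status == "in-frame"
        assert ann.productivity == "productive"

    def test_truncation_below_half_is_unproductive(self, igh_model):
        j = igh_model.segment("IGHJ1")
        rng = np.random.default_rng(4)
        trim_j = j.length - 20  # keep 20 of 51 coding bases: fraction < 0.5
        # phase continuity: (retained_left + n) = trim_j (mod 3) keeps frame
        n_len = 3 + ((trim_j - 3) % 3)
        ann = self._annotated_deletion(
            igh_model, "IGHV1", "IGHJ1", (0, trim_j), n_len, rng
        )
        assert ann.frame_status == "in-frame"
        assert ann.productivity == "unproductive"
        assert ann.productivity_reason == "truncation"

    def test_frame_shift_by_one_is_unproductive(self, igh_model):
        rng = np.random.default_rng(5)
        ann = self._annotated_deletion(igh_model, "IGHV1", "IGHJ1", (0, 0), 4, rng)
        assert ann.frame_status == "out-of-frame"
        assert (ann.productivity, ann.productivity_reason) == ("unproductive", "frame")

    def test_pseudogene_partner_unproductive(self, rng):
        bp = LocusBlueprint(
            loci=[LocusSpec(name="IGK", n_v=1, n_d=0, n_j=1, spacing=600)], seed=8
        )
        m = build_synthetic_model(bp)
        m.segment("IGKV1").functional = False
        ann = self._annotated_deletion(m, "IGKV1", "IGKJ1", (0, 0), 3, rng)
        assert ann.productivity == "unproductive"
        assert ann.productivity_reason == "pseudogene"


class TestCategorize:
    def test_v_replacement_is_vv(self):
        bp = LocusBlueprint(
            loci=[LocusSpec(name="IGH", n_v=2, n_d=0, n_j=1, cryptic_in_v={1: 120})],
            seed=3,
        )
        m = build_synthetic_model(bp)
        rng = np.random.default_rng(1)
        _, truth = recombine_v_replacement(
            m, "IGHV1", "IGHV2", 120, 3, n_seq=random_dna(rng, 5), rng=rng
        )
        ann = annotate_calls(calls_from_truth([truth]), m, sample_lineage="B")[0]
        assert ann.category == "V-V"
        assert ann.joint_type == "hybrid"
        assert ann.left.rss_used == "segment RSS"
        assert ann.twelve_23 == "not-applicable"

    def test_igh_vd_in_t_cell_is_lineage_inappropriate(self, igh_model, rng):
        v, d = igh_model.segment("IGHV1"), igh_model.segment("IGHD1")
        _, truth = recombine_deletion(
            igh_model, v.rss_3prime, d.rss_5prime, trims=(1, 1), n_len=3, rng=rng,
            partners=(v.id, d.id), category="V-D",
        )
        ann = annotate_calls(calls_from_truth([truth]), igh_model, sample_lineage="T")[0]
        assert ann.category == "V-D"
        assert ann.lineage_flag == "inappropriate"

    def test_trb_vj_with_retained_j_rss_is_order_violating(self, rng):
        """V joined directly to J in a D-bearing locus, with the J's
        12-spacer RSS observed in a signal joint: 12/23-compliant but
        order-violating."""
        bp = LocusBlueprint(
            loci=[LocusSpec(name="TRB", n_v=1, n_d=2, n_j=2, invert_j=True,
                            spacing=600)],
            seed=13,
        )
        m = build_synthetic_model(bp)
        v, j = m.segment("TRBV1"), m.segment("TRBJ1")
        _, truth = recombine_inversion(
            m, v.rss_3prime, j.rss_5prime, trims=(0, 0), n_len=0, rng=rng,
            partners=(v.id, j.id), category="V-J",
        )
        anns = annotate_calls(calls_from_truth([truth]), m, sample_lineage="T")
        signal = next(a for a in anns if a.joint_type == "signal")
        assert signal.twelve_23 == "compliant"
        assert signal.order_flag == "order-violating"
        assert signal.lineage_flag == "appropriate"

    def test_unknown_lineage_not_assessed(self, igh_model, rng):
        v, j = igh_model.segment("IGHV1"), igh_model.segment("IGHJ1")
        _, truth = recombine_deletion(igh_model, v.rss_3prime, j.rss_5prime, rng=rng)
        ann = annotate_calls(calls_from_truth([truth]), igh_model, sample_lineage=None)[0]
        assert ann.lineage_flag == "not-assessed"

    def test_locus_lineage_mapping(self):
        assert locus_lineage("IGH") == "B" == locus_lineage("IGK")
        assert locus_lineage("TRB") == "T"
        assert locus_lineage("ONC") is None


class TestLedger:
    def _model(self, la=20000, lb=20000):
        return LocusModel(
            sequences={"chr2": "A" * la, "chr8": "C" * lb}, segments=[]
        )

    def _call(self, cid, left, right, n=""):
        return JunctionCall(cid, "interchromosomal", left, right, "base-pair",
                            (0, 1), (0, 1), 5, n_seq=n)

    def test_published_t2_8_offsets_give_252(self):
        """Breakpoints 2603 and 2855 bp telomeric of the oncogene marker:
        252 bases of that chromosome on neither derivative."""
        marker = 10000
        m = self._model()
        der2 = self._call("der2", JunctionSide("chr2", 9683, "+"),
                          JunctionSide("chr8", marker + 2855, "+"))
        der8 = self._call("der8", JunctionSide("chr8", marker + 2603, "+"),
                          JunctionSide("chr2", 10000, "+"))
        led = ledger_reciprocal(der2, der8, m)
        assert led.per_chrom["chr8"].lost == 252
        assert led.per_chrom["chr2"].lost == 317

    def test_identical_breakpoints_lose_nothing(self):
        m = self._model()
        a = self._call("a", JunctionSide("chr2", 5000, "+"), JunctionSide("chr8", 7000, "+"))
        b = self._call("b", JunctionSide("chr8", 7000, "+"), JunctionSide("chr2", 5000, "+"))
        led = ledger_reciprocal(a, b, m)
        assert led.lost_total == 0 and led.inserted == 0
        assert led.expected_derivative_total == 40000

    def test_large_and_small_losses_reported_per_chromosome(self):
        m = self._model(la=50000, lb=20000)
        a = self._call("a", JunctionSide("chr2", 5000, "+"),
                       JunctionSide("chr8", 7012, "+"), n="G" * 11)
        b = self._call("b", JunctionSide("chr8", 7000, "+"),
                       JunctionSide("chr2", 43492, "+"), n="T" * 8)
        led = ledger_reciprocal(a, b, m)
        assert led.per_chrom["chr2"].lost == 38492
        assert led.per_chrom["chr8"].lost == 12
        assert led.inserted == 19
        assert led.expected_derivative_total == 70000 - 38492 - 12 + 19

    def test_non_reciprocal_pair_rejected(self):
        m = self._model()
        a = self._call("a", JunctionSide("chr2", 5000, "+"), JunctionSide("chr8", 7000, "+"))
        b = self._call("b", JunctionSide("chr2", 6000, "+"), JunctionSide("chr8", 8000, "+"))
        with pytest.raises(PairingError):
            ledger_reciprocal(a, b, m)

    def test_conservation_against_simulated_derivatives(self, rng):
        m = self._model()
        derivs, truth = translocate(m, "chr2", "chr8", 4000, 4300, 9000, 8990,
                                    n_seqs=(random_dna(rng, 5), random_dna(rng, 3)),
                                    rng=rng)
        calls = calls_from_truth([truth])
        led = ledger_reciprocal(calls[0], calls[1], m)
        lengths = [d.length(m.sequences) for d in derivs]
        assert led.conserves(lengths)
        assert led.per_chrom["chr2"].lost == 300
        assert led.per_chrom["chr8"].lost == 10
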