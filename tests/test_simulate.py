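"""Simulator: recombination mechanics, junction truth, capture sequencing."""

import numpy as np
import pytest

from vdjcapture._util import random_dna, revcomp
from vdjcapture.locus import LocusBlueprint, LocusSpec, build_synthetic_model, design_baits
from vdjcapture.simulate import (
    CaptureConfig,
    EMPIRICAL_N_LENGTHS,
    JunctionSide,
    MechanismError,
    canonical_junction,
    draw_n_region,
    germline_contig,
    normalize_junction,
    recombine_deletion,
    recombine_inversion,
    recombine_v_replacement,
    recombine_vdj_two_step,
    simulate_capture_and_reads,
    translocate,
)


def junction_string(model, truth_junction, flank=30):
    """Reference-based reconstruction of a junction's local sequence."""
    seqs = model.sequences
    l, r = truth_junction.left, truth_junction.right
    if l.orient == "+":
        lf = seqs[l.chrom][l.pos - flank : l.pos]
    else:
        lf = revcomp(seqs[l.chrom][l.pos : l.pos + flank])
    if r.orient == "+":
        rf = seqs[r.chrom][r.pos : r.pos + flank]
    else:
        rf = revcomp(seqs[r.chrom][r.pos - flank : r.pos])
    return lf + truth_junction.n_seq + rf


def junction_in_contig(model, truth_junction, contig, flank=30):
    """True if the junction's local sequence occurs in the contig on
    either strand (truth is stored in the canonical junction frame)."""
    js = junction_string(model, truth_junction, flank)
    seq = contig.sequence(model.sequences)
    return js in seq or revcomp(js) in seq


class TestDeletion:
    def test_conservation_zero_trims_zero_n(self, igh_model, rng):
        v, j = igh_model.segment("IGHV1"), igh_model.segment("IGHJ1")
        derivs, truth = recombine_deletion(
            igh_model, v.rss_3prime, j.rss_5prime, trims=(0, 0), n_len=0, rng=rng
        )
        L = len(igh_model.sequences["chr_IGH"])
        dist = j.rss_5prime.end - v.rss_3prime.start
        assert derivs[0].length(igh_model.sequences) == L - dist

    def test_junction_decomposes_to_planted_n(self, igh_model, rng):
        """D-J joint with a 2-5 nt insert: the emitted junction contains
        exactly the drawn untemplated bases between the two flanks."""
        d, j = igh_model.segment("IGHD1"), igh_model.segment("IGHJ1")
        for n_len in (2, 3, 4, 5):
            derivs, truth = recombine_deletion(
                igh_model, d.rss_3prime, j.rss_5prime, trims=(1, 1), n_len=n_len, rng=rng
            )
            jt = truth.junctions[0]
            assert len(jt.n_seq) == n_len
            assert junction_string(igh_model, jt) in derivs[0].sequence(igh_model.sequences)

    def test_excised_circle_carries_signal_joint(self, igh_model, rng):
        v, j = igh_model.segment("IGHV1"), igh_model.segment("IGHJ1")
        derivs, truth = recombine_deletion(
            igh_model, v.rss_3prime, j.rss_5prime, rng=rng, emit_circle=True
        )
        assert len(derivs) == 2
        signal = [jt for jt in truth.junctions if jt.kind == "signal"]
        assert len(signal) == 1 and signal[0].n_seq == ""
        assert junction_in_contig(igh_model, signal[0], derivs[1])

    def test_nonfacing_rss_rejected(self, igh_model, rng):
        v1, v2 = igh_model.segment("IGHV1"), igh_model.segment("IGHV2")
        with pytest.raises(MechanismError):
            recombine_deletion(igh_model, v1.rss_3prime, v2.rss_3prime, rng=rng)

    def test_12_23_violation_requires_force(self, igh_model, rng):
        d1, d2 = igh_model.segment("IGHD1"), igh_model.segment("IGHD2")
        with pytest.raises(MechanismError):
            recombine_deletion(igh_model, d1.rss_3prime, d2.rss_3prime, rng=rng)

    def test_truncating_trim_recorded(self, igh_model, rng):
        """A J-side trim deep into the coding segment is visible in truth."""
        d, j = igh_model.segment("IGHD1"), igh_model.segment("IGHJ1")
        trim = j.length - 35 if j.length > 35 else 5
        derivs, truth = recombine_deletion(
            igh_model, d.rss_3prime, j.rss_5prime, trims=(0, trim), n_len=3, rng=rng
        )
        assert truth.trims[1] == trim
        assert truth.junctions[0].right.pos == j.rss_5prime.end + trim


class TestInversion:
    def test_conserves_sequence_plus_n(self, igk_inverted_model, rng):
        m = igk_inverted_model
        v, j = m.segment("IGKV1"), m.segment("IGKJ1")
        derivs, truth = recombine_inversion(
            m, v.rss_3prime, j.rss_5prime, trims=(0, 0), n_len=4, rng=rng
        )
        L = len(m.sequences["chr_IGK"])
        assert derivs[0].length(m.sequences) == L + truth.inserted_bases

    def test_signal_joint_is_precise_rss_fusion(self, igk_inverted_model, rng):
        m = igk_inverted_model
        v, j = m.segment("IGKV2"), m.segment("IGKJ2")
        derivs, truth = recombine_inversion(
            m, v.rss_3prime, j.rss_5prime, trims=(3, 1), n_len=5, rng=rng
        )
        kinds = {jt.kind for jt in truth.junctions}
        assert kinds == {"coding", "signal"}
        signal = next(jt for jt in truth.junctions if jt.kind == "signal")
        assert signal.n_seq == ""
        seq = derivs[0].sequence(m.sequences)
        assert junction_string(m, signal) in seq
        coding = next(jt for jt in truth.junctions if jt.kind == "coding")
        assert junction_string(m, coding) in seq

    def test_two_step_trb_style_event(self):
        """D-J deletion then V joining: final contig carries both coding
        joints recorded in truth."""
        bp = LocusBlueprint(
            loci=[LocusSpec(name="TRB", n_v=1, n_d=1, n_j=1, spacing=600)], seed=4
        )
        m = build_synthetic_model(bp)
        rng = np.random.default_rng(0)
        derivs, truth = recombine_vdj_two_step(
            m, "TRBV1", "TRBD1", "TRBJ1", trims=(2, 1, 1, 2), n_lens=(3, 4), rng=rng
        )
        assert truth.category == "V-D-J"
        assert len(truth.junctions) == 2
        for jt in truth.junctions:
            assert junction_in_contig(m, jt, derivs[0], flank=8)
        lost = truth.deleted_bases
        L = len(m.sequences["chr_TRB"])
        assert derivs[0].length(m.sequences) == L - lost + truth.inserted_bases


class TestVReplacement:
    def test_zero_stub_zero_n_fuses_rss_to_cryptic(self):
        bp = LocusBlueprint(
            loci=[LocusSpec(name="IGH", n_v=2, n_d=0, n_j=1, cryptic_in_v={1: 120})],
            seed=3,
        )
        m = build_synthetic_model(bp)
        derivs, truth = recombine_v_replacement(m, "IGHV1", "IGHV2", 120, 0, n_seq="")
        jt = truth.junctions[0]
        inv = m.segment("IGHV1")
        rep = m.segment("IGHV2")
        # breakpoints match the RSS signal end / cryptic heptamer up to
        # the leftmost-shift through junctional microhomology
        assert jt.n_seq == ""
        assert jt.left.pos <= inv.rss_3prime.end <= jt.left.pos + jt.micro
        assert jt.right.pos <= rep.start + 120 <= jt.right.pos + jt.micro
        assert junction_in_contig(m, jt, derivs[0])

    def test_same_partners_different_n_distinct_junctions(self):
        bp = LocusBlueprint(
            loci=[LocusSpec(name="IGH", n_v=2, n_d=0, n_j=1, cryptic_in_v={1: 120})],
            seed=3,
        )
        m = build_synthetic_model(bp)
        seqs = set()
        breakpoints = set()
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            derivs, truth = recombine_v_replacement(
                m, "IGHV1", "IGHV2", 120, 2, n_seq=random_dna(rng, 5), rng=rng
            )
            jt = truth.junctions[0]
            seqs.add(jt.n_seq)
            breakpoints.add((jt.left.pos, jt.right.pos))
        assert len(seqs) == 3 and len(breakpoints) == 1

    def test_missing_cryptic_heptamer_rejected(self, igh_model):
        with pytest.raises(Exception):
            recombine_v_replacement(igh_model, "IGHV1", "IGHV2", 50, 0, n_seq="")


class TestTranslocate:
    def test_unequal_breakpoints_lose_sequence(self, rng):
        seqs = {"cA": random_dna(rng, 20000), "cB": random_dna(rng, 20000)}
        from vdjcapture.locus import LocusModel
        m = LocusModel(sequences=seqs, segments=[])
        derivs, truth = translocate(m, "cA", "cB", 10000, 10252, 8000, 8000, rng=rng)
        assert truth.lost_per_chrom == {"cA": 252, "cB": 0}
        total = sum(d.length(seqs) for d in derivs)
        assert total == 40000 - 252 + truth.inserted_bases

    def test_perfectly_reciprocal_conserves_exactly(self, rng):
        seqs = {"cA": random_dna(rng, 5000), "cB": random_dna(rng, 5000)}
        from vdjcapture.locus import LocusModel
        m = LocusModel(sequences=seqs, segments=[])
        derivs, truth = translocate(m, "cA", "cB", 2000, 2000, 3000, 3000, rng=rng)
        assert truth.lost_per_chrom == {"cA": 0, "cB": 0}
        assert sum(d.length(seqs) for d in derivs) == 10000

    def test_complex_junction_losses_and_inserts(self, rng):
        """12 bp lost on one side with 8+11 nt inserts: the ledger terms
        satisfy the conservation identity."""
        seqs = {"cA": random_dna(rng, 30000), "cB": random_dna(rng, 15000)}
        from vdjcapture.locus import LocusModel
        m = LocusModel(sequences=seqs, segments=[])
        derivs, truth = translocate(
            m, "cA", "cB", 9988, 10000, 7000, 7000,
            n_seqs=(random_dna(rng, 11), random_dna(rng, 8)), rng=rng,
        )
        assert truth.lost_per_chrom["cA"] == 12
        assert truth.inserted_bases == 19
        assert sum(d.length(seqs) for d in derivs) == 45000 - 12 + 19

    def test_out_of_bounds_breakpoint_rejected(self, rng):
        seqs = {"cA": "ACGT" * 100, "cB": "ACGT" * 100}
        from vdjcapture.locus import LocusModel
        m = LocusModel(sequences=seqs, segments=[])
        with pytest.raises(ValueError):
            translocate(m, "cA", "cB", 5000, 0, 0, 0, rng=rng)


class TestNRegion:
    def test_fixed_lengths(self, rng):
        assert len(draw_n_region(rng, 23)) == 23
        assert draw_n_region(rng, 0) == ""

    def test_negative_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_n_region(rng, -1)

    def test_empirical_favours_short_additions(self, rng):
        draws = [len(draw_n_region(rng, "empirical")) for _ in range(10000)]
        short = sum(1 for d in draws if 2 <= d <= 5)
        longer = sum(1 for d in draws if d > 5)
        assert short > longer
        assert set(draws) <= set(EMPIRICAL_N_LENGTHS)


class TestNormalization:
    def test_canonical_flip_roundtrip(self, igh_model):
        l = JunctionSide("chr_IGH", 3000, "+")
        r = JunctionSide("chr_IGH", 1000, "+")
        cl, cr, n = canonical_junction(l, r, "ACG")
        assert (cl.chrom, cl.pos) <= (cr.chrom, cr.pos)
        assert n == revcomp("ACG")

    def test_absorbable_n_bases_move_into_flanks(self, igh_model):
        g = igh_model.sequences["chr_IGH"]
        left = JunctionSide("chr_IGH", 1000, "+")
        right = JunctionSide("chr_IGH", 5000, "+")
        # an N that begins with the reference continuation is absorbed
        n = g[1000] + "X"  # X placeholder replaced below
        for b in "ACGT":
            if b != g[1001] and b != g[4999]:
                n = g[1000] + b
                break
        l2, r2, n2, micro = normalize_junction(igh_model.sequences, left, right, n)
        assert l2.pos == 1001 and len(n2) == 1

    def test_microhomology_shifts_leftmost(self):
        # left flank ends in ACG and the deleted interval also ends in
        # ACG: the seam can sit at three equivalent positions and must
        # be parked at the leftmost one
        seqs = {"c": "TTTTTACG" + "GGACG" + "CCCCC"}
        left = JunctionSide("c", 8, "+")
        right = JunctionSide("c", 13, "+")
        l2, r2, n2, micro = normalize_junction(seqs, left, right, "")
        assert micro == 3
        assert (l2.pos, r2.pos) == (5, 10)


class TestCaptureSim:
    def test_zero_coverage_empty(self, igh_model, igh_baits):
        contig = germline_contig("chr_IGH", igh_model.sequences)
        pairs, tm, stats = simulate_capture_and_reads(
            [contig], igh_model, igh_baits, CaptureConfig(coverage=0, seed=1)
        )
        assert pairs == [] and stats["n_pairs"] == 0

    def test_fully_baited_contig_read_count_and_insert(self, rng):
        """10 kb fully-baited contig at 50x: pair count within 3 sigma of
        L*cov/(2*read_len); realized median insert within 10 of target."""
        from vdjcapture.locus import BaitSet, LocusModel
        seq = random_dna(rng, 10000)
        m = LocusModel(sequences={"c": seq}, segments=[])
        baits = BaitSet([("c", 0, 10000)], [("c", 0, 10000)])
        cfg = CaptureConfig(coverage=50, seed=5, on_target_fraction=1.0)
        pairs, tm, stats = simulate_capture_and_reads(
            [germline_contig("c", m.sequences)], m, baits, cfg
        )
        expected = 10000 * 50 / 200
        sigma = np.sqrt(expected)
        assert abs(stats["n_pairs"] - expected) <= 3 * sigma
        inserts = [tm[p.name]["end"] - tm[p.name]["start"] for p in pairs]
        assert abs(np.median(inserts) - 254) <= 10

    def test_defaults_match_library_geometry(self):
        cfg = CaptureConfig()
        assert cfg.read_len == 100 and cfg.insert_median == 254
        assert cfg.fragment_len == 500

    def test_determinism_byte_identical(self, igh_model, igh_baits):
        contigs = [germline_contig(c, igh_model.sequences) for c in igh_model.sequences]
        cfg = CaptureConfig(coverage=20, seed=42)
        out1 = simulate_capture_and_reads(contigs, igh_model, igh_baits, cfg)
        out2 = simulate_capture_and_reads(contigs, igh_model, igh_baits, cfg)
        assert [(p.name, p.seq1, p.seq2) for p in out1[0]] == [
            (p.name, p.seq1, p.seq2) for p in out2[0]
        ]

    def test_on_target_fraction_calibrated(self, igh_model, igh_baits):
        contigs = [germline_contig(c, igh_model.sequences) for c in igh_model.sequences]
        cfg = CaptureConfig(coverage=60, seed=7, on_target_fraction=0.5)
        _, _, stats = simulate_capture_and_reads(contigs, igh_model, igh_baits, cfg)
        assert 0.38 <= stats["on_target_fraction"] <= 0.54

    def test_truth_map_positions_match_reads(self, igh_model, igh_baits):
        contigs = [germline_contig(c, igh_model.sequences) for c in igh_model.sequences]
        cfg = CaptureConfig(coverage=10, seed=3, error_rate=0.0)
        pairs, tm, _ = simulate_capture_and_reads(contigs, igh_model, igh_baits, cfg)
        for p in pairs[:50]:
            info = tm[p.name]
            frag = igh_model.sequences[info["contig"]][info["start"] : info["end"]]
            if info["r1_strand"] == "-":
                frag = revcomp(frag)
            assert p.seq1 == frag[:100]
            assert p.seq2 == revcomp(frag)[:100]


class TestTruthInvariants:
    def test_sequence_conservation_across_mechanisms(self, igh_model, igk_inverted_model, rng):
        cases = []
        v, j = igh_model.segment("IGHV2"), igh_model.segment("IGHJ2")
        cases.append((igh_model, recombine_deletion(
            igh_model, v.rss_3prime, j.rss_5prime, trims=(2, 2), n_len=4, rng=rng)))
        v, j = igk_inverted_model.segment("IGKV1"), igk_inverted_model.segment("IGKJ2")
        cases.append((igk_inverted_model, recombine_inversion(
            igk_inverted_model, v.rss_3prime, j.rss_5prime, trims=(1, 3), n_len=2, rng=rng)))
        for model, (derivs, truth) in cases:
            chroms = {p[1] for d in derivs for p in d.pieces if p[0] == "ref"}
            parent = sum(len(model.sequences[c]) for c in chroms)
            total = sum(d.length(model.sequences) for d in derivs)
            assert total == parent - truth.deleted_bases + truth.inserted_bases

    def test_simulated_signal_joints_never_carry_n(self, igk_inverted_model, rng):
        m = igk_inverted_model
        for seed in range(5):
            r = np.random.default_rng(seed)
            v, j = m.segment("IGKV1"), m.segment("IGKJ1")
            _, truth = recombine_inversion(m, v.rss_3prime, j.rss_5prime,
                                           n_len=int(r.integers(0, 6)), rng=r)
            for jt in truth.junctions:
                if jt.kind == "signal":
                    assert jt.n_seq == ""
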