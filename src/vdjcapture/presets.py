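"""Ready-made simulation scenarios emulating the study conditions.

Each preset builds a small synthetic locus model, plants one or more
recombination events with the junction structure reported for the
corresponding real event (N-region lengths, per-derivative losses,
RSS-RSS signal-joint precision), and returns everything needed to run
capture sequencing and detection over it.  Chromosome-scale distances
are scaled to desk size; junction-local structure (trims, inserts,
breakpoint separations that define per-derivative loss) is kept exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import random_dna
from .locus import BaitSet, LocusBlueprint, LocusModel, LocusSpec, build_synthetic_model, design_baits
from .simulate import (
    CaptureConfig,
    Contig,
    RearrangementTruth,
    germline_contig,
    recombine_deletion,
    recombine_inversion,
    recombine_v_replacement,
    recombine_vdj_two_step,
    simulate_capture_and_reads,
    translocate,
)

EVENT_CATEGORIES = ("V-D-J", "V-J", "D-J", "V-D", "V-V", "translocation")


@dataclass
class Scenario:
    """A simulated sample: model, bait design, contigs and ground truth."""

    model: LocusModel
    baits: BaitSet
    contigs: list[Contig]
    truths: list[RearrangementTruth]
    lineage: str = "B"
    meta: dict = field(default_factory=dict)

    def reads(self, coverage: float = 50.0, seed: int = 0, **kw):
        cfg = CaptureConfig(coverage=coverage, seed=seed, **kw)
        return simulate_capture_and_reads(self.contigs, self.model, self.baits, cfg)


def _with_germline(model: LocusModel, derivs: list[Contig]) -> list[Contig]:
    return derivs + [germline_contig(c, model.sequences) for c in model.sequences]


# ---------------------------------------------------------------------------
# published-event presets
# ---------------------------------------------------------------------------


def db_t14_18(seed: int = 0) -> Scenario:
    """DB-style t(14;18): unbalanced IGH-BCL2 reciprocal translocation.

    der(14) joins the partner chromosome to the IGH J cluster with an
    11 nt N-region; der(18) keeps IGH up to a D segment with an 8 nt
    N-region; the partner-chromosome breakpoints sit 12 bp apart, so
    12 bp are lost from the der(18)-side parent.  The 38.5 kb loss
    between the IGH D and J clusters scales down to the synthetic
    locus's D-to-J distance.
    """
    rng = np.random.default_rng(seed)
    bp = LocusBlueprint(
        loci=[
            LocusSpec(name="IGH", n_v=2, n_d=2, n_j=2, spacing=600, margin=2000),
            LocusSpec(name="BCL2", n_v=0, n_d=0, n_j=0, margin=7000),
        ],
        seed=seed,
    )
    model = build_synthetic_model(bp)
    baits = design_baits(model)
    d = model.segment("IGHD1")
    j = model.segment("IGHJ2")
    b2 = d.rss_3prime.end  # der(18) keeps IGH through the D segment and its RSS
    b1 = j.rss_5prime.start - 110  # der(14) joins 110 bp outside the J's RSS
    igh_loss = b1 - b2  # defined by the synthetic locus geometry
    a2 = 7000  # partner-chromosome anchor ("BCL2" placeholder position)
    a1 = a2 - 12  # 12 bp of the partner chromosome on neither derivative
    n14 = random_dna(rng, 11)
    n18 = random_dna(rng, 8)
    derivs, truth = translocate(
        model, "chr_BCL2", "chr_IGH", a1, a2, b1, b2,
        n_seqs=(n14, n18), rng=rng, event_id="t14_18",
    )
    return Scenario(
        model, baits, _with_germline(model, derivs), [truth], "B",
        meta={
            "der14_contig": derivs[0].name,
            "der18_contig": derivs[1].name,
            "igh_loss": igh_loss,
            "partner_loss": 12,
            "n_der14": 11,
            "n_der18": 8,
            "igh_bp_der14": b1,
            "igh_bp_der18": b2,
        },
    )


def arh77_v_replacement(seed: int = 0, n_len: int = 23, stub_len: int = 5) -> Scenario:
    """ARH-77-style V-to-V interstitial deletion with a long N-region.

    The invading V's RSS pairs with a cryptic heptamer inside a
    downstream V; a short stub of the removed coding segment is
    retained next to an unusually long (23 nt) untemplated insert.
    """
    rng = np.random.default_rng(seed)
    bp = LocusBlueprint(
        loci=[LocusSpec(name="IGH", n_v=3, n_d=1, n_j=1, spacing=700, margin=2000,
                        cryptic_in_v={2: 150})],
        seed=seed,
    )
    model = build_synthetic_model(bp)
    baits = design_baits(model)
    derivs, truth = recombine_v_replacement(
        model, "IGHV1", "IGHV3", 150, retained_stub_len=stub_len,
        n_seq=random_dna(rng, n_len), rng=rng, event_id="arh77_vv",
    )
    return Scenario(
        model, baits, _with_germline(model, derivs), [truth], "B",
        meta={"n_len": n_len},
    )


def inversion_panel(seed: int = 0, n_events: int = 6) -> Scenario:
    """Panel of inversional V-J rearrangements, one per synthetic locus.

    Every event retains a precise RSS-RSS signal joint (zero
    untemplated bases) alongside its coding joint; capture baits sit on
    the signal side of each RSS, so the signal joints are the
    well-covered ones -- the enrichment bias that favours inversion
    detection.
    """
    rng = np.random.default_rng(seed)
    loci = [
        LocusSpec(name=f"IGK{i + 1}", n_v=2, n_d=0, n_j=2, invert_j=True,
                  spacing=650, margin=1500)
        for i in range(n_events)
    ]
    model = build_synthetic_model(LocusBlueprint(loci=loci, seed=seed))
    baits = design_baits(model)
    contigs: list[Contig] = []
    truths: list[RearrangementTruth] = []
    for i in range(n_events):
        v = model.segment(f"IGK{i + 1}V{1 + int(rng.integers(2))}")
        j = model.segment(f"IGK{i + 1}J{1 + int(rng.integers(2))}")
        derivs, truth = recombine_inversion(
            model, v.rss_3prime, j.rss_5prime,
            trims=(int(rng.integers(0, 4)), int(rng.integers(0, 4))),
            n_len=int(rng.integers(2, 6)), rng=rng,
            partners=(v.id, j.id), event_id=f"inv{i + 1}",
        )
        contigs.extend(derivs)
        truths.append(truth)
    germline = [
        germline_contig(c, model.sequences)
        for c in model.sequences
        if not any(t.junctions[0].left.chrom == c for t in truths)
    ]
    return Scenario(model, baits, contigs + germline, truths, "B",
                    meta={"n_events": n_events})


# ---------------------------------------------------------------------------
# per-category single-event scenarios (soundness / recall panels)
# ---------------------------------------------------------------------------


def single_event(category: str, seed: int, suffix: str = "") -> Scenario:
    """One recombination event of the given category in a minimal model.

    Trims and N-region lengths are drawn from the short-addition regime
    (0-4 nt trims, 2-5 nt inserts).  Baits are laid symmetrically
    around each RSS so coding joints are as well covered as signal
    joints -- panels probe detector soundness, not enrichment bias.
    ``suffix`` uniquifies locus/chromosome names so scenarios can be
    merged into one sample.
    """
    if category not in EVENT_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    rng = np.random.default_rng(seed)
    trims = (int(rng.integers(0, 5)), int(rng.integers(0, 5)))
    n_len = int(rng.integers(2, 6))
    lineage = "B"
    meta: dict = {"category": category}
    if category == "D-J":
        igh = f"IGH{suffix}"
        spec = LocusSpec(name=igh, n_v=1, n_d=2, n_j=2, spacing=550, margin=1500)
        model = build_synthetic_model(LocusBlueprint(loci=[spec], seed=seed))
        d = model.segment(f"{igh}D{1 + int(rng.integers(2))}")
        j = model.segment(f"{igh}J{1 + int(rng.integers(2))}")
        derivs, truth = recombine_deletion(
            model, d.rss_3prime, j.rss_5prime, trims, n_len, rng,
            partners=(d.id, j.id), category="D-J", event_id=f"dj_{seed}",
        )
    elif category == "V-D":
        igh = f"IGH{suffix}"
        spec = LocusSpec(name=igh, n_v=2, n_d=2, n_j=1, spacing=550, margin=1500)
        model = build_synthetic_model(LocusBlueprint(loci=[spec], seed=seed))
        v = model.segment(f"{igh}V{1 + int(rng.integers(2))}")
        d = model.segment(f"{igh}D{1 + int(rng.integers(2))}")
        derivs, truth = recombine_deletion(
            model, v.rss_3prime, d.rss_5prime, trims, n_len, rng,
            partners=(v.id, d.id), category="V-D", event_id=f"vd_{seed}",
        )
        lineage = "T"  # the observed V-D events were lineage-inappropriate
        truth.lineage_appropriate = False
    elif category == "V-J":
        igk = f"IGK{suffix}"
        spec = LocusSpec(name=igk, n_v=2, n_d=0, n_j=2, invert_j=(seed % 2 == 1),
                         spacing=550, margin=1500)
        model = build_synthetic_model(LocusBlueprint(loci=[spec], seed=seed))
        v = model.segment(f"{igk}V{1 + int(rng.integers(2))}")
        j = model.segment(f"{igk}J{1 + int(rng.integers(2))}")
        op = recombine_inversion if seed % 2 == 1 else recombine_deletion
        derivs, truth = op(
            model, v.rss_3prime, j.rss_5prime, trims, n_len, rng,
            partners=(v.id, j.id), category="V-J", event_id=f"vj_{seed}",
        )
    elif category == "V-D-J":
        trb = f"TRB{suffix}"
        spec = LocusSpec(name=trb, n_v=1, n_d=1, n_j=1, spacing=550, margin=1500)
        model = build_synthetic_model(LocusBlueprint(loci=[spec], seed=seed))
        derivs, truth = recombine_vdj_two_step(
            model, f"{trb}V1", f"{trb}D1", f"{trb}J1",
            trims=(trims[0], trims[1], int(rng.integers(0, 5)), int(rng.integers(0, 5))),
            n_lens=(n_len, int(rng.integers(2, 6))), rng=rng, event_id=f"vdj_{seed}",
        )
        lineage = "T"
    elif category == "V-V":
        igh = f"IGH{suffix}"
        spec = LocusSpec(name=igh, n_v=2, n_d=0, n_j=1, spacing=550, margin=1500,
                         cryptic_in_v={1: 120})
        model = build_synthetic_model(LocusBlueprint(loci=[spec], seed=seed))
        derivs, truth = recombine_v_replacement(
            model, f"{igh}V1", f"{igh}V2", 120, retained_stub_len=int(rng.integers(0, 6)),
            n_seq=random_dna(rng, n_len), rng=rng, event_id=f"vv_{seed}",
        )
    else:  # translocation
        igh, onc = f"IGH{suffix}", f"ONC{suffix}"
        bp = LocusBlueprint(
            loci=[
                LocusSpec(name=igh, n_v=1, n_d=1, n_j=1, spacing=550, margin=1500),
                LocusSpec(name=onc, n_v=0, n_d=0, n_j=0, margin=3000),
            ],
            seed=seed,
        )
        model = build_synthetic_model(bp)
        d = model.segment(f"{igh}D1")
        j = model.segment(f"{igh}J1")
        b2 = d.rss_3prime.end
        b1 = j.rss_5prime.start - int(rng.integers(30, 120))
        a2 = 3000
        a1 = a2 - int(rng.integers(0, 40))
        derivs, truth = translocate(
            model, f"chr_{onc}", f"chr_{igh}", a1, a2, b1, b2,
            n_seqs=(random_dna(rng, n_len), random_dna(rng, int(rng.integers(2, 6)))),
            rng=rng, event_id=f"tx_{seed}",
        )
    baits = design_baits(model, symmetric=True)
    return Scenario(model, baits, _with_germline(model, derivs), [truth], lineage, meta)


def merge_scenarios(scenarios: list[Scenario], lineage: str = "B") -> Scenario:
    """Combine independent scenarios into one multi-locus sample.

    Chromosome names must be disjoint (use the ``suffix`` argument of
    :func:`single_event`).
    """
    sequences: dict[str, str] = {}
    segments = []
    dups = []
    contigs: list[Contig] = []
    truths: list[RearrangementTruth] = []
    windows, bait_list = [], []
    for sc in scenarios:
        overlap = set(sequences) & set(sc.model.sequences)
        if overlap:
            raise ValueError(f"chromosome name collision: {sorted(overlap)}")
        sequences.update(sc.model.sequences)
        segments.extend(sc.model.segments)
        dups.extend(sc.model.seg_dups)
        contigs.extend(sc.contigs)
        truths.extend(sc.truths)
        windows.extend(sc.baits.target_windows)
        bait_list.extend(sc.baits.baits)
    first = scenarios[0].baits
    model = LocusModel(sequences=sequences, segments=segments, seg_dups=dups)
    baits = BaitSet(windows, bait_list, first.window_len, first.bait_len, first.tiling)
    return Scenario(model, baits, contigs, truths, lineage,
                    meta={"n_events": len(truths)})


def table1_panel(seed: int = 0, per_category: int = 1) -> Scenario:
    """A mixed panel with events of every category, one merged sample."""
    scenarios = []
    i = 0
    for rep in range(per_category):
        for cat in EVENT_CATEGORIES:
            scenarios.append(single_event(cat, seed * 1000 + i, suffix=f"s{i}"))
            i += 1
    return merge_scenarios(scenarios)
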