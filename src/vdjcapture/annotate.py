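"""Junction interpretation: joint type, N-region, 12/23, frame, category.

Each detected junction is decomposed against the germline flanks into
left match / microhomology / untemplated (N-region) insert / right
match, then classified the way a hematopathology-oriented analysis
would read it: which side is a coding end and which a signal (RSS) end,
whether the RSS pair obeys the 12/23 rule, whether a coding joint
preserves reading frame and full-length functional segments, what event
category the partner segments imply (V-D-J, V-J, D-J, V-D, V-V,
translocation), and whether the event is appropriate for the sample's
lymphoid lineage.

Microhomology convention: the seam is shifted to its leftmost
equivalent position; bases attributable to either flank are counted as
microhomology, never as N.  A junction therefore has either N > 0 and
microhomology 0, or N = 0 and microhomology >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import longest_common_prefix, longest_common_suffix, revcomp
from .detect import JunctionCall
from .locus import GeneSegment, LocusModel, RSSMotif
from .simulate import JunctionSide

#: lineage of a locus by nomenclature prefix: immunoglobulin loci are
#: B-lineage, T-cell receptor loci T-lineage.
def locus_lineage(locus: str) -> str | None:
    if locus.upper().startswith("IG"):
        return "B"
    if locus.upper().startswith("TR"):
        return "T"
    return None


class DecompositionError(ValueError):
    """Consensus does not contain the expected flanks (likely misassembly)."""


class PairingError(ValueError):
    """Two junctions do not form a reciprocal translocation pair."""


@dataclass
class Decomposition:
    left_match: int
    right_match: int
    microhomology: int
    n_region: str

    @property
    def n_len(self) -> int:
        return len(self.n_region)


def decompose_junction(
    consensus: str,
    left_flank_ref: str,
    right_flank_ref: str,
    min_anchor: int = 10,
) -> Decomposition:
    """Decompose a junction consensus against its two reference flanks.

    ``left_flank_ref`` is the reference sequence expected to match the
    consensus from its first base onward (extending across the
    breakpoint); ``right_flank_ref`` matches the consensus backwards
    from its last base.  The maximal prefix and suffix matches either
    leave a gap (the N-region) or overlap (junctional microhomology,
    with the seam reported at its leftmost equivalent position).
    """
    a = longest_common_prefix(consensus, left_flank_ref)
    b = longest_common_suffix(consensus, right_flank_ref)
    if a < min_anchor or b < min_anchor:
        raise DecompositionError(
            f"flank anchors too short (left {a}, right {b} < {min_anchor})"
        )
    if a + b <= len(consensus):
        return Decomposition(a, b, 0, consensus[a : len(consensus) - b])
    return Decomposition(a, b, a + b - len(consensus), "")


# ---------------------------------------------------------------------------
# per-side classification
# ---------------------------------------------------------------------------


@dataclass
class SideAnnotation:
    side: JunctionSide
    role: str  # 'left' | 'right'
    kind: str  # 'coding' | 'signal' | 'non-RSS'
    segment: str | None = None
    rss: RSSMotif | None = None
    rss_used: str = "none"  # 'segment RSS' | 'cryptic heptamer' | 'none'
    retained_coding: int = 0
    coding_fraction: float = 1.0


def _retained_direction(role: str, orient: str) -> str:
    """Which genomic side of the breakpoint the retained flank occupies."""
    if role == "left":
        return "left" if orient == "+" else "right"
    return "right" if orient == "+" else "left"


def _find_cryptic_heptamer(
    seq: str, pos: int, window: int, max_mm: int = 1
) -> int | None:
    """CAC-rooted heptamer within ``window`` of ``pos``, either orientation.

    Returns the offset of the closest hit or None.  A cryptic heptamer
    is a 7-mer whose CAC root is exact and which matches the heptamer
    consensus with <= ``max_mm`` mismatches elsewhere.
    """
    from .locus import HEPTAMER_CONSENSUS
    from ._util import count_mismatches

    best = None
    for s in range(max(0, pos - window), min(len(seq) - 7, pos + window) + 1):
        for candidate in (seq[s : s + 7], revcomp(seq[s : s + 7])):
            if candidate[:3] != "CAC":
                continue
            if count_mismatches(candidate[3:], HEPTAMER_CONSENSUS[3:], max_mm) <= max_mm:
                if best is None or abs(s - pos) < abs(best - pos):
                    best = s
    return best


def classify_side(
    side: JunctionSide, role: str, model: LocusModel, cryptic_window: int = 50
) -> SideAnnotation:
    """Assign coding / signal / non-RSS status to one junction side."""
    ann = SideAnnotation(side, role, "non-RSS")
    direction = _retained_direction(role, side.orient)
    pos = side.pos
    slack = 10  # seam may sit a few bases off an annotated edge after
    # the leftmost shift through junctional microhomology
    for seg in model.segments_on(side.chrom):
        for rss in seg.rss_list():
            if not rss.start - slack <= pos <= rss.end + slack:
                continue
            # a signal end: the retained flank keeps (most of) the RSS
            kept = (min(pos, rss.end) - rss.start) if direction == "left" \
                else (rss.end - max(pos, rss.start))
            if kept * 2 >= rss.end - rss.start:
                ann.kind = "signal"
                ann.segment = seg.id
                ann.rss = rss
                ann.rss_used = "segment RSS"
                return ann
    for seg in model.segments_on(side.chrom):
        if direction == "left" and seg.start < pos <= seg.end + slack:
            retained = min(pos, seg.end) - seg.start
        elif direction == "right" and seg.start - slack <= pos < seg.end:
            retained = seg.end - max(pos, seg.start)
        else:
            continue
        if retained > 0:
            _fill_coding(ann, seg, retained, direction)
            break
    if ann.kind == "non-RSS":
        # coding-edge breakpoints (zero trim) sit exactly at a segment boundary
        for seg in model.segments_on(side.chrom):
            if (pos == seg.end and direction == "left") or (
                pos == seg.start and direction == "right"
            ):
                _fill_coding(ann, seg, seg.length, direction)
                break
    if ann.rss is None:
        # no annotated RSS explains this side: look for an illegitimate
        # CAC-rooted recombinase target near the breakpoint
        off = _find_cryptic_heptamer(model.sequences[side.chrom], pos, cryptic_window)
        if off is not None:
            ann.rss_used = "cryptic heptamer"
    return ann


def _fill_coding(ann: SideAnnotation, seg: GeneSegment, retained: int, direction: str) -> None:
    """Coding-side annotation; the mediating RSS is the one at the
    junction-facing (non-retained) end of the segment, excised with the
    intervening DNA but still the RSS the recombinase used."""
    ann.kind = "coding"
    ann.segment = seg.id
    ann.retained_coding = retained
    ann.coding_fraction = retained / seg.length
    for rss in seg.rss_list():
        facing_right = rss.start >= seg.end
        if (direction == "left" and facing_right) or (direction == "right" and not facing_right):
            ann.rss = rss
            ann.rss_used = "segment RSS"
    return None


def classify_joint(left_ann: SideAnnotation, right_ann: SideAnnotation) -> str:
    """Joint type from the two side classifications."""
    kinds = {left_ann.kind, right_ann.kind}
    if "non-RSS" in kinds:
        return "non-RSS"
    if kinds == {"signal"}:
        return "signal"
    if kinds == {"coding"}:
        return "coding"
    return "hybrid"


def check_12_23(rss_a: RSSMotif | None, rss_b: RSSMotif | None, slack: int = 1) -> str:
    """12/23-rule verdict for an RSS pair; symmetric in its arguments.

    ``not-applicable`` when either side lacks a full RSS (e.g. a
    cryptic heptamer without a nonamer).
    """
    if rss_a is None or rss_b is None:
        return "not-applicable"

    def cls(rss: RSSMotif) -> int | None:
        if abs(rss.spacer_len - 12) <= slack:
            return 12
        if abs(rss.spacer_len - 23) <= slack:
            return 23
        return None

    ca, cb = cls(rss_a), cls(rss_b)
    if ca is None or cb is None:
        return "violation"
    return "compliant" if {ca, cb} == {12, 23} else "violation"


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------


def call_productivity(
    left_ann: SideAnnotation,
    right_ann: SideAnnotation,
    n_len: int,
    model: LocusModel,
    min_coding_fraction: float = 0.5,
) -> tuple[str, str, str | None]:
    """Frame and productivity for a coding joint.

    Returns ``(frame_status, productivity, reason)``.  A joint is
    in-frame when the codon phase at the end of the retained left
    coding sequence, advanced through the N insert, matches the
    annotated phase at the first retained base of the right segment.
    In-frame joints are productive only if both segments are annotated
    functional and neither is truncated below ``min_coding_fraction``
    of its length.
    """
    if left_ann.kind != "coding" or right_ann.kind != "coding":
        return "not-applicable", "not-applicable", None
    seg_l = model.segment(left_ann.segment)
    seg_r = model.segment(right_ann.segment)
    if seg_l.reading_frame is None or seg_r.reading_frame is None:
        return "not-applicable", "not-applicable", None
    phase_after_left = (seg_l.reading_frame + left_ann.retained_coding + n_len) % 3
    entry_offset_right = seg_r.length - right_ann.retained_coding
    phase_right = (seg_r.reading_frame + entry_offset_right) % 3
    if phase_after_left != phase_right:
        return "out-of-frame", "unproductive", "frame"
    if not (seg_l.functional and seg_r.functional):
        return "in-frame", "unproductive", "pseudogene"
    if min(left_ann.coding_fraction, right_ann.coding_fraction) < min_coding_fraction:
        return "in-frame", "unproductive", "truncation"
    return "in-frame", "productive", None


# ---------------------------------------------------------------------------
# full junction annotation
# ---------------------------------------------------------------------------


@dataclass
class JunctionAnnotation:
    junction_id: str
    left: SideAnnotation
    right: SideAnnotation
    joint_type: str
    n_region: str
    microhomology: int
    twelve_23: str
    frame_status: str
    productivity: str
    productivity_reason: str | None
    category: str
    lineage_flag: str  # 'appropriate' | 'inappropriate' | 'not-assessed'
    order_flag: str  # 'canonical' | 'order-violating' | 'not-applicable'

    @property
    def n_len(self) -> int:
        return len(self.n_region)


def _partner_types(left_ann, right_ann, model) -> tuple[str | None, str | None]:
    def t(ann):
        return model.segment(ann.segment).seg_type if ann.segment else None

    return t(left_ann), t(right_ann)


def categorize_junction(
    left_ann: SideAnnotation, right_ann: SideAnnotation, model: LocusModel
) -> str:
    tl, tr = _partner_types(left_ann, right_ann, model)
    if left_ann.side.chrom != right_ann.side.chrom or None in (tl, tr):
        return "translocation"
    pair = frozenset((tl, tr)) if tl != tr else frozenset((tl,))
    return {
        frozenset(("V", "J")): "V-J",
        frozenset(("D", "J")): "D-J",
        frozenset(("V", "D")): "V-D",
        frozenset(("V",)): "V-V",
        frozenset(("D",)): "D-D",
        frozenset(("J",)): "J-J",
    }.get(pair, "other")


def categorize_event(
    annotations: list["JunctionAnnotation"], model: LocusModel, sample_lineage: str | None
) -> None:
    """Event-level adjustments applied across a sample's junction set.

    Promotes a V-D junction to V-D-J when the same D's other flank
    carries a D-J junction (the two-step assembly), flags lineage
    inappropriateness from the sample lineage, and marks V-J events as
    order-violating when the locus contains D segments and the J's own
    RSS is observed retained in a signal or hybrid joint -- proof that
    no D-J joining preceded V incorporation.
    """
    dj_partners: set[str] = set()
    for ann in annotations:
        if ann.category == "D-J":
            for side in (ann.left, ann.right):
                if side.segment and model.segment(side.segment).seg_type == "D":
                    dj_partners.add(side.segment)
    for ann in annotations:
        if ann.category == "V-D":
            for side in (ann.left, ann.right):
                if side.segment and side.segment in dj_partners:
                    ann.category = "V-D-J"
        for side in (ann.left, ann.right):
            if not side.segment:
                continue
            seg = model.segment(side.segment)
            lin = locus_lineage(seg.locus)
            if sample_lineage is None or lin is None:
                continue
            if lin != sample_lineage:
                ann.lineage_flag = "inappropriate"
        if ann.lineage_flag == "not-assessed" and sample_lineage is not None:
            if any(s.segment for s in (ann.left, ann.right)):
                ann.lineage_flag = "appropriate"
        if ann.category == "V-J":
            loci = {
                model.segment(s.segment).locus
                for s in (ann.left, ann.right)
                if s.segment
            }
            has_d = any(seg.seg_type == "D" and seg.locus in loci for seg in model.segments)
            j_rss_retained = any(
                s.kind == "signal" and model.segment(s.segment).seg_type == "J"
                for s in (ann.left, ann.right)
                if s.segment
            )
            if has_d and j_rss_retained:
                ann.order_flag = "order-violating"


def annotate_junction(
    call: JunctionCall,
    model: LocusModel,
    sample_lineage: str | None = None,
    min_coding_fraction: float = 0.5,
    cryptic_window: int = 50,
) -> JunctionAnnotation:
    """Annotate one junction call (base-pair calls get the full workup).

    Interval-resolution calls receive provisional typing only: sides
    are classified from interval midpoints and no frame call is made.
    """
    left_ann = classify_side(call.left, "left", model, cryptic_window)
    right_ann = classify_side(call.right, "right", model, cryptic_window)
    joint = classify_joint(left_ann, right_ann)
    rss_l = left_ann.rss if left_ann.rss_used == "segment RSS" else None
    rss_r = right_ann.rss if right_ann.rss_used == "segment RSS" else None
    twelve = check_12_23(rss_l, rss_r)
    if call.resolution == "base-pair" and joint == "coding":
        frame, prod, reason = call_productivity(
            left_ann, right_ann, len(call.n_seq), model, min_coding_fraction
        )
    else:
        frame, prod, reason = "not-applicable", "not-applicable", None
    category = categorize_junction(left_ann, right_ann, model)
    return JunctionAnnotation(
        junction_id=call.call_id,
        left=left_ann,
        right=right_ann,
        joint_type=joint,
        n_region=call.n_seq,
        microhomology=call.micro,
        twelve_23=twelve,
        frame_status=frame,
        productivity=prod,
        productivity_reason=reason,
        category=category,
        lineage_flag="not-assessed",
        order_flag="canonical" if category != "translocation" else "not-applicable",
    )


def annotate_calls(
    calls: list[JunctionCall],
    model: LocusModel,
    sample_lineage: str | None = None,
    min_coding_fraction: float = 0.5,
) -> list[JunctionAnnotation]:
    anns = [
        annotate_junction(c, model, sample_lineage, min_coding_fraction) for c in calls
    ]
    categorize_event(anns, model, sample_lineage)
    return anns


# ---------------------------------------------------------------------------
# reciprocal translocation bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class ChromLoss:
    breakpoints: tuple[int, int]  # (end of left-retained, start of right-retained)
    lost: int
    lost_interval: tuple[int, int] | None
    shared: int  # bases retained on both derivatives (imperfect reciprocity)


@dataclass
class DerivativeLedger:
    """Per-parent-chromosome accounting for a reciprocal translocation."""

    per_chrom: dict[str, ChromLoss]
    inserted: int
    parent_total: int
    expected_derivative_total: int

    @property
    def lost_total(self) -> int:
        return sum(c.lost for c in self.per_chrom.values())

    @property
    def shared_total(self) -> int:
        return sum(c.shared for c in self.per_chrom.values())

    def conserves(self, derivative_lengths: list[int]) -> bool:
        """Check sum(derivatives) = sum(parents) - lost + inserted + shared."""
        return sum(derivative_lengths) == self.expected_derivative_total


def ledger_reciprocal(
    call_a: JunctionCall, call_b: JunctionCall, model: LocusModel
) -> DerivativeLedger:
    """Account for sequence lost and gained across a reciprocal pair.

    For each parent chromosome, one derivative retains sequence to the
    left of its breakpoint and the other retains sequence to the right;
    the interval in between (if any) is present on neither derivative
    and reported lost.  The conservation identity
    ``sum(derivatives) = sum(parents) - lost + inserted + shared``
    is emitted with the ledger.
    """
    sides: dict[str, list[tuple[int, str]]] = {}
    for call in (call_a, call_b):
        for side, role in ((call.left, "left"), (call.right, "right")):
            sides.setdefault(side.chrom, []).append(
                (side.pos, _retained_direction(role, side.orient))
            )
    per_chrom: dict[str, ChromLoss] = {}
    for chrom, entries in sorted(sides.items()):
        if len(entries) != 2:
            raise PairingError(f"chromosome {chrom} appears {len(entries)} time(s)")
        dirs = {d for _, d in entries}
        if dirs != {"left", "right"}:
            raise PairingError(
                f"junctions are not reciprocal on {chrom}: retained sides {dirs}"
            )
        p_left = next(p for p, d in entries if d == "left")
        p_right = next(p for p, d in entries if d == "right")
        lost = max(0, p_right - p_left)
        shared = max(0, p_left - p_right)
        per_chrom[chrom] = ChromLoss(
            breakpoints=(p_left, p_right),
            lost=lost,
            lost_interval=(p_left, p_right) if lost else None,
            shared=shared,
        )
    inserted = len(call_a.n_seq) + len(call_b.n_seq)
    parent_total = sum(len(model.sequences[c]) for c in per_chrom)
    expected = parent_total - sum(c.lost - c.shared for c in per_chrom.values()) + inserted
    return DerivativeLedger(per_chrom, inserted, parent_total, expected)


# ---------------------------------------------------------------------------
# sample-level summaries
# ---------------------------------------------------------------------------


def summarize_events(annotations: list[JunctionAnnotation], model: LocusModel) -> dict:
    """Table-style per-sample tallies: category counts and J usage."""
    categories: dict[str, int] = {}
    j_usage: dict[str, int] = {}
    seen_events: set[frozenset] = set()
    for ann in annotations:
        partners = frozenset(
            s.segment for s in (ann.left, ann.right) if s.segment
        ) or frozenset({ann.junction_id})
        key = partners | {ann.category}
        if key in seen_events:
            continue  # two junctions of one event (e.g. inversion) count once
        seen_events.add(key)
        categories[ann.category] = categories.get(ann.category, 0) + 1
        for s in (ann.left, ann.right):
            if s.segment and model.segment(s.segment).seg_type == "J":
                j_usage[s.segment] = j_usage.get(s.segment, 0) + 1
    return {"categories": categories, "j_usage": j_usage}
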