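"""Simulation of V(D)J recombinase products and capture sequencing.

Derivative chromosomes are represented as *piece lists* over the parent
(germline) model: each piece is either a reference slice
``("ref", chrom, start, end, strand)`` or an untemplated insertion
``("ins", seq)``.  Every recombination operation returns the derivative
contig plus a :class:`RearrangementTruth` recording the exact junction
structure, so downstream detection and annotation can be scored against
ground truth.

Junction convention
-------------------
A junction is an ordered pair of sides plus an untemplated (N-region)
insert.  The *left* side ``(chrom, pos, orient)`` contributes the flank
entering the junction: ``+`` means reference bases ``[.., pos)`` read
forward, ``-`` means ``revcomp(reference[pos, ..])``.  The *right* side
contributes the flank leaving the junction: ``+`` means
``reference[pos, ..)`` forward, ``-`` means ``revcomp(reference[.., pos))``.
Junctions are canonicalized (lower-coordinate side first) and then
left-shifted through any junctional microhomology, so that a breakpoint
is a single well-defined base pair; simulator truth and detector output
share this normal form.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import asdict, dataclass, field

import numpy as np

from ._util import merge_intervals, random_dna, revcomp
from .locus import ConfigError, LocusModel, RSSMotif, BaitSet

_COMP = str.maketrans("ACGTN", "TGCAN")

Piece = tuple


@dataclass(frozen=True)
class JunctionSide:
    chrom: str
    pos: int
    orient: str  # '+' or '-'


@dataclass
class JunctionTruth:
    """One two-sided junction carried by a derivative contig."""

    left: JunctionSide
    right: JunctionSide
    n_seq: str
    kind: str  # 'coding' | 'signal' | 'hybrid' | 'non-RSS'
    micro: int = 0
    contig: str = ""
    offset: int = -1  # position of the junction seam (N start) in the contig


@dataclass
class RearrangementTruth:
    """Simulator record of one recombination event."""

    event_id: str
    category: str  # 'V-D-J' | 'V-J' | 'D-J' | 'V-D' | 'V-V' | 'translocation'
    mechanism: str  # 'deletion' | 'inversion' | 'interchromosomal'
    partners: list[str]
    junctions: list[JunctionTruth]
    trims: list[int] = field(default_factory=list)
    n_lengths: list[int] = field(default_factory=list)
    lineage_appropriate: bool = True
    derivative_names: list[str] = field(default_factory=list)
    deleted_bases: int = 0
    inserted_bases: int = 0
    lost_per_chrom: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class Contig:
    """A (derivative) contig assembled from reference slices and inserts."""

    name: str
    pieces: list[Piece]

    def length(self, sequences: dict[str, str]) -> int:
        n = 0
        for p in self.pieces:
            n += len(p[1]) if p[0] == "ins" else p[3] - p[2]
        return n

    def sequence(self, sequences: dict[str, str]) -> str:
        parts = []
        for p in self.pieces:
            if p[0] == "ins":
                parts.append(p[1])
            else:
                _, chrom, s, e, strand = p
                sl = sequences[chrom][s:e]
                parts.append(sl if strand == "+" else revcomp(sl))
        return "".join(parts)

    def lift_baits(self, baits: BaitSet) -> list[tuple[int, int]]:
        """Project bait intervals from parent coordinates onto this contig."""
        out: list[tuple[int, int]] = []
        offset = 0
        for p in self.pieces:
            if p[0] == "ins":
                offset += len(p[1])
                continue
            _, chrom, s, e, strand = p
            for bs, be in baits.baits_on(chrom):
                lo, hi = max(bs, s), min(be, e)
                if lo >= hi:
                    continue
                if strand == "+":
                    out.append((offset + lo - s, offset + hi - s))
                else:
                    out.append((offset + e - hi, offset + e - lo))
            offset += e - s
        return merge_intervals(out)


def germline_contig(chrom: str, sequences: dict[str, str]) -> Contig:
    return Contig(chrom, [("ref", chrom, 0, len(sequences[chrom]), "+")])


# ---------------------------------------------------------------------------
# junction normalization
# ---------------------------------------------------------------------------


def _comp(base: str) -> str:
    return base.translate(_COMP)


def _left_last(seqs, s: JunctionSide) -> str:
    g = seqs[s.chrom]
    return g[s.pos - 1] if s.orient == "+" else _comp(g[s.pos])


def _left_ext(seqs, s: JunctionSide) -> str:
    """Reference base that would extend the left flank past the breakpoint."""
    g = seqs[s.chrom]
    return g[s.pos] if s.orient == "+" else _comp(g[s.pos - 1])


def _right_first(seqs, s: JunctionSide) -> str:
    g = seqs[s.chrom]
    return g[s.pos] if s.orient == "+" else _comp(g[s.pos - 1])


def _right_pre(seqs, s: JunctionSide) -> str:
    """Reference base that would precede the right flank before the breakpoint."""
    g = seqs[s.chrom]
    return g[s.pos - 1] if s.orient == "+" else _comp(g[s.pos])


def _shift(s: JunctionSide, delta: int) -> JunctionSide:
    """Move the breakpoint by ``delta`` bases in derivative reading direction."""
    return JunctionSide(s.chrom, s.pos + (delta if s.orient == "+" else -delta), s.orient)


def _in_bounds(seqs, s: JunctionSide) -> bool:
    return 1 <= s.pos <= len(seqs[s.chrom]) - 1


def flip_junction(left: JunctionSide, right: JunctionSide, n_seq: str):
    """The same junction read from the opposite strand of the derivative."""
    fl = {"+": "-", "-": "+"}
    return (
        JunctionSide(right.chrom, right.pos, fl[right.orient]),
        JunctionSide(left.chrom, left.pos, fl[left.orient]),
        revcomp(n_seq),
    )


def canonical_junction(left: JunctionSide, right: JunctionSide, n_seq: str):
    """Orient the junction so the lower-coordinate side comes first."""
    if (left.chrom, left.pos) > (right.chrom, right.pos):
        return flip_junction(left, right, n_seq)
    return left, right, n_seq


def normalize_junction(
    sequences: dict[str, str],
    left: JunctionSide,
    right: JunctionSide,
    n_seq: str,
    max_shift: int = 200,
):
    """Canonicalize and left-shift a junction to its normal form.

    Untemplated bases that coincide with the flank continuation are
    absorbed into the flanks (they are indistinguishable from templated
    sequence); with no insert remaining, the seam is slid through any
    microhomology to the leftmost equivalent position.  Returns
    ``(left, right, n_seq, micro)``.
    """
    left, right, n_seq = canonical_junction(left, right, n_seq)
    # absorb N bases indistinguishable from left-flank continuation
    while n_seq and _in_bounds(sequences, left) and n_seq[0] == _left_ext(sequences, left):
        left = _shift(left, +1)
        n_seq = n_seq[1:]
    while n_seq and _in_bounds(sequences, right) and n_seq[-1] == _right_pre(sequences, right):
        right = _shift(right, -1)
        n_seq = n_seq[:-1]
    micro = 0
    if not n_seq:
        # count the full microhomology range, then park at the leftmost end
        shifts_left = 0
        lft, rgt = left, right
        while (
            shifts_left < max_shift
            and _in_bounds(sequences, lft)
            and _in_bounds(sequences, rgt)
            and _left_last(sequences, lft) == _right_pre(sequences, rgt)
        ):
            lft = _shift(lft, -1)
            rgt = _shift(rgt, -1)
            shifts_left += 1
        shifts_right = 0
        l2, r2 = left, right
        while (
            shifts_right < max_shift
            and _in_bounds(sequences, l2)
            and _in_bounds(sequences, r2)
            and _left_ext(sequences, l2) == _right_first(sequences, r2)
        ):
            l2 = _shift(l2, +1)
            r2 = _shift(r2, +1)
            shifts_right += 1
        micro = shifts_left + shifts_right
        left, right = lft, rgt
    return left, right, n_seq, micro


# ---------------------------------------------------------------------------
# N-region model
# ---------------------------------------------------------------------------

#: N-region lengths observed at coding-end junctions: mostly short (2-5 nt)
#: additions, occasional intermediate (8, 11) and rare long (23) ones.
EMPIRICAL_N_LENGTHS = (2, 3, 4, 5, 8, 11, 23)


def draw_n_region(rng: np.random.Generator, length_model="empirical") -> str:
    """Draw an untemplated (TdT) insert.

    ``length_model`` is either an integer (fixed length) or
    ``"empirical"``: uniform over the observed length support
    ``EMPIRICAL_N_LENGTHS``, which puts more mass on short (2-5 nt)
    additions than on longer ones.
    """
    if isinstance(length_model, str):
        if length_model != "empirical":
            raise ValueError(f"unknown N length model: {length_model}")
        length = int(rng.choice(EMPIRICAL_N_LENGTHS))
    else:
        length = int(length_model)
    if length < 0:
        raise ValueError("N-region length must be >= 0")
    return random_dna(rng, length)


def _unambiguous_n(
    rng: np.random.Generator,
    n_seq: str,
    sequences: dict[str, str],
    left: JunctionSide,
    right: JunctionSide,
) -> str:
    """Resample N edge bases that would be absorbed into a flank.

    The decomposition of a junction into flank / N / flank is only
    unique when the first N base differs from the left-flank
    continuation and the last differs from the right-flank lead-in;
    this redraws edge bases until the planted N survives decomposition
    intact.
    """
    if not n_seq:
        return n_seq
    forbid_first = _left_ext(sequences, left)
    forbid_last = _right_pre(sequences, right)
    n = list(n_seq)
    if len(n) == 1:
        choices = [b for b in "ACGT" if b != forbid_first and b != forbid_last]
        if n[0] in (forbid_first, forbid_last):
            n[0] = str(rng.choice(choices))
    else:
        if n[0] == forbid_first:
            n[0] = str(rng.choice([b for b in "ACGT" if b != forbid_first]))
        if n[-1] == forbid_last:
            n[-1] = str(rng.choice([b for b in "ACGT" if b != forbid_last]))
    return "".join(n)


# ---------------------------------------------------------------------------
# recombination operations
# ---------------------------------------------------------------------------


class MechanismError(ValueError):
    """Raised when the requested RSS pair cannot support the mechanism."""


def _check_12_23_classes(a: RSSMotif, b: RSSMotif, force: bool) -> None:
    if {a.spacer_class, b.spacer_class} != {12, 23} and not force:
        raise MechanismError(
            "RSS pair violates the 12/23 rule; pass force_violation=True to simulate it"
        )


def _junction(seqs, left, right, n_seq, kind, contig="", offset=-1) -> JunctionTruth:
    l, r, n, micro = normalize_junction(seqs, left, right, n_seq)
    if offset >= 0 and l.chrom == left.chrom and l.orient == left.orient:
        # keep the contig offset pointing at the normalized seam
        delta = (left.pos - l.pos) if l.orient == "+" else (l.pos - left.pos)
        offset -= delta
    return JunctionTruth(l, r, n, kind, micro, contig, offset)


def recombine_deletion(
    model: LocusModel,
    rss_a: RSSMotif,
    rss_b: RSSMotif,
    trims: tuple[int, int] = (0, 0),
    n_len: int | None = 0,
    rng: np.random.Generator | None = None,
    *,
    partners: tuple[str, str] | None = None,
    category: str = "V-J",
    event_id: str = "del",
    force_violation: bool = False,
    emit_circle: bool = False,
    n_seq: str | None = None,
):
    """Deletional recombination between two facing RSSs on one chromosome.

    The intervening DNA (both RSSs included) is excised; the retained
    chromosome carries the coding joint: left coding end (trimmed) +
    N-region + right coding end (trimmed).  The optional excised circle
    carries the precise RSS-RSS signal joint.
    """
    if rss_a.chrom != rss_b.chrom:
        raise MechanismError("RSSs on different chromosomes: use translocate()")
    if rss_a.start > rss_b.start:
        rss_a, rss_b = rss_b, rss_a
        trims = (trims[1], trims[0])
    if not (rss_a.orientation == "+" and rss_b.orientation == "-") and not force_violation:
        raise MechanismError("deletional recombination requires facing RSS heptamers")
    _check_12_23_classes(rss_a, rss_b, force_violation)
    rng = rng or np.random.default_rng(0)
    chrom = rss_a.chrom
    seqs = model.sequences
    L = len(seqs[chrom])
    cut_a = rss_a.heptamer_edge
    cut_b = rss_b.heptamer_edge
    left_pos = cut_a - trims[0]
    right_pos = cut_b + trims[1]
    if not (0 < left_pos < right_pos < L):
        raise MechanismError("trims exceed available sequence")
    left = JunctionSide(chrom, left_pos, "+")
    right = JunctionSide(chrom, right_pos, "+")
    if n_seq is None:
        n_seq = draw_n_region(rng, n_len if n_len is not None else "empirical")
    n_seq = _unambiguous_n(rng, n_seq, seqs, left, right)
    name = f"{event_id}_der"
    contig = Contig(
        name,
        [("ref", chrom, 0, left_pos, "+"), ("ins", n_seq), ("ref", chrom, right_pos, L, "+")],
    )
    junctions = [_junction(seqs, left, right, n_seq, "coding", name, left_pos)]
    derivs = [contig]
    if emit_circle:
        mid = (cut_a + cut_b) // 2
        circ = Contig(
            f"{event_id}_circle",
            [("ref", chrom, mid, cut_b, "+"), ("ref", chrom, cut_a, mid, "+")],
        )
        junctions.append(
            _junction(
                seqs,
                JunctionSide(chrom, cut_b, "+"),
                JunctionSide(chrom, cut_a, "+"),
                "",
                "signal",
                circ.name,
                cut_b - mid,
            )
        )
        derivs.append(circ)
    truth = RearrangementTruth(
        event_id=event_id,
        category=category,
        mechanism="deletion",
        partners=list(partners or ()),
        junctions=junctions,
        trims=list(trims),
        n_lengths=[len(n_seq)],
        derivative_names=[c.name for c in derivs],
        deleted_bases=right_pos - left_pos,
        inserted_bases=len(n_seq),
    )
    return derivs, truth


def recombine_inversion(
    model: LocusModel,
    rss_a: RSSMotif,
    rss_b: RSSMotif,
    trims: tuple[int, int] = (0, 0),
    n_len: int | None = 0,
    rng: np.random.Generator | None = None,
    *,
    partners: tuple[str, str] | None = None,
    category: str = "V-J",
    event_id: str = "inv",
    force_violation: bool = False,
    n_seq: str | None = None,
):
    """Inversional recombination between two same-orientation RSSs.

    The intervening segment is reverse-complemented in place.  The
    chromosome retains both products: a coding joint (with optional
    N-region) and a precise RSS-RSS signal joint at the other seam.
    """
    if rss_a.chrom != rss_b.chrom:
        raise MechanismError("RSSs on different chromosomes: use translocate()")
    if rss_a.start > rss_b.start:
        rss_a, rss_b = rss_b, rss_a
        trims = (trims[1], trims[0])
    if rss_a.orientation != rss_b.orientation and not force_violation:
        raise MechanismError("inversional recombination requires same-orientation RSSs")
    _check_12_23_classes(rss_a, rss_b, force_violation)
    rng = rng or np.random.default_rng(0)
    chrom = rss_a.chrom
    seqs = model.sequences
    L = len(seqs[chrom])
    cut_a = rss_a.heptamer_edge
    cut_b = rss_b.heptamer_edge
    ta, tb = trims
    name = f"{event_id}_der"
    if rss_a.orientation == "+":
        # coding ends on the outside: coding joint at the left seam,
        # signal joint (head-to-head heptamers) at the right seam
        if n_seq is None:
            n_seq = draw_n_region(rng, n_len if n_len is not None else "empirical")
        cj_left = JunctionSide(chrom, cut_a - ta, "+")
        cj_right = JunctionSide(chrom, cut_b - tb, "-")
        n_seq = _unambiguous_n(rng, n_seq, seqs, cj_left, cj_right)
        pieces = [
            ("ref", chrom, 0, cut_a - ta, "+"),
            ("ins", n_seq),
            ("ref", chrom, cut_a, cut_b - tb, "-"),
            ("ref", chrom, cut_b, L, "+"),
        ]
        junctions = [
            _junction(seqs, cj_left, cj_right, n_seq, "coding", name, cut_a - ta),
            _junction(
                seqs,
                JunctionSide(chrom, cut_a, "-"),
                JunctionSide(chrom, cut_b, "+"),
                "",
                "signal",
                name,
                (cut_a - ta) + len(n_seq) + (cut_b - tb - cut_a),
            ),
        ]
    else:
        # '-'/'-' pair: signal joint at the left seam, coding joint right
        if n_seq is None:
            n_seq = draw_n_region(rng, n_len if n_len is not None else "empirical")
        cj_left = JunctionSide(chrom, cut_a + ta, "-")
        cj_right = JunctionSide(chrom, cut_b + tb, "+")
        n_seq = _unambiguous_n(rng, n_seq, seqs, cj_left, cj_right)
        pieces = [
            ("ref", chrom, 0, cut_a, "+"),
            ("ref", chrom, cut_a + ta, cut_b, "-"),
            ("ins", n_seq),
            ("ref", chrom, cut_b + tb, L, "+"),
        ]
        junctions = [
            _junction(
                seqs,
                JunctionSide(chrom, cut_a, "+"),
                JunctionSide(chrom, cut_b, "-"),
                "",
                "signal",
                name,
                cut_a,
            ),
            _junction(
                seqs, cj_left, cj_right, n_seq, "coding", name, cut_a + (cut_b - cut_a - ta)
            ),
        ]
    contig = Contig(name, pieces)
    truth = RearrangementTruth(
        event_id=event_id,
        category=category,
        mechanism="inversion",
        partners=list(partners or ()),
        junctions=junctions,
        trims=list(trims),
        n_lengths=[len(n_seq), 0],
        derivative_names=[name],
        deleted_bases=ta + tb,
        inserted_bases=len(n_seq),
    )
    return [contig], truth


def recombine_v_replacement(
    model: LocusModel,
    invading_v: str,
    replaced_v: str,
    cryptic_offset: int,
    retained_stub_len: int = 0,
    n_len: int | None = "empirical",
    rng: np.random.Generator | None = None,
    *,
    event_id: str = "vv",
    n_seq: str | None = None,
):
    """V-to-V interstitial deletion via a cryptic heptamer.

    The invading V's RSS pairs with an oppositely oriented, CAC-rooted
    cryptic heptamer inside the replaced V's coding sequence.  The
    retained chromosome keeps the invading V *with its RSS* (a signal
    end) fused -- optionally across a short retained stub of the removed
    coding sequence and an N-region -- to the replaced V at the cryptic
    heptamer.
    """
    rng = rng or np.random.default_rng(0)
    inv = model.segment(invading_v)
    rep = model.segment(replaced_v)
    if inv.chrom != rep.chrom:
        raise MechanismError("V segments must share a chromosome")
    rss = inv.rss_3prime or inv.rss_5prime
    chrom = inv.chrom
    seqs = model.sequences
    g = seqs[chrom]
    c = rep.start + cryptic_offset
    if not (rep.start <= c <= rep.end - 7):
        raise ConfigError("cryptic offset outside replaced V coding interval")
    window = g[c : c + 7]
    cryptic = revcomp(window)  # oppositely oriented to the invading '+' RSS
    from ._util import count_mismatches
    from .locus import HEPTAMER_CONSENSUS

    if cryptic[:3] != "CAC" or count_mismatches(cryptic[3:], HEPTAMER_CONSENSUS[3:]) > 1:
        raise ConfigError(f"no CAC-rooted cryptic heptamer at offset {cryptic_offset}")
    L = len(g)
    left_pos = rss.end  # retain the full invading RSS: a signal end
    right_pos = c - retained_stub_len
    if right_pos <= left_pos:
        raise MechanismError("cryptic heptamer must lie beyond the invading RSS")
    if n_seq is None or n_seq == "":
        n_seq = "" if n_seq == "" else draw_n_region(rng, n_len)
    left = JunctionSide(chrom, left_pos, "+")
    right = JunctionSide(chrom, right_pos, "+")
    n_seq = _unambiguous_n(rng, n_seq, seqs, left, right)
    name = f"{event_id}_der"
    contig = Contig(
        name,
        [("ref", chrom, 0, left_pos, "+"), ("ins", n_seq), ("ref", chrom, right_pos, L, "+")],
    )
    truth = RearrangementTruth(
        event_id=event_id,
        category="V-V",
        mechanism="deletion",
        partners=[invading_v, replaced_v],
        junctions=[_junction(seqs, left, right, n_seq, "hybrid", name, left_pos)],
        trims=[0, retained_stub_len],
        n_lengths=[len(n_seq)],
        derivative_names=[name],
        deleted_bases=right_pos - left_pos,
        inserted_bases=len(n_seq),
    )
    return [contig], truth


def recombine_vdj_two_step(
    model: LocusModel,
    v_id: str,
    d_id: str,
    j_id: str,
    trims: tuple[int, int, int, int] = (0, 0, 0, 0),
    n_lens: tuple[int, int] = (3, 3),
    rng: np.random.Generator | None = None,
    *,
    event_id: str = "vdj",
):
    """Full V-D-J assembly: a D-J deletion followed by V-to-DJ joining.

    Both steps are deletional (V, D and J in standard facing layout);
    the product carries two coding joints, V-D and D-J, each with its
    own trims and N-region.  Trims are ``(v_3prime, d_5prime, d_3prime,
    j_5prime)``.
    """
    rng = rng or np.random.default_rng(0)
    v, d, j = model.segment(v_id), model.segment(d_id), model.segment(j_id)
    if not (v.chrom == d.chrom == j.chrom):
        raise MechanismError("V, D and J must share a chromosome")
    seqs = model.sequences
    chrom = v.chrom
    L = len(seqs[chrom])
    v_cut = v.rss_3prime.heptamer_edge - trims[0]
    d5_cut = d.rss_5prime.heptamer_edge + trims[1]
    d3_cut = d.rss_3prime.heptamer_edge - trims[2]
    j_cut = j.rss_5prime.heptamer_edge + trims[3]
    if not (0 < v_cut < d5_cut < d3_cut < j_cut < L):
        raise MechanismError("segments not in V < D < J facing layout")
    vd_left = JunctionSide(chrom, v_cut, "+")
    vd_right = JunctionSide(chrom, d5_cut, "+")
    dj_left = JunctionSide(chrom, d3_cut, "+")
    dj_right = JunctionSide(chrom, j_cut, "+")
    n1 = _unambiguous_n(rng, draw_n_region(rng, n_lens[0]), seqs, vd_left, vd_right)
    n2 = _unambiguous_n(rng, draw_n_region(rng, n_lens[1]), seqs, dj_left, dj_right)
    name = f"{event_id}_der"
    contig = Contig(
        name,
        [
            ("ref", chrom, 0, v_cut, "+"),
            ("ins", n1),
            ("ref", chrom, d5_cut, d3_cut, "+"),
            ("ins", n2),
            ("ref", chrom, j_cut, L, "+"),
        ],
    )
    junctions = [
        _junction(seqs, vd_left, vd_right, n1, "coding", name, v_cut),
        _junction(seqs, dj_left, dj_right, n2, "coding", name, v_cut + len(n1) + (d3_cut - d5_cut)),
    ]
    truth = RearrangementTruth(
        event_id=event_id,
        category="V-D-J",
        mechanism="deletion",
        partners=[v_id, d_id, j_id],
        junctions=junctions,
        trims=list(trims),
        n_lengths=[len(n1), len(n2)],
        derivative_names=[name],
        deleted_bases=(d5_cut - v_cut) + (j_cut - d3_cut),
        inserted_bases=len(n1) + len(n2),
    )
    return [contig], truth


def translocate(
    model: LocusModel,
    chrom_a: str,
    chrom_b: str,
    bp_a1: int,
    bp_a2: int,
    bp_b1: int,
    bp_b2: int,
    n_seqs: tuple[str, str] = ("", ""),
    rng: np.random.Generator | None = None,
    *,
    event_id: str = "tx",
):
    """Reciprocal translocation with (possibly unequal) per-derivative loss.

    ``der(A) = A[0, bp_a1) + N1 + B[bp_b1, ..)`` and
    ``der(B) = B[0, bp_b2) + N2 + A[bp_a2, ..)``.  When ``bp_a2 > bp_a1``
    the interval between them is present on neither derivative (lost
    from chromosome A), and likewise ``bp_b1 > bp_b2`` for B.
    """
    rng = rng or np.random.default_rng(0)
    seqs = model.sequences
    la, lb = len(seqs[chrom_a]), len(seqs[chrom_b])
    for bp, lim in ((bp_a1, la), (bp_a2, la), (bp_b1, lb), (bp_b2, lb)):
        if not 0 <= bp <= lim:
            raise ValueError("translocation breakpoint out of chromosome bounds")
    n1 = _unambiguous_n(
        rng, n_seqs[0], seqs, JunctionSide(chrom_a, bp_a1, "+"), JunctionSide(chrom_b, bp_b1, "+")
    )
    n2 = _unambiguous_n(
        rng, n_seqs[1], seqs, JunctionSide(chrom_b, bp_b2, "+"), JunctionSide(chrom_a, bp_a2, "+")
    )
    der_a = Contig(
        f"{event_id}_derA",
        [("ref", chrom_a, 0, bp_a1, "+"), ("ins", n1), ("ref", chrom_b, bp_b1, lb, "+")],
    )
    der_b = Contig(
        f"{event_id}_derB",
        [("ref", chrom_b, 0, bp_b2, "+"), ("ins", n2), ("ref", chrom_a, bp_a2, la, "+")],
    )
    junctions = [
        _junction(
            seqs,
            JunctionSide(chrom_a, bp_a1, "+"),
            JunctionSide(chrom_b, bp_b1, "+"),
            n1,
            "non-RSS",
            der_a.name,
            bp_a1,
        ),
        _junction(
            seqs,
            JunctionSide(chrom_b, bp_b2, "+"),
            JunctionSide(chrom_a, bp_a2, "+"),
            n2,
            "non-RSS",
            der_b.name,
            bp_b2,
        ),
    ]
    lost = {chrom_a: max(0, bp_a2 - bp_a1), chrom_b: max(0, bp_b1 - bp_b2)}
    truth = RearrangementTruth(
        event_id=event_id,
        category="translocation",
        mechanism="interchromosomal",
        partners=[chrom_a, chrom_b],
        junctions=junctions,
        n_lengths=[len(n1), len(n2)],
        derivative_names=[der_a.name, der_b.name],
        deleted_bases=sum(lost.values()),
        inserted_bases=len(n1) + len(n2),
        lost_per_chrom=lost,
    )
    return [der_a, der_b], truth


# ---------------------------------------------------------------------------
# capture + paired-end read simulation
# ---------------------------------------------------------------------------


@dataclass
class CaptureConfig:
    """Hybrid-capture and sequencing parameters.

    Defaults emulate a targeted library: 100 bp paired-end reads with a
    median insert of 254 nt, ~50% of retained fragments on target, and a
    low uniform substitution error rate.  ``fragment_len`` records the
    median sonication fragment size; read-pair geometry is driven by the
    sequenced-insert distribution (log-normal around ``insert_median``).
    """

    read_len: int = 100
    insert_median: int = 254
    insert_sigma: float = 0.10
    fragment_len: int = 500
    coverage: float = 50.0
    on_target_fraction: float = 0.5
    p_on: float = 0.95
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.on_target_fraction <= 1 or not 0 <= self.p_on <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if min(self.read_len, self.insert_median, self.fragment_len) <= 0:
            raise ValueError("lengths must be positive")
        if self.read_len > self.insert_median:
            raise ValueError("read_len must not exceed insert_median")


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def simulate_capture_and_reads(
    contigs: list[Contig],
    model: LocusModel,
    baits: BaitSet,
    cfg: CaptureConfig,
):
    """Draw captured fragments and emit paired-end reads with truth map.

    Fragments are sampled uniformly along all contigs with log-normal
    insert lengths; a fragment is retained with probability ``p_on`` if
    it overlaps a (lifted) bait interval, else with an off-target
    probability calibrated so the realized on-target fraction
    approximates ``cfg.on_target_fraction``.  The number of fragments is
    chosen so retained on-target pairs give ``cfg.coverage`` fold
    coverage over bait-covered bases.  Returns
    ``(pairs, truth_map, stats)`` where ``truth_map[name]`` records the
    source contig, fragment interval and R1 strand.
    """
    rng = np.random.default_rng(cfg.seed)
    seqs = model.sequences
    contig_seqs = {c.name: c.sequence(seqs) for c in contigs}
    bait_map = {c.name: c.lift_baits(baits) for c in contigs}
    lengths = {c.name: len(contig_seqs[c.name]) for c in contigs}
    total_len = sum(lengths.values())
    target_len = sum(e - s for iv in bait_map.values() for s, e in iv)
    if cfg.coverage <= 0 or total_len == 0:
        return [], {}, {"on_target_fraction": 0.0, "n_pairs": 0}
    desired_on = max(1, int(round(cfg.coverage * target_len / (2 * cfg.read_len))))
    f_med = cfg.insert_median
    p_overlap = min(
        0.999,
        sum(min(e - s + f_med, lengths[n]) for n, iv in bait_map.items() for s, e in iv)
        / total_len,
    )
    if target_len == 0:
        return [], {}, {"on_target_fraction": 0.0, "n_pairs": 0}
    n_attempts = int(np.ceil(desired_on / (p_overlap * cfg.p_on)))
    f = cfg.on_target_fraction
    if f >= 1.0:
        p_off = 0.0
    else:
        p_off = cfg.p_on * p_overlap * (1 - f) / max(1e-12, (1 - p_overlap) * f)
        p_off = min(1.0, p_off)
    names = sorted(lengths)
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    mu = np.log(cfg.insert_median)
    pairs: list[ReadPair] = []
    truth_map: dict[str, dict] = {}
    n_on = 0
    bait_starts = {n: [s for s, _ in iv] for n, iv in bait_map.items()}
    cidx = rng.choice(len(names), size=n_attempts, p=weights)
    flens = np.round(np.exp(rng.normal(mu, cfg.insert_sigma, size=n_attempts))).astype(int)
    u_start = rng.random(n_attempts)
    u_keep = rng.random(n_attempts)
    flips = rng.random(n_attempts) < 0.5
    for i in range(n_attempts):
        cname = names[cidx[i]]
        clen = lengths[cname]
        flen = max(cfg.read_len, min(int(flens[i]), clen))
        start = int(u_start[i] * (clen - flen + 1))
        end = start + flen
        iv = bait_map[cname]
        on = False
        if iv:
            j = bisect_left(bait_starts[cname], end)
            if j > 0 and iv[j - 1][1] > start:
                on = True
            elif j < len(iv) and iv[j][0] < end:
                on = True
        keep_p = cfg.p_on if on else p_off
        if u_keep[i] >= keep_p:
            continue
        frag = contig_seqs[cname][start:end]
        flip = bool(flips[i])
        fwd = frag if not flip else revcomp(frag)
        r1 = _add_errors(fwd[: cfg.read_len], rng, cfg.error_rate)
        r2 = _add_errors(revcomp(fwd)[: cfg.read_len], rng, cfg.error_rate)
        name = f"rd{len(pairs):06d}"
        pairs.append(ReadPair(name, r1, r2))
        truth_map[name] = {
            "contig": cname,
            "start": start,
            "end": end,
            "r1_strand": "-" if flip else "+",
        }
        if on:
            n_on += 1
    stats = {
        "on_target_fraction": n_on / len(pairs) if pairs else 0.0,
        "n_pairs": len(pairs),
        "n_on_target": n_on,
    }
    return pairs, truth_map, stats
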