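"""Junction discovery from paired-end reads.

The detector mirrors the classic capture-seq workflow: align reads to
the (germline) reference, find clusters of discordant pairs whose
geometry implies a rearrangement, then split junction-spanning reads
and remap the halves to pin each breakpoint to a single base.  The
built-in aligner (k-mer seeding plus banded edit-distance verification)
is intended for desk-scale synthetic genomes; pre-aligned SAM from any
production aligner can be ingested instead.

Breakpoints are reported in the canonical junction frame defined in
:mod:`vdjcapture.simulate` (lower-coordinate side first, seam
left-shifted through microhomology), so calls are directly comparable
to simulator truth.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._util import revcomp
from .locus import LocusModel
from .simulate import JunctionSide, ReadPair, normalize_junction


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int
    end: int
    strand: str
    nm: int


@dataclass
class AlignmentRecord:
    """One read's alignment state: best placements, or unaligned."""

    name: str
    mate: int  # 1 or 2
    seq: str
    placements: list[Placement] = field(default_factory=list)

    @property
    def aligned(self) -> bool:
        return bool(self.placements)

    @property
    def primary(self) -> Placement:
        return self.placements[0]

    @property
    def multi(self) -> bool:
        if len(self.placements) < 2:
            return False
        return self.placements[1].nm == self.placements[0].nm


@dataclass
class InsertStats:
    median: float
    sigma: float

    @property
    def window(self) -> int:
        return int(self.median + 3 * self.sigma)


@dataclass
class CandidateEvent:
    """A cluster of discordant pairs implying one junction."""

    orientation_class: str  # 'deletion-like' | 'inversion-like' | 'interchromosomal'
    chrom_a: str
    interval_a: tuple[int, int]
    orient_a: str
    chrom_b: str
    interval_b: tuple[int, int]
    orient_b: str
    pair_names: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_names)


@dataclass
class JunctionCall:
    """A detected junction, at base-pair or interval resolution."""

    call_id: str
    orientation_class: str
    left: JunctionSide
    right: JunctionSide
    resolution: str  # 'base-pair' | 'interval'
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    n_pairs: int
    n_splits: int = 0
    n_seq: str = ""
    micro: int = 0
    consensus: str = ""
    consensus_offset: int = -1
    ambiguity: str = "unique"  # 'unique' | 'resolved' | 'unresolved'
    conflict: bool = False
    split_read_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


class ReadAligner:
    """Exhaustive-enough aligner for small synthetic references.

    Seeds reads with non-overlapping k-mers against a full-genome k-mer
    index, verifies each candidate diagonal with a banded edit-distance
    alignment, and reports *all* placements within ``alt_margin`` edits
    of the best (ties flagged as multi-mappings).  Reads whose best
    placement exceeds ``max_edits`` are unaligned -- on a rearranged
    template these are exactly the junction-spanning reads.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        k: int = 21,
        max_edits: int = 5,
        alt_margin: int = 3,
        max_placements: int = 8,
    ) -> None:
        self.sequences = sequences
        self.k = k
        self.max_edits = max_edits
        self.alt_margin = alt_margin
        self.max_placements = max_placements
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(sequences):
            seq = sequences[chrom]
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((chrom, i))

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        k = self.k
        offs = list(range(0, max(1, len(seq) - k + 1), k))
        if len(seq) >= k and offs[-1] != len(seq) - k:
            offs.append(len(seq) - k)
        cands: set[tuple[str, int]] = set()
        for off in offs:
            for chrom, pos in self._index.get(seq[off : off + k], ()):
                cands.add((chrom, pos - off))
        return cands

    def align(self, seq: str) -> list[Placement]:
        hits: list[Placement] = []
        budget = self.max_edits + self.alt_margin
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            diags: dict[tuple[str, int], int] = {}
            for chrom, diag in self._candidates(s):
                diags[(chrom, diag // 16 * 16)] = 1
                diags[(chrom, (diag // 16 + 1) * 16)] = 1
            for chrom, diag in diags:
                ws = max(0, diag - 12)
                we = min(len(self.sequences[chrom]), diag + len(s) + 28)
                res = edlib.align(s, self.sequences[chrom][ws:we], mode="HW", task="locations", k=budget)
                if res["editDistance"] < 0:
                    continue
                for loc in res["locations"][:2]:
                    start = ws + loc[0]
                    # substitution-dominated libraries: fix the footprint to
                    # the query length so placements are SAM-round-trippable
                    hits.append(
                        Placement(chrom, start, start + len(s), strand, res["editDistance"])
                    )
        if not hits:
            return []
        best = min(h.nm for h in hits)
        if best > self.max_edits:
            return []
        # deduplicate near-identical placements, keep best per site
        bysite: dict[tuple[str, str, int], Placement] = {}
        for h in sorted(hits, key=lambda h: (h.nm, h.chrom, h.start)):
            key = (h.chrom, h.strand, h.start // 8)
            if key not in bysite:
                bysite[key] = h
        final = sorted(
            (h for h in bysite.values() if h.nm <= best + self.alt_margin),
            key=lambda h: (h.nm, h.chrom, h.start, h.strand),
        )
        return final[: self.max_placements]


def align_reads(pairs: list[ReadPair], aligner: ReadAligner) -> list[AlignmentRecord]:
    """Align both mates of every pair; deterministic in read-name order."""
    records: list[AlignmentRecord] = []
    for pair in sorted(pairs, key=lambda p: p.name):
        records.append(AlignmentRecord(pair.name, 1, pair.seq1, aligner.align(pair.seq1)))
        records.append(AlignmentRecord(pair.name, 2, pair.seq2, aligner.align(pair.seq2)))
    return records


def align_or_ingest(
    model: LocusModel | None = None,
    pairs: list[ReadPair] | None = None,
    sam_path=None,
    **aligner_kw,
) -> list[AlignmentRecord]:
    """Produce alignment records from paired reads or a SAM file.

    With ``pairs`` + ``model`` the built-in aligner is used; with
    ``sam_path`` the (externally produced) SAM is ingested as-is.
    """
    if sam_path is not None:
        from .io import read_sam

        return read_sam(sam_path)
    if pairs is None or model is None:
        raise ValueError("provide pairs + model, or sam_path")
    return align_reads(pairs, ReadAligner(model.sequences, **aligner_kw))


def pair_records(records: list[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    by_name: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_name[rec.name].append(rec)
    return by_name


# ---------------------------------------------------------------------------
# discordant-pair clustering
# ---------------------------------------------------------------------------


def estimate_insert_stats(records: list[AlignmentRecord]) -> InsertStats:
    """Median and robust dispersion of the insert from concordant pairs."""
    inserts = []
    for name, recs in sorted(pair_records(records).items()):
        if len(recs) != 2 or not all(r.aligned and not r.multi for r in recs):
            continue
        p1, p2 = recs[0].primary, recs[1].primary
        if p1.chrom != p2.chrom or p1.strand == p2.strand:
            continue
        fwd, rev = (p1, p2) if p1.strand == "+" else (p2, p1)
        if fwd.start > rev.start:
            continue
        ins = rev.end - fwd.start
        if 0 < ins < 100000:
            inserts.append(ins)
    if len(inserts) < 20:
        raise ValueError(
            "too few concordant pairs to estimate insert distribution; supply InsertStats"
        )
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    sigma = float(1.4826 * np.median(np.abs(arr - med))) or 1.0
    return InsertStats(med, sigma)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _classify_pair(p1: Placement, p2: Placement, stats: InsertStats):
    """Return (class, sideA placement, sideB placement) or None if concordant."""
    a, b = sorted((p1, p2), key=lambda p: (p.chrom, p.start))
    if a.chrom != b.chrom:
        return "interchromosomal", a, b
    if a.strand == b.strand:
        return "inversion-like", a, b
    if a.strand == "-":
        return None  # everted pair: not a junction geometry we call
    ins = b.end - a.start
    if ins > stats.median + 3 * stats.sigma:
        return "deletion-like", a, b
    return None


def find_discordant_clusters(
    records: list[AlignmentRecord],
    insert_stats: InsertStats | None = None,
    min_support: int = 1,
) -> list[CandidateEvent]:
    """Cluster discordant read pairs into candidate junctions.

    A pair is discordant when its mates map to different chromosomes,
    in unexpected relative orientation, or with an implied insert
    beyond median + 3 x dispersion.  Pairs whose two footprints both
    fall within one insert-length window are clustered; the orientation
    class and the flank orientations entering the junction follow from
    the mate strands.
    """
    stats = insert_stats or estimate_insert_stats(records)
    w = stats.window
    groups: dict[tuple, list[tuple]] = defaultdict(list)
    for name, recs in sorted(pair_records(records).items()):
        if len(recs) != 2 or not all(r.aligned for r in recs):
            continue
        cls = _classify_pair(recs[0].primary, recs[1].primary, stats)
        if cls is None:
            continue
        kind, a, b = cls
        orient_a = a.strand
        orient_b = _flip(b.strand)
        groups[(kind, a.chrom, b.chrom, orient_a, orient_b)].append((a, b, name))
    events: list[CandidateEvent] = []
    for key in sorted(groups):
        kind, chrom_a, chrom_b, orient_a, orient_b = key
        members = sorted(groups[key], key=lambda t: (t[0].start, t[1].start))
        # single-linkage components: two pairs support the same junction
        # only when BOTH footprints fall within one insert-length window
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j][0].start - members[i][0].start > w:
                    break
                if abs(members[i][1].start - members[j][1].start) <= w:
                    parent[find(i)] = find(j)
        comps: dict[int, list[tuple]] = defaultdict(list)
        for i, m in enumerate(members):
            comps[find(i)].append(m)
        for grp in comps.values():
            if len(grp) < min_support:
                continue
            events.append(
                CandidateEvent(
                    orientation_class=kind,
                    chrom_a=chrom_a,
                    interval_a=_bp_interval([g[0] for g in grp], orient_a, "left", w),
                    orient_a=orient_a,
                    chrom_b=chrom_b,
                    interval_b=_bp_interval([g[1] for g in grp], orient_b, "right", w),
                    orient_b=orient_b,
                    pair_names=sorted(g[2] for g in grp),
                )
            )
    events.sort(key=lambda e: (e.chrom_a, e.interval_a, e.chrom_b, e.interval_b))
    return events


def _bp_interval(placements: list[Placement], orient: str, role: str, w: int):
    """Interval guaranteed to contain the breakpoint implied by mate footprints."""
    flank_left_of_bp = (role == "left") == (orient == "+")
    if flank_left_of_bp:
        hi = max(p.end for p in placements)
        return (hi - 8, hi + w)
    lo = min(p.start for p in placements)
    return (lo - w, lo + 8)


# ---------------------------------------------------------------------------
# split-read refinement
# ---------------------------------------------------------------------------


def _oriented_window(sequences, chrom, lo, hi, orient):
    lo = max(0, lo)
    hi = min(len(sequences[chrom]), hi)
    seq = sequences[chrom][lo:hi]
    return (seq, lo, hi) if orient == "+" else (revcomp(seq), lo, hi)


def _ref_coord(idx: int, lo: int, hi: int, orient: str) -> int:
    return lo + idx if orient == "+" else hi - idx


def _max_prefix_match(read: str, ref: str, seed: int) -> tuple[int, int]:
    """Longest exact prefix of ``read`` found in ``ref``; returns (start, length)."""
    best = (-1, 0)
    if len(read) < seed:
        return best
    probe = read[:seed]
    pos = ref.find(probe)
    while pos >= 0:
        n = seed
        while pos + n < len(ref) and n < len(read) and ref[pos + n] == read[n]:
            n += 1
        if n > best[1]:
            best = (pos, n)
        pos = ref.find(probe, pos + 1)
    return best


def _max_suffix_match(read: str, ref: str, seed: int) -> tuple[int, int]:
    """Longest exact suffix of ``read`` found in ``ref``; returns (end, length)."""
    best = (-1, 0)
    if len(read) < seed:
        return best
    probe = read[-seed:]
    pos = ref.find(probe)
    while pos >= 0:
        n = seed
        i = pos - 1
        j = len(read) - seed - 1
        while i >= 0 and j >= 0 and ref[i] == read[j]:
            n += 1
            i -= 1
            j -= 1
        if n > best[1]:
            best = (pos + seed, n)
        pos = ref.find(probe, pos + 1)
    return best


def _elementary_junctions(seqs, left, right, n_seq, j_off, min_block: int = 14):
    """Normalize one read's decomposition into elementary junction votes.

    A long 'insert' that contains a >= ``min_block`` templated run from
    the intervening reference is a compound seam (two joins with a
    short retained segment between them, e.g. a trimmed D); it is split
    so the read votes for both constituent junctions.  Returns tuples
    ``(left, right, n, micro, junction offset in read)``.
    """
    if (
        len(n_seq) >= min_block
        and left.chrom == right.chrom
        and left.orient == "+" == right.orient
        and right.pos > left.pos
    ):
        region = seqs[left.chrom][left.pos : right.pos]
        hit = _longest_block_in(region, n_seq, min_block)
        if hit is not None:
            qi, qj, rpos = hit
            g_start = left.pos + rpos
            g_end = g_start + (qj - qi)
            out = []
            l1, r1, n1, m1 = normalize_junction(
                seqs, left, JunctionSide(left.chrom, g_start, "+"), n_seq[:qi]
            )
            out.append((l1, r1, n1, m1, j_off))
            l2, r2, n2, m2 = normalize_junction(
                seqs, JunctionSide(left.chrom, g_end, "+"), right, n_seq[qj:]
            )
            out.append((l2, r2, n2, m2, j_off + qj))
            return out
    try:
        l, r, n, micro = normalize_junction(seqs, left, right, n_seq)
    except IndexError:
        return []
    return [(l, r, n, micro, j_off)]


def gather_split_candidates(
    candidate: CandidateEvent,
    by_name: dict[str, list[AlignmentRecord]],
    reach: int,
) -> list[AlignmentRecord]:
    """Reads that may span the junction: unaligned or poorly aligned reads
    whose mate is anchored in either candidate locus."""
    out = []
    (a0, a1), (b0, b1) = candidate.interval_a, candidate.interval_b

    def near(p: Placement) -> bool:
        if p.chrom == candidate.chrom_a and p.start < a1 + reach and p.end > a0 - reach:
            return True
        return p.chrom == candidate.chrom_b and p.start < b1 + reach and p.end > b0 - reach

    for name in sorted(by_name):
        recs = by_name[name]
        if len(recs) != 2:
            continue
        for rec, mate in ((recs[0], recs[1]), (recs[1], recs[0])):
            if not mate.aligned or not any(near(p) for p in mate.placements[:4]):
                continue
            if not rec.aligned or rec.primary.nm >= 3:
                out.append(rec)
    return out


def refine_by_split_reads(
    candidate: CandidateEvent,
    by_name: dict[str, list[AlignmentRecord]],
    model: LocusModel,
    min_anchor: int = 20,
    reach: int = 600,
    seed_len: int = 18,
    call_id: str = "jx",
    min_span: int = 40,
) -> list[JunctionCall]:
    """Refine a candidate to base-pair breakpoints using split reads.

    Each candidate spanning read is decomposed into a maximal prefix
    matching the side-A flank and a maximal suffix matching the side-B
    flank (each anchored by >= ``min_anchor`` matching bases); the gap
    between the two is the untemplated insert, an overlap is junctional
    microhomology.  Per-read breakpoints are normalized to the
    left-shifted canonical frame and tallied; every well-separated
    junction supported by the votes is emitted (a two-step assembly can
    put two seams under one discordant cluster), with near-duplicate
    minority votes folded into a conflict flag on the winner.
    Same-chromosome seams spanning < ``min_span`` bases are ignored --
    they are what an ordinary read with a sequencing error decomposes
    to, not a recombinase product.  With no qualifying split read the
    candidate keeps interval resolution.
    """
    seqs = model.sequences
    (a0, a1), (b0, b1) = candidate.interval_a, candidate.interval_b
    la, la_lo, la_hi = _oriented_window(
        seqs, candidate.chrom_a, a0 - reach, a1 + reach, candidate.orient_a
    )
    rb, rb_lo, rb_hi = _oriented_window(
        seqs, candidate.chrom_b, b0 - reach, b1 + reach, candidate.orient_b
    )
    votes: Counter = Counter()
    read_info: dict[tuple, list[tuple[str, int]]] = defaultdict(list)
    for rec in gather_split_candidates(candidate, by_name, reach):
        for seq in (rec.seq, revcomp(rec.seq)):
            la_pos, a_len = _max_prefix_match(seq, la, seed_len)
            rb_pos, b_len = _max_suffix_match(seq, rb, seed_len)
            if a_len < min_anchor or b_len < min_anchor:
                continue
            if a_len + b_len > len(seq) + 60 or a_len + b_len < len(seq) - 60:
                continue
            n_seq = seq[a_len : len(seq) - b_len] if a_len + b_len < len(seq) else ""
            left_idx = a_len if n_seq else len(seq) - b_len
            bp_a = _ref_coord(la_pos + left_idx, la_lo, la_hi, candidate.orient_a)
            bp_b = _ref_coord(rb_pos - b_len, rb_lo, rb_hi, candidate.orient_b)
            left = JunctionSide(candidate.chrom_a, bp_a, candidate.orient_a)
            right = JunctionSide(candidate.chrom_b, bp_b, candidate.orient_b)
            j_off = a_len if n_seq else len(seq) - b_len
            registered = False
            for l, r, n, micro, off in _elementary_junctions(
                seqs, left, right, n_seq, j_off
            ):
                if (
                    l.chrom == r.chrom
                    and l.orient == "+" == r.orient
                    and r.pos - l.pos < min_span
                ):
                    continue
                key = (l.chrom, l.pos, l.orient, r.chrom, r.pos, r.orient, n, micro)
                votes[key] += 1
                read_info[key].append((seq, off, rec.name))
                registered = True
            if registered:
                break
    if not votes:
        la_side = JunctionSide(candidate.chrom_a, (a0 + a1) // 2, candidate.orient_a)
        rb_side = JunctionSide(candidate.chrom_b, (b0 + b1) // 2, candidate.orient_b)
        return [
            JunctionCall(
                call_id,
                candidate.orientation_class,
                la_side,
                rb_side,
                "interval",
                candidate.interval_a,
                candidate.interval_b,
                candidate.n_pairs,
            )
        ]
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    top_support = ranked[0][1]
    calls: list[JunctionCall] = []
    accepted: list[tuple] = []
    for key, support in ranked:
        if support < top_support and support < max(2, top_support // 4):
            continue
        near = [
            (k, s) for k, s in accepted
            if key[0] == k[0] and key[3] == k[3]
            and abs(key[1] - k[1]) <= 5 and abs(key[4] - k[4]) <= 5
        ]
        if near:
            # disagreeing decomposition of an already-accepted seam
            if near[0][1] == support:
                for c in calls:
                    if (c.left.chrom, c.left.pos) == (near[0][0][0], near[0][0][1]):
                        c.conflict = True
            continue
        accepted.append((key, support))
        l = JunctionSide(key[0], key[1], key[2])
        r = JunctionSide(key[3], key[4], key[5])
        spanning = read_info[key]
        consensus, offset = build_consensus([(s, j) for s, j, _ in spanning])
        calls.append(
            JunctionCall(
                call_id,
                candidate.orientation_class,
                l,
                r,
                "base-pair",
                candidate.interval_a,
                candidate.interval_b,
                candidate.n_pairs,
                n_splits=support,
                n_seq=key[6],
                micro=key[7],
                consensus=consensus,
                consensus_offset=offset,
                split_read_names=sorted(name for _, _, name in spanning),
            )
        )
    return calls


def build_consensus(spanning: list[tuple[str, int]], flank_len: int = 60) -> tuple[str, int]:
    """Majority-vote consensus over junction-anchored spanning reads.

    Each entry is ``(oriented read sequence, junction offset)``; reads
    are stacked so their junction seams coincide.  Column ties break
    toward the lexicographically first base.  Returns the consensus and
    the seam offset within it.
    """
    if not spanning:
        raise ValueError("need at least one spanning read")
    cols: dict[int, Counter] = defaultdict(Counter)
    for seq, j in spanning:
        for i, base in enumerate(seq):
            cols[i - j][base] += 1
    lo = max(min(cols), -flank_len)
    hi = min(max(cols), flank_len + max(len(s) for s, _ in spanning))
    out = []
    for c in range(lo, hi + 1):
        counter = cols.get(c)
        if not counter:
            break
        best = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out), -lo


# ---------------------------------------------------------------------------
# templated-insert resolution (compound junctions)
# ---------------------------------------------------------------------------


def _longest_block_in(region: str, query: str, min_block: int):
    """Longest substring of ``query`` occurring in ``region``; returns
    (query_start, query_end, region_pos) or None."""
    best = None
    n = len(query)
    for i in range(n):
        lo = min_block
        if best is not None:
            lo = best[1] - best[0] + 1
        for ln in range(n - i, lo - 1, -1):
            pos = region.find(query[i : i + ln])
            if pos >= 0:
                if best is None or ln > best[1] - best[0]:
                    best = (i, i + ln, pos)
                break
    return best


def resolve_templated_inserts(
    calls: list[JunctionCall], model: LocusModel, min_block: int = 12
) -> list[JunctionCall]:
    """Split compound junctions whose 'insert' is templated sequence.

    When two joins happen in sequence with only a short segment retained
    between them (a V-D-J assembly keeping a trimmed D between two
    N-regions), a spanning read shows left flank + N1 + segment + N2 +
    right flank, and single-junction decomposition reports one long
    insert.  Any insert of >= ``min_block`` bases is searched against
    the intervening reference; a templated block splits the call into
    its two constituent junctions.
    """
    out: list[JunctionCall] = []
    for call in calls:
        n = call.n_seq
        if (
            call.resolution != "base-pair"
            or len(n) < min_block
            or call.left.chrom != call.right.chrom
            or call.left.orient != "+"
            or call.right.orient != "+"
            or call.right.pos <= call.left.pos
        ):
            out.append(call)
            continue
        region = model.sequences[call.left.chrom][call.left.pos : call.right.pos]
        hit = _longest_block_in(region, n, min_block)
        if hit is None:
            out.append(call)
            continue
        qi, qj, rpos = hit
        g_start = call.left.pos + rpos
        g_end = g_start + (qj - qi)
        seqs = model.sequences
        l1, r1, n1, m1 = normalize_junction(
            seqs, call.left, JunctionSide(call.left.chrom, g_start, "+"), n[:qi]
        )
        l2, r2, n2, m2 = normalize_junction(
            seqs, JunctionSide(call.left.chrom, g_end, "+"), call.right, n[qj:]
        )
        for left, right, nseq, micro in ((l1, r1, n1, m1), (l2, r2, n2, m2)):
            out.append(
                JunctionCall(
                    call.call_id,
                    call.orientation_class,
                    left,
                    right,
                    "base-pair",
                    call.interval_a,
                    call.interval_b,
                    call.n_pairs,
                    n_splits=call.n_splits,
                    n_seq=nseq,
                    micro=micro,
                    consensus=call.consensus,
                    consensus_offset=call.consensus_offset,
                    conflict=call.conflict,
                    split_read_names=call.split_read_names,
                )
            )
    return out


# ---------------------------------------------------------------------------
# ambiguity resolution
# ---------------------------------------------------------------------------


def _junction_reference(seqs, left: JunctionSide, right: JunctionSide, n_seq: str, flank: int):
    g1 = seqs[left.chrom]
    if left.orient == "+":
        lf = g1[max(0, left.pos - flank) : left.pos]
    else:
        lf = revcomp(g1[left.pos : left.pos + flank])
    g2 = seqs[right.chrom]
    if right.orient == "+":
        rf = g2[right.pos : right.pos + flank]
    else:
        rf = revcomp(g2[max(0, right.pos - flank) : right.pos])
    return lf + n_seq + rf


def _map_through_dups(model: LocusModel, side: JunctionSide) -> list[JunctionSide]:
    alts = []
    for dup in model.seg_dups:
        if side.chrom == dup.chrom_a and dup.start_a <= side.pos <= dup.end_a:
            alts.append(JunctionSide(dup.chrom_b, dup.map_a_to_b(side.pos), side.orient))
        if side.chrom == dup.chrom_b and dup.start_b <= side.pos <= dup.end_b:
            alts.append(JunctionSide(dup.chrom_a, dup.map_b_to_a(side.pos), side.orient))
    return alts


def resolve_ambiguous(
    calls: list[JunctionCall],
    by_name: dict[str, list[AlignmentRecord]],
    model: LocusModel,
    score_margin: int = 2,
    min_resolved: int = 2,
    flank: int = 150,
) -> list[JunctionCall]:
    """Annotate calls inside segmental duplications as resolved/unresolved.

    For every supporting split read, the called junction sequence is
    scored against the homologous junction obtained by mapping either
    flank through the duplication.  The call is *resolved* when the
    called placement beats every alternative by >= ``score_margin``
    edits for >= ``min_resolved`` reads; if the duplicated flanks carry
    no diagnostic bases the scores tie and the call stays *unresolved*
    (reported, never dropped).  Calls outside duplications keep the
    ``unique`` flag.
    """
    seqs = model.sequences
    for call in calls:
        alt_lefts = _map_through_dups(model, call.left)
        alt_rights = _map_through_dups(model, call.right)
        if not alt_lefts and not alt_rights:
            call.ambiguity = "unique"
            continue
        ref_called = _junction_reference(seqs, call.left, call.right, call.n_seq, flank)
        alt_refs = []
        for al in alt_lefts:
            alt_refs.append(_junction_reference(seqs, al, call.right, call.n_seq, flank))
        for ar in alt_rights:
            alt_refs.append(_junction_reference(seqs, call.left, ar, call.n_seq, flank))
        for al in alt_lefts:
            for ar in alt_rights:
                alt_refs.append(_junction_reference(seqs, al, ar, call.n_seq, flank))
        n_better = 0
        for name in call.split_read_names:
            # evaluate the junction-spanning mate only, once per pair
            best_seq, best_d = None, 10
            for rec in by_name.get(name, ()):
                for seq in (rec.seq, revcomp(rec.seq)):
                    d = edlib.align(seq, ref_called, mode="HW", k=10)["editDistance"]
                    if 0 <= d < best_d:
                        best_seq, best_d = seq, d
            if best_seq is None:
                continue
            d_alts = []
            for ref in alt_refs:
                d = edlib.align(best_seq, ref, mode="HW")["editDistance"]
                d_alts.append(d if d >= 0 else 10**9)
            if min(d_alts) - best_d >= score_margin:
                n_better += 1
        call.ambiguity = "resolved" if n_better >= min_resolved else "unresolved"
    return calls


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def detect_junctions(
    model: LocusModel,
    pairs: list[ReadPair] | None = None,
    records: list[AlignmentRecord] | None = None,
    insert_stats: InsertStats | None = None,
    min_support: int = 2,
    min_interval_support: int = 4,
    min_anchor: int = 20,
    aligner_k: int = 21,
    max_edits: int = 5,
) -> list[JunctionCall]:
    """End-to-end detection: align, cluster, refine, resolve.

    Candidate clusters are kept when supported by >= ``min_support``
    pairs or rescued by at least one split read.  Clusters that never
    acquire a split read stay at interval resolution and must clear the
    stricter ``min_interval_support``, which suppresses chance clusters
    of insert-length outliers.  Output is sorted by coordinates and
    independent of input read order.
    """
    if records is None:
        if pairs is None:
            raise ValueError("provide reads or alignments")
        aligner = ReadAligner(model.sequences, k=aligner_k, max_edits=max_edits)
        records = align_reads(pairs, aligner)
    by_name = pair_records(records)
    stats = insert_stats or estimate_insert_stats(records)
    candidates = find_discordant_clusters(records, stats, min_support=1)
    calls: list[JunctionCall] = []
    seen: set[tuple] = set()
    refined: list[JunctionCall] = []
    for i, cand in enumerate(candidates):
        refined.extend(
            refine_by_split_reads(
                cand, by_name, model, min_anchor=min_anchor, call_id=f"jx{i:03d}"
            )
        )
    for call in refined:
        if call.n_splits == 0 and call.n_pairs < max(min_support, min_interval_support):
            continue
        key = (
            call.left.chrom,
            call.left.pos if call.resolution == "base-pair" else call.interval_a[0] // 50,
            call.right.chrom,
            call.right.pos if call.resolution == "base-pair" else call.interval_b[0] // 50,
            call.left.orient,
            call.right.orient,
        )
        if key in seen:
            continue
        seen.add(key)
        calls.append(call)
    calls = resolve_templated_inserts(calls, model)
    unique: dict[tuple, JunctionCall] = {}
    for call in sorted(calls, key=lambda c: -c.n_splits):
        k = (call.left, call.right, call.n_seq, call.resolution)
        unique.setdefault(k, call)
    calls = list(unique.values())
    calls = resolve_ambiguous(calls, by_name, model)
    calls.sort(key=lambda c: (c.left.chrom, c.left.pos, c.right.chrom, c.right.pos))
    for i, call in enumerate(calls):
        call.call_id = f"jx{i:03d}"
    return calls
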