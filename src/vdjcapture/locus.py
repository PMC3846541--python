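"""Antigen-receptor locus models: segments, RSS motifs, bait design.

An antigen-receptor locus (IGH, IGK, IGL, TRB, or a synthetic stand-in)
is an array of V, D and J gene segments, each flanked by recombination
signal sequences (RSSs).  An RSS is a conserved heptamer (consensus
``CACAGTG``) and nonamer (consensus ``ACAAAAACC``) separated by a spacer
of ~12 or ~23 nt; the RAG recombinase joins one 12-spacer RSS to one
23-spacer RSS (the 12/23 rule), with the heptamer abutting the coding
segment at the cut site.

Coordinates are 0-based half-open throughout.  An RSS motif with
orientation ``+`` reads heptamer -> spacer -> nonamer left-to-right on
the plus strand; orientation ``-`` means the reverse complement of the
genomic slice reads heptamer -> spacer -> nonamer, i.e. the heptamer
sits at the *right* edge of the interval.  Two RSSs are in deletional
("facing") configuration when the left one is ``+`` and the right one is
``-``; same orientation means inversional configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import (
    count_mismatches,
    merge_intervals,
    random_dna,
    revcomp,
    validate_dna,
)

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

#: default spacer classes scanned for: (nominal length, slack in nt)
DEFAULT_SPACER_CLASSES = ((12, 1), (23, 1))


class ConfigError(ValueError):
    """Raised when a blueprint or operation request is internally inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RSSMotif:
    """One recombination signal sequence occurrence on a chromosome.

    ``heptamer``/``nonamer`` are stored in motif orientation (i.e. as the
    recombinase reads them), not necessarily as the plus strand reads.
    """

    chrom: str
    start: int
    end: int
    spacer_len: int
    orientation: str  # '+' or '-'
    heptamer: str
    nonamer: str

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7:
            raise ValueError("heptamer must be 7 nt")
        if len(self.nonamer) != 9:
            raise ValueError("nonamer must be 9 nt")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if self.end - self.start != 16 + self.spacer_len:
            raise ValueError("RSS interval length must equal 7 + spacer + 9")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")

    @property
    def spacer_class(self) -> int:
        """Nearest canonical spacer class (12 or 23)."""
        return 12 if abs(self.spacer_len - 12) <= abs(self.spacer_len - 23) else 23

    @property
    def heptamer_edge(self) -> int:
        """Coordinate of the heptamer/coding boundary (the recombinase cut site)."""
        return self.start if self.orientation == "+" else self.end


@dataclass
class GeneSegment:
    """A V, D or J gene segment with its flanking RSS annotation.

    ``reading_frame`` is the codon phase of the first coding base
    (0/1/2) or None when unannotated; ``functional`` mirrors ORF
    annotation (pseudogenes are non-functional).
    """

    id: str
    locus: str
    seg_type: str  # 'V', 'D' or 'J'
    chrom: str
    start: int
    end: int
    strand: str = "+"
    reading_frame: int | None = 0
    functional: bool = True
    rss_5prime: RSSMotif | None = None
    rss_3prime: RSSMotif | None = None

    def __post_init__(self) -> None:
        n_rss = (self.rss_5prime is not None) + (self.rss_3prime is not None)
        if self.seg_type in ("V", "J") and n_rss != 1:
            raise ValueError(f"{self.seg_type} segment {self.id} must carry exactly one RSS")
        if self.seg_type == "D" and n_rss != 2:
            raise ValueError(f"D segment {self.id} must carry two RSSs")
        for rss in self.rss_list():
            if rss.chrom != self.chrom:
                raise ValueError("RSS chromosome differs from segment chromosome")
            if not (rss.end == self.start or rss.start == self.end):
                raise ValueError(f"RSS of {self.id} must abut the coding interval")

    def rss_list(self) -> list[RSSMotif]:
        return [r for r in (self.rss_5prime, self.rss_3prime) if r is not None]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DupPair:
    """A pair of near-identical duplicated intervals (segmental duplication)."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float

    def map_a_to_b(self, pos: int) -> int:
        return self.start_b + (pos - self.start_a)

    def map_b_to_a(self, pos: int) -> int:
        return self.start_a + (pos - self.start_b)


@dataclass
class LocusModel:
    """Named chromosome sequences plus annotated gene segments."""

    sequences: dict[str, str]
    segments: list[GeneSegment] = field(default_factory=list)
    seg_dups: list[DupPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValueError("segment ids must be unique")
        for seg in self.segments:
            if seg.chrom not in self.sequences:
                raise ValueError(f"segment {seg.id} on unknown chromosome {seg.chrom}")
            lo = min([seg.start] + [r.start for r in seg.rss_list()])
            hi = max([seg.end] + [r.end for r in seg.rss_list()])
            if lo < 0 or hi > len(self.sequences[seg.chrom]):
                raise ValueError(f"segment {seg.id} outside chromosome bounds")

    def segment(self, seg_id: str) -> GeneSegment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise KeyError(seg_id)

    def all_rss(self) -> list[RSSMotif]:
        return [r for seg in self.segments for r in seg.rss_list()]

    def segments_on(self, chrom: str) -> list[GeneSegment]:
        return [s for s in self.segments if s.chrom == chrom]


@dataclass
class BaitSet:
    """Capture design: merged target windows tiled with fixed-length baits."""

    target_windows: list[tuple[str, int, int]]
    baits: list[tuple[str, int, int]]
    window_len: int = 200
    bait_len: int = 120
    tiling: int = 5

    def windows_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.target_windows if c == chrom]

    def baits_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.baits if c == chrom]


# ---------------------------------------------------------------------------
# RSS scanning
# ---------------------------------------------------------------------------


def _scan_plus(
    seq: str,
    hept_mm: int,
    nona_mm: int,
    spacer_classes,
    require_cac: bool,
) -> list[tuple[int, int]]:
    """Return (start, spacer_len) for plus-orientation motifs in seq."""
    hits: list[tuple[int, int]] = []
    n = len(seq)
    max_spacer = max(sp + slack for sp, slack in spacer_classes)
    if n < 16 + min(sp - slack for sp, slack in spacer_classes):
        return hits
    for i in range(0, n - 16 + 1):
        if require_cac:
            if seq[i : i + 3] != "CAC":
                continue
            if count_mismatches(seq[i + 3 : i + 7], HEPTAMER_CONSENSUS[3:], hept_mm) > hept_mm:
                continue
        else:
            if count_mismatches(seq[i : i + 7], HEPTAMER_CONSENSUS, hept_mm) > hept_mm:
                continue
        best: tuple[int, int] | None = None  # (|offset from nominal|, spacer_len)
        for sp, slack in spacer_classes:
            for d in sorted(range(-slack, slack + 1), key=abs):
                spacer = sp + d
                if spacer < 0 or spacer > max_spacer:
                    continue
                j = i + 7 + spacer
                if j + 9 > n:
                    continue
                if count_mismatches(seq[j : j + 9], NONAMER_CONSENSUS, nona_mm) <= nona_mm:
                    if best is None or abs(d) < best[0]:
                        best = (abs(d), spacer)
                    break
        if best is not None:
            hits.append((i, best[1]))
    return hits


def scan_rss(
    seq: str,
    *,
    max_heptamer_mismatches: int = 2,
    max_nonamer_mismatches: int = 3,
    spacer_classes=DEFAULT_SPACER_CLASSES,
    require_cac: bool = True,
    chrom: str = "seq",
) -> list[RSSMotif]:
    """Scan a sequence for RSS motifs on both strands.

    The heptamer's first three bases (CAC) are required exact by default;
    mismatch budgets apply to the remainder of the heptamer and to the
    nonamer independently.  Each spacer class is a (length, slack) pair;
    observed spacers within +/- slack of the nominal length are accepted
    and the nominal-closest spacer is recorded.

    Returns motifs sorted by start coordinate.  Ns never match.
    """
    seq = seq.upper()
    validate_dna(seq)
    if max_heptamer_mismatches < 0 or max_nonamer_mismatches < 0:
        raise ValueError("mismatch budgets must be >= 0")
    motifs: list[RSSMotif] = []
    for start, spacer in _scan_plus(
        seq, max_heptamer_mismatches, max_nonamer_mismatches, spacer_classes, require_cac
    ):
        end = start + 16 + spacer
        motifs.append(
            RSSMotif(
                chrom=chrom,
                start=start,
                end=end,
                spacer_len=spacer,
                orientation="+",
                heptamer=seq[start : start + 7],
                nonamer=seq[end - 9 : end],
            )
        )
    rc = revcomp(seq)
    n = len(seq)
    for start_rc, spacer in _scan_plus(
        rc, max_heptamer_mismatches, max_nonamer_mismatches, spacer_classes, require_cac
    ):
        end_rc = start_rc + 16 + spacer
        motifs.append(
            RSSMotif(
                chrom=chrom,
                start=n - end_rc,
                end=n - start_rc,
                spacer_len=spacer,
                orientation="-",
                heptamer=rc[start_rc : start_rc + 7],
                nonamer=rc[end_rc - 9 : end_rc],
            )
        )
    motifs.sort(key=lambda m: (m.start, m.orientation))
    return motifs


# ---------------------------------------------------------------------------
# bait design
# ---------------------------------------------------------------------------


def _rss_window(seg: GeneSegment, rss: RSSMotif, window_len: int, symmetric: bool) -> tuple[int, int]:
    if symmetric:
        mid = (rss.start + rss.end) // 2
        return (mid - window_len // 2, mid - window_len // 2 + window_len)
    # asymmetric (default): start at the coding-abutting RSS edge and extend
    # across the RSS into non-coding sequence, away from the coding segment.
    if rss.start >= seg.end:  # RSS right of coding
        return (rss.start, rss.start + window_len)
    # RSS left of coding
    return (rss.end - window_len, rss.end)


def design_baits(
    model: LocusModel,
    window_len: int = 200,
    bait_len: int = 120,
    tiling: int = 5,
    symmetric: bool = False,
) -> BaitSet:
    """Design a tiled capture bait set over every annotated RSS.

    One ``window_len`` window is laid per RSS, anchored at the coding
    edge and extending across the entire RSS into flanking non-coding
    sequence (this reproduces the signal-side enrichment bias that makes
    inversional rearrangements, which retain their RSSs, easier to
    capture than deletional ones; ``symmetric=True`` centres the window
    on the RSS instead).  Windows are merged per chromosome and tiled
    with ``bait_len``-mers at spacing ``round(bait_len / tiling)``.
    """
    if tiling < 1 or bait_len < 1 or window_len < 1:
        raise ValueError("window_len, bait_len and tiling must be positive")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in model.segments:
        for rss in seg.rss_list():
            if window_len < rss.end - rss.start:
                raise ConfigError("window_len shorter than RSS interval")
            s, e = _rss_window(seg, rss, window_len, symmetric)
            lim = len(model.sequences[seg.chrom])
            per_chrom.setdefault(seg.chrom, []).append((max(0, s), min(lim, e)))
    return _merge_and_tile(per_chrom, model.sequences, window_len, bait_len, tiling)


def _merge_and_tile(
    per_chrom: dict[str, list[tuple[int, int]]],
    sequences: dict[str, str],
    window_len: int,
    bait_len: int,
    tiling: int,
) -> BaitSet:
    windows: list[tuple[str, int, int]] = []
    baits: list[tuple[str, int, int]] = []
    spacing = max(1, round(bait_len / tiling))
    for chrom in sorted(per_chrom):
        lim = len(sequences[chrom])
        for s, e in merge_intervals(per_chrom[chrom]):
            windows.append((chrom, s, e))
            if e - s <= bait_len:
                start = max(0, min(s - (bait_len - (e - s)) // 2, lim - bait_len))
                baits.append((chrom, start, start + bait_len))
                continue
            starts = list(range(s, e - bait_len + 1, spacing))
            if starts[-1] != e - bait_len:
                starts.append(e - bait_len)
            baits.extend((chrom, t, t + bait_len) for t in starts)
    return BaitSet(windows, baits, window_len=window_len, bait_len=bait_len, tiling=tiling)


def design_baits_from_scan(
    sequences: dict[str, str],
    window_len: int = 200,
    bait_len: int = 120,
    tiling: int = 5,
    **scan_kw,
) -> BaitSet:
    """Bait design for an unannotated FASTA: scan for RSS motifs first.

    Without segment annotation the coding side of each motif is
    unknown, so windows are centred on the motif (symmetric design).
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted(sequences):
        for m in scan_rss(sequences[chrom], chrom=chrom, **scan_kw):
            mid = (m.start + m.end) // 2
            s = max(0, mid - window_len // 2)
            e = min(len(sequences[chrom]), s + window_len)
            per_chrom.setdefault(chrom, []).append((s, e))
    return _merge_and_tile(per_chrom, sequences, window_len, bait_len, tiling)


# ---------------------------------------------------------------------------
# synthetic locus construction
# ---------------------------------------------------------------------------


@dataclass
class LocusSpec:
    """Blueprint for one synthetic antigen-receptor locus.

    Defaults follow an IGH-like layout: V segments carry a 3' 23-spacer
    RSS, J segments a 5' 12-spacer RSS, and D segments a 5' 12-spacer
    and 3' 23-spacer RSS so that every canonical join (V-D, D-J, V-J)
    satisfies the 12/23 rule.  ``invert_j`` places J segments in
    inverted genomic orientation so that V-to-J joining proceeds by
    inversion rather than deletion (the IGK-like configuration).
    """

    name: str = "IGH"
    lineage: str = "B"  # 'B' for Ig loci, 'T' for TCR loci
    n_v: int = 3
    n_d: int = 0
    n_j: int = 2
    v_spacer: int = 23
    j_spacer: int = 12
    d_spacer_5: int = 12
    d_spacer_3: int = 23
    v_len: int = 300
    d_len: int = 24
    j_len: int = 51
    spacing: int = 400
    margin: int = 1500
    invert_j: bool = False
    cryptic_in_v: dict[int, int] = field(default_factory=dict)
    """Map V index -> offset within the V coding sequence at which an
    oppositely oriented cryptic heptamer is planted."""
    dup_v: tuple[int, float] | None = None
    """Optionally append a near-identical copy of V block ``index`` at the
    given sequence identity, recorded as a segmental duplication."""
    degenerate_rss: int = 0
    """Number of mismatches to introduce outside CAC in each heptamer."""


@dataclass
class LocusBlueprint:
    """Full blueprint: one chromosome per locus plus a random background."""

    loci: list[LocusSpec]
    seed: int = 0
    chrom_prefix: str = "chr"


def _rss_seq(spacer_len: int, rng: np.random.Generator, degenerate: int = 0) -> str:
    hept = list(HEPTAMER_CONSENSUS)
    if degenerate:
        pos = rng.choice(np.arange(3, 7), size=min(degenerate, 4), replace=False)
        for p in pos:
            hept[p] = rng.choice([b for b in "ACGT" if b != hept[p]])
    return "".join(hept) + random_dna(rng, spacer_len) + NONAMER_CONSENSUS


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_mut = int(round(len(seq) * (1.0 - identity)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def build_synthetic_model(blueprint: LocusBlueprint) -> LocusModel:
    """Build a deterministic synthetic genome from a locus blueprint.

    Each locus occupies its own chromosome: margin, then the V array,
    then the D array (if any), then the J array, then margin.  Random
    background sequence is drawn from a generator seeded by the
    blueprint seed, so identical blueprints yield byte-identical models.
    """
    rng = np.random.default_rng(blueprint.seed)
    sequences: dict[str, str] = {}
    segments: list[GeneSegment] = []
    dups: list[DupPair] = []
    for spec in blueprint.loci:
        if min(spec.n_v, spec.n_d, spec.n_j) < 0:
            raise ConfigError("segment counts must be >= 0")
        if spec.spacing < 1:
            raise ConfigError("spacing must leave room between segments")
        min_gap = 16 + max(spec.v_spacer, spec.j_spacer, spec.d_spacer_5, spec.d_spacer_3)
        if spec.spacing < min_gap:
            raise ConfigError(
                f"spacing {spec.spacing} too small to fit segments and their RSSs"
            )
        chrom = f"{blueprint.chrom_prefix}_{spec.name}"
        parts: list[str] = [random_dna(rng, spec.margin)]
        pos = spec.margin
        pending: list[tuple] = []  # (kind, id, start, end, strand, rss specs...)

        def emit(piece: str) -> int:
            parts.append(piece)
            return len(piece)

        v_block_spans: dict[int, tuple[int, int]] = {}
        for i in range(spec.n_v):
            coding = random_dna(rng, spec.v_len)
            off = spec.cryptic_in_v.get(i)
            if off is not None:
                if not 0 <= off <= spec.v_len - 7:
                    raise ConfigError("cryptic heptamer offset outside V coding interval")
                # oppositely oriented to the V's own '+' RSS => '-' motif,
                # i.e. the plus strand carries revcomp(heptamer)
                coding = coding[:off] + revcomp(HEPTAMER_CONSENSUS) + coding[off + 7 :]
            rss = _rss_seq(spec.v_spacer, rng, spec.degenerate_rss)
            start = pos
            pos += emit(coding)
            rss_start = pos
            pos += emit(rss)
            pending.append(("V", f"{spec.name}V{i + 1}", start, rss_start, "+",
                            None, (rss_start, pos, spec.v_spacer, "+")))
            v_block_spans[i] = (start, pos)
            pos += emit(random_dna(rng, spec.spacing))
        if spec.dup_v is not None:
            idx, identity = spec.dup_v
            if idx not in v_block_spans:
                raise ConfigError("dup_v index out of range")
            src_s, src_e = v_block_spans[idx]
            src = "".join(parts)[src_s:src_e]
            copy = _mutate(src, identity, rng)
            start = pos
            pos += emit(copy)
            rss_start = start + spec.v_len
            pending.append(("V", f"{spec.name}V{idx + 1}D", start, rss_start, "+",
                            None, (rss_start, pos, spec.v_spacer, "+")))
            dups.append(DupPair(chrom, src_s, src_e, chrom, start, pos, identity))
            pos += emit(random_dna(rng, spec.spacing))
        for i in range(spec.n_d):
            rss5 = _rss_seq(spec.d_spacer_5, rng, spec.degenerate_rss)
            coding = random_dna(rng, spec.d_len)
            rss3 = _rss_seq(spec.d_spacer_3, rng, spec.degenerate_rss)
            rss5_start = pos
            pos += emit(revcomp(rss5))  # 5' RSS: heptamer at right edge => '-' motif
            start = pos
            pos += emit(coding)
            rss3_start = pos
            pos += emit(rss3)
            pending.append(("D", f"{spec.name}D{i + 1}", start, rss3_start, "+",
                            (rss5_start, start, spec.d_spacer_5, "-"),
                            (rss3_start, pos, spec.d_spacer_3, "+")))
            pos += emit(random_dna(rng, spec.spacing))
        for i in range(spec.n_j):
            rss = _rss_seq(spec.j_spacer, rng, spec.degenerate_rss)
            coding = random_dna(rng, spec.j_len)
            if not spec.invert_j:
                rss_start = pos
                pos += emit(revcomp(rss))  # 5' RSS on plus strand: '-' motif
                start = pos
                pos += emit(coding)
                pending.append(("J", f"{spec.name}J{i + 1}", start, pos, "+",
                                (rss_start, start, spec.j_spacer, "-"), None))
            else:
                # J on the minus strand: revcomp(coding) then the RSS as a
                # '+' motif, heptamer abutting the coding interval.
                start = pos
                pos += emit(revcomp(coding))
                rss_start = pos
                pos += emit(rss)
                pending.append(("J", f"{spec.name}J{i + 1}", start, rss_start, "-",
                                (rss_start, pos, spec.j_spacer, "+"), None))
            pos += emit(random_dna(rng, spec.spacing))
        parts.append(random_dna(rng, spec.margin))
        seq = "".join(parts)
        sequences[chrom] = seq

        def motif(tup) -> RSSMotif | None:
            if tup is None:
                return None
            s, e, spacer, orient = tup
            sl = seq[s:e]
            m = sl if orient == "+" else revcomp(sl)
            return RSSMotif(chrom, s, e, spacer, orient, m[:7], m[-9:])

        for kind, sid, s, e, strand, r5, r3 in pending:
            segments.append(
                GeneSegment(
                    id=sid, locus=spec.name, seg_type=kind, chrom=chrom,
                    start=s, end=e, strand=strand,
                    reading_frame=0, functional=True,
                    rss_5prime=motif(r5), rss_3prime=motif(r3),
                )
            )
    return LocusModel(sequences=sequences, segments=segments, seg_dups=dups)
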