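"""Readers and writers for the standard formats the toolkit speaks.

FASTA via Biopython, SAM via pysam (text SAM in and out, suitable for
ingesting alignments from any external aligner), BED / BEDPE as plain
tab-separated text with 0-based half-open coordinates, truth records as
JSON lines, annotations as TSV (one row per junction side) or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .annotate import JunctionAnnotation
from .detect import AlignmentRecord, JunctionCall, Placement
from .locus import BaitSet, LocusModel
from .simulate import JunctionSide, ReadPair, RearrangementTruth

# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(
    pairs: list[ReadPair], path1: str | Path, path2: str | Path, suffix: bool = True
) -> None:
    """Write paired reads to two FASTQ files (optionally /1 /2 suffixed)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            tag1 = f"{p.name}/1" if suffix else p.name
            tag2 = f"{p.name}/2" if suffix else p.name
            f1.write(f"@{tag1}\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{tag2}\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    def load(path):
        out = []
        with open(path) as fh:
            while True:
                header = fh.readline().strip()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                name = header[1:].split()[0]
                if name.endswith("/1") or name.endswith("/2"):
                    name = name[:-2]
                out.append((name, seq.upper()))
        return out

    r1, r2 = load(path1), load(path2)
    if [n for n, _ in r1] != [n for n, _ in r2]:
        raise ValueError("FASTQ mates are not in matching order")
    return [ReadPair(n, s1, s2) for (n, s1), (_, s2) in zip(r1, r2)]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_segments_bed(model: LocusModel, path: str | Path) -> None:
    """Segments and their RSSs as BED6-style rows (name = id or id:RSS)."""
    with open(path, "w") as fh:
        for seg in model.segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.id}\t0\t{seg.strand}\n"
            )
            for label, rss in (("5RSS", seg.rss_5prime), ("3RSS", seg.rss_3prime)):
                if rss is None:
                    continue
                fh.write(
                    f"{rss.chrom}\t{rss.start}\t{rss.end}\t{seg.id}:{label}:"
                    f"{rss.spacer_len}\t0\t{rss.orientation}\n"
                )


def write_baits_bed(baits: BaitSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(baits.baits):
            fh.write(f"{chrom}\t{s}\t{e}\tbait{i:05d}\n")


def write_windows_bed(baits: BaitSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(baits.target_windows):
            fh.write(f"{chrom}\t{s}\t{e}\twindow{i:04d}\n")


# ---------------------------------------------------------------------------
# locus blueprint JSON
# ---------------------------------------------------------------------------


def write_blueprint(blueprint, path: str | Path) -> None:
    """Serialize a :class:`~vdjcapture.locus.LocusBlueprint` to JSON."""
    payload = dataclasses.asdict(blueprint)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_blueprint(path: str | Path):
    from .locus import LocusBlueprint, LocusSpec

    payload = json.loads(Path(path).read_text())
    loci = []
    for spec in payload.pop("loci"):
        spec["cryptic_in_v"] = {int(k): v for k, v in spec.get("cryptic_in_v", {}).items()}
        if spec.get("dup_v") is not None:
            spec["dup_v"] = tuple(spec["dup_v"])
        loci.append(LocusSpec(**spec))
    return LocusBlueprint(loci=loci, **payload)


# ---------------------------------------------------------------------------
# locus model persistence: FASTA + JSON sidecar
# ---------------------------------------------------------------------------


def write_model(model: LocusModel, outdir: str | Path) -> None:
    """Persist a locus model as reference.fasta + model.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(model.sequences, outdir / "reference.fasta")
    payload = {
        "segments": [
            {
                **{k: getattr(seg, k) for k in
                   ("id", "locus", "seg_type", "chrom", "start", "end", "strand",
                    "reading_frame", "functional")},
                "rss_5prime": dataclasses.asdict(seg.rss_5prime) if seg.rss_5prime else None,
                "rss_3prime": dataclasses.asdict(seg.rss_3prime) if seg.rss_3prime else None,
            }
            for seg in model.segments
        ],
        "seg_dups": [dataclasses.asdict(d) for d in model.seg_dups],
    }
    (outdir / "model.json").write_text(json.dumps(payload, indent=1))


def read_model(outdir: str | Path) -> LocusModel:
    from .locus import DupPair, GeneSegment, RSSMotif

    outdir = Path(outdir)
    sequences = read_fasta(outdir / "reference.fasta")
    payload = json.loads((outdir / "model.json").read_text())
    segments = []
    for s in payload["segments"]:
        r5 = RSSMotif(**s.pop("rss_5prime")) if s.get("rss_5prime") else None
        r3 = RSSMotif(**s.pop("rss_3prime")) if s.get("rss_3prime") else None
        s.pop("rss_5prime", None)
        s.pop("rss_3prime", None)
        segments.append(GeneSegment(**s, rss_5prime=r5, rss_3prime=r3))
    dups = [DupPair(**d) for d in payload.get("seg_dups", [])]
    return LocusModel(sequences=sequences, segments=segments, seg_dups=dups)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def write_sam(
    records: list[AlignmentRecord], sequences: dict[str, str], path: str | Path
) -> None:
    """Write alignment records as text SAM.

    The primary placement becomes the main record (reverse-strand reads
    are stored reverse-complemented, per SAM convention); additional
    placements are encoded in an XA tag ``chrom,strand,pos,nm;``.
    """
    names = sorted(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(sequences[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.name
            a.is_paired = True
            a.is_read1 = rec.mate == 1
            a.is_read2 = rec.mate == 2
            if not rec.aligned:
                a.is_unmapped = True
                a.query_sequence = rec.seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
                out.write(a)
                continue
            p = rec.primary
            a.reference_id = names.index(p.chrom)
            a.reference_start = p.start
            a.is_reverse = p.strand == "-"
            a.query_sequence = rec.seq if p.strand == "+" else revcomp(rec.seq)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            a.cigarstring = f"{len(rec.seq)}M"
            a.mapping_quality = 0 if rec.multi else 60
            tags = [("NM", p.nm)]
            if len(rec.placements) > 1:
                xa = ";".join(
                    f"{q.chrom},{q.strand},{q.start},{q.nm}" for q in rec.placements[1:]
                )
                tags.append(("XA", xa + ";"))
            a.set_tags(tags)
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Ingest text SAM (from :func:`write_sam` or an external aligner).

    Soft-clipped reads keep their full query sequence; secondary and
    supplementary records are folded into the primary record's
    placement list.
    """
    primaries: dict[tuple[str, int], AlignmentRecord] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            mate = 2 if a.is_read2 else 1
            key = (a.query_name, mate)
            seq = a.query_sequence or ""
            if a.is_unmapped:
                primaries.setdefault(key, AlignmentRecord(a.query_name, mate, seq))
                continue
            strand = "-" if a.is_reverse else "+"
            oriented = seq if strand == "+" else revcomp(seq)
            placements = [
                Placement(
                    a.reference_name,
                    a.reference_start,
                    a.reference_start + len(seq),
                    strand,
                    int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                )
            ]
            if a.has_tag("XA"):
                for chunk in a.get_tag("XA").rstrip(";").split(";"):
                    chrom, s, pos, nm = chunk.split(",")
                    placements.append(
                        Placement(chrom, int(pos), int(pos) + len(seq), s, int(nm))
                    )
            if a.is_secondary or a.is_supplementary:
                rec = primaries.get(key)
                if rec is not None:
                    rec.placements.extend(placements)
                continue
            rec = primaries.get(key)
            if rec is None or not rec.aligned:
                primaries[key] = AlignmentRecord(a.query_name, mate, oriented, placements)
            else:
                rec.placements.extend(placements)
    out = list(primaries.values())
    for rec in out:
        rec.placements.sort(key=lambda p: (p.nm, p.chrom, p.start, p.strand))
    out.sort(key=lambda r: (r.name, r.mate))
    return out


# ---------------------------------------------------------------------------
# BEDPE + consensus FASTA for junction calls
# ---------------------------------------------------------------------------

BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tstrand1\tstrand2\t"
    "class\tpairs\tsplits\tresolution\tambiguity\tmicro\tn_seq"
)


def write_bedpe(calls: list[JunctionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(BEDPE_HEADER + "\n")
        for c in calls:
            if c.resolution == "base-pair":
                s1, e1 = c.left.pos, c.left.pos + 1
                s2, e2 = c.right.pos, c.right.pos + 1
            else:
                s1, e1 = c.interval_a
                s2, e2 = c.interval_b
            fh.write(
                f"{c.left.chrom}\t{s1}\t{e1}\t{c.right.chrom}\t{s2}\t{e2}\t"
                f"{c.call_id}\t{c.n_pairs + c.n_splits}\t{c.left.orient}\t{c.right.orient}\t"
                f"{c.orientation_class}\t{c.n_pairs}\t{c.n_splits}\t{c.resolution}\t"
                f"{c.ambiguity}\t{c.micro}\t{c.n_seq or '.'}\n"
            )


def read_bedpe(path: str | Path) -> list[JunctionCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            resolution = f[13]
            left = JunctionSide(f[0], int(f[1]), f[8])
            right = JunctionSide(f[3], int(f[4]), f[9])
            calls.append(
                JunctionCall(
                    call_id=f[6],
                    orientation_class=f[10],
                    left=left,
                    right=right,
                    resolution=resolution,
                    interval_a=(int(f[1]), int(f[2])),
                    interval_b=(int(f[4]), int(f[5])),
                    n_pairs=int(f[11]),
                    n_splits=int(f[12]),
                    ambiguity=f[14],
                    micro=int(f[15]),
                    n_seq="" if f[16] == "." else f[16],
                )
            )
    return calls


def write_consensus_fasta(calls: list[JunctionCall], path: str | Path) -> None:
    seqs = {
        c.call_id: c.consensus for c in calls if c.consensus
    }
    write_fasta(seqs, path)


# ---------------------------------------------------------------------------
# truth + annotations
# ---------------------------------------------------------------------------


def write_truth_jsonl(truths: list[RearrangementTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(t.to_json() + "\n")


def read_truth_jsonl(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


ANNOTATION_COLUMNS = [
    "junction_id", "side", "chrom", "pos", "orient", "side_kind", "segment",
    "rss_used", "spacer", "joint_type", "n_len", "n_seq", "microhomology",
    "twelve_23", "frame_status", "productivity", "productivity_reason",
    "category", "lineage_flag", "order_flag",
]


def write_annotations_tsv(annotations: list[JunctionAnnotation], path: str | Path) -> None:
    """One row per junction side (two rows per junction)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for ann in annotations:
            for role, side in (("left", ann.left), ("right", ann.right)):
                row = [
                    ann.junction_id, role, side.side.chrom, str(side.side.pos),
                    side.side.orient, side.kind, side.segment or ".",
                    side.rss_used, str(side.rss.spacer_len) if side.rss else ".",
                    ann.joint_type, str(ann.n_len), ann.n_region or ".",
                    str(ann.microhomology), ann.twelve_23, ann.frame_status,
                    ann.productivity, ann.productivity_reason or ".",
                    ann.category, ann.lineage_flag, ann.order_flag,
                ]
                fh.write("\t".join(row) + "\n")


def write_annotations_json(annotations: list[JunctionAnnotation], path: str | Path) -> None:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))

    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(a) for a in annotations], fh, indent=1, default=encode)
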