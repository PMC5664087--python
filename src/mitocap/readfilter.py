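"""Aligned-read model, quality filtering and duplicate marking.

Reads aligned to the linear mitochondrial reference are kept when their
mapping quality exceeds 30 and more than 75% of their read bases are
aligned rather than soft-clipped.  Fragments that span the circular
origin necessarily arrive soft-clipped against the linearised
reference, so reads covering position 1 or position 16569 are exempt
from the clip-ratio test (not from the mapping-quality test).

Duplicate marking groups reads by unclipped 5' reference coordinate and
strand; within each group the read with the highest base-quality sum
survives, ties broken by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .mtref import CircularReference

FORWARD = "forward"
REVERSE = "reverse"

#: CIGAR operations consuming read bases / reference positions.
READ_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MD=X")

#: Read classification labels (the hg19 secondary alignment of the
#: original workflow is replaced by an explicit label channel).
LABELS = ("mt", "human", "unaligned", "unknown")

_CIGAR_OPS = "MIDNSHP=X"  # pysam numeric op order


class ReadParseError(ValueError):
    pass


@dataclass
class AlignedRead:
    """One sequencing read, possibly aligned to the circular reference."""

    name: str
    aligned: bool
    start: int | None  # 1-based leftmost reference position
    mapq: int
    strand: str  # FORWARD or REVERSE
    cigar: list[tuple[str, int]]  # [(op, count), ...]
    bases: str
    quals: list[int]
    label: str = "unknown"
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ReadParseError(f"negative mapq for {self.name}")
        if self.aligned:
            consumed = sum(n for op, n in self.cigar if op in READ_OPS)
            if consumed != len(self.bases):
                raise ReadParseError(
                    f"{self.name}: CIGAR consumes {consumed} read bases, "
                    f"sequence has {len(self.bases)}"
                )

    @property
    def read_length(self) -> int:
        """Full molecule length: all read bases including soft clips."""
        return len(self.bases)

    @property
    def reference_span(self) -> int:
        """Reference bases consumed by the alignment (M, D, =, X)."""
        return sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        if not self.aligned:
            raise ReadParseError(f"{self.name} is unaligned")
        return self.start + self.reference_span - 1

    @property
    def qualsum(self) -> int:
        return int(sum(self.quals))

    def leading_softclip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    def trailing_softclip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0


@dataclass
class FilterReport:
    """Partition of the input reads into kept and discarded (with reasons)."""

    kept: list[AlignedRead]
    discarded: list[tuple[AlignedRead, str]] = field(default_factory=list)

    def summary(self) -> dict:
        reasons: dict[str, int] = {}
        for _, reason in self.discarded:
            reasons[reason] = reasons.get(reason, 0) + 1
        return {
            "input": len(self.kept) + len(self.discarded),
            "kept": len(self.kept),
            "discarded": len(self.discarded),
            "reasons": reasons,
        }


def clip_ratio(read: AlignedRead) -> float:
    """Fraction of read bases that are aligned rather than soft-clipped.

    Returns A/(A+S) with A = M, =, X, I counts (insertions are read
    bases placed by the aligner) and S = soft-clip counts.  Hard clips
    carry no bases and are ignored.  Reads without soft clips score 1.0.
    """
    if not read.aligned:
        raise ReadParseError(f"clip_ratio on unaligned read {read.name}")
    a = sum(n for op, n in read.cigar if op in "M=XI")
    s = sum(n for op, n in read.cigar if op == "S")
    if s == 0:
        return 1.0
    return a / (a + s)


def covers_origin(read: AlignedRead, ref: CircularReference | int) -> bool:
    """True iff the aligned reference interval touches position 1 or L."""
    if not read.aligned:
        raise ReadParseError(f"covers_origin on unaligned read {read.name}")
    length = ref if isinstance(ref, int) else ref.length
    return read.start == 1 or read.reference_end >= length


def filter_reads(
    reads,
    ref: CircularReference | int,
    mapq_min: int = 30,
    ratio_min: float = 0.75,
) -> FilterReport:
    """Apply the mapping-quality and clip-ratio filters.

    A read is kept iff it is aligned, its mapq is strictly above
    `mapq_min`, and its aligned-base fraction is strictly above
    `ratio_min` unless it covers the circular origin (the exemption).
    Unaligned reads are discarded with reason ``unaligned``.  Input
    order of kept reads is preserved.
    """
    if not 0 <= ratio_min <= 1:
        raise ValueError("ratio_min must be in [0,1]")
    kept: list[AlignedRead] = []
    discarded: list[tuple[AlignedRead, str]] = []
    for read in reads:
        if not read.aligned:
            discarded.append((read, "unaligned"))
        elif read.mapq <= mapq_min:
            discarded.append((read, "mapq"))
        elif clip_ratio(read) > ratio_min or covers_origin(read, ref):
            kept.append(read)
        else:
            discarded.append((read, "clip_ratio"))
    return FilterReport(kept=kept, discarded=discarded)


def unclipped_start(read: AlignedRead) -> int:
    """Unclipped 5' reference coordinate of the sequenced molecule.

    Forward reads: alignment start minus leading soft clip.  Reverse
    reads: alignment end plus trailing soft clip (their molecule 5' end
    is the right-hand end in reference orientation).  May fall outside
    1..L; used only as a grouping key.
    """
    if not read.aligned:
        raise ReadParseError(f"unclipped_start on unaligned read {read.name}")
    if read.strand == FORWARD:
        return read.start - read.leading_softclip()
    return read.reference_end + read.trailing_softclip()


def mark_duplicates(reads) -> list[AlignedRead]:
    """Flag PCR/optical duplicates in place and return the read list.

    Reads sharing (unclipped 5' coordinate, strand) form a duplicate
    group; the member with the greatest base-quality sum (ties: lexico-
    graphically smallest name) keeps ``duplicate=False``, the rest are
    flagged.  Idempotent: flags are recomputed from scratch each call.
    """
    reads = list(reads)
    groups: dict[tuple[int, str], list[AlignedRead]] = {}
    for read in reads:
        groups.setdefault((unclipped_start(read), read.strand), []).append(read)
    for members in groups.values():
        survivor = min(members, key=lambda r: (-r.qualsum, r.name))
        for r in members:
            r.duplicate = r is not survivor
    return reads


# ---------------------------------------------------------------------------
# SAM/BAM I/O (pysam-backed)


def load_labels(path) -> dict[str, str]:
    """Read a two-column TSV (read name, label) into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, label = line.split("\t")[:2]
            if label not in LABELS:
                raise ReadParseError(f"unknown label {label!r} for read {name}")
            labels[name] = label
    return labels


def load_sam(path, labels: dict[str, str] | None = None) -> list[AlignedRead]:
    """Parse SAM/BAM into AlignedRead records.

    Secondary and supplementary records are dropped so each molecule
    enters the pileup once.  Mapped reads default to label ``mt``
    (they aligned to the mitochondrial reference), unmapped reads to
    ``unaligned``; an explicit label table overrides both.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            aligned = not rec.is_unmapped
            cigar = (
                [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
                if aligned and rec.cigartuples
                else []
            )
            quals = list(rec.query_qualities) if rec.query_qualities is not None else []
            default_label = "mt" if aligned else "unaligned"
            reads.append(
                AlignedRead(
                    name=rec.query_name,
                    aligned=aligned,
                    start=rec.reference_start + 1 if aligned else None,
                    mapq=rec.mapping_quality,
                    strand=REVERSE if (aligned and rec.is_reverse) else FORWARD,
                    cigar=cigar,
                    bases=rec.query_sequence or "",
                    quals=quals,
                    label=(labels or {}).get(rec.query_name, default_label),
                    duplicate=rec.is_duplicate,
                )
            )
    return reads


def write_sam(reads, ref: CircularReference, path) -> None:
    """Write reads as SAM (or BAM if the path ends in .bam)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.query_sequence = read.bases
            if read.quals:
                rec.query_qualities = read.quals
            flag = 0
            if not read.aligned:
                flag |= 4
            if read.strand == REVERSE:
                flag |= 16
            if read.duplicate:
                flag |= 1024
            rec.flag = flag
            if read.aligned:
                rec.reference_id = 0
                rec.reference_start = read.start - 1
                rec.mapping_quality = read.mapq
                rec.cigartuples = [
                    (_CIGAR_OPS.index(op), n) for op, n in read.cigar
                ]
            out.write(rec)


def write_filter_report(report: FilterReport, path) -> None:
    """Filter decisions as TSV: read name, decision, reason."""
    with open(path, "w") as fh:
        fh.write("read\tdecision\treason\n")
        for read in report.kept:
            fh.write(f"{read.name}\tkept\t.\n")
        for read, reason in report.discarded:
            fh.write(f"{read.name}\tdiscarded\t{reason}\n")
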