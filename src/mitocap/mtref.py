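"""Circular mitochondrial reference model and region arithmetic.

The human mitochondrial genome is a 16,569 bp circle.  The control
region (CR) spans positions 16024-576, i.e. it crosses the origin
between positions 16569 and 1.  Every coordinate in this package is
1-based and inclusive; a region whose start exceeds its end wraps
around the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

#: rCRS-like control region, crossing the origin.
CR_START = 16024
CR_END = 576
MT_LENGTH = 16569


class ReferenceError(ValueError):
    """Raised for malformed reference input or invalid coordinates."""


@dataclass(frozen=True)
class CircularReference:
    """A single circular reference sequence.

    Parameters
    ----------
    name:
        Sequence identifier (FASTA header word).
    sequence:
        Upper-case base string over the alphabet A, C, G, T, N.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        for i, b in enumerate(self.sequence):
            if b not in VALID_BASES:
                raise ReferenceError(
                    f"non-IUPAC character {b!r} at position {i + 1} in {self.name!r}"
                )
        if not self.sequence:
            raise ReferenceError(f"empty sequence for {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= pos <= self.length:
            raise ReferenceError(f"position {pos} outside 1..{self.length}")
        return self.sequence[pos - 1]

    def fetch(self, start: int, length: int) -> str:
        """Circular substring of `length` bases starting at 1-based `start`."""
        if not 1 <= start <= self.length:
            raise ReferenceError(f"start {start} outside 1..{self.length}")
        if length < 0:
            raise ReferenceError("negative fetch length")
        s = start - 1
        doubled = self.sequence + self.sequence
        if length > self.length:
            raise ReferenceError("fetch longer than the reference")
        return doubled[s : s + length]


@dataclass(frozen=True)
class Region:
    """1-based inclusive region on a circular reference.

    ``start > end`` denotes a region wrapping across the origin, e.g.
    the control region 16024-576.
    """

    start: int
    end: int

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def validate(self, ref) -> None:
        n = ref_length(ref)
        if not (1 <= self.start <= n and 1 <= self.end <= n):
            raise ReferenceError(
                f"region {self.start}-{self.end} outside 1..{n}"
            )


def ref_length(ref) -> int:
    """Length of a reference given either a CircularReference or an int."""
    return ref if isinstance(ref, int) else ref.length


def load_reference(path) -> CircularReference:
    """Read a single-record FASTA file into a :class:`CircularReference`.

    Lower-case bases are upper-cased.  Multi-record files and files with
    characters outside A/C/G/T/N are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ReferenceError(f"reference file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ReferenceError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ReferenceError(f"multiple records in {path}; expected exactly one")
    rec = records[0]
    return CircularReference(name=rec.id, sequence=str(rec.seq).upper())


def write_reference(ref: CircularReference, path) -> None:
    """Write the reference as single-record FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, 60):
            fh.write(ref.sequence[i : i + 60] + "\n")


def parse_region(text: str) -> Region:
    """Parse a CLI region string ``start-end`` (1-based inclusive).

    ``16024-576`` denotes the wrapping control region.
    """
    try:
        start_s, end_s = text.split("-")
        return Region(int(start_s), int(end_s))
    except (ValueError, TypeError) as exc:
        raise ReferenceError(f"bad region string {text!r}; expected start-end") from exc


def region_length(region: Region, ref) -> int:
    """Number of positions in a region (wrap-aware), in O(1)."""
    n = ref_length(ref)
    region.validate(n)
    if region.wraps:
        return (n - region.start + 1) + region.end
    return region.end - region.start + 1


def region_positions(region: Region, ref) -> list[int]:
    """Ordered 1-based positions of a region.

    Non-wrapping regions enumerate start..end; wrapping regions
    enumerate start..length then 1..end.  Each position appears once.
    """
    n = ref_length(ref)
    region.validate(n)
    if region.wraps:
        return list(range(region.start, n + 1)) + list(range(1, region.end + 1))
    return list(range(region.start, region.end + 1))


def position_in_region(pos: int, region: Region, ref) -> bool:
    """Membership test, O(1) arithmetic (no enumeration)."""
    n = ref_length(ref)
    if not 1 <= pos <= n:
        raise ReferenceError(f"position {pos} outside 1..{n}")
    region.validate(n)
    if region.wraps:
        return pos >= region.start or pos <= region.end
    return region.start <= pos <= region.end


def interval_overlaps_region(start: int, end: int, region: Region, ref) -> bool:
    """True iff the linear interval [start, end] shares >= 1 bp with the region.

    The interval is a linear alignment span (alignments against the
    linearised reference never wrap); the region may wrap.
    """
    n = ref_length(ref)
    if not (1 <= start <= end <= n):
        raise ReferenceError(f"bad interval {start}-{end} on length {n}")
    region.validate(n)
    if region.wraps:
        # arms [region.start, n] and [1, region.end]
        return end >= region.start or start <= region.end
    return start <= region.end and end >= region.start


# Base composition of the human mitochondrial genome (approximate),
# used for the bundled synthetic test reference.
_MT_BASE_FREQS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}


def synthetic_reference(
    length: int = MT_LENGTH, seed: int = 20_101, name: str = "synthMT"
) -> CircularReference:
    """Generate a synthetic circular reference with mtDNA-like base composition.

    This is a stand-in for the real 16,569 bp human mitochondrial
    reference, so the test suite and simulator run without any external
    download; a real rCRS FASTA is accepted as user input everywhere a
    reference is required.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_MT_BASE_FREQS), dtype="U1")
    probs = np.array(list(_MT_BASE_FREQS.values()))
    probs = probs / probs.sum()
    seq = "".join(rng.choice(bases, size=length, p=probs))
    return CircularReference(name=name, sequence=seq)


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]
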