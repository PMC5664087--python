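"""Strand-separated per-position base counts and coverage.

The pileup is a position x strand x base integer tensor over the whole
circular reference.  Deletions are tallied in a dedicated DEL channel
but excluded from depth, so "coverage" always means observed sequenced
bases; the consensus caller reads the DEL channel explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mtref import CircularReference, Region, region_positions
from .readfilter import FORWARD, REVERSE

BASES = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEL = "DEL"
DEL_INDEX = 5
CHANNELS = list(BASES) + [DEL]
STRANDS = (FORWARD, REVERSE)
STRAND_INDEX = {FORWARD: 0, REVERSE: 1}


class PileupError(ValueError):
    pass


@dataclass
class BaseCountMatrix:
    """Per-position, per-strand, per-base counts over a circular reference.

    ``counts`` has shape (length, 2, 6): axis 0 is the 0-based position
    (reference position - 1), axis 1 the read strand (forward, reverse),
    axis 2 the channel (A, C, G, T, N, DEL).
    """

    counts: np.ndarray
    ref_name: str

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def at(self, pos: int) -> np.ndarray:
        """(2, 6) count slab at a 1-based position."""
        return self.counts[pos - 1]

    def depth(self, pos: int) -> int:
        """Observed-base depth (both strands, DEL excluded)."""
        return int(self.counts[pos - 1, :, :DEL_INDEX].sum())

    def total_bases(self) -> int:
        """Total aligned read bases tallied (DEL excluded)."""
        return int(self.counts[:, :, :DEL_INDEX].sum())

    def to_tsv(self, path) -> None:
        """Serialise as TSV: position, strand, A, C, G, T, N, DEL.

        Only rows with at least one count are written; round-trips
        losslessly through :func:`matrix_from_tsv` given the length.
        """
        rows = []
        nonzero = np.nonzero(self.counts.sum(axis=(1, 2)))[0]
        for p in nonzero:
            for s, strand in enumerate(STRANDS):
                if self.counts[p, s].sum() == 0:
                    continue
                rows.append([int(p + 1), strand] + [int(c) for c in self.counts[p, s]])
        df = pd.DataFrame(rows, columns=["position", "strand"] + CHANNELS)
        df.to_csv(path, sep="\t", index=False)


def matrix_from_tsv(path, length: int, ref_name: str = "ref") -> BaseCountMatrix:
    """Load a matrix serialised by :meth:`BaseCountMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    counts = np.zeros((length, 2, 6), dtype=np.int64)
    for _, row in df.iterrows():
        counts[int(row["position"]) - 1, STRAND_INDEX[row["strand"]]] = [
            row[c] for c in CHANNELS
        ]
    return BaseCountMatrix(counts=counts, ref_name=ref_name)


def build_basecounts(
    reads, ref: CircularReference, unique_only: bool = False
) -> BaseCountMatrix:
    """Tally filtered reads into a :class:`BaseCountMatrix`.

    Walking each read's CIGAR: M/=/X bases increment (position, strand,
    base); D increments the DEL channel; I and S consume read bases but
    touch no reference position.  With ``unique_only`` duplicate-flagged
    reads are skipped.  A read whose alignment runs past the reference
    end is rejected (it should have arrived soft-clipped).
    """
    counts = np.zeros((ref.length, 2, 6), dtype=np.int64)
    for read in reads:
        if not read.aligned:
            continue
        if unique_only and read.duplicate:
            continue
        if read.reference_end > ref.length:
            raise PileupError(
                f"{read.name}: alignment ends at {read.reference_end} beyond "
                f"reference length {ref.length} (expected soft-clipping)"
            )
        s = STRAND_INDEX[read.strand]
        refpos = read.start - 1  # 0-based
        readpos = 0
        for op, n in read.cigar:
            if op in "M=X":
                for i in range(n):
                    counts[refpos + i, s, BASE_INDEX[read.bases[readpos + i]]] += 1
                refpos += n
                readpos += n
            elif op == "D":
                counts[refpos : refpos + n, s, DEL_INDEX] += 1
                refpos += n
            elif op in "IS":
                readpos += n
            # H, P consume nothing tallied here
    return BaseCountMatrix(counts=counts, ref_name=ref.name)


def coverage_vector(matrix: BaseCountMatrix, region: Region) -> np.ndarray:
    """Observed-base depth at each region position, in region order."""
    positions = region_positions(region, matrix.length)
    idx = np.asarray(positions) - 1
    return matrix.counts[idx, :, :DEL_INDEX].sum(axis=(1, 2))


def strand_bias(
    matrix: BaseCountMatrix, region: Region, weighted: bool = False
) -> float:
    """Mean forward-read fraction over covered region positions.

    Per covered position the fraction of forward-strand bases among all
    bases is computed; the unweighted arithmetic mean of these fractions
    is returned (the primary definition).  With ``weighted=True`` the
    pooled ratio total-forward / total is returned instead.  Regions
    with no covered position score 0.
    """
    positions = np.asarray(region_positions(region, matrix.length)) - 1
    fwd = matrix.counts[positions, 0, :DEL_INDEX].sum(axis=1)
    total = fwd + matrix.counts[positions, 1, :DEL_INDEX].sum(axis=1)
    covered = total > 0
    if not covered.any():
        return 0.0
    if weighted:
        return float(fwd[covered].sum() / total[covered].sum())
    return float((fwd[covered] / total[covered]).mean())
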