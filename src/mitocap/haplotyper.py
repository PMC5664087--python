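"""Consensus haplotype calling against the circular reference.

A difference to the reference is called at a position when at least 75%
of the (duplicate-removed) reads covering it show the same divergent
base.  Positions whose majority base diverges below the threshold are
reported as uncalled point-heteroplasmy candidates, never as variants.
Length variation in poly-cytosine tracts (310-316 by default) is
excluded from calling, as is conventional for forensic mtDNA reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .basecount import BASES, DEL, DEL_INDEX, BaseCountMatrix
from .mtref import CircularReference, Region, position_in_region, region_positions

#: The C-tract between 310 and 316, excluded by default.
DEFAULT_TRACTS = (Region(310, 316),)

#: Additional poly-C tracts commonly excluded, offered via config.
OPTIONAL_TRACTS = (Region(16183, 16194), Region(568, 573))

_CALLABLE = list(BASES[:4]) + [DEL]  # A C G T DEL; N is never called


class CallError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """One consensus difference to the reference."""

    position: int
    ref_base: str
    called_base: str  # A/C/G/T or DEL
    support: float  # fraction of reads showing called_base
    depth: int  # reads covering the position


@dataclass(frozen=True)
class UncalledSite:
    position: int
    reason: str  # no_coverage | below_threshold | excluded_tract | ref_is_N
    majority_base: str | None = None
    support: float | None = None
    depth: int = 0


@dataclass
class Haplotype:
    """Consensus call set over a region of the reference."""

    variants: list[Variant]
    uncalled: list[UncalledSite]
    region: Region
    ref_name: str

    def callable_positions(self, length: int) -> set[int]:
        """Region positions at which a confident call (ref or variant) exists."""
        positions = set(region_positions(self.region, length))
        return positions - {u.position for u in self.uncalled}


@dataclass(frozen=True)
class ExclusionTracts:
    """Poly-cytosine (or other homopolymer) tracts excluded from calling."""

    tracts: tuple[Region, ...] = DEFAULT_TRACTS

    def contains(self, pos: int, length: int) -> bool:
        return any(position_in_region(pos, t, length) for t in self.tracts)


def call_consensus(
    matrix: BaseCountMatrix,
    ref: CircularReference,
    region: Region,
    threshold: float = 0.75,
    tracts: ExclusionTracts = ExclusionTracts(),
    min_depth: int = 2,
    per_strand: bool = False,
) -> Haplotype:
    """Call the consensus haplotype over ``region`` using the >= 75% rule.

    At each region position outside the excluded tracts with total read
    depth >= ``min_depth``, the majority channel among A, C, G, T and
    DEL is compared to the reference base: a divergent majority with
    support fraction >= ``threshold`` becomes a :class:`Variant`; a
    divergent majority below the threshold is recorded uncalled with
    reason ``below_threshold`` (point heteroplasmy is disregarded, not
    asserted).  Support is computed over all reads covering the
    position (N and DEL evidence included in the denominator).

    ``per_strand=True`` additionally requires the support fraction to
    reach the threshold on each strand with coverage (stricter mode).
    Ties for the majority prefer the reference base, then alphabetical
    order, so noise never produces a call.
    """
    if not 0.5 < threshold <= 1:
        raise CallError(f"threshold {threshold} outside (0.5, 1]")
    if min_depth < 1:
        raise CallError("min_depth must be >= 1")
    region.validate(ref)

    variants: list[Variant] = []
    uncalled: list[UncalledSite] = []
    for pos in region_positions(region, ref):
        if tracts.contains(pos, ref.length):
            uncalled.append(UncalledSite(pos, "excluded_tract"))
            continue
        ref_base = ref.base(pos)
        if ref_base == "N":
            uncalled.append(UncalledSite(pos, "ref_is_N"))
            continue
        slab = matrix.at(pos)  # (2, 6)
        totals = slab.sum(axis=0)  # per channel, both strands
        depth = int(totals.sum())  # includes N and DEL reads
        if depth < min_depth:
            uncalled.append(UncalledSite(pos, "no_coverage", depth=depth))
            continue
        # majority among callable channels; ties prefer ref, then A<C<DEL<G<T
        channel_counts = {
            b: int(totals[DEL_INDEX] if b == DEL else totals["ACGTN".index(b)])
            for b in _CALLABLE
        }
        top = max(channel_counts.values())
        tied = sorted(b for b, c in channel_counts.items() if c == top)
        best = ref_base if ref_base in tied else tied[0]
        support = channel_counts[best] / depth
        if best == ref_base:
            continue
        if support < threshold:
            uncalled.append(
                UncalledSite(pos, "below_threshold", best, support, depth)
            )
            continue
        if per_strand:
            ok = True
            for s in (0, 1):
                sdepth = int(slab[s].sum())
                if sdepth == 0:
                    continue
                scount = int(slab[s, DEL_INDEX if best == DEL else "ACGTN".index(best)])
                if scount / sdepth < threshold:
                    ok = False
            if not ok:
                uncalled.append(
                    UncalledSite(pos, "below_threshold", best, support, depth)
                )
                continue
        variants.append(Variant(pos, ref_base, best, support, depth))

    return Haplotype(
        variants=variants, uncalled=uncalled, region=region, ref_name=ref.name
    )


def format_haplotype(h: Haplotype) -> str:
    """Forensic-style difference string, e.g. ``"263G 16126C"``.

    Tokens are ``<position><base>`` sorted by position; deletions render
    as ``<position>DEL``.  The empty haplotype formats as "".
    """
    tokens = [
        f"{v.position}{v.called_base}"
        for v in sorted(h.variants, key=lambda v: v.position)
    ]
    return " ".join(tokens)


@dataclass
class ComparisonReport:
    """Concordance of two haplotypes over their jointly callable region."""

    shared: list[Variant]
    conflicting: list[tuple[Variant, Variant]]
    only_a: list[Variant]
    only_b: list[Variant]
    overlap_size: int
    concordant: bool

    def to_dict(self) -> dict:
        def tok(v: Variant) -> str:
            return f"{v.position}{v.called_base}"

        return {
            "shared": [tok(v) for v in self.shared],
            "conflicting": [[tok(a), tok(b)] for a, b in self.conflicting],
            "only_a": [tok(v) for v in self.only_a],
            "only_b": [tok(v) for v in self.only_b],
            "overlap_size": self.overlap_size,
            "concordant": self.concordant,
        }


def compare_haplotypes(a: Haplotype, b: Haplotype, length: int) -> ComparisonReport:
    """Compare two haplotypes restricted to jointly callable positions.

    Positions uncalled on either side are excluded.  Within the overlap,
    a conflict is any position where the two confident calls differ —
    two different divergent bases, or a variant on one side against a
    confident reference call on the other.  ``concordant`` is True iff
    no such conflict exists.
    """
    if a.ref_name != b.ref_name:
        raise CallError(f"different references: {a.ref_name!r} vs {b.ref_name!r}")
    overlap = a.callable_positions(length) & b.callable_positions(length)
    va = {v.position: v for v in a.variants if v.position in overlap}
    vb = {v.position: v for v in b.variants if v.position in overlap}
    shared, conflicting, only_a, only_b = [], [], [], []
    for pos in sorted(set(va) | set(vb)):
        if pos in va and pos in vb:
            if va[pos].called_base == vb[pos].called_base:
                shared.append(va[pos])
            else:
                conflicting.append((va[pos], vb[pos]))
        elif pos in va:
            only_a.append(va[pos])
        else:
            only_b.append(vb[pos])
    concordant = not conflicting and not only_a and not only_b
    return ComparisonReport(
        shared=shared,
        conflicting=conflicting,
        only_a=only_a,
        only_b=only_b,
        overlap_size=len(overlap),
        concordant=concordant,
    )


def haplotype_to_tsv(h: Haplotype, path) -> None:
    """Per-position call table: position, ref, call, support, depth, status."""
    with open(path, "w") as fh:
        fh.write("position\tref\tcall\tsupport\tdepth\tstatus\n")
        rows = [
            (v.position, v.ref_base, v.called_base, f"{v.support:.4f}", v.depth, "variant")
            for v in h.variants
        ] + [
            (
                u.position,
                ".",
                u.majority_base or ".",
                f"{u.support:.4f}" if u.support is not None else ".",
                u.depth,
                u.reason,
            )
            for u in h.uncalled
        ]
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
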