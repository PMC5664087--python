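"""Shared fixtures: references and an aligned-read factory."""

import pytest

from mitocap.mtref import CircularReference, synthetic_reference
from mitocap.readfilter import FORWARD, AlignedRead


@pytest.fixture(scope="session")
def mt_ref() -> CircularReference:
    """Full-size (16,569 bp) synthetic circular reference."""
    return synthetic_reference()


@pytest.fixture
def small_ref() -> CircularReference:
    """12 bp toy reference for hand-checkable coordinate arithmetic."""
    return CircularReference(name="toy", sequence="ACGTACGTACGT")


def build_read(
    name="r",
    start=1,
    cigar=((("M", 10)),),
    bases=None,
    mapq=60,
    strand=FORWARD,
    quals=None,
    aligned=True,
    label="mt",
):
    """AlignedRead factory with consistent defaults.

    ``bases`` defaults to 'A' * (read-consuming CIGAR length) so tests
    only spell out what they assert on.
    """
    cigar = [tuple(c) for c in cigar] if aligned else []
    if bases is None:
        n = sum(c for op, c in cigar if op in "MIS=X") if aligned else 10
        bases = "A" * n
    if quals is None:
        quals = [30] * len(bases)
    return AlignedRead(
        name=name,
        aligned=aligned,
        start=start if aligned else None,
        mapq=mapq if aligned else 0,
        strand=strand,
        cigar=cigar,
        bases=bases,
        quals=quals,
        label=label,
    )


@pytest.fixture
def read_factory():
    return build_read
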