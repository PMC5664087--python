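"""Terminal deamination damage profiling and geometric-decay fitting.

Post-mortem cytosine deamination reads out as C->T mismatches near the
5' end of a degraded molecule and G->A mismatches near its 3' end, with
frequencies decaying towards the interior.  The empirical profile
(mismatches over opportunities per distance-from-end) plus a weighted
least-squares fit of f(i) = amplitude * decay^i is this package's
authenticity readout for degraded-sample sequencing; ancient material
shows elevated terminal frequencies, modern material does not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .mtref import COMPLEMENT, CircularReference
from .readfilter import REVERSE, AlignedRead

DEFAULT_WINDOW = 25


class DamageError(ValueError):
    pass


@dataclass
class EndProfile:
    """Mismatch counts per distance from one molecule end."""

    mismatches: np.ndarray  # int, length = window
    opportunities: np.ndarray  # int, length = window

    def frequencies(self) -> np.ndarray:
        """Per-distance frequency; NaN where there was no opportunity."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.mismatches / self.opportunities
        return np.where(self.opportunities > 0, f, np.nan)


@dataclass
class DamageProfile:
    """C->T (5') and G->A (3') misincorporation profiles."""

    f5: EndProfile
    f3: EndProfile
    window: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("end\tdistance\tmismatches\topportunities\tfrequency\n")
            for end, prof in (("5p_CT", self.f5), ("3p_GA", self.f3)):
                freqs = prof.frequencies()
                for i in range(self.window):
                    freq = "." if math.isnan(freqs[i]) else f"{freqs[i]:.6f}"
                    fh.write(
                        f"{end}\t{i}\t{prof.mismatches[i]}\t"
                        f"{prof.opportunities[i]}\t{freq}\n"
                    )


@dataclass
class DecayFit:
    """Geometric decay fit f(i) = amplitude * decay^i."""

    amplitude: float  # damage probability at the terminal base
    decay: float  # per-position geometric factor
    residual: float  # weighted sum of squared errors
    identifiable: bool = True  # False when decay cannot be estimated

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "decay": self.decay,
            "residual": self.residual,
            "identifiable": self.identifiable,
        }


def _molecule_columns(read: AlignedRead, ref: CircularReference):
    """Aligned (molecule_offset, ref_base, read_base) columns in molecule frame.

    Offsets index the full read (soft clips included) so distances are
    measured along the sequenced molecule; only aligned columns (M/=/X)
    yield a reference base.  Reverse-strand alignments are flipped and
    complemented so offset 0 is the molecule's 5' terminal base.
    """
    cols: list[tuple[int, str, str]] = []
    refpos = read.start
    readpos = 0
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                cols.append(
                    (readpos + i, ref.base(refpos + i), read.bases[readpos + i])
                )
            refpos += n
            readpos += n
        elif op == "D":
            refpos += n
        elif op in "IS":
            readpos += n
    if read.strand == REVERSE:
        L = read.read_length
        cols = [
            (L - 1 - off, rb.translate(COMPLEMENT), qb.translate(COMPLEMENT))
            for off, rb, qb in cols
        ]
    return cols


def misincorporation_profile(
    reads, ref: CircularReference, window: int = DEFAULT_WINDOW
) -> DamageProfile:
    """Empirical C->T / G->A terminal mismatch profile of aligned reads.

    For each read, at molecule distance i < window from the 5' end where
    the reference shows C, an opportunity is counted and a mismatch when
    the read shows T; symmetrically G->A from the 3' end.  For reads
    shorter than two windows, positions beyond the molecule midpoint
    belong to the far end only, so no base is counted from both ends.
    """
    if window < 1:
        raise DamageError("window must be >= 1")
    m5 = np.zeros(window, dtype=np.int64)
    o5 = np.zeros(window, dtype=np.int64)
    m3 = np.zeros(window, dtype=np.int64)
    o3 = np.zeros(window, dtype=np.int64)
    for read in reads:
        if not read.aligned:
            continue
        L = read.read_length
        lim5 = min(window, (L + 1) // 2)  # 5' side owns the middle base
        lim3 = min(window, L // 2)
        for off, ref_base, read_base in _molecule_columns(read, ref):
            if off < lim5 and ref_base == "C":
                o5[off] += 1
                if read_base == "T":
                    m5[off] += 1
            d3 = L - 1 - off
            if d3 < lim3 and ref_base == "G":
                o3[d3] += 1
                if read_base == "A":
                    m3[d3] += 1
    return DamageProfile(
        f5=EndProfile(m5, o5), f3=EndProfile(m3, o3), window=window
    )


def _geometric(i, amplitude, decay):
    return amplitude * decay**i


def fit_decay(profile: DamageProfile, end: str = "5p") -> DecayFit:
    """Weighted least-squares fit of amplitude * decay^i to a profile end.

    Distances with no opportunities are dropped; weights are the
    opportunity counts (binomial precision proxy).  Requires >= 3
    defined distances.  An all-zero profile returns amplitude 0 with
    the decay flagged unidentifiable.
    """
    prof = profile.f5 if end == "5p" else profile.f3
    freqs = prof.frequencies()
    defined = ~np.isnan(freqs)
    if defined.sum() < 3:
        raise DamageError("need >= 3 distances with defined frequencies")
    i = np.arange(profile.window)[defined].astype(float)
    f = freqs[defined]
    w = prof.opportunities[defined].astype(float)
    if not f.any():
        return DecayFit(amplitude=0.0, decay=float("nan"), residual=0.0,
                        identifiable=False)
    a0 = float(np.clip(f[0] if f[0] > 0 else f.max(), 1e-4, 1.0))
    d0 = 0.5
    try:
        popt, _ = curve_fit(
            _geometric,
            i,
            f,
            p0=[a0, d0],
            sigma=1.0 / np.sqrt(w),
            absolute_sigma=False,
            bounds=([0.0, 1e-9], [1.0, 1.0 - 1e-9]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological profiles
        raise DamageError(f"decay fit did not converge: {exc}") from exc
    amplitude, decay = float(popt[0]), float(popt[1])
    residual = float(np.sum(w * (f - _geometric(i, amplitude, decay)) ** 2))
    return DecayFit(amplitude=amplitude, decay=decay, residual=residual)


@dataclass
class ProfileComparison:
    """Per-distance frequency differences between two profiles."""

    diff5: np.ndarray  # ancient - modern, NaN where either undefined
    diff3: np.ndarray
    terminal_ratio_5p: float  # ancient f5[0] / modern f5[0]; inf/NaN-safe

    def to_dict(self) -> dict:
        return {
            "diff5": [None if math.isnan(x) else x for x in self.diff5],
            "diff3": [None if math.isnan(x) else x for x in self.diff3],
            "terminal_ratio_5p": None
            if math.isnan(self.terminal_ratio_5p)
            else self.terminal_ratio_5p,
        }


def compare_profiles(ancient: DamageProfile, modern: DamageProfile) -> ProfileComparison:
    """Frequency-difference summary between two same-window profiles.

    A descriptive contrast (no hypothesis test): degraded material shows
    positive terminal differences against a modern control.
    """
    if ancient.window != modern.window:
        raise DamageError(
            f"window mismatch: {ancient.window} vs {modern.window}"
        )
    a5, m5 = ancient.f5.frequencies(), modern.f5.frequencies()
    a3, m3 = ancient.f3.frequencies(), modern.f3.frequencies()
    with np.errstate(invalid="ignore", divide="ignore"):
        if ancient.window and not (math.isnan(a5[0]) or math.isnan(m5[0])) and m5[0] > 0:
            ratio = float(a5[0] / m5[0])
        else:
            ratio = float("nan")
    return ProfileComparison(diff5=a5 - m5, diff3=a3 - m3, terminal_ratio_5p=ratio)


def fits_to_json(fits: dict[str, DecayFit], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh, indent=2)
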