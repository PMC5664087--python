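"""Per-run sequencing QC metrics and cross-run aggregation.

One sequencing run is summarised by the percentages of mitochondrial,
human-genome and unaligned reads, unique (duplicate-removed) read
counts, control-region read fraction, strand bias, coverage breadth at
a minimum depth of 2x, control-region depth statistics and read-length
statistics.  Cross-run aggregation reports the mean with both sample
(n-1) and population (n) standard deviations, because published summary
tables mix the two conventions between columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps

from .basecount import BaseCountMatrix, coverage_vector, strand_bias
from .mtref import CircularReference, Region, interval_overlaps_region, region_length

AVOGADRO = 6.022_140_76e23
#: Average molar mass of a double-stranded DNA base pair, g/mol.
DSDNA_G_PER_MOL_BP = 660.0


class MetricsError(ValueError):
    pass


@dataclass
class RunMetrics:
    """One run's summary row (Table-style numerical description)."""

    total_reads: int
    pct_mt_of_total: float  # gross: duplicates included
    pct_unique_mt_of_total: float
    n_unique_mt: int
    pct_cr_of_mt: float  # CR-overlapping mt reads / total mt reads
    pct_human_of_total: float
    pct_unaligned_of_total: float
    mean_strand_bias: float
    pct_mitogenome_cov2: float  # % reference positions with depth >= 2
    pct_cr_cov2: float
    cr_cov_min: float
    cr_cov_mean: float
    cr_cov_sd: float
    cr_cov_max: float
    rl_min: float
    rl_mean: float
    rl_sd: float
    rl_max: float
    rl_mean_aligned: float  # mt-labelled reads
    rl_mean_other: float  # non-mt reads

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class AggregateStats:
    """Mean and both standard-deviation conventions over run values."""

    mean: float
    sd_sample: float  # n-1 denominator
    sd_population: float  # n denominator
    n: int


@dataclass
class ReadLengthHistogram:
    """Counts of reads per observed read length (bp)."""

    bins: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def mean(self) -> float:
        if self.total == 0:
            return 0.0
        return sum(l * c for l, c in self.bins.items()) / self.total

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for length in sorted(self.bins):
                fh.write(f"{length}\t{self.bins[length]}\n")


def read_length_histogram(reads) -> ReadLengthHistogram:
    """Bin reads by full molecule length (soft clips included)."""
    bins: dict[int, int] = {}
    for read in reads:
        bins[read.read_length] = bins.get(read.read_length, 0) + 1
    return ReadLengthHistogram(bins=bins)


def _mean(values) -> float:
    values = list(values)
    return float(np.mean(values)) if values else 0.0


def _pct(num: int, denom: int) -> float:
    return 100.0 * num / denom if denom else 0.0


def compute_run_metrics(
    all_reads,
    filtered_mt_reads,
    matrix_all: BaseCountMatrix,
    matrix_unique: BaseCountMatrix,
    ref: CircularReference,
    cr_region: Region,
) -> RunMetrics:
    """Compute one run's metrics row.

    ``all_reads`` carries per-read labels (mt / human / unaligned /
    unknown); ``filtered_mt_reads`` are the quality-filtered,
    duplicate-marked mitochondrial reads from which ``matrix_all``
    (duplicates included) and ``matrix_unique`` (duplicates excluded)
    were built.  Coverage fields use the gross matrix.  Zero
    denominators yield 0, matching published rows for empty runs.
    """
    all_reads = list(all_reads)
    total = len(all_reads)
    n_mt = sum(1 for r in all_reads if r.label == "mt")
    n_human = sum(1 for r in all_reads if r.label == "human")
    n_unaligned = sum(1 for r in all_reads if r.label == "unaligned")
    unique_mt = [r for r in filtered_mt_reads if not r.duplicate]
    n_cr = sum(
        1
        for r in filtered_mt_reads
        if interval_overlaps_region(r.start, r.reference_end, cr_region, ref)
    )

    cr_depth = coverage_vector(matrix_all, cr_region).astype(float)
    full = Region(1, ref.length)
    mito_depth = coverage_vector(matrix_all, full)
    cr_len = region_length(cr_region, ref)

    lengths = np.array([r.read_length for r in all_reads], dtype=float)
    mt_lengths = [r.read_length for r in all_reads if r.label == "mt"]
    other_lengths = [r.read_length for r in all_reads if r.label != "mt"]

    return RunMetrics(
        total_reads=total,
        pct_mt_of_total=_pct(n_mt, total),
        pct_unique_mt_of_total=_pct(len(unique_mt), total),
        n_unique_mt=len(unique_mt),
        pct_cr_of_mt=_pct(n_cr, len(filtered_mt_reads)),
        pct_human_of_total=_pct(n_human, total),
        pct_unaligned_of_total=_pct(n_unaligned, total),
        mean_strand_bias=strand_bias(matrix_all, full),
        pct_mitogenome_cov2=_pct(int((mito_depth >= 2).sum()), ref.length),
        pct_cr_cov2=_pct(int((cr_depth >= 2).sum()), cr_len),
        cr_cov_min=float(cr_depth.min()) if cr_len else 0.0,
        cr_cov_mean=float(cr_depth.mean()) if cr_len else 0.0,
        cr_cov_sd=float(cr_depth.std()) if cr_len else 0.0,
        cr_cov_max=float(cr_depth.max()) if cr_len else 0.0,
        rl_min=float(lengths.min()) if total else 0.0,
        rl_mean=float(lengths.mean()) if total else 0.0,
        rl_sd=float(lengths.std()) if total else 0.0,
        rl_max=float(lengths.max()) if total else 0.0,
        rl_mean_aligned=_mean(mt_lengths),
        rl_mean_other=_mean(other_lengths),
    )


def aggregate(values, round_to: int | None = None) -> AggregateStats:
    """Mean and both SD conventions over per-run values.

    A single value yields SD 0 under both conventions.  ``round_to``
    rounds the reported statistics (half-up) for display; internal
    computation is never rounded.
    """
    values = [float(v) for v in values]
    if not values:
        raise MetricsError("aggregate of an empty list")
    arr = np.asarray(values)
    mean = float(arr.mean())
    if len(values) == 1:
        sd_s = sd_p = 0.0
    else:
        sd_s = float(arr.std(ddof=1))
        sd_p = float(arr.std(ddof=0))
    if round_to is not None:
        mean, sd_s, sd_p = (round_half_up(x, round_to) for x in (mean, sd_s, sd_p))
    return AggregateStats(mean=mean, sd_sample=sd_s, sd_population=sd_p, n=len(values))


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal round-half-up (what summary tables typically print)."""
    factor = 10.0**digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def pearson(x, y) -> float:
    """Product-moment correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MetricsError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise MetricsError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise MetricsError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


def copies_from_mass(
    mass_pg: float,
    length_bp: int,
    mass_per_bp: float = DSDNA_G_PER_MOL_BP,
    avogadro: float = AVOGADRO,
) -> float:
    """Molecule count of a dsDNA amplicon from its mass.

    N = m * N_A / (L * M) with the mass in grams, L the amplicon length
    in bp and M the average molar mass per base pair (default 660
    g/mol/bp).  Zero mass gives zero molecules; negative inputs and
    non-positive lengths are rejected.
    """
    if mass_pg < 0 or length_bp <= 0 or mass_per_bp <= 0:
        raise MetricsError("mass must be >= 0, length and molar mass > 0")
    return mass_pg * 1e-12 * avogadro / (length_bp * mass_per_bp)


def linguistic_complexity(seq: str, k_max: int = 3) -> float:
    """Sequence complexity: product over k of observed/possible k-mer counts.

    For k = 1..k_max the factor is (distinct observed k-mers) divided by
    min(4^k, |seq| - k + 1).  Low-complexity reads (homopolymers, di-
    and trimeric repeats) score far below random sequence of equal
    length.  Requires |seq| > k_max.
    """
    if k_max < 1:
        raise MetricsError("k_max must be >= 1")
    if len(seq) <= k_max:
        raise MetricsError(f"sequence length {len(seq)} <= k_max {k_max}")
    score = 1.0
    for k in range(1, k_max + 1):
        observed = len({seq[i : i + k] for i in range(len(seq) - k + 1)})
        possible = min(4**k, len(seq) - k + 1)
        score *= observed / possible
    return score


def aggregate_runs(metric_dicts: list[dict], round_to: int = 2) -> dict:
    """Aggregate a list of RunMetrics dicts field-wise.

    Returns {field: {mean, sd_sample, sd_population, n}} for every
    numeric field, at display rounding.
    """
    if not metric_dicts:
        raise MetricsError("no runs to aggregate")
    out: dict[str, dict] = {}
    for key in metric_dicts[0]:
        values = [d[key] for d in metric_dicts]
        if not all(isinstance(v, (int, float)) for v in values):
            continue
        agg = aggregate(values, round_to=round_to)
        out[key] = asdict(agg)
    return out
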