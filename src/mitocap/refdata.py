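"""Published control-run summary metrics for the PEC control-region assay.

These are the run-level summary values reported for the original
characterization of mtDNA control-region primer-extension-capture
sequencing: six positive-control runs (sheared high-quantity blood
DNA, sequenced over six months) and six negative-control runs
(no-primer, library-preparation and extraction blanks).  The raw reads
behind them were never deposited, so the per-run rows themselves are
inputs here, not something this package recomputes; they serve as a
fixed cross-check that :func:`mitocap.qcmetrics.aggregate` reproduces
the published mean-row summaries digit for digit, including the mixed
sample/population SD conventions those summaries used.
"""

from __future__ import annotations

#: Six positive-control runs.  Keys mirror RunMetrics field names.
POSITIVE_CONTROL_RUNS: tuple[dict, ...] = (
    {
        "sample": "PC1",
        "total_reads": 102_534,
        "pct_mt_of_total": 3.11,
        "pct_unique_mt_of_total": 1.57,
        "n_unique_mt": 1605,
        "pct_cr_of_mt": 67.66,
        "pct_human_of_total": 57.55,
        "pct_unaligned_of_total": 39.34,
        "mean_strand_bias": 0.43,
        "cr_cov_mean": 110.33,
        "cr_cov_sd": 27.13,
        "rl_mean": 148.20,
    },
    {
        "sample": "PC2",
        "total_reads": 233_078,
        "pct_mt_of_total": 3.50,
        "pct_unique_mt_of_total": 1.07,
        "n_unique_mt": 2495,
        "pct_cr_of_mt": 66.33,
        "pct_human_of_total": 56.08,
        "pct_unaligned_of_total": 40.42,
        "mean_strand_bias": 0.40,
        "cr_cov_mean": 176.01,
        "cr_cov_sd": 41.71,
        "rl_mean": 154.69,
    },
    {
        "sample": "PC3",
        "total_reads": 842_114,
        "pct_mt_of_total": 2.40,
        "pct_unique_mt_of_total": 0.40,
        "n_unique_mt": 3346,
        "pct_cr_of_mt": 61.78,
        "pct_human_of_total": 38.31,
        "pct_unaligned_of_total": 59.29,
        "mean_strand_bias": 0.39,
        "cr_cov_mean": 215.50,
        "cr_cov_sd": 54.49,
        "rl_mean": 150.84,
    },
    {
        "sample": "PC4",
        "total_reads": 125_099,
        "pct_mt_of_total": 3.22,
        "pct_unique_mt_of_total": 1.42,
        "n_unique_mt": 1777,
        "pct_cr_of_mt": 66.18,
        "pct_human_of_total": 54.03,
        "pct_unaligned_of_total": 42.75,
        "mean_strand_bias": 0.40,
        "cr_cov_mean": 114.85,
        "cr_cov_sd": 25.00,
        "rl_mean": 135.68,
    },
    {
        "sample": "PC5",
        "total_reads": 197_285,
        "pct_mt_of_total": 2.89,
        "pct_unique_mt_of_total": 1.11,
        "n_unique_mt": 2191,
        "pct_cr_of_mt": 66.77,
        "pct_human_of_total": 58.97,
        "pct_unaligned_of_total": 38.14,
        "mean_strand_bias": 0.40,
        "cr_cov_mean": 150.50,
        "cr_cov_sd": 37.15,
        "rl_mean": 146.81,
    },
    {
        "sample": "PC6",
        "total_reads": 348_593,
        "pct_mt_of_total": 3.87,
        "pct_unique_mt_of_total": 0.85,
        "n_unique_mt": 2957,
        "pct_cr_of_mt": 62.09,
        "pct_human_of_total": 63.09,
        "pct_unaligned_of_total": 33.04,
        "mean_strand_bias": 0.39,
        "cr_cov_mean": 191.57,
        "cr_cov_sd": 43.81,
        "rl_mean": 146.26,
    },
)

#: Six negative-control runs: total reads and reads aligning to the
#: mitogenome (at most a handful, in low-complexity repeats).
NEGATIVE_CONTROL_RUNS: tuple[dict, ...] = (
    {"sample": "NPC", "total_reads": 4_146, "n_mt_reads": 5},
    {"sample": "NTC-LP-1", "total_reads": 48_396, "n_mt_reads": 0},
    {"sample": "NTC-LP-2", "total_reads": 37_769, "n_mt_reads": 1},
    {"sample": "NTC-LP-3", "total_reads": 81_476, "n_mt_reads": 2},
    {"sample": "EX0-1", "total_reads": 31_886, "n_mt_reads": 0},
    {"sample": "EX0-2", "total_reads": 158_827, "n_mt_reads": 1},
)


def column(runs, key: str) -> list[float]:
    """Extract one numeric column from a run table."""
    return [r[key] for r in runs]
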