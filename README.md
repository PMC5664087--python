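# mitocap

Consensus haplotyping, QC metrics and damage profiling for
mitochondrial control-region capture sequencing of degraded samples.

## Who this is for

Forensic and ancient-DNA laboratories sequence the mitochondrial
control region (CR, positions 16024–576 across the origin of the
16,569 bp circular mitogenome) from highly compromised material —
rootless hair shafts, old bone and teeth — using capture enrichment of
very short fragments followed by massively parallel sequencing.
`mitocap` is the analysis side of that workflow: it consumes reads
aligned to the circular mitochondrial reference (SAM/BAM) and produces
a forensic-style consensus haplotype, run-level QC metrics, and
terminal-deamination damage profiles, plus a fully seeded simulator of
degraded capture libraries so the entire pipeline can be exercised and
validated without any external data.

## What it computes

- **Filtering.** Keep aligned reads with mapping quality > 30 and an
  aligned-to-soft-clipped base ratio > 75%; reads covering position 1
  or 16569 are exempt from the ratio test, because fragments spanning
  the circular origin necessarily arrive soft-clipped against the
  linearised reference.
- **Duplicate marking.** Group by (unclipped 5′ coordinate, strand);
  the highest base-quality-sum read survives.
- **Base counts.** A position × strand × {A,C,G,T,N,DEL} pileup tensor
  over the circular genome.
- **Consensus haplotype.** At each CR position with depth ≥ 2, a
  difference to the reference is called when the divergent majority
  base reaches support ≥ 75% of reads; sub-threshold majorities are
  reported but never called (point heteroplasmy is disregarded), and
  poly-C tracts (310–316 by default) are excluded. Output is the
  standard difference notation, e.g. `73G 263T 16210T`.
- **Run metrics.** Total reads, gross and unique mitochondrial-read
  percentages, CR-read fraction, human/unaligned percentages, strand
  bias, coverage breadth (min 2×), CR depth statistics, read-length
  statistics — and cross-run aggregation reporting both the n−1 and n
  standard-deviation conventions.
- **Damage.** Empirical C→T (5′) / G→A (3′) misincorporation
  frequencies by distance from the molecule end, and a weighted
  least-squares fit of f(i) = a·d^i whose amplitude separates degraded
  from modern material.
- **Simulation.** Truncated-normal fragment lengths, planted
  haplotypes, terminal damage, sequencing error, Poisson PCR
  duplication and unalignable background, all with truth records and
  truth SAM output.

See `docs/methods.md` for conventions, assumptions and limitations.

## Worked example

The one-command demo simulates a capture-like run on a bundled
synthetic circular reference (2,500 template fragments, 90%
background, five planted CR substitutions, terminal damage amplitude
0.25 with decay 0.6, 1% sequencing error, Poisson duplication) and
runs the full pipeline on it:

```sh
mitocap demo --outdir demo_out --seed 42
```

prints

```json
{
  "planted_haplotype": "73G 263T 489C 16210T 16320C",
  "called_haplotype": "73G 263T 489C 16210T 16320C",
  "recovered": true,
  "damage_amplitude_truth": 0.25,
  "damage_amplitude_fit": 0.2618489488867567,
  "outdir": "demo_out"
}
```

and `demo_out/summary.txt` reads

```
mitocap pipeline summary
========================
reads in: 7434  kept: 687  discarded: 6747
unique mt reads: 234
consensus haplotype: 73G 263T 489C 16210T 16320C
mean CR coverage: 54.85 (SD 22.98, min 0, max 98)
CR coverage breadth (min 2x): 99.38%
mean strand bias: 0.573
mean read length: 111.36 bp
damage fit 5p: amplitude 0.2618, decay 0.6623
damage fit 3p: amplitude 0.1442, decay 0.7273
```

Reading this: of 7,434 simulated reads, 687 aligned mitochondrial
reads survive filtering (the rest are unalignable/nuclear background or
fail the quality filters), 234 remain after duplicate removal, and the
consensus over the 1,122 CR positions recovers the five planted
differences exactly. The fitted 5′ damage amplitude (0.26) recovers
the simulated deamination level (0.25); the 3′ estimate is noisier
because guanine opportunities are scarcer at this depth. The bundle
also contains the filter report, both pileup TSVs, the per-position
haplotype table, run-metrics JSON, damage profile TSV and read-length
histogram.

The same stages are available individually (`mitocap simulate`,
`filter`, `pileup`, `call`, `metrics`, `aggregate`, `damage`, `run`)
and as library functions (`mitocap.filter_reads`,
`mitocap.call_consensus`, ...).

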