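"""Synthetic degraded-read simulator with truth output.

Emulates the statistical structure of a primer-extension-capture
library sequenced from a degraded sample: short fragments (truncated-
normal lengths), a planted haplotype, position-dependent terminal
deamination (C->T in the molecule 5' frame, G->A in the 3' frame, with
probability amplitude * decay^i at distance i from the end), uniform
per-base sequencing error, Poisson PCR duplication, and non-target
background reads of random composition.  Every read carries a truth
record, so filtering, duplicate marking, base counting, consensus
calling, QC metrics and damage profiling all have an exact oracle.

Defaults reproduce the conditions observed in positive-control capture
runs of such assays: ~3% of reads mitochondrial (97% background),
~65% of mitochondrial reads on the control-region target, mean
fragment length ~147 bp (SD 50, minimum 30), background read length
~52 bp, and roughly one third of mitochondrial reads unique after
duplicate marking (Poisson duplication rate 2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pysam

from .mtref import CR_END, CR_START, CircularReference, Region, region_positions, revcomp
from .readfilter import FORWARD, REVERSE, AlignedRead

BASES4 = np.array(list("ACGT"), dtype="U1")


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; all randomness flows from ``seed``."""

    seed: int = 1
    n_fragments: int = 1000  # template molecules before PCR duplication
    haplotype: tuple[tuple[int, str], ...] = ()  # planted substitutions
    frag_len_mean: float = 147.08  # bp, mitochondrial fragments
    frag_len_sd: float = 50.0
    frag_len_min: int = 30  # truncation
    target_region: Region = field(default_factory=lambda: Region(CR_START, CR_END))
    off_target_fraction: float = 0.35  # mt fragments from the whole mitogenome
    damage_amplitude: float = 0.0  # terminal deamination probability
    damage_decay: float = 0.5  # per-position geometric factor
    seq_error_rate: float = 0.01  # per-base substitution probability
    duplication_rate: float = 2.0  # mean extra PCR copies (Poisson)
    duplicate_fresh_errors: bool = False  # fresh error draws per copy
    background_fraction: float = 0.97  # non-mitochondrial reads
    background_len_mean: float = 52.0
    background_len_sd: float = 25.0
    background_human_fraction: float = 0.565  # label channel only
    qual_score: int = 30

    def __post_init__(self) -> None:
        for name in (
            "off_target_fraction",
            "damage_amplitude",
            "damage_decay",
            "seq_error_rate",
            "background_fraction",
            "background_human_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimError(f"{name}={v} outside [0,1]")
        if self.frag_len_min < 1 or self.n_fragments < 0:
            raise SimError("frag_len_min >= 1 and n_fragments >= 0 required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_region"] = f"{self.target_region.start}-{self.target_region.end}"
        d["haplotype"] = [[p, b] for p, b in self.haplotype]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class TruthRecord:
    """Ground truth for one simulated read (the oracle channel)."""

    name: str
    origin: str  # mt_target | mt_offtarget | background
    start: int | None  # 1-based molecule start on the reference
    end: int | None  # 1-based circular end position
    length: int
    strand: str | None
    is_duplicate_of: str | None
    damage_events: list[tuple[int, str]]  # (read offset, "CT" | "GA")
    error_events: list[tuple[int, str, str]]  # (read offset, from, to)
    label: str  # mt | human | unaligned


@dataclass
class SimRead:
    """One simulated read: molecule-frame sequence plus its truth."""

    name: str
    seq: str  # 5'->3' as sequenced (FASTQ orientation)
    truth: TruthRecord


@dataclass
class SimResult:
    reads: list[SimRead]
    config: SimConfig
    ref_name: str

    @property
    def n_duplicates(self) -> int:
        return sum(1 for r in self.reads if r.truth.is_duplicate_of is not None)

    def labels(self) -> dict[str, str]:
        return {r.name: r.truth.label for r in self.reads}


def _truncated_length(rng, mean: float, sd: float, minimum: int, maximum: int) -> int:
    """Integer fragment length from normal(mean, sd) conditioned on >= minimum."""
    for _ in range(10_000):
        x = int(round(rng.normal(mean, sd)))
        if minimum <= x <= maximum:
            return x
    raise SimError("fragment-length sampling failed; check mean/sd/min")


def apply_haplotype(ref: CircularReference, haplotype) -> str:
    """Substitute the planted variants into the reference sequence."""
    seq = list(ref.sequence)
    for pos, base in haplotype:
        if not 1 <= pos <= ref.length:
            raise SimError(f"planted variant position {pos} outside reference")
        if base not in "ACGT":
            raise SimError(f"planted variant base {base!r} not a substitution")
        if ref.base(pos) == "N":
            raise SimError(f"planted variant at reference N (position {pos})")
        if ref.base(pos) == base:
            raise SimError(f"planted variant {pos}{base} equals the reference")
        seq[pos - 1] = base
    return "".join(seq)


def _damage_molecule(mol: np.ndarray, amp: float, decay: float, rng):
    """Apply terminal deamination in molecule frame; returns events."""
    events: list[tuple[int, str]] = []
    if amp <= 0:
        return events
    L = len(mol)
    p = amp * decay ** np.arange(L)
    hit5 = (mol == "C") & (rng.random(L) < p)
    hit3 = (mol == "G") & (rng.random(L) < p[::-1])
    for i in np.nonzero(hit5)[0]:
        mol[i] = "T"
        events.append((int(i), "CT"))
    for i in np.nonzero(hit3)[0]:
        mol[i] = "A"
        events.append((int(i), "GA"))
    return events


def _sequencing_errors(mol: np.ndarray, rate: float, rng):
    """Uniform substitution errors; returns events (offset, from, to)."""
    events: list[tuple[int, str, str]] = []
    if rate <= 0:
        return events
    L = len(mol)
    hits = np.nonzero(rng.random(L) < rate)[0]
    for i in hits:
        old = str(mol[i])
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(3)]
        mol[i] = new
        events.append((int(i), old, new))
    return events


def simulate(config: SimConfig, ref: CircularReference) -> SimResult:
    """Generate reads and truth records; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    config.target_region.validate(ref)
    mutated = apply_haplotype(ref, config.haplotype)
    doubled = mutated + mutated
    target_pos = np.array(region_positions(config.target_region, ref), dtype=np.int64)
    max_len = ref.length

    reads: list[SimRead] = []
    for idx in range(config.n_fragments):
        name = f"frag{idx:06d}"
        if rng.random() < config.background_fraction:
            label = (
                "human"
                if rng.random() < config.background_human_fraction
                else "unaligned"
            )
            # human-genome background shows mt-like fragment lengths;
            # only the unalignable fraction is skewed short
            if label == "human":
                len_mean, len_sd = config.frag_len_mean, config.frag_len_sd
            else:
                len_mean, len_sd = config.background_len_mean, config.background_len_sd
            length = _truncated_length(
                rng, len_mean, len_sd, config.frag_len_min, max_len
            )
            seq = "".join(rng.choice(BASES4, size=length))
            truth = TruthRecord(
                name=name,
                origin="background",
                start=None,
                end=None,
                length=length,
                strand=None,
                is_duplicate_of=None,
                damage_events=[],
                error_events=[],
                label=label,
            )
            parent = SimRead(name=name, seq=seq, truth=truth)
        else:
            if rng.random() < config.off_target_fraction:
                start = int(rng.integers(1, ref.length + 1))
                origin = "mt_offtarget"
            else:
                start = int(target_pos[rng.integers(len(target_pos))])
                origin = "mt_target"
            length = _truncated_length(
                rng,
                config.frag_len_mean,
                config.frag_len_sd,
                config.frag_len_min,
                max_len,
            )
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            ref_oriented = doubled[start - 1 : start - 1 + length]
            molecule = ref_oriented if strand == FORWARD else revcomp(ref_oriented)
            mol = np.array(list(molecule), dtype="U1")
            damage_events = _damage_molecule(
                mol, config.damage_amplitude, config.damage_decay, rng
            )
            error_events = _sequencing_errors(mol, config.seq_error_rate, rng)
            end = (start + length - 2) % ref.length + 1
            truth = TruthRecord(
                name=name,
                origin=origin,
                start=start,
                end=end,
                length=length,
                strand=strand,
                is_duplicate_of=None,
                damage_events=damage_events,
                error_events=error_events,
                label="mt",
            )
            parent = SimRead(name=name, seq="".join(mol), truth=truth)
        reads.append(parent)

        n_copies = (
            int(rng.poisson(config.duplication_rate))
            if config.duplication_rate > 0
            else 0
        )
        for j in range(n_copies):
            dup_name = f"{name}.dup{j + 1}"
            if config.duplicate_fresh_errors and parent.truth.origin != "background":
                # re-sequence the damaged (pre-error) molecule
                base_mol = np.array(list(parent.seq), dtype="U1")
                for off, old, _new in parent.truth.error_events:
                    base_mol[off] = old
                err = _sequencing_errors(base_mol, config.seq_error_rate, rng)
                dup_seq = "".join(base_mol)
                dup_errors = err
            else:
                dup_seq = parent.seq
                dup_errors = list(parent.truth.error_events)
            truth = TruthRecord(
                name=dup_name,
                origin=parent.truth.origin,
                start=parent.truth.start,
                end=parent.truth.end,
                length=parent.truth.length,
                strand=parent.truth.strand,
                is_duplicate_of=parent.name,
                damage_events=list(parent.truth.damage_events),
                error_events=dup_errors,
                label=parent.truth.label,
            )
            reads.append(SimRead(name=dup_name, seq=dup_seq, truth=truth))

    return SimResult(reads=reads, config=config, ref_name=ref.name)


# ---------------------------------------------------------------------------
# Truth alignment emission (bypasses external aligners)


def _truth_cigar_and_bases(read: SimRead, ref_length: int) -> tuple[list, str]:
    """Reference-oriented bases and truth CIGAR for an mt-origin read.

    Fragments spanning the circular origin are emitted against the
    linear reference as an aligned arm up to position L followed by a
    soft-clipped arm, which is exactly how origin-spanning molecules
    arrive from a linear aligner (and what the clip-ratio exemption is
    for).
    """
    t = read.truth
    bases = read.seq if t.strand == FORWARD else revcomp(read.seq)
    arm = min(t.length, ref_length - t.start + 1)
    if arm == t.length:
        cigar = [("M", t.length)]
    else:
        cigar = [("M", arm), ("S", t.length - arm)]
    return cigar, bases


def to_aligned_reads(result: SimResult, ref: CircularReference, mapq: int = 60):
    """Convert simulated reads to :class:`AlignedRead` records in memory.

    Mirrors :func:`emit_truth_sam` exactly (same coordinates, CIGARs and
    reference-oriented bases) without touching disk.
    """
    out: list[AlignedRead] = []
    q = result.config.qual_score
    for read in result.reads:
        t = read.truth
        if t.origin == "background":
            out.append(
                AlignedRead(
                    name=read.name,
                    aligned=False,
                    start=None,
                    mapq=0,
                    strand=FORWARD,
                    cigar=[],
                    bases=read.seq,
                    quals=[q] * t.length,
                    label=t.label,
                )
            )
            continue
        cigar, bases = _truth_cigar_and_bases(read, ref.length)
        out.append(
            AlignedRead(
                name=read.name,
                aligned=True,
                start=t.start,
                mapq=mapq,
                strand=t.strand,
                cigar=cigar,
                bases=bases,
                quals=[q] * t.length,
                label=t.label,
            )
        )
    return out


def emit_truth_sam(result: SimResult, ref: CircularReference, path, mapq: int = 60) -> None:
    """Write truth alignments as SAM/BAM (background reads unmapped)."""
    from .readfilter import write_sam

    write_sam(to_aligned_reads(result, ref, mapq=mapq), ref, path)


def write_fastq(result: SimResult, path) -> None:
    q = result.config.qual_score
    with open(path, "w") as fh:
        for read in result.reads:
            fh.write(f"@{read.name}\n{read.seq}\n+\n{chr(q + 33) * len(read.seq)}\n")


def write_truth_table(result: SimResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "name\torigin\tstart\tend\tlength\tstrand\tis_duplicate_of\t"
            "n_damage\tn_errors\tlabel\n"
        )
        for read in result.reads:
            t = read.truth
            fh.write(
                f"{t.name}\t{t.origin}\t{t.start or '.'}\t{t.end or '.'}\t"
                f"{t.length}\t{t.strand or '.'}\t{t.is_duplicate_of or '.'}\t"
                f"{len(t.damage_events)}\t{len(t.error_events)}\t{t.label}\n"
            )


def write_labels(result: SimResult, path) -> None:
    """Two-column TSV (read, label) consumed by the metrics stage."""
    with open(path, "w") as fh:
        for name, label in result.labels().items():
            fh.write(f"{name}\t{label}\n")
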