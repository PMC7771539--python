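"""Synthetic competition experiments and amplicon sequencing reads.

This module makes the whole pipeline testable end to end without a
sequencer: it grows a barcoded population deterministically, optionally
squeezes it through a multinomial bottleneck (as happens at host
colonization), builds the dual-indexed amplicon each strain would yield,
and writes FASTQ reads with a configurable per-base substitution error
rate.  True per-strain read counts are returned alongside the reads so
the counting module can be checked against a known answer.

It also houses two bits of bench arithmetic used when setting up a
competition: the equal-OD mixing volume and the number of doublings
implied by serial dilution and regrowth.
"""

from __future__ import annotations

import gzip
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constructs import ScarSequence, revcomp

__all__ = [
    "mix_volume",
    "generations_from_dilution",
    "CompetitionScenario",
    "simulate_competition",
    "AmpliconDesign",
    "Amplicon",
    "build_amplicon",
    "SequencingScenario",
    "SimulatedSample",
    "simulate_reads",
    "write_fastq",
    "write_truth_tsv",
    "write_sample_sheet",
]


def mix_volume(od600: float) -> float:
    """Volume (µL) of a culture to pool for equal-cell mixing.

    volume = (1.25 / OD600) × 50, i.e. 50 µL of an OD 1.25 culture's
    worth of cells regardless of the culture's actual density.
    """
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return (1.25 / od600) * 50


def generations_from_dilution(dilution_factor: float, rounds: int = 1) -> float:
    """Doublings implied by serial dilution with regrowth to starting density.

    Each round of diluting 1:d and regrowing to the pre-dilution density
    is log2(d) doublings; e.g. two rounds of 1:181 give ~15 generations.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    if rounds < 1:
        raise ValueError("rounds must be a positive integer")
    return rounds * math.log2(dilution_factor)


# ---------------------------------------------------------------------------
# Competition dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompetitionScenario:
    """A pooled competition: input frequencies, fitness, generations.

    ``fitness`` is each strain's multiplicative growth factor per
    generation relative to absolute time (a neutral strain has fitness
    1); ``bottleneck`` is an optional population size for a single
    multinomial subsampling event.
    """

    strains: tuple[str, ...]
    input_freqs: tuple[float, ...]
    fitness: tuple[float, ...]
    generations: float
    bottleneck: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.strains)
        if len(self.input_freqs) != n or len(self.fitness) != n:
            raise ValueError("strains, input_freqs and fitness must align")
        if any(f < 0 for f in self.input_freqs):
            raise ValueError("input frequencies must be nonnegative")
        if abs(sum(self.input_freqs) - 1.0) > 1e-12:
            raise ValueError("input frequencies must sum to 1")
        if self.generations < 0:
            raise ValueError("generations must be nonnegative")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValueError("bottleneck must be a positive integer")

    @classmethod
    def equal_mix(
        cls,
        strains: Sequence[str],
        fitness: Sequence[float],
        generations: float,
        bottleneck: int | None = None,
        seed: int = 0,
    ) -> "CompetitionScenario":
        """1-to-1 mixing of all strains, as produced by equal-OD pooling."""
        n = len(strains)
        return cls(
            strains=tuple(strains),
            input_freqs=tuple([1.0 / n] * n),
            fitness=tuple(fitness),
            generations=generations,
            bottleneck=bottleneck,
            seed=seed,
        )


def simulate_competition(scenario: CompetitionScenario) -> np.ndarray:
    """Output strain frequencies after deterministic exponential growth.

    f_i ∝ input_i × fitness_i^generations, renormalized.  If a
    bottleneck is set, a single seeded multinomial draw of that size is
    taken and the counts renormalized.  Deterministic under fixed seed.
    """
    freqs = np.asarray(scenario.input_freqs, dtype=float)
    growth = np.asarray(scenario.fitness, dtype=float) ** scenario.generations
    weighted = freqs * growth
    total = weighted.sum()
    if total <= 0:
        raise ValueError("all strain frequencies are zero after growth")
    out = weighted / total
    if scenario.bottleneck is not None:
        rng = np.random.default_rng(scenario.seed)
        counts = rng.multinomial(scenario.bottleneck, out)
        out = counts / counts.sum()
    return out


# ---------------------------------------------------------------------------
# Amplicon construction
# ---------------------------------------------------------------------------

# Illumina flow-cell adapters (public sequences).
_P5 = "AATGATACGGCGACCACCGAGATCTACAC"
_P7 = "CAAGCAGAAGACGGCATACGAGAT"


@dataclass(frozen=True)
class AmpliconDesign:
    """Fixed parts of the dual-indexed BarSeq amplicon.

    ``head`` and ``tail`` stand in for the locus-specific primer
    segments between the index and the scar; they are synthetic
    placeholder sequences, not any published primer.  With 8-nt indexes
    and the 138-bp scar the default amplicon is 231 bp.
    """

    p5: str = _P5
    p7: str = _P7
    head: str = "TCGTCGGCAGCG"  # synthetic locus-specific head, 12 nt
    tail: str = "GTCTCGTGGGCT"  # synthetic locus-specific tail, 12 nt


DEFAULT_AMPLICON_DESIGN = AmpliconDesign()


@dataclass(frozen=True)
class Amplicon:
    """One strain's sequencing template with component layout intervals."""

    seq: str
    layout: dict[str, tuple[int, int]]

    def component(self, name: str) -> str:
        a, b = self.layout[name]
        return self.seq[a:b]

    def __len__(self) -> int:
        return len(self.seq)


def build_amplicon(
    scar: ScarSequence,
    i5: str,
    i7: str,
    design: AmpliconDesign = DEFAULT_AMPLICON_DESIGN,
) -> Amplicon:
    """Concatenate P5-i5-head-scar-tail-i7'-P7' into a sequencing template.

    The scar fragment carries the spacer + barcode + RL, so the barcode
    is recoverable from a read traversing the amplicon.  The i7 index
    and P7 adapter appear reverse-complemented on the top strand.
    """
    if scar.kind != "bar":
        raise ValueError("amplicons are built from the unmarked bar scar")
    for label, val in (("i5", i5), ("i7", i7)):
        if not val:
            raise ValueError(f"missing {label} index sequence")
    parts = [
        ("P5", design.p5),
        ("i5", i5),
        ("head", design.head),
        ("scar", scar.seq),
        ("tail", design.tail),
        ("i7_rc", revcomp(i7)),
        ("P7_rc", revcomp(design.p7)),
    ]
    layout: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, s in parts:
        layout[name] = (pos, pos + len(s))
        pos += len(s)
    return Amplicon(seq="".join(s for _, s in parts), layout=layout)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_MIN_READ_LENGTH = 54  # spacer (18) + barcode (18) + right flank (18)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SequencingScenario:
    """Read-generation settings for one sample."""

    reads_per_sample: int
    read_length: int = 250
    substitution_rate: float = 0.0
    revcomp_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be nonnegative")
        if self.read_length < _MIN_READ_LENGTH:
            raise ValueError(
                f"read_length must be >= {_MIN_READ_LENGTH} to span"
                " spacer + barcode + right flank"
            )
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0 <= self.revcomp_fraction <= 1:
            raise ValueError("revcomp_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedSample:
    """Reads for one sample plus the per-strain truth counts."""

    reads: tuple[tuple[str, str], ...]  # (read name, sequence)
    truth_counts: dict[str, int]


def _mutate(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions to a (n_reads, read_len) uint8 array."""
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    # Replace each hit base by one of the three other bases, uniformly.
    current = reads[mask]
    offset = rng.integers(1, 4, size=n_err)
    idx = np.searchsorted(_BASES, current)
    reads[mask] = _BASES[(idx + offset) % 4]
    return reads


def simulate_reads(
    abundances: Mapping[str, float] | Mapping[str, int],
    amplicons: Mapping[str, Amplicon | str],
    scenario: SequencingScenario,
) -> SimulatedSample:
    """Sample reads from strain amplicons and apply sequencing error.

    ``abundances`` maps strain → relative frequency (drawn multinomially
    to ``reads_per_sample`` reads) or strain → exact integer read count.
    Each read is the first ``read_length`` nt of its amplicon (the whole
    amplicon if shorter), with i.i.d. substitutions at
    ``substitution_rate`` and a seeded fraction of reads emitted as
    reverse complements.  Read order is a seeded permutation, so output
    is byte-identical for identical inputs and seeds.
    """
    strains = list(abundances)
    if set(strains) - set(amplicons):
        missing = sorted(set(strains) - set(amplicons))
        raise ValueError(f"no amplicon for strain(s): {missing}")
    rng = np.random.default_rng(scenario.seed)

    values = np.asarray([abundances[s] for s in strains], dtype=float)
    if np.all(values == np.round(values)) and values.sum() > 1.5:
        counts = values.astype(int)
    else:
        probs = values / values.sum()
        counts = rng.multinomial(scenario.reads_per_sample, probs)
    truth = {s: int(c) for s, c in zip(strains, counts)}

    chunks: list[np.ndarray] = []
    for strain, n in zip(strains, counts):
        if n == 0:
            continue
        amp = amplicons[strain]
        template = amp.seq if isinstance(amp, Amplicon) else amp
        read = template[: scenario.read_length]
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        chunks.append(np.tile(arr, (n, 1)))

    names: list[str] = []
    seqs: list[str] = []
    if chunks:
        all_seqs: list[str] = []
        for block in chunks:
            block = _mutate(np.ascontiguousarray(block), scenario.substitution_rate, rng)
            if scenario.revcomp_fraction > 0:
                flip = rng.random(block.shape[0]) < scenario.revcomp_fraction
            else:
                flip = np.zeros(block.shape[0], dtype=bool)
            for i in range(block.shape[0]):
                s = block[i].tobytes().decode()
                all_seqs.append(revcomp(s) if flip[i] else s)
        order = rng.permutation(len(all_seqs))
        seqs = [all_seqs[i] for i in order]
        names = [f"read_{i + 1:07d}" for i in range(len(seqs))]

    return SimulatedSample(
        reads=tuple(zip(names, seqs)),
        truth_counts=truth,
    )


def write_fastq(sample: SimulatedSample, path: str | Path, quality_char: str = "I") -> None:
    """Write reads as 4-line FASTQ (gzipped if the path ends in .gz).

    Quality strings are constant placeholders; quality is not used
    downstream.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in sample.reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth_tsv(
    truths: Mapping[str, Mapping[str, int]], path: str | Path
) -> None:
    """Write true per-strain read counts, one row per (sample, strain)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tstrain\tcount\n")
        for sample_name in truths:
            for strain, count in truths[sample_name].items():
                fh.write(f"{sample_name}\t{strain}\t{count}\n")


def write_sample_sheet(
    rows: Sequence[tuple[str, str, str, str]], path: str | Path
) -> None:
    """Write a sample sheet: sample, role (input/output), replicate group, FASTQ path."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\trole\treplicate_group\tfastq\n")
        for sample_name, role, group, fastq in rows:
            fh.write(f"{sample_name}\t{role}\t{group}\t{fastq}\n")
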