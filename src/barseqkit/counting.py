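"""Flank-anchored barcode counting from amplicon FASTQ reads.

Each read is scanned for the fixed left flank (the 18-nt spacer) and
right flank (the first 18 nt of the right linker) with exactly 18 nt
between them — the candidate barcode.  Candidates are looked up in the
strain barcode library by exact match; hits increment the strain's
count, misses fall into the reserved ``_other`` row, and reads without
resolvable flanks are tallied only in the per-sample read total.  The
result is an integer counts table, strains (+ ``_other``) × samples,
satisfying per-sample conservation:

    sum(strain counts) + _other == reads_with_flanks <= reads_total
"""

from __future__ import annotations

import gzip
import re
from collections.abc import Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcodes import BARCODE_LENGTH, RESERVED_STRAIN_NAME, BarcodeLibrary
from .constructs import RIGHT_FLANK, SPACER_SEQUENCE

__all__ = [
    "FlankPattern",
    "CountsTable",
    "SampleSpec",
    "extract_candidate_barcode",
    "classify_read",
    "count_sample",
    "count_samples",
    "merge_counts",
    "read_sample_sheet",
    "MalformedFastqError",
]


@dataclass(frozen=True)
class FlankPattern:
    """The fixed sequences anchoring barcode extraction.

    Defaults are the scar's spacer (left) and the first 18 nt of the
    right linker (right).  ``max_flank_mismatches`` allows that many
    substitutions in *each* flank (0 = exact literal match);
    ``search_revcomp`` additionally searches the reverse complement of a
    read when the forward orientation yields nothing.
    """

    left: str = SPACER_SEQUENCE
    right: str = RIGHT_FLANK
    barcode_len: int = BARCODE_LENGTH
    max_flank_mismatches: int = 0
    search_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.max_flank_mismatches < 0:
            raise ValueError("max_flank_mismatches must be nonnegative")
        if not self.left or not self.right:
            raise ValueError("both flanks must be nonempty")

    @property
    def regex(self) -> re.Pattern[str]:
        return re.compile(
            re.escape(self.left)
            + f"([ACGTN]{{{self.barcode_len}}})"
            + re.escape(self.right)
        )


def _mismatches_at(seq: str, pos: int, probe: str, budget: int) -> bool:
    """True if seq[pos:pos+len(probe)] matches probe with <= budget mismatches."""
    if pos + len(probe) > len(seq):
        return False
    mm = 0
    for a, b in zip(seq[pos : pos + len(probe)], probe):
        if a != b:
            mm += 1
            if mm > budget:
                return False
    return True


def _search_one_strand(seq: str, pattern: FlankPattern) -> str | None:
    if pattern.max_flank_mismatches == 0:
        m = pattern.regex.search(seq)
        return m.group(1) if m else None
    budget = pattern.max_flank_mismatches
    ll, bl, rl = len(pattern.left), pattern.barcode_len, len(pattern.right)
    for i in range(len(seq) - (ll + bl + rl) + 1):
        if _mismatches_at(seq, i, pattern.left, budget) and _mismatches_at(
            seq, i + ll + bl, pattern.right, budget
        ):
            return seq[i + ll : i + ll + bl]
    return None


def extract_candidate_barcode(
    read: str, pattern: FlankPattern = FlankPattern()
) -> str | None:
    """Pull the 18-nt candidate barcode out of a read, if present.

    Returns the window between the first left-flank match and an
    immediately following right-flank match (the window must be exactly
    ``barcode_len``).  If nothing is found forward and
    ``search_revcomp`` is set, the reverse complement of the read is
    searched.  Absence yields ``None``, never an exception.
    """
    read = read.upper()
    hit = _search_one_strand(read, pattern)
    if hit is None and pattern.search_revcomp:
        hit = _search_one_strand(reverse_complement(read), pattern)
    return hit


def classify_read(
    candidate: str | None, library: BarcodeLibrary
) -> str | None:
    """Map a candidate barcode to a strain name, ``_other``, or None.

    Exact-match lookup: a library barcode returns its strain; any other
    candidate (including ones containing N) returns the reserved
    ``_other`` name; an unextractable read (candidate None) returns
    None and is excluded from the counts table, contributing only to
    the sample's total read count.
    """
    if candidate is None:
        return None
    return library.barcode_to_strain().get(candidate, RESERVED_STRAIN_NAME)


class MalformedFastqError(ValueError):
    """A FASTQ stream failed to parse; carries the failing record index."""

    def __init__(self, path: str, record_index: int, reason: str):
        self.path = path
        self.record_index = record_index
        super().__init__(
            f"{path}: malformed FASTQ at record {record_index}: {reason}"
        )


def _iter_fastq(path: str | Path) -> Iterator[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    try:
        with opener(path, "rt") as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                n += 1
                yield seq
    except ValueError as exc:
        raise MalformedFastqError(str(path), n + 1, str(exc)) from exc


@dataclass
class SampleColumn:
    """Counts for one sample plus its read accounting."""

    counts: dict[str, int]
    reads_total: int

    @property
    def reads_with_flanks(self) -> int:
        return sum(self.counts.values())


def count_sample(
    fastq_paths: str | Path | Sequence[str | Path],
    library: BarcodeLibrary,
    pattern: FlankPattern = FlankPattern(),
) -> SampleColumn:
    """Count barcode hits in one sample's FASTQ file(s).

    Streams records (constant memory in the number of reads); plain and
    gzipped FASTQ both accepted.  Reads with multiple candidate windows
    are counted once, at the first window.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    lookup = library.barcode_to_strain()
    counts = {name: 0 for name in library.strains}
    counts[RESERVED_STRAIN_NAME] = 0
    total = 0
    for path in fastq_paths:
        for seq in _iter_fastq(path):
            total += 1
            candidate = extract_candidate_barcode(seq, pattern)
            if candidate is None:
                continue
            counts[lookup.get(candidate, RESERVED_STRAIN_NAME)] += 1
    return SampleColumn(counts=counts, reads_total=total)


@dataclass
class CountsTable:
    """Strains (+ ``_other``) × samples integer matrix with read accounting.

    ``df`` rows are ordered as in the library followed by ``_other``;
    ``reads_total`` records every read seen per sample, including those
    without resolvable flanks.
    """

    df: pd.DataFrame
    reads_total: pd.Series

    def __post_init__(self) -> None:
        if RESERVED_STRAIN_NAME not in self.df.index:
            raise ValueError(f"counts table must contain a {RESERVED_STRAIN_NAME} row")
        if (self.df.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.reads_total = self.reads_total.reindex(self.df.columns)
        bad = self.df.sum(axis=0) > self.reads_total
        if bad.any():
            raise ValueError(
                "reads_with_flanks exceeds reads_total for sample(s): "
                + ", ".join(self.df.columns[bad])
            )

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def strains(self) -> list[str]:
        return [s for s in self.df.index if s != RESERVED_STRAIN_NAME]

    @property
    def reads_with_flanks(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        """Write the matrix as TSV; optional ``#``-prefixed header lines."""
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("strain\t" + "\t".join(self.df.columns) + "\n")
            for strain in self.df.index:
                row = "\t".join(str(int(v)) for v in self.df.loc[strain])
                fh.write(f"{strain}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountsTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df = df.astype(int)
        # reads_total is not stored in the matrix; the flank-bearing
        # reads (column sums) are a lower bound.
        return cls(df=df, reads_total=df.sum(axis=0))


def count_samples(
    samples: dict[str, Sequence[str | Path]],
    library: BarcodeLibrary,
    pattern: FlankPattern = FlankPattern(),
) -> CountsTable:
    """Count every sample and assemble the full counts table."""
    columns: dict[str, SampleColumn] = {
        name: count_sample(paths, library, pattern)
        for name, paths in samples.items()
    }
    index = library.strains + [RESERVED_STRAIN_NAME]
    df = pd.DataFrame(
        {name: [col.counts[s] for s in index] for name, col in columns.items()},
        index=index,
        dtype=int,
    )
    totals = pd.Series(
        {name: col.reads_total for name, col in columns.items()}, dtype=int
    )
    return CountsTable(df=df, reads_total=totals)


def merge_counts(
    table: CountsTable, replicate_map: dict[str, Sequence[str]]
) -> CountsTable:
    """Sum technical replicates into one column per biological sample.

    ``replicate_map`` maps merged sample name → list of existing
    columns.  Conservation is preserved: merged totals are the sums of
    the members' totals.
    """
    for group, members in replicate_map.items():
        missing = [m for m in members if m not in table.df.columns]
        if missing:
            raise KeyError(
                f"replicate group {group!r} references missing column(s): {missing}"
            )
    df = pd.DataFrame(
        {g: table.df[list(m)].sum(axis=1) for g, m in replicate_map.items()},
        index=table.df.index,
        dtype=int,
    )
    totals = pd.Series(
        {g: int(table.reads_total[list(m)].sum()) for g, m in replicate_map.items()},
        dtype=int,
    )
    return CountsTable(df=df, reads_total=totals)


@dataclass(frozen=True)
class SampleSpec:
    """One sample-sheet row: sample name, role, replicate group, FASTQ paths."""

    sample: str
    role: str  # "input" | "output"
    replicate_group: str
    fastq_paths: tuple[str, ...]


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    """Parse the TSV sample sheet (sample, role, replicate_group, fastq).

    Multiple FASTQ files for one sample may be given separated by
    commas.  Paths are resolved relative to the sheet's directory.
    """
    path = Path(path)
    specs: list[SampleSpec] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty sample sheet")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["sample", "role", "replicate_group", "fastq"]
    if header != expected:
        raise ValueError(f"{path}: expected header {expected}, got {header}")
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        sample, role, group, fastq = parts
        if role not in {"input", "output"}:
            raise ValueError(f"{path}:{lineno}: role must be input or output")
        if sample in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
        seen.add(sample)
        paths = tuple(
            str((path.parent / p.strip())) for p in fastq.split(",") if p.strip()
        )
        specs.append(SampleSpec(sample, role, group, paths))
    return specs
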