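"""Semirandom 18-nt strain barcodes and the strain ↔ barcode library.

Barcodes are built from six trimers drawn from the 48 ``VNN`` codons
(first base A, C or G; any second and third base).  Because every stop
codon (TAA, TAG, TGA) starts with T, a barcode composed of VNN trimers
can never place a stop codon at a trimer-aligned position — the property
that keeps the deletion scar translatable in-frame.  Equivalently, the
reverse complement of the barcode is six ``NNB`` trimers, which is how
the degenerate segment is ordered on the reverse construction primer.
"""

from __future__ import annotations

import io
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BARCODE_LENGTH",
    "VNN_CODONS",
    "STOP_CODONS",
    "RESERVED_STRAIN_NAME",
    "Barcode",
    "BarcodeValidation",
    "BarcodeLibrary",
    "LibraryDesignError",
    "validate_barcode",
    "generate_barcode",
    "build_library",
    "hamming_distance",
]

BARCODE_LENGTH = 18
CODONS_PER_BARCODE = BARCODE_LENGTH // 3

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: All 48 codons matching the degenerate pattern VNN (V = A/C/G, N = any).
VNN_CODONS: tuple[str, ...] = tuple(
    v + n1 + n2 for v in "ACG" for n1 in "ACGT" for n2 in "ACGT"
)

#: Reserved counts-table row for barcodes absent from the library.
RESERVED_STRAIN_NAME = "_other"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class BarcodeValidation:
    """Verdict of :func:`validate_barcode` with human-readable violations."""

    valid: bool
    violations: tuple[str, ...] = ()


def validate_barcode(seq: str) -> BarcodeValidation:
    """Check a sequence against the barcode invariants.

    A valid barcode is exactly 18 nt over {A,C,G,T} and every
    trimer-aligned codon starts with A, C or G, so no trimer-aligned
    codon is a stop codon.  Invalid input yields a false verdict with
    one message per violated rule; it never raises.
    """
    violations: list[str] = []
    if not isinstance(seq, str):
        return BarcodeValidation(False, ("not a string",))
    if len(seq) != BARCODE_LENGTH:
        violations.append(f"length is {len(seq)}, expected {BARCODE_LENGTH}")
    bad_chars = sorted(set(seq) - _VALID_BASES)
    if bad_chars:
        violations.append(
            "contains characters outside {A,C,G,T}: " + ",".join(bad_chars)
        )
    if not violations:
        for i in range(0, BARCODE_LENGTH, 3):
            codon = seq[i : i + 3]
            if codon[0] == "T":
                violations.append(
                    f"codon {i // 3} ({codon}) at position {i} starts with T"
                    " (must be V = A/C/G)"
                )
    return BarcodeValidation(not violations, tuple(violations))


@dataclass(frozen=True)
class Barcode:
    """An 18-nt VNN-codon barcode. Construction enforces all invariants."""

    seq: str

    def __post_init__(self) -> None:
        verdict = validate_barcode(self.seq)
        if not verdict.valid:
            raise ValueError(
                "invalid barcode: " + "; ".join(verdict.violations)
            )

    def __str__(self) -> str:
        return self.seq

    def __len__(self) -> int:
        return len(self.seq)


def generate_barcode(rng: np.random.Generator) -> Barcode:
    """Draw one barcode: six codons sampled uniformly from the 48 VNN codons.

    Deterministic for a given generator state; pass
    ``numpy.random.default_rng(seed)`` for reproducible draws.
    """
    idx = rng.integers(0, len(VNN_CODONS), size=CODONS_PER_BARCODE)
    return Barcode("".join(VNN_CODONS[i] for i in idx))


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatched positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


class LibraryDesignError(RuntimeError):
    """Raised when a barcode library cannot satisfy its constraints."""


@dataclass
class BarcodeLibrary(Mapping[str, Barcode]):
    """Ordered map of strain name → barcode used for read classification.

    Invariants: strain names unique and not the reserved ``_other``;
    barcodes unique and individually valid; if ``min_distance`` > 0,
    all pairwise Hamming distances are at least ``min_distance``.
    """

    entries: dict[str, Barcode] = field(default_factory=dict)
    min_distance: int = 0

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ValueError("min_distance must be nonnegative")
        entries = dict(self.entries)
        if RESERVED_STRAIN_NAME in entries:
            raise ValueError(
                f"{RESERVED_STRAIN_NAME!r} is a reserved strain name"
            )
        entries = {
            name: bc if isinstance(bc, Barcode) else Barcode(bc)
            for name, bc in entries.items()
        }
        seqs = [bc.seq for bc in entries.values()]
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcodes are not unique")
        if self.min_distance > 0:
            names = list(entries)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    d = hamming_distance(entries[a].seq, entries[b].seq)
                    if d < self.min_distance:
                        raise ValueError(
                            f"barcodes for {a!r} and {b!r} are at Hamming"
                            f" distance {d} < min_distance {self.min_distance}"
                        )
        self.entries = entries

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, strain: str) -> Barcode:
        return self.entries[strain]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def strains(self) -> list[str]:
        return list(self.entries)

    def barcode_to_strain(self) -> dict[str, str]:
        """Inverse lookup table (barcode sequence → strain name)."""
        return {bc.seq: name for name, bc in self.entries.items()}

    # I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the library as ``strain<TAB>barcode`` with a header line."""
        Path(path).write_text(self.to_tsv_string(), encoding="utf-8")

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        buf.write("strain\tbarcode\n")
        for name, bc in self.entries.items():
            buf.write(f"{name}\t{bc.seq}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, path: str | Path, min_distance: int = 0) -> "BarcodeLibrary":
        text = Path(path).read_text(encoding="utf-8")
        lines = text.splitlines()
        if not lines or lines[0].split("\t")[:2] != ["strain", "barcode"]:
            raise ValueError(
                f"{path}: expected header line 'strain\\tbarcode'"
            )
        entries: dict[str, Barcode] = {}
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, seq = parts
            if name in entries:
                raise ValueError(f"{path}:{lineno}: duplicate strain {name!r}")
            entries[name] = Barcode(seq)
        return cls(entries=entries, min_distance=min_distance)


def build_library(
    strain_names: list[str],
    rng: np.random.Generator,
    min_distance: int = 3,
    max_attempts_per_strain: int = 10_000,
) -> BarcodeLibrary:
    """Assign one freshly generated barcode to each strain.

    Barcodes are rejection-sampled until each new one is unique and at
    Hamming distance >= ``min_distance`` from all previously assigned
    barcodes.  Deterministic under a fixed generator seed.

    Raises
    ------
    LibraryDesignError
        If a conforming barcode cannot be found for some strain within
        ``max_attempts_per_strain`` draws (the constraint is then
        considered unsatisfiable at this library size).
    ValueError
        On duplicate or reserved strain names.
    """
    if len(set(strain_names)) != len(strain_names):
        raise ValueError("strain names must be unique")
    if RESERVED_STRAIN_NAME in strain_names:
        raise ValueError(f"{RESERVED_STRAIN_NAME!r} is a reserved strain name")
    chosen: dict[str, Barcode] = {}
    for name in strain_names:
        for _ in range(max_attempts_per_strain):
            candidate = generate_barcode(rng)
            if any(
                hamming_distance(candidate.seq, prev.seq)
                < max(min_distance, 1)
                for prev in chosen.values()
            ):
                continue
            chosen[name] = candidate
            break
        else:
            raise LibraryDesignError(
                f"could not place a barcode for strain {name!r} at"
                f" min_distance {min_distance} after"
                f" {max_attempts_per_strain} attempts"
                f" ({len(chosen)} barcodes already placed)"
            )
    return BarcodeLibrary(entries=chosen, min_distance=min_distance)
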