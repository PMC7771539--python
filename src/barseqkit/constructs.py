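"""In-silico design of barcoded in-frame deletions.

The deletion strategy replaces the body of a target gene — everything
between the start codon and the last seven codons (six amino acids plus
the stop) — with a barcoded scar.  Two scar forms exist:

* ``erm_bar``: the marked precursor, carrying an erythromycin-resistance
  cassette between two FRT sites (layout ATG-LL-FRT-erm-FRT-spacer-
  barcode-RL).
* ``bar``: the final 138-bp scar left after FLP recombinase excises the
  cassette, leaving a single FRT site (layout ATG-LL-FRT-spacer-
  barcode-RL).

The scar carries the gene's own start codon in frame, contributes 45
additional codons, and is free of trimer-aligned stop codons, so the
deletion reads through as a short in-frame ORF and avoids polar effects
on downstream genes in an operon.

Eight oligos drive construction and verification per target: F1/R1-LL
amplify 1 kb upstream (tagged with the left linker), F2-RL/R2 amplify
1 kb downstream (tagged with the right linker), FO/RO sit 500 bp outside
F1/R2 to screen the locus, and FW/RW amplify an internal fragment whose
absence confirms the deletion.  The three fragments fuse by
splicing-by-overlap-extension (SOE) PCR through the shared LL and RL
homology.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .barcodes import Barcode, validate_barcode

__all__ = [
    "R1_LL_EXTENSION",
    "LL_FORWARD",
    "RL_SEQUENCE",
    "SPACER_SEQUENCE",
    "FRT_SITE",
    "LinkerSet",
    "DEFAULT_LINKERS",
    "GeneTarget",
    "Oligo",
    "OligoSet",
    "OligoParams",
    "ScarSequence",
    "FlankTooShortError",
    "SoeJoinError",
    "design_oligos",
    "assemble_bar_scar",
    "assemble_erm_bar_scar",
    "flp_excise",
    "soe_join",
    "apply_deletion",
    "verify_in_frame",
    "codon_family_usage",
    "revcomp",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


#: 32-nt extension carried on the 5' end of the R1 oligo (reverse primer).
R1_LL_EXTENSION = "CTGGCGAAGCATATATAAGAAGCTCGTCTCGT"

#: Left linker in scar (forward) orientation = revcomp of the R1 extension.
LL_FORWARD = revcomp(R1_LL_EXTENSION)

#: 33-nt right linker; its first 18 nt are the right flank used in counting.
RL_SEQUENCE = "GACTTGACCTGGATGTCTCTACCCACAAGATCG"

#: 18-nt spacer immediately left of the barcode; the left counting flank.
SPACER_SEQUENCE = "GCTCATGCACTTGATTCC"

#: Canonical 34-nt minimal FRT site (13-bp repeat, 8-bp core, 13-bp
#: inverted repeat) used as the post-excision remnant.
FRT_SITE = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"

_STOPS = {"TAA", "TAG", "TGA"}


def _synthetic_erm_filler(length: int = 880, seed: int = 20_220_415) -> str:
    """Deterministic synthetic stand-in for the erm cassette interior.

    A fixed pseudorandom sequence sized so that the full marked middle
    fragment (LL + cassette + spacer + barcode + RL) is 1,049 bp.  It is
    a synthetic placeholder, not the sequence of any real plasmid.
    """
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@dataclass(frozen=True)
class LinkerSet:
    """The fixed sequences shared by every barcoded deletion."""

    ll_fwd: str = LL_FORWARD
    rl: str = RL_SEQUENCE
    spacer: str = SPACER_SEQUENCE
    frt_remnant: str = FRT_SITE
    erm_cassette: str = field(
        default_factory=lambda: FRT_SITE + _synthetic_erm_filler() + FRT_SITE
    )

    def __post_init__(self) -> None:
        if len(self.frt_remnant) != 34:
            raise ValueError("frt_remnant must be 34 nt")
        if not (
            self.erm_cassette.startswith(self.frt_remnant)
            and self.erm_cassette.endswith(self.frt_remnant)
        ):
            raise ValueError("erm_cassette must begin and end with the FRT site")


DEFAULT_LINKERS = LinkerSet()

#: Right flank searched by the counting module (first 18 nt of RL).
RIGHT_FLANK = RL_SEQUENCE[:18]


# ---------------------------------------------------------------------------
# Gene targets and oligo design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTarget:
    """A gene slated for deletion, in 0-based half-open forward coordinates."""

    replicon_id: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start < 27:
            raise ValueError(
                f"gene {self.name}: length {self.end - self.start} < 27 nt"
                " (must retain start codon and last seven codons)"
            )
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"gene {self.name}: length {self.end - self.start}"
                " not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class FlankTooShortError(ValueError):
    """Not enough genomic sequence flanks the target for oligo design."""

    def __init__(self, side: str, available: int, required: int):
        self.side = side
        self.available = available
        self.required = required
        super().__init__(
            f"{side} flank too short: {available} nt available,"
            f" {required} nt required"
        )


@dataclass(frozen=True)
class Oligo:
    """One primer: name, 5'→3' sequence, and genomic anneal interval.

    ``anneal`` is 0-based half-open on the forward strand of the
    replicon; ``anneal_strand`` gives the strand the 3' end extends
    along.  Extensions (LL / RL tails) are part of ``seq`` but not of
    the anneal interval.
    """

    name: str
    seq: str
    anneal: tuple[int, int]
    anneal_strand: str


@dataclass(frozen=True)
class OligoParams:
    anneal_length: int = 22
    anneal_bounds: tuple[int, int] = (18, 30)
    arm_length: int = 1000
    outside_offset: int = 500
    check_product_bounds: tuple[int, int] = (500, 1000)

    def __post_init__(self) -> None:
        lo, hi = self.anneal_bounds
        if not lo <= self.anneal_length <= hi:
            raise ValueError("anneal_length outside anneal_bounds")


@dataclass(frozen=True)
class OligoSet:
    """The eight oligos for one deletion, plus derived product sizes."""

    target: GeneTarget
    oligos: dict[str, Oligo]
    check_product_length: int  # predicted FW/RW product on the WT template

    def __getitem__(self, name: str) -> Oligo:
        return self.oligos[name]


def design_oligos(
    genome: Mapping[str, str],
    target: GeneTarget,
    params: OligoParams | None = None,
    linkers: LinkerSet = DEFAULT_LINKERS,
) -> OligoSet:
    """Design the eight construction/verification oligos for one target.

    Minus-strand genes are handled by designing on the coding
    orientation (the reverse complement of the replicon) and mapping the
    anneal intervals back to forward-strand coordinates.

    Raises
    ------
    FlankTooShortError
        If fewer than ``arm_length + outside_offset`` nt flank either
        deletion junction.
    """
    params = params or OligoParams()
    replicon = genome[target.replicon_id]
    L = len(replicon)
    if target.end > L or target.start < 0:
        raise ValueError(f"gene {target.name}: coordinates outside replicon")

    if target.strand == "+":
        seq = replicon
        start, end = target.start, target.end
    else:
        seq = revcomp(replicon)
        start, end = L - target.end, L - target.start

    need = params.arm_length + params.outside_offset
    if start < need:
        side = "upstream" if target.strand == "+" else "downstream"
        raise FlankTooShortError(side, start, need)
    if L - end < need:
        side = "downstream" if target.strand == "+" else "upstream"
        raise FlankTooShortError(side, L - end, need)

    al = params.anneal_length
    arm = params.arm_length
    off = params.outside_offset

    # Anneal intervals in coding-orientation coordinates.
    coords = {
        "F1": (start - arm, start - arm + al, "+"),
        "R1_LL": (start + 3 - al, start + 3, "-"),
        "F2_RL": (end - 21, end - 21 + al, "+"),
        "R2": (end + arm - al, end + arm, "-"),
        "FO": (start - arm - off, start - arm - off + al, "+"),
        "RO": (end + arm + off - al, end + arm + off, "-"),
    }

    # FW/RW amplify within the deleted span; their product on the WT
    # template should fall in check_product_bounds when the gene allows.
    internal_start, internal_end = start + 3, end - 21
    internal_len = internal_end - internal_start
    lo, hi = params.check_product_bounds
    if internal_len < lo:
        warnings.warn(
            f"gene {target.name}: internal span {internal_len} nt cannot"
            f" host a {lo}-bp check product; using the full span",
            stacklevel=2,
        )
        product = internal_len
    else:
        product = min(internal_len, hi)
    coords["FW"] = (internal_start, internal_start + al, "+")
    coords["RW"] = (internal_start + product - al, internal_start + product, "-")

    oligos: dict[str, Oligo] = {}
    for name, (a, b, strand_here) in coords.items():
        anneal_seq = seq[a:b]
        oseq = anneal_seq if strand_here == "+" else revcomp(anneal_seq)
        if name == "R1_LL":
            oseq = R1_LL_EXTENSION + oseq
        elif name == "F2_RL":
            oseq = linkers.rl + oseq
        if target.strand == "+":
            fwd_a, fwd_b = a, b
            fwd_strand = strand_here
        else:
            fwd_a, fwd_b = L - b, L - a
            fwd_strand = "+" if strand_here == "-" else "-"
        oligos[name] = Oligo(name, oseq, (fwd_a, fwd_b), fwd_strand)

    return OligoSet(target=target, oligos=oligos, check_product_length=product)


# ---------------------------------------------------------------------------
# Scar assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScarSequence:
    """An assembled deletion scar with per-component half-open offsets."""

    seq: str
    offsets: dict[str, tuple[int, int]]
    kind: str  # "bar" | "erm_bar"

    def component(self, name: str) -> str:
        a, b = self.offsets[name]
        return self.seq[a:b]

    def __len__(self) -> int:
        return len(self.seq)


def _assemble(parts: Sequence[tuple[str, str]], kind: str) -> ScarSequence:
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    chunks = []
    for name, s in parts:
        offsets[name] = (pos, pos + len(s))
        chunks.append(s)
        pos += len(s)
    return ScarSequence(seq="".join(chunks), offsets=offsets, kind=kind)


def _check_barcode(barcode: Barcode | str) -> str:
    seq = barcode.seq if isinstance(barcode, Barcode) else barcode
    verdict = validate_barcode(seq)
    if not verdict.valid:
        raise ValueError("invalid barcode: " + "; ".join(verdict.violations))
    return seq


def assemble_bar_scar(
    barcode: Barcode | str, linkers: LinkerSet = DEFAULT_LINKERS
) -> ScarSequence:
    """Assemble the unmarked *bar* scar: ATG-LL-FRT-spacer-barcode-RL.

    With the default 34-nt FRT remnant the scar is 138 bp; the barcode
    occupies whole codons (offset 87 is divisible by 3), so a VNN
    barcode can never introduce an in-frame stop.
    """
    seq = _check_barcode(barcode)
    return _assemble(
        [
            ("start_codon", "ATG"),
            ("LL", linkers.ll_fwd),
            ("FRT", linkers.frt_remnant),
            ("spacer", linkers.spacer),
            ("barcode", seq),
            ("RL", linkers.rl),
        ],
        kind="bar",
    )


def assemble_erm_bar_scar(
    barcode: Barcode | str, linkers: LinkerSet = DEFAULT_LINKERS
) -> ScarSequence:
    """Assemble the marked *erm-bar* scar: ATG-LL-[FRT-erm-FRT]-spacer-barcode-RL."""
    seq = _check_barcode(barcode)
    return _assemble(
        [
            ("start_codon", "ATG"),
            ("LL", linkers.ll_fwd),
            ("erm_cassette", linkers.erm_cassette),
            ("spacer", linkers.spacer),
            ("barcode", seq),
            ("RL", linkers.rl),
        ],
        kind="erm_bar",
    )


def flp_excise(
    scar: ScarSequence, linkers: LinkerSet = DEFAULT_LINKERS
) -> ScarSequence:
    """Simulate FLP recombination: collapse FRT-erm-FRT to a single FRT.

    The cassette interval of an ``erm_bar`` scar is replaced by the FRT
    remnant by direct string surgery; the result must equal the *bar*
    scar assembled from the same barcode.
    """
    if scar.kind != "erm_bar":
        raise ValueError("flp_excise expects an erm_bar scar")
    a, b = scar.offsets["erm_cassette"]
    new_seq = scar.seq[:a] + linkers.frt_remnant + scar.seq[b:]
    shift = len(linkers.frt_remnant) - (b - a)
    offsets: dict[str, tuple[int, int]] = {}
    for name, (x, y) in scar.offsets.items():
        if name == "erm_cassette":
            offsets["FRT"] = (a, a + len(linkers.frt_remnant))
        elif x >= b:
            offsets[name] = (x + shift, y + shift)
        else:
            offsets[name] = (x, y)
    return ScarSequence(seq=new_seq, offsets=offsets, kind="bar")


# ---------------------------------------------------------------------------
# SOE-PCR joining
# ---------------------------------------------------------------------------

class SoeJoinError(ValueError):
    """A junction cannot be resolved into a single overlap."""


def _terminal_overlaps(a: str, b: str, min_overlap: int) -> list[int]:
    hits = []
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            hits.append(k)
    return hits


def soe_join(fragments: Sequence[str], min_overlap: int = 15) -> str:
    """Fuse fragments at their unique terminal overlaps, left to right.

    Models splicing-by-overlap-extension PCR: each adjacent pair must
    share exactly one suffix/prefix overlap of at least ``min_overlap``
    nt.  Joined length equals the sum of fragment lengths minus the sum
    of overlaps.

    Raises
    ------
    SoeJoinError
        Naming the junction, if a pair shares no overlap or overlaps at
        more than one offset.
    """
    if len(fragments) < 2:
        raise ValueError("need at least two fragments")
    joined = fragments[0]
    for i, frag in enumerate(fragments[1:], start=1):
        hits = _terminal_overlaps(joined, frag, min_overlap)
        if not hits:
            raise SoeJoinError(
                f"no terminal overlap >= {min_overlap} nt at junction"
                f" {i - 1}/{i}"
            )
        if len(hits) > 1:
            raise SoeJoinError(
                f"ambiguous overlap at junction {i - 1}/{i}:"
                f" lengths {sorted(hits)}"
            )
        joined = joined + frag[hits[0] :]
    return joined


# ---------------------------------------------------------------------------
# Genome surgery and verification
# ---------------------------------------------------------------------------

def apply_deletion(
    genome: Mapping[str, str], target: GeneTarget, scar: ScarSequence
) -> dict[str, str]:
    """Replace the gene body with the scar, returning a new genome dict.

    The gene's first codon and last seven codons are retained; the scar
    is inserted in the gene's coding orientation with its ATG aligned to
    the gene's start codon (so scar[3:] replaces the excised body).
    Mutant replicon length = original - gene length + len(scar) + 21.
    """
    if scar.kind not in {"bar", "erm_bar"}:
        raise ValueError(f"unknown scar kind {scar.kind!r}")
    replicon = genome[target.replicon_id]
    if target.end > len(replicon):
        raise ValueError(f"gene {target.name}: coordinates outside replicon")
    body = scar.seq[3:]  # scar ATG coincides with the gene's own start codon
    if target.strand == "+":
        mutant = replicon[: target.start + 3] + body + replicon[target.end - 21 :]
    else:
        mutant = (
            replicon[: target.start + 21]
            + revcomp(body)
            + replicon[target.end - 3 :]
        )
    out = dict(genome)
    out[target.replicon_id] = mutant
    return out


@dataclass(frozen=True)
class FrameReport:
    """Outcome of in-frame verification of an applied deletion scar."""

    passed: bool
    starts_with_atg: bool
    in_frame: bool
    scar_codons: int  # codons in the scar including the ATG
    stop_positions: tuple[int, ...]  # nt offsets of stops before the terminal one
    messages: tuple[str, ...]


def verify_in_frame(
    mutant_genome: Mapping[str, str],
    target: GeneTarget,
    linkers: LinkerSet = DEFAULT_LINKERS,
) -> FrameReport:
    """Verify the scar region of a mutant genome reads through in frame.

    Extracts the scar plus the retained 21 nt tail (in coding
    orientation), then checks: the region starts with ATG; its length is
    divisible by 3; the only trimer-aligned stop codon is the terminal
    one (the gene's original stop); and the scar proper contributes 46
    codons including the ATG.  Violations are reported, never raised.
    """
    replicon = mutant_genome[target.replicon_id]
    if target.strand == "+":
        region = replicon[target.start :]
    else:
        # Coordinates downstream of the insertion have shifted, so anchor
        # on the scar's ATG+LL (which appears reverse-complemented on the
        # forward strand) within a window above the retained tail.
        anchor = revcomp("ATG" + linkers.ll_fwd)
        window = replicon[target.start : target.start + 2500]
        at = window.find(anchor)
        if at < 0:
            return FrameReport(
                False, False, False, 0, (),
                ("scar start codon + left linker not found on the minus strand",),
            )
        atg_end = target.start + at + len(anchor)
        region = revcomp(replicon[:atg_end])
    messages: list[str] = []
    rl_at = region.find(linkers.rl, 3)
    if rl_at < 0:
        return FrameReport(
            False, region.startswith("ATG"), False, 0, (),
            ("right linker not found downstream of the deletion junction",),
        )
    scar_len = rl_at + len(linkers.rl)
    orf = region[: scar_len + 21]

    starts_with_atg = orf.startswith("ATG")
    if not starts_with_atg:
        messages.append("scar ORF does not begin with ATG")
    in_frame = len(orf) % 3 == 0
    if not in_frame:
        messages.append(f"scar + retained tail length {len(orf)} not divisible by 3")

    stops = [i for i in range(0, len(orf) - 2, 3) if orf[i : i + 3] in _STOPS]
    terminal = len(orf) - 3
    premature = tuple(i for i in stops if i != terminal)
    if premature:
        messages.append(
            "premature in-frame stop codon(s) at nt offset(s) "
            + ", ".join(map(str, premature))
        )
    if in_frame and terminal not in stops:
        messages.append("terminal codon of retained tail is not a stop codon")

    scar_codons = scar_len // 3
    if scar_len % 3 != 0:
        messages.append(f"scar length {scar_len} not divisible by 3")

    return FrameReport(
        passed=not messages,
        starts_with_atg=starts_with_atg,
        in_frame=in_frame,
        scar_codons=scar_codons,
        stop_positions=premature,
        messages=tuple(messages),
    )


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

def codon_family_usage(cds_set: Sequence[str], query: str) -> float:
    """Frequency of ``query`` among synonymous codons across a CDS set.

    Counts every codon in every CDS (all lengths must be divisible by
    3) and returns count(query) / count(codons encoding the same amino
    acid) under the standard genetic code.
    """
    query = query.upper()
    table = unambiguous_dna_by_id[1]
    if query in table.stop_codons:
        raise ValueError(f"{query} is a stop codon; it has no amino-acid family")
    if query not in table.forward_table:
        raise ValueError(f"{query!r} is not a valid sense codon")
    aa = table.forward_table[query]
    family = {c for c, a in table.forward_table.items() if a == aa}

    query_count = 0
    family_count = 0
    for idx, cds in enumerate(cds_set):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {idx}: length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in family:
                family_count += 1
                if codon == query:
                    query_count += 1
    if family_count == 0:
        raise ValueError(f"no codons encoding {aa} found in the CDS set")
    return query_count / family_count
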