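"""Relative frequencies, competitive indices, and qPCR polarity ratios.

The competitive index (CI) of a mutant in an output sample, against a
set of barcoded wild-type reference strains, is

    CI = log10[ (RF_mut / mean RF_WT)_output / (RF_mut / mean RF_WT)_input ]

where RF is the strain's relative frequency among library-matched reads.
A neutral strain drifts around CI = 0; CI < 0 means the mutant lost
ground relative to the wild-type references between the input library
and the output sample.  Strains absent from an output sample (zero
reads) cannot yield a finite CI and are censored: the value reported is
the CI recomputed with a 0.5-read pseudocount, flagged as an upper
bound.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .barcodes import RESERVED_STRAIN_NAME
from .counting import CountsTable

__all__ = [
    "FrequencyTable",
    "CIResult",
    "relative_frequencies",
    "competitive_index",
    "filter_strains",
    "polarity_ratio",
]


@dataclass
class FrequencyTable:
    """Per-sample relative frequencies with their source counts.

    ``rf`` columns each sum to 1 over the included strains.  The source
    counts are retained so downstream censoring can recompute a
    frequency under a pseudocount.
    """

    rf: pd.DataFrame
    counts: pd.DataFrame
    include_other: bool

    @property
    def samples(self) -> list[str]:
        return list(self.rf.columns)


def relative_frequencies(
    counts: CountsTable, include_other: bool = False
) -> FrequencyTable:
    """Convert a counts table to per-sample relative frequencies.

    By default the reserved ``_other`` row is excluded from both the
    numerator set and the denominator, so frequencies describe the
    library-matched population only.
    """
    df = counts.df
    if not include_other:
        df = df.drop(index=RESERVED_STRAIN_NAME)
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            "zero matched reads in sample(s): " + ", ".join(zero.index)
        )
    return FrequencyTable(rf=df / totals, counts=df.copy(), include_other=include_other)


@dataclass
class CIResult:
    """Per-strain, per-sample competitive indices.

    ``table`` columns: strain, sample, ci, censored, input_rf,
    output_rf.  Censored rows carry the pseudocount-derived detection
    floor in ``ci`` (the true value is at or below it).
    """

    table: pd.DataFrame
    wt_strains: tuple[str, ...]
    input_sample: str

    def ci_of(self, strain: str, sample: str) -> float:
        sel = self.table[
            (self.table.strain == strain) & (self.table["sample"] == sample)
        ]
        return float(sel.ci.iloc[0])

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CIResult":
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(table=table, wt_strains=(), input_sample="")


def competitive_index(
    freqs: FrequencyTable,
    wt_strains: Sequence[str],
    input_sample: str,
    output_samples: Sequence[str] | None = None,
    zero_policy: str = "censor",
    pseudocount: float = 0.5,
) -> CIResult:
    """Compute log10 competitive indices against wild-type references.

    The wild-type reference frequency is the arithmetic mean RF over
    ``wt_strains`` in each sample.  Every strain in the table, wild-type
    references included, receives a CI per output sample; the WT strains
    act as internal controls expected near 0.

    ``zero_policy`` governs strains with zero reads in a sample:
    ``"censor"`` (default) reports the CI computed under a
    ``pseudocount``-read substitute and flags the row; ``"pseudocount"``
    reports the same value unflagged.

    Raises
    ------
    ValueError
        If no wild-type strains are given, one is missing from the
        table, or the wild-type mean frequency is zero in the input or
        an output sample.
    """
    if not wt_strains:
        raise ValueError("wt_strains must be nonempty")
    if zero_policy not in {"censor", "pseudocount"}:
        raise ValueError("zero_policy must be 'censor' or 'pseudocount'")
    rf = freqs.rf
    counts = freqs.counts
    missing = [w for w in wt_strains if w not in rf.index]
    if missing:
        raise ValueError(f"wild-type strain(s) not in table: {missing}")
    if input_sample not in rf.columns:
        raise ValueError(f"input sample {input_sample!r} not in table")
    if output_samples is None:
        output_samples = [s for s in rf.columns if s != input_sample]

    def rf_with_pseudo(sample: str, strain: str) -> float:
        # Frequency the strain would have had with `pseudocount` reads.
        total = counts[sample].sum()
        return pseudocount / (total + pseudocount)

    wt = list(wt_strains)
    wt_mean = rf.loc[wt].mean(axis=0)
    if wt_mean[input_sample] == 0:
        raise ValueError("wild-type mean frequency is zero in the input sample")

    rows = []
    for sample in output_samples:
        if sample not in rf.columns:
            raise ValueError(f"output sample {sample!r} not in table")
        if wt_mean[sample] == 0:
            raise ValueError(
                f"wild-type mean frequency is zero in sample {sample!r}"
            )
        for strain in rf.index:
            in_rf = float(rf.loc[strain, input_sample])
            out_rf = float(rf.loc[strain, sample])
            censored = False
            in_eff, out_eff = in_rf, out_rf
            if in_eff == 0:
                in_eff = rf_with_pseudo(input_sample, strain)
                censored = True
            if out_eff == 0:
                out_eff = rf_with_pseudo(sample, strain)
                censored = True
            ci = math.log10(
                (out_eff / wt_mean[sample]) / (in_eff / wt_mean[input_sample])
            )
            rows.append(
                {
                    "strain": strain,
                    "sample": sample,
                    "ci": ci,
                    "censored": censored if zero_policy == "censor" else False,
                    "input_rf": in_rf,
                    "output_rf": out_rf,
                }
            )
    table = pd.DataFrame(rows, columns=["strain", "sample", "ci", "censored", "input_rf", "output_rf"])
    return CIResult(
        table=table,
        wt_strains=tuple(wt_strains),
        input_sample=input_sample,
    )


def filter_strains(
    counts: CountsTable, exclude: Sequence[str]
) -> CountsTable:
    """Drop strains (e.g. mutants still under validation) before analysis.

    Removed strains vanish from downstream denominators; names not in
    the table produce a warning rather than an error.  The reserved
    ``_other`` row cannot be excluded this way.
    """
    import warnings

    present = [s for s in exclude if s in counts.df.index]
    absent = [s for s in exclude if s not in counts.df.index]
    if RESERVED_STRAIN_NAME in present:
        raise ValueError(f"cannot exclude the reserved {RESERVED_STRAIN_NAME} row")
    if absent:
        warnings.warn(f"exclude list names absent strain(s): {absent}", stacklevel=2)
    df = counts.df.drop(index=present)
    return CountsTable(df=df, reads_total=counts.reads_total.copy())


def polarity_ratio(
    ct: pd.DataFrame,
    mutant: str,
    wildtype: str,
    upstream_gene: str,
    downstream_gene: str,
    reference_gene: str = "rpoD",
) -> float:
    """Operon polarity ratio from qPCR Ct values via the 2^-ddCt method.

    ``ct`` has columns strain, gene, ct; repeated (strain, gene) rows
    are technical replicates and are averaged.  For each gene g and
    strain s, expression relative to the reference gene is
    rel(g,s) = 2^-(Ct(g,s) - Ct(ref,s)); the mutant's fold change is
    fold(g) = rel(g, mutant) / rel(g, wildtype); the polarity ratio is
    fold(downstream) / fold(upstream).  A ratio near 1 means the
    deletion left flanking-gene expression balanced (non-polar).
    """
    required = {"strain", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    means = ct.groupby(["strain", "gene"])["ct"].mean()

    def get(strain: str, gene: str) -> float:
        try:
            value = means.loc[(strain, gene)]
        except KeyError:
            raise ValueError(f"missing Ct for strain {strain!r}, gene {gene!r}")
        if value <= 0:
            raise ValueError(f"nonpositive Ct for strain {strain!r}, gene {gene!r}")
        return float(value)

    def fold(gene: str) -> float:
        rel_mut = 2 ** -(get(mutant, gene) - get(mutant, reference_gene))
        rel_wt = 2 ** -(get(wildtype, gene) - get(wildtype, reference_gene))
        return rel_mut / rel_wt

    return fold(downstream_gene) / fold(upstream_gene)
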