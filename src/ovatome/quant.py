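"""FPKM computation and threshold-based expression / differential calling.

Expression is quantified as fragments per kilobase of transcript per million
mapped fragments (FPKM). A gene is called expressed when FPKM > 5 (strict).
Between the two conditions (mutant vs wildtype ovary) a gene expressed in at
least one condition is called up-in-mutant when FPKM_mut / FPKM_wt > 2 and
up-in-wildtype when the same ratio is < 0.5; otherwise it is unchanged.
No statistical test is applied: the method is a pure threshold rule.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InvalidInputError

FPKM_THRESHOLD = 5.0
RATIO_THRESHOLD = 2.0


class DiffCall(str, enum.Enum):
    UP_IN_MUTANT = "up_in_mutant"
    UP_IN_WILDTYPE = "up_in_wildtype"
    UNCHANGED = "unchanged"
    NOT_EXPRESSED = "not_expressed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GeneQuant:
    """Per-gene quantification across the two conditions."""

    gene_id: str
    length_nt: int
    count_mut: int
    count_wt: int
    fpkm_mut: float
    fpkm_wt: float
    expressed_mut: bool
    expressed_wt: bool
    call: DiffCall


def compute_fpkm(count: float, length_nt: float, total_mapped: float) -> float:
    """FPKM = count * 1e9 / (length_nt * total_mapped)."""
    if length_nt <= 0:
        raise InvalidInputError(f"transcript length must be positive, got {length_nt}")
    if total_mapped <= 0:
        raise InvalidInputError(f"library size must be positive, got {total_mapped}")
    if count < 0:
        raise InvalidInputError(f"fragment count must be non-negative, got {count}")
    return count * 1e9 / (length_nt * total_mapped)


def call_expressed(fpkm: float, threshold: float = FPKM_THRESHOLD) -> bool:
    """Strictly greater-than expression call (FPKM of exactly 5 is not expressed)."""
    if fpkm < 0:
        raise InvalidInputError(f"FPKM must be non-negative, got {fpkm}")
    return fpkm > threshold


def call_differential(
    fpkm_mut: float,
    fpkm_wt: float,
    ratio_threshold: float = RATIO_THRESHOLD,
    fpkm_min: float = FPKM_THRESHOLD,
) -> DiffCall:
    """Classify a gene by the mutant/wildtype FPKM ratio.

    Genes expressed in neither condition are ``not_expressed``. A wildtype
    FPKM of zero with an expressed mutant side is treated as an infinite
    ratio (up_in_mutant); symmetrically for a zero mutant side. Both ratio
    comparisons are strict, and since ratio_threshold > 1 the two directions
    are mutually exclusive.
    """
    if ratio_threshold <= 1:
        raise InvalidInputError("ratio threshold must exceed 1")
    exp_mut = call_expressed(fpkm_mut, fpkm_min)
    exp_wt = call_expressed(fpkm_wt, fpkm_min)
    if not exp_mut and not exp_wt:
        return DiffCall.NOT_EXPRESSED
    ratio = fpkm_mut / fpkm_wt if fpkm_wt > 0 else math.inf
    if ratio > ratio_threshold:
        return DiffCall.UP_IN_MUTANT
    if ratio < 1 / ratio_threshold:
        return DiffCall.UP_IN_WILDTYPE
    return DiffCall.UNCHANGED


def quantify(
    counts: pd.DataFrame,
    total_mut: float | None = None,
    total_wt: float | None = None,
    fpkm_min: float = FPKM_THRESHOLD,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Quantify a two-condition count table.

    ``counts`` needs columns gene_id, length_nt, count_mut, count_wt.
    Library sizes default to the column sums of the provided table.
    Returns one row per gene with FPKM values, expression flags and the
    differential call.
    """
    required = {"gene_id", "length_nt", "count_mut", "count_wt"}
    missing = required - set(counts.columns)
    if missing:
        raise InvalidInputError(f"count table missing columns: {sorted(missing)}")
    if counts.empty:
        raise InvalidInputError("count table is empty")
    total_mut = float(counts["count_mut"].sum()) if total_mut is None else total_mut
    total_wt = float(counts["count_wt"].sum()) if total_wt is None else total_wt
    out = counts.copy()
    out["fpkm_mut"] = [
        compute_fpkm(c, l, total_mut)
        for c, l in zip(out["count_mut"], out["length_nt"])
    ]
    out["fpkm_wt"] = [
        compute_fpkm(c, l, total_wt)
        for c, l in zip(out["count_wt"], out["length_nt"])
    ]
    out["expressed_mut"] = out["fpkm_mut"] > fpkm_min
    out["expressed_wt"] = out["fpkm_wt"] > fpkm_min
    out["call"] = [
        call_differential(m, w, ratio_threshold, fpkm_min).value
        for m, w in zip(out["fpkm_mut"], out["fpkm_wt"])
    ]
    return out


def scatter_table(quants: pd.DataFrame) -> pd.DataFrame:
    """FPKM scatter rows (mutant on x, wildtype on y) for genes expressed
    in at least one condition."""
    if quants.empty:
        return pd.DataFrame(columns=["gene_id", "fpkm_mut", "fpkm_wt"])
    mask = quants["expressed_mut"] | quants["expressed_wt"]
    return quants.loc[mask, ["gene_id", "fpkm_mut", "fpkm_wt"]].reset_index(drop=True)


def to_gene_quants(quants: pd.DataFrame) -> list[GeneQuant]:
    return [
        GeneQuant(
            gene_id=row.gene_id,
            length_nt=int(row.length_nt),
            count_mut=int(row.count_mut),
            count_wt=int(row.count_wt),
            fpkm_mut=float(row.fpkm_mut),
            fpkm_wt=float(row.fpkm_wt),
            expressed_mut=bool(row.expressed_mut),
            expressed_wt=bool(row.expressed_wt),
            call=DiffCall(row.call),
        )
        for row in quants.itertuples()
    ]


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
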