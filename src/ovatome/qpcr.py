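"""Relative expression from qPCR Ct tables by the ddCt method.

dCt for a sample is mean Ct(target) - mean Ct(reference gene, here
Ci-GAPDH); ddCt is dCt(test sample) - dCt(calibrator sample, here the
wildtype); relative expression is 2^(-ddCt), assuming a doubling of product
per cycle (no efficiency correction). Replicate Ct values are averaged
before differencing and their standard deviations propagate to a standard
error on ddCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InvalidInputError


@dataclass
class DdCtResult:
    target: str
    reference: str
    test: str
    calibrator: str
    dct_test: float
    dct_calibrator: float
    ddct: float
    relative_expression: float
    se_ddct: float


class CtTable:
    """Replicate Ct values per (sample, gene).

    Built from a long-format table with columns sample, gene, ct (one row
    per replicate). Ct values must be positive and every sample must carry
    the reference gene when used for ddCt.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"sample", "gene", "ct"}
        missing = required - set(data.columns)
        if missing:
            raise InvalidInputError(f"Ct table missing columns: {sorted(missing)}")
        if data.empty:
            raise InvalidInputError("Ct table is empty")
        if (data["ct"] <= 0).any():
            bad = data.loc[data["ct"] <= 0]
            raise InvalidInputError(
                f"non-positive Ct values for {bad[['sample', 'gene']].values.tolist()}"
            )
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path))

    def replicates(self, sample: str, gene: str) -> pd.Series:
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise InvalidInputError(f"no Ct values for sample={sample!r}, gene={gene!r}")
        return sel["ct"]

    def mean_se(self, sample: str, gene: str) -> tuple[float, float]:
        reps = self.replicates(sample, gene)
        mean = float(reps.mean())
        se = 0.0 if len(reps) < 2 else float(reps.std(ddof=1)) / math.sqrt(len(reps))
        return mean, se


def delta_delta_ct(
    table: CtTable,
    target: str,
    reference: str,
    calibrator: str = "wildtype",
    test: str = "mutant",
) -> DdCtResult:
    """Compute ddCt and relative expression for one target gene.

    Missing (sample, gene) combinations raise an error naming the gap.
    """
    means = {}
    ses = {}
    for sample in (test, calibrator):
        for gene in (target, reference):
            means[(sample, gene)], ses[(sample, gene)] = table.mean_se(sample, gene)
    dct_test = means[(test, target)] - means[(test, reference)]
    dct_cal = means[(calibrator, target)] - means[(calibrator, reference)]
    ddct = dct_test - dct_cal
    se = math.sqrt(sum(s**2 for s in ses.values()))
    return DdCtResult(
        target=target,
        reference=reference,
        test=test,
        calibrator=calibrator,
        dct_test=dct_test,
        dct_calibrator=dct_cal,
        ddct=ddct,
        relative_expression=2.0 ** (-ddct),
        se_ddct=se,
    )


def fold_report(results: Iterable[DdCtResult], ndigits: int = 1) -> pd.DataFrame:
    """Render relative expression as >= 1 fold values with a direction.

    RQ 0.5 becomes "2.0-fold lower"; RQ 2.1 "2.1-fold higher"; RQ 1.0 is
    reported as no change. The reciprocal relationship is exact on the raw
    ``fold`` column (rounding applies only to the label).
    """
    results = list(results)
    if not results:
        raise InvalidInputError("no ddCt results to report")
    rows = []
    for r in results:
        rq = r.relative_expression
        if rq >= 1:
            fold, direction = rq, "higher" if rq > 1 else "no change"
        else:
            fold, direction = 1.0 / rq, "lower"
        label = (
            f"{round(fold, ndigits)}-fold (no change)"
            if direction == "no change"
            else f"{round(fold, ndigits)}-fold {direction} in {r.test}"
        )
        rows.append(
            {
                "gene": r.target,
                "ddct": r.ddct,
                "rq": rq,
                "fold": fold,
                "direction": direction,
                "label": label,
                "se_ddct": r.se_ddct,
            }
        )
    return pd.DataFrame(rows)
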