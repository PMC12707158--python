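"""Summary statistics for rank-annotation scores of a gene subset.

Implements the boxplot-style summary used to compare a gene group's scores
against chance (50%): median, quartiles by linear interpolation of order
statistics, and the one-sided 1.5×IQR low-outlier rule — a gene is flagged
when its score falls below Q1 − 1.5·(Q3 − Q1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from ._format import round_half_up


@dataclass
class ScoreSetSummary:
    gene_set_label: str
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    low_outliers: list[tuple[str, float]]

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Presentation values rounded half-up; internals keep full precision."""
        return {
            "median": round_half_up(self.median, ndigits),
            "q1": round_half_up(self.q1, ndigits),
            "q3": round_half_up(self.q3, ndigits),
            "iqr": round_half_up(self.iqr, ndigits),
        }


def summarize_scores(
    scores: Mapping[str, float],
    subset: Iterable[str],
    label: str = "gene set",
) -> ScoreSetSummary:
    """Median/quartile summary and low outliers for ``subset`` of ``scores``.

    Quartiles interpolate linearly between order statistics (positions
    ``(n-1)*p``).  Low outliers are genes scoring below Q1 − 1.5·IQR.
    """
    subset = sorted(set(subset))
    if not subset:
        raise ValueError("gene subset is empty")
    missing = [g for g in subset if g not in scores]
    if missing:
        raise KeyError(f"subset gene(s) without a score: {', '.join(missing)}")

    values = np.array([scores[g] for g in subset], dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    iqr = q3 - q1
    fence = q1 - 1.5 * iqr
    outliers = [(g, float(scores[g])) for g in subset if scores[g] < fence]
    outliers.sort(key=lambda t: t[1])
    return ScoreSetSummary(
        gene_set_label=label,
        n=len(subset),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        low_outliers=outliers,
    )
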