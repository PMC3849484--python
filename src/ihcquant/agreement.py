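"""Method-agreement statistics over paired per-image counts.

Two tools, both standard in method-comparison studies of cell counting:

* Bland-Altman analysis — per-image differences ``count_a - count_b``
  against pair means, with limits of agreement ``mean +- 1.96 sd``.
* Cumulative-difference curves — the empirical survival function of the
  absolute difference, ``P(|diff| >= d)``, the probability of observing a
  count discrepancy of at least d nuclei between the two methods. There is
  no censoring in a paired-count design, so the survival curve reduces to
  simple counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AgreementSummary",
    "DifferenceCurve",
    "paired_counts",
    "bland_altman",
    "difference_curve",
    "stratified_compare",
]


@dataclass(frozen=True)
class AgreementSummary:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    points: Tuple[Tuple[float, float], ...]  # (mean of pair, diff) per image


@dataclass(frozen=True)
class DifferenceCurve:
    """Step function P(|diff| >= d) over ascending thresholds d.

    ``thresholds`` always starts at 0 with probability 1; beyond the largest
    observed |diff| the probability is 0.
    """

    thresholds: Tuple[float, ...]
    probabilities: Tuple[float, ...]

    def probability_at(self, d: float) -> float:
        """P(|diff| >= d) for an arbitrary threshold d >= 0.

        Because |diff| only takes the observed values, the survival
        probability at d equals the one at the smallest observed value
        >= d, and 0 beyond the largest.
        """
        ts = np.asarray(self.thresholds)
        i = int(np.searchsorted(ts, d, side="left"))
        if i >= len(ts):
            return 0.0
        return self.probabilities[i]


def paired_counts(
    image_ids: Sequence[str],
    count_a: Sequence[float],
    count_b: Sequence[float],
    stratum: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble a validated paired-count table."""
    df = pd.DataFrame(
        {"image_id": [str(i) for i in image_ids],
         "count_a": np.asarray(count_a, dtype=float),
         "count_b": np.asarray(count_b, dtype=float)}
    )
    if stratum is not None:
        df["stratum"] = list(stratum)
    if df["image_id"].duplicated().any():
        raise ValueError("image_ids must be unique")
    if (df[["count_a", "count_b"]] < 0).any().any():
        raise ValueError("counts must be >= 0")
    return df


def _diffs(pairs: pd.DataFrame) -> np.ndarray:
    return pairs["count_a"].to_numpy(float) - pairs["count_b"].to_numpy(float)


def bland_altman(pairs: pd.DataFrame, loa_multiplier: float = 1.96) -> AgreementSummary:
    """Bland-Altman agreement of two counting methods.

    diff_i = count_a - count_b; limits of agreement are
    mean(diff) +- ``loa_multiplier`` * sd(diff) with the sample (n-1) sd.
    Requires at least two pairs.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError(f"Bland-Altman needs >= 2 pairs, got {n}")
    d = _diffs(pairs)
    means = (pairs["count_a"].to_numpy(float) + pairs["count_b"].to_numpy(float)) / 2.0
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return AgreementSummary(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - loa_multiplier * sd_diff,
        loa_high=mean_diff + loa_multiplier * sd_diff,
        points=tuple(zip(means.tolist(), d.tolist())),
    )


def difference_curve(pairs: pd.DataFrame) -> DifferenceCurve:
    """Empirical survival function of |count_a - count_b|.

    P(|diff| >= d) = #{i : |diff_i| >= d} / n, evaluated at d = 0 and at
    every distinct observed |diff|.
    """
    n = len(pairs)
    if n < 1:
        raise ValueError("difference_curve needs at least one pair")
    absd = np.abs(_diffs(pairs))
    thresholds = np.unique(np.concatenate([[0.0], absd]))
    probs = [(absd >= t).sum() / n for t in thresholds]
    return DifferenceCurve(
        thresholds=tuple(float(t) for t in thresholds),
        probabilities=tuple(float(p) for p in probs),
    )


def stratified_compare(
    pairs: pd.DataFrame, by: str = "stratum"
) -> Dict[str, Tuple[Optional[AgreementSummary], DifferenceCurve]]:
    """Independent agreement summary and curve per stratum.

    Strata with a single image get the curve only (Bland-Altman is
    undefined there and reported as ``None``).
    """
    if by not in pairs.columns:
        raise ValueError(f"unknown grouping key {by!r}")
    out: Dict[str, Tuple[Optional[AgreementSummary], DifferenceCurve]] = {}
    for key, sub in pairs.groupby(by, sort=True):
        summary = bland_altman(sub) if len(sub) >= 2 else None
        out[str(key)] = (summary, difference_curve(sub))
    return out
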