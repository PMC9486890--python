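"""Serology positivity statistics: assay cut-offs, end-point titres,
2x2 contingency tables with exact tests, and multiplicity correction.

The serological readout is a live cell-based assay scored as a continuous
signal; a sample is called positive when its signal exceeds a cut-off
derived from control sera (median plus raw median absolute deviation).
Positive samples are serially diluted on a doubling ladder starting at
1:20 and reported as the reciprocal end-point dilution (the last dilution
of the initial consecutive positive run; 0 codes a negative sample).
Group comparisons of positivity frequencies use the two-sided Fisher
exact test with conditional maximum-likelihood odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import contingency as _contingency

__all__ = [
    "TITRE_LADDER",
    "ContingencyTable",
    "FisherResult",
    "derive_cutoff",
    "endpoint_titre",
    "contingency_from_calls",
    "fisher_exact",
    "bh_adjust",
]

#: Reciprocal end-point dilution ladder: doubling series from 1:20.
TITRE_LADDER: tuple[int, ...] = tuple(20 * 2**k for k in range(11))  # 20 .. 20480


def derive_cutoff(control_values: Sequence[float]) -> float:
    """Positivity cut-off from control assay signals.

    Computed as ``median + MAD`` where MAD is the *raw* (unscaled) median
    absolute deviation — no 1.4826 normality factor.

    Parameters
    ----------
    control_values
        Continuous assay scores of at least two control sera.
    """
    values = np.asarray(control_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two control values to derive a cut-off")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + mad


def endpoint_titre(signals: Sequence[tuple[float, bool]]) -> float:
    """Reciprocal end-point titre from a serial-dilution readout.

    ``signals`` is an ordered sequence of ``(reciprocal_dilution, above_cutoff)``
    pairs with strictly increasing dilutions.  The titre is the largest
    dilution in the *initial consecutive run* of positive readings; 0 when
    the first dilution already reads negative.
    """
    if len(signals) == 0:
        raise ValueError("empty dilution series")
    dilutions = [d for d, _ in signals]
    if any(b <= a for a, b in zip(dilutions, dilutions[1:])):
        raise ValueError("dilutions must be strictly increasing")
    titre = 0.0
    for dilution, positive in signals:
        if not positive:
            break
        titre = float(dilution)
    return titre


# ---------------------------------------------------------------------------
# Exact 2x2 statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 count table; rows are groups, columns positive/negative."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        for count in (self.a, self.b, self.c, self.d):
            if count < 0 or int(count) != count:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d,
                                self.col_labels, self.row_labels)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float          # conditional MLE (exact machinery)
    ci95_low: float
    ci95_high: float
    sample_odds_ratio: float   # cross-product a*d / (b*c)


_COMB_CACHE_N = 128
_COMB: list[list[int]] = [[math.comb(n, k) for k in range(n + 1)]
                          for n in range(_COMB_CACHE_N + 1)]


def _comb(n: int, k: int) -> int:
    if n <= _COMB_CACHE_N:
        return _COMB[n][k]
    return math.comb(n, k)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed that of the observed table.
    All arithmetic is exact integer arithmetic, so ties between table
    probabilities are decided exactly (no floating-point tolerance).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    weights = [_comb(r1, k) * _comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
    observed = weights[a - kmin]
    numer = sum(w for w in weights if w <= observed)
    return float(Fraction(numer, _comb(n, c1)))


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]],
                 compute_ci: bool = True) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns the exact two-sided p, the conditional maximum-likelihood odds
    ratio with its exact (conditional) 95% CI, and the sample cross-product
    odds ratio.  Zero cells are handled by the exact machinery: the p-value
    needs no continuity correction and CI bounds may be 0 or ``inf``.

    ``compute_ci=False`` skips the (comparatively expensive) conditional-MLE
    point estimate and CI root-finding; the p-value is always computed.
    """
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    p = fisher_exact_p(a, b, c, d)
    if b * c == 0:
        sample_or = math.inf if a * d > 0 else math.nan
    else:
        sample_or = (a * d) / (b * c)
    if compute_ci:
        res = _contingency.odds_ratio(table.counts, kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        cmle, lo, hi = float(res.statistic), float(ci.low), float(ci.high)
    else:
        cmle = lo = hi = math.nan
    return FisherResult(p, cmle, lo, hi, sample_or)


# ---------------------------------------------------------------------------
# Positivity calls -> contingency
# ---------------------------------------------------------------------------

_ISOTYPES = ("IgM", "IgA", "IgG")


def contingency_from_calls(samples: pd.DataFrame, isotype: str,
                           grouping: str = "ot",
                           cutoff: float = 20.0) -> ContingencyTable:
    """Count positive/negative calls per group into a 2x2 table.

    Parameters
    ----------
    samples
        Table with columns ``ot_status`` (values ``OT``/``non-OT``/``control``)
        and ``titre_<isotype>``.
    isotype
        One of ``IgM``, ``IgA``, ``IgG``.
    grouping
        ``"ot"`` compares OT vs non-OT patient samples; ``"case_control"``
        compares all patient samples (OT plus non-OT) vs controls.
    cutoff
        Positivity threshold on the reciprocal titre (serum convention 20;
        CSF is scored positive when the undiluted signal exceeds the assay
        cut-off, which the titre encoding represents as titre >= 1).
    """
    if isotype not in _ISOTYPES:
        raise ValueError(f"unknown isotype {isotype!r}; expected one of {_ISOTYPES}")
    col = f"titre_{isotype}"
    if col not in samples.columns:
        raise ValueError(f"missing column {col!r}")
    status = samples["ot_status"].astype(str)
    if grouping == "ot":
        masks = [("OT", status == "OT"), ("non-OT", status == "non-OT")]
    elif grouping == "case_control":
        masks = [("case", status.isin(["OT", "non-OT"])), ("control", status == "control")]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    counts = []
    for label, mask in masks:
        sub = samples.loc[mask, col]
        if sub.empty:
            raise ValueError(f"empty group {label!r}")
        pos = int((sub >= cutoff).sum())
        counts.append((pos, int(sub.size) - pos))
    (a, b), (c, d) = counts
    return ContingencyTable(a, b, c, d,
                            row_labels=(masks[0][0], masks[1][0]))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
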