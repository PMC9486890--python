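"""B-cell-receptor repertoire statistics.

Covers the single-cell BCR analyses: per-cell dominant constant-region
(isotype) calls, somatic-mutation rates per kilobase of V region,
rank-sum comparisons of mutation load between isotypes, clonal-expansion
odds ratios estimated by repeated downsampling to a common cell number,
and Wilson confidence intervals for constant-region usage proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .serology import ContingencyTable, bh_adjust, fisher_exact

__all__ = [
    "ISOTYPE_ORDER",
    "ExpansionResult",
    "dominant_isotype",
    "dominant_isotypes",
    "mutation_rate",
    "mutation_rates",
    "compare_mutation_rates",
    "expansion_or",
    "constant_region_proportions",
]

#: IGH constant genes in genomic order — also the tie-break order for
#: dominant-isotype calls (earlier gene wins an expression tie).
ISOTYPE_ORDER: tuple[str, ...] = (
    "IGHM", "IGHD", "IGHG3", "IGHG1", "IGHA1", "IGHG2", "IGHG4", "IGHE", "IGHA2",
)

UNASSIGNED = "unassigned"


def dominant_isotype(expression: Mapping[str, float]) -> str:
    """Constant region with maximal expression; ``"unassigned"`` if all zero.

    Ties are broken by genomic gene order (IGHM first, IGHA2 last).
    """
    best, best_val = UNASSIGNED, 0.0
    for gene in ISOTYPE_ORDER:
        val = float(expression.get(gene, 0.0))
        if val > best_val:
            best, best_val = gene, val
    return best


def dominant_isotypes(cells: pd.DataFrame) -> pd.Series:
    """Vectorised dominant-isotype call over expression columns."""
    genes = [g for g in ISOTYPE_ORDER if g in cells.columns]
    if not genes:
        raise ValueError("no constant-region expression columns present")
    expr = cells[genes].to_numpy(dtype=float)
    idx = np.argmax(expr, axis=1)  # first maximum = genomic-order tie-break
    calls = np.array(genes, dtype=object)[idx]
    calls[expr.max(axis=1) <= 0.0] = UNASSIGNED
    return pd.Series(calls, index=cells.index, name="dominant_isotype")


def mutation_rate(v_mutation_count: int, v_length_nt: int,
                  floor_mutations: float = 0.5) -> dict[str, float]:
    """V-region mutations per kilobase, with a floored log10 display value.

    The display floor corresponds to ``floor_mutations`` (default 0.5)
    mutations over the cell's own V length, so unmutated cells plot at a
    finite value instead of -inf.
    """
    if v_length_nt <= 0:
        raise ValueError("V length must be positive")
    if v_mutation_count < 0:
        raise ValueError("mutation count must be non-negative")
    kb = v_length_nt / 1000.0
    rate = v_mutation_count / kb
    floor = floor_mutations / kb
    return {"rate_per_kb": rate, "log10_display": math.log10(max(rate, floor))}


def mutation_rates(cells: pd.DataFrame) -> pd.DataFrame:
    kb = cells["v_length_nt"].to_numpy(dtype=float) / 1000.0
    if np.any(kb <= 0):
        raise ValueError("V length must be positive")
    rate = cells["v_mutation_count"].to_numpy(dtype=float) / kb
    display = np.log10(np.maximum(rate, 0.5 / kb))
    return pd.DataFrame({"rate_per_kb": rate, "log10_display": display},
                        index=cells.index)


def _hodges_lehmann_ci(x: np.ndarray, y: np.ndarray,
                       alpha: float = 0.05,
                       max_pairs: int = 4_000_000) -> tuple[float, float, float]:
    """Hodges–Lehmann shift (median of pairwise x-y differences) with the
    Moses rank-sum-inversion CI (normal approximation for the order index)."""
    n, m = len(x), len(y)
    if n * m > max_pairs:  # subsample pairs; estimator stays consistent
        rng = np.random.default_rng(0)
        x = rng.choice(x, size=int(np.sqrt(max_pairs)), replace=False)
        y = rng.choice(y, size=int(np.sqrt(max_pairs)), replace=False)
        n, m = len(x), len(y)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    shift = float(np.median(diffs))
    z = stats.norm.ppf(1 - alpha / 2)
    k = int(np.floor(n * m / 2 - z * math.sqrt(n * m * (n + m + 1) / 12.0)))
    k = max(k, 0)
    return shift, float(diffs[k]), float(diffs[n * m - 1 - k])


def compare_mutation_rates(cells: pd.DataFrame, group_by: str = "dominant_isotype",
                           value_col: str = "rate_per_kb",
                           pairs: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Pairwise two-sided rank-sum comparisons of mutation rate between groups.

    For each group pair: Mann–Whitney p, BH-adjusted p across pairs, and the
    Hodges–Lehmann location shift with 95% CI.  Groups with fewer than two
    cells are skipped with a warning.
    """
    if value_col not in cells.columns:
        cells = cells.join(mutation_rates(cells))
    groups = {k: v[value_col].to_numpy(dtype=float)
              for k, v in cells.groupby(group_by)}
    names = list(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        if len(groups.get(a, ())) < 2 or len(groups.get(b, ())) < 2:
            warnings.warn(f"skipping pair ({a}, {b}): fewer than 2 cells in a group")
            continue
        x, y = groups[a], groups[b]
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        shift, lo, hi = _hodges_lehmann_ci(x, y)
        rows.append({"group_a": a, "group_b": b, "n_a": len(x), "n_b": len(y),
                     "statistic": float(res.statistic), "p": float(res.pvalue),
                     "shift": shift, "ci95_low": lo, "ci95_high": hi})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Clonal expansion by repeated downsampling
# ---------------------------------------------------------------------------


@dataclass
class ExpansionResult:
    """Downsampling-based clonal-expansion odds ratio between two tissues."""

    or_point: float                  # median OR over downsamples
    ci95: tuple[float, float]        # 2.5/97.5 percentiles of downsample ORs
    n_downsamples: int
    target_size: int
    low_power: bool
    haldane_or_full: float           # +0.5-corrected OR on the full data
    fisher_full: object              # FisherResult on the full (un-downsampled) table
    or_samples: np.ndarray | None = field(default=None, repr=False)


def _expanded_cell_count(clones: np.ndarray, min_cells: int) -> int:
    _, counts = np.unique(clones, return_counts=True)
    return int(counts[counts >= min_cells].sum())


def _expansion_table(clones_a: np.ndarray, clones_b: np.ndarray,
                     min_cells: int, unit: str) -> tuple[int, int, int, int]:
    if unit == "cell":
        ea = _expanded_cell_count(clones_a, min_cells)
        eb = _expanded_cell_count(clones_b, min_cells)
        return ea, len(clones_a) - ea, eb, len(clones_b) - eb
    if unit == "clonotype":
        _, ca = np.unique(clones_a, return_counts=True)
        _, cb = np.unique(clones_b, return_counts=True)
        ea, eb = int((ca >= min_cells).sum()), int((cb >= min_cells).sum())
        return ea, len(ca) - ea, eb, len(cb) - eb
    raise ValueError(f"unknown unit {unit!r}")


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def haldane_or(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with the Haldane–Anscombe +0.5 correction."""
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def expansion_or(clones_tissue_a: Sequence, clones_tissue_b: Sequence,
                 n_downsamples: int = 1000, seed: int | None = None,
                 min_cells_expanded: int = 2, unit: str = "cell",
                 target_size: int | None = None,
                 keep_samples: bool = False) -> ExpansionResult:
    """Clonal-expansion odds ratio between two tissues by downsampling.

    Each of ``n_downsamples`` rounds subsamples both tissues without
    replacement to the smaller tissue's cell number (or ``target_size``),
    calls a clonotype "expanded" when at least ``min_cells_expanded`` of the
    subsampled cells share its clone id within that tissue, and forms the
    2x2 table of cells (or clonotypes, ``unit="clonotype"``) in expanded
    versus non-expanded clonotypes by tissue.  The OR point estimate is the
    median over rounds; the 95% CI the 2.5/97.5 percentiles.

    The full-data table's exact Fisher test and a Haldane (+0.5) corrected
    OR are retained alongside for finite summaries when cells are zero.
    """
    clones_a = np.asarray(clones_tissue_a)
    clones_b = np.asarray(clones_tissue_b)
    if clones_a.size == 0 or clones_b.size == 0:
        raise ValueError("both tissues must contain cells")
    m = min(clones_a.size, clones_b.size) if target_size is None else int(target_size)
    if m > min(clones_a.size, clones_b.size):
        raise ValueError("target_size exceeds the smaller tissue")
    low_power = m < 10
    if low_power:
        warnings.warn(f"downsample target {m} < 10 cells: low-power estimate")
    rng = np.random.default_rng(seed)
    ors = np.empty(n_downsamples)
    for i in range(n_downsamples):
        sub_a = clones_a if clones_a.size == m else rng.choice(clones_a, m, replace=False)
        sub_b = clones_b if clones_b.size == m else rng.choice(clones_b, m, replace=False)
        ors[i] = _odds_ratio(*_expansion_table(sub_a, sub_b, min_cells_expanded, unit))
    full = _expansion_table(clones_a, clones_b, min_cells_expanded, unit)
    valid = ors[~np.isnan(ors)]  # inf (a zero cell) is a legitimate exact OR
    if valid.size:
        point = float(np.median(valid))
        # nearest-rank quantiles: robust to exact-OR inf values in the tails
        lo, hi = np.quantile(valid, [0.025, 0.975], method="nearest")
    else:
        point, lo, hi = math.nan, math.nan, math.nan
    return ExpansionResult(
        or_point=point,
        ci95=(float(lo), float(hi)),
        n_downsamples=n_downsamples,
        target_size=m,
        low_power=low_power,
        haldane_or_full=haldane_or(*full),
        fisher_full=fisher_exact(ContingencyTable(*full)),
        or_samples=ors if keep_samples else None,
    )


def constant_region_proportions(cells: pd.DataFrame,
                                call_col: str = "dominant_isotype") -> pd.DataFrame:
    """Proportion of cells expressing each constant region, with Wilson 95% CI.

    The denominator is all cells; the ``unassigned`` category is included so
    proportions sum to 1.  Raises if no cell carries an isotype call.
    """
    if call_col not in cells.columns:
        calls = dominant_isotypes(cells)
    else:
        calls = cells[call_col]
    n = len(calls)
    if n == 0 or (calls == UNASSIGNED).all():
        raise ValueError("no assigned cells")
    rows = []
    for gene in list(ISOTYPE_ORDER) + [UNASSIGNED]:
        k = int((calls == gene).sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append({"constant_region": gene, "count": k, "n": n,
                     "proportion": k / n, "ci95_low": float(lo), "ci95_high": float(hi)})
    return pd.DataFrame(rows)
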