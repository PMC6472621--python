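"""Fitness-comparison metrics, summary statistics, ANOVA and tipping points.

Seed yield is the fitness proxy. Treatments are compared to a baseline as a
percentage yield decrease (cost) or increase (benefit):

    C = (1 - Yield_T / Yield_C) * 100
    B = (Yield_T / Yield_C - 1) * 100

Baselines follow the study design: a defended monostand is compared to the
undefended monostand under the same herbivory regime (the undamaged control
when herbivory is absent), while defended plants in a mixture are compared
to the undefended plants of the same run (a paired, within-stand contrast).

The one-way ANOVA is computed from first principles (between/within sums of
squares); the p-value comes from the F distribution via the regularised
incomplete beta function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "SummaryStat",
    "cost",
    "benefit",
    "summarize",
    "anova_oneway",
    "tipping_point",
    "replicate_genotype_means",
    "baseline_for",
    "cost_benefit_table",
    "tipping_table",
]

_CELL_KEYS = ["stand", "D", "c", "d", "h", "pay_costs"]


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    se: float    # standard error of the mean, sd / sqrt(n)
    n: int


def cost(yield_t: float, yield_c: float) -> float:
    """Cost of a treatment as % yield decrease relative to the baseline."""
    if yield_c <= 0:
        raise ValueError("baseline yield must be positive")
    return (1.0 - yield_t / yield_c) * 100.0


def benefit(yield_t: float, yield_c: float) -> float:
    """Benefit of a treatment as % yield increase relative to the baseline."""
    if yield_c <= 0:
        raise ValueError("baseline yield must be positive")
    return (yield_t / yield_c - 1.0) * 100.0


def summarize(values: Sequence[float]) -> SummaryStat:
    """Mean and standard error of the mean over replicates (n >= 2)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("standard error needs at least two values")
    return SummaryStat(
        mean=float(arr.mean()),
        se=float(arr.std(ddof=1) / math.sqrt(arr.size)),
        n=int(arr.size),
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from sums of squares; returns (F, p).

    Raises on fewer than two groups, groups of size < 2, or zero
    within-group variance everywhere (degenerate F).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = n_total - len(arrays)
    if ss_within == 0.0:
        raise ValueError("zero within-group variance in every group; F undefined")
    f_stat = (ss_between / df1) / (ss_within / df2)
    # survival function of the F distribution via the regularised incomplete beta
    p_value = float(special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f_stat)))
    return float(f_stat), p_value


def tipping_point(benefit_by_d: Mapping[float, float]) -> float | None:
    """Smallest damage-reduction level d with positive mean net benefit.

    The grid must be supplied (or sortable) in ascending d; returns None if
    the benefit never turns positive.
    """
    if not benefit_by_d:
        raise ValueError("empty benefit mapping")
    for d in sorted(benefit_by_d):
        if benefit_by_d[d] > 0.0:
            return d
    return None


def replicate_genotype_means(results: pd.DataFrame) -> pd.DataFrame:
    """Mean per-plant seed yield per (cell, replicate, genotype)."""
    keys = _CELL_KEYS + ["cell_id", "replicate", "genotype"]
    out = results.groupby(keys, as_index=False)["seed_yield"].mean()
    return out.rename(columns={"seed_yield": "mean_yield"})


def baseline_for(results: pd.DataFrame, cell: Mapping) -> pd.Series:
    """Per-replicate baseline yields for one treatment cell.

    Mixtures use the undefended co-occupants of the same runs; defended
    monostands use the undefended monostand under the same herbivory level
    (which is the undamaged control when c = 0). Raises if no matching
    control rows exist.
    """
    means = replicate_genotype_means(results)
    if cell["stand"] == "mixture":
        sel = means[
            (means["cell_id"] == cell["cell_id"]) & (means["genotype"] == "undefended")
        ]
    elif cell["stand"] == "monostand_defended":
        sel = means[
            (means["stand"] == "monostand_undefended")
            & np.isclose(means["c"], cell["c"])
        ]
    else:
        raise ValueError("baselines are defined for defended cells only")
    if sel.empty:
        raise LookupError(f"no baseline rows found for cell {cell['cell_id']}")
    return sel.set_index("replicate")["mean_yield"]


def cost_benefit_table(results: pd.DataFrame) -> pd.DataFrame:
    """Cost and benefit of every defended cell, summarised over replicates.

    Per replicate, the treatment yield is the defended-genotype mean and the
    baseline follows :func:`baseline_for` (paired by replicate index); the
    replicate-level C and B are then averaged, with standard errors.
    """
    means = replicate_genotype_means(results)
    defended = means[means["genotype"] == "defended"]
    rows = []
    for cell_id, cell_rows in defended.groupby("cell_id"):
        cell = cell_rows.iloc[0].to_dict()
        baseline = baseline_for(results, cell)
        merged = cell_rows.set_index("replicate")["mean_yield"].to_frame("treat")
        merged["base"] = baseline
        merged = merged.dropna()
        c_vals = [cost(t, b) for t, b in zip(merged["treat"], merged["base"])]
        b_vals = [benefit(t, b) for t, b in zip(merged["treat"], merged["base"])]
        c_stat = summarize(c_vals)
        b_stat = summarize(b_vals)
        rows.append(
            {
                "cell_id": cell_id,
                **{k: cell[k] for k in _CELL_KEYS},
                "cost_mean": c_stat.mean,
                "cost_se": c_stat.se,
                "benefit_mean": b_stat.mean,
                "benefit_se": b_stat.se,
                "n": c_stat.n,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(_CELL_KEYS, kind="mergesort").reset_index(drop=True)


def tipping_table(results: pd.DataFrame) -> pd.DataFrame:
    """Tipping-point d per (c, h): minimal damage reduction with net benefit > 0.

    Intended for mixture suites (net costs-versus-benefits design); benefits
    are the paired within-run defended-vs-undefended contrasts.
    """
    table = cost_benefit_table(results)
    mixtures = table[table["stand"] == "mixture"]
    rows = []
    for (c, h), grp in mixtures.groupby(["c", "h"]):
        mapping = dict(zip(grp["d"], grp["benefit_mean"]))
        rows.append({"c": c, "h": h, "tipping_d": tipping_point(mapping)})
    return pd.DataFrame(rows).sort_values(["c", "h"]).reset_index(drop=True)
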