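"""Two-factor ANOVA comparing aligned vs jittered center-bin correlations.

The center-bin (co-occurrence) correlations of the recorded, temporally
aligned sessions are compared with their jitter-null counterparts in a
two-way ANOVA with factors *alignment* (aligned / jittered) and *pair class*
(L-L / L-U), using Type II sums of squares to accommodate the unbalanced
group sizes, followed by Sidak-corrected pairwise post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .ccp import CCPResult, JitterEnsemble


@dataclass
class EffectResult:
    name: str
    sum_sq: float
    df: float
    f_value: float
    p_value: float


@dataclass
class PosthocResult:
    contrast: str
    estimate: float
    t_value: float
    p_raw: float
    p_sidak: float


@dataclass
class ComparisonReport:
    """ANOVA table plus Sidak post hoc contrasts; degenerate if variance is 0."""

    effects: List[EffectResult] = field(default_factory=list)
    posthoc: List[PosthocResult] = field(default_factory=list)
    degenerate: bool = False

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def build_alignment_table(
    ccps: Sequence[CCPResult],
    ensembles: Sequence[JitterEnsemble],
    jitter_summary: str = "mean",
) -> pd.DataFrame:
    """Long-format table of center-bin values for the alignment ANOVA.

    Each session contributes its aligned center-bin correlation and either
    the mean of its jitter ensemble's center values (``jitter_summary='mean'``)
    or every iteration (``'all'``).
    """
    by_id = {e.session_id: e for e in ensembles}
    rows = []
    for ccp in ccps:
        ens = by_id[ccp.session_id]
        rows.append({"session_id": ccp.session_id, "pair_class": ccp.pair_class,
                     "alignment": "aligned", "value": ccp.r_center})
        if jitter_summary == "mean":
            rows.append({"session_id": ccp.session_id, "pair_class": ccp.pair_class,
                         "alignment": "jittered",
                         "value": float(ens.center_values.mean())})
        elif jitter_summary == "all":
            for v in ens.center_values:
                rows.append({"session_id": ccp.session_id, "pair_class": ccp.pair_class,
                             "alignment": "jittered", "value": float(v)})
        else:
            raise ValueError(f"unknown jitter_summary {jitter_summary!r}")
    return pd.DataFrame(rows)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment 1 - (1 - p)^m for m comparisons."""
    if p >= 1.0:
        return 1.0
    # expm1/log1p keep precision for tiny p, where the naive form underflows
    return float(-np.expm1(m * np.log1p(-p)))


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "alignment",
    factor_b: str = "pair_class",
    posthoc_pairs: Sequence[Tuple[Tuple[str, str], Tuple[str, str]]] = (),
) -> ComparisonReport:
    """Type II two-way ANOVA with interaction and Sidak post hoc contrasts.

    ``posthoc_pairs`` lists cell-vs-cell contrasts as pairs of
    ``(level_a, level_b)`` tuples; by default every aligned-vs-jittered
    contrast within pair class and LL-vs-LU contrast within alignment is
    tested when both factors have exactly two levels.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats

    for factor in (factor_a, factor_b):
        counts = table.groupby(factor)[value].count()
        if (counts < 2).any():
            raise ValueError(f"factor {factor}: every level needs >=2 observations")

    report = ComparisonReport()
    if np.ptp(table[value].to_numpy()) == 0:
        report.degenerate = True
        for name in (factor_a, factor_b, f"{factor_a}:{factor_b}"):
            report.effects.append(EffectResult(name, 0.0, np.nan, np.nan, np.nan))
        return report

    model = smf.ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    rename = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    for row_name, row in anova.iterrows():
        report.effects.append(EffectResult(
            name=rename.get(row_name, str(row_name)),
            sum_sq=float(row["sum_sq"]),
            df=float(row["df"]),
            f_value=float(row["F"]) if not np.isnan(row["F"]) else np.nan,
            p_value=float(row["PR(>F)"]) if not np.isnan(row["PR(>F)"]) else np.nan,
        ))

    if not posthoc_pairs:
        posthoc_pairs = _default_pairs(table, factor_a, factor_b)
    mse = model.mse_resid
    df_resid = model.df_resid
    cells: Dict[Tuple[str, str], np.ndarray] = {
        (str(a), str(b)): grp[value].to_numpy()
        for (a, b), grp in table.groupby([factor_a, factor_b])
    }
    m = len(posthoc_pairs)
    for cell1, cell2 in posthoc_pairs:
        x, y = cells[cell1], cells[cell2]
        est = float(x.mean() - y.mean())
        se = np.sqrt(mse * (1.0 / x.size + 1.0 / y.size))
        t = est / se if se > 0 else np.nan
        p = float(2.0 * stats.t.sf(abs(t), df_resid)) if np.isfinite(t) else np.nan
        report.posthoc.append(PosthocResult(
            contrast=f"{'/'.join(cell1)} vs {'/'.join(cell2)}",
            estimate=est, t_value=float(t), p_raw=p,
            p_sidak=sidak_adjust(p, m) if np.isfinite(t) else np.nan,
        ))
    return report


def _default_pairs(table, factor_a, factor_b):
    la = sorted(table[factor_a].unique())
    lb = sorted(table[factor_b].unique())
    pairs = []
    if len(la) == 2:
        for b in lb:
            pairs.append(((la[0], b), (la[1], b)))
    if len(lb) == 2:
        for a in la:
            pairs.append(((a, lb[0]), (a, lb[1])))
    return pairs


def compare_aligned_jittered(
    ccps: Sequence[CCPResult],
    ensembles: Sequence[JitterEnsemble],
    jitter_summary: str = "all",
) -> ComparisonReport:
    """Full alignment-by-pair-class comparison of center-bin correlations."""
    table = build_alignment_table(ccps, ensembles, jitter_summary=jitter_summary)
    return two_way_anova(table)
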