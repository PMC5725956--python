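"""Group statistics for cultivar discrimination.

For each morphological trait measured across cultivar groups the analysis
is the classical univariate one: per-group mean ± standard error, a
fixed-effects one-way ANOVA, and Tukey–Kramer honestly-significant-
difference multiple comparisons at a chosen confidence level.  No
multivariate step is involved by design — each trait is judged on its own
discriminative power.

The ANOVA is computed from the textbook sums of squares so that the pooled
within-group mean square is shared, unchanged, with the Tukey–Kramer rule:
pair (i, j) is declared distinct when

    |mean_i - mean_j| / sqrt( (MS_within / 2) (1/n_i + 1/n_j) )
        >  q(1 - alpha; k, N - k)

with q the studentized-range quantile (the unequal-n Kramer form).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientReplicatesError

__all__ = ["GroupedTrait", "GroupStats", "summarize", "one_way_anova",
           "tukey_kramer", "group_stats", "stats_tables"]


@dataclass(frozen=True)
class GroupedTrait:
    """One trait's values, grouped by cultivar (or any label)."""

    trait_name: str
    groups: tuple  # of (label, np.ndarray)

    @staticmethod
    def from_dict(trait_name: str, d: dict) -> "GroupedTrait":
        return GroupedTrait(
            trait_name,
            tuple((k, np.asarray(v, dtype=float)) for k, v in d.items()),
        )

    def validated(self) -> "GroupedTrait":
        if len(self.groups) < 2:
            raise InsufficientReplicatesError("need >= 2 groups")
        for label, vals in self.groups:
            if len(vals) < 2:
                raise InsufficientReplicatesError(
                    f"group {label!r} has {len(vals)} value(s); need >= 2"
                )
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {label!r} contains non-finite values")
        return self


@dataclass(frozen=True)
class GroupStats:
    trait_name: str
    summary: dict  # label -> {"mean", "se", "n"}
    anova_f: float
    anova_p: float
    distinct_pairs: frozenset = field(default_factory=frozenset)
    alpha: float = 0.05


def summarize(gt: GroupedTrait) -> dict:
    """Per-group mean, standard error (sd/sqrt(n), sample sd) and n."""
    gt = gt.validated()
    out = {}
    for label, vals in gt.groups:
        n = len(vals)
        sd = float(np.std(vals, ddof=1))
        out[label] = {"mean": float(np.mean(vals)), "se": sd / np.sqrt(n), "n": n}
    return out


def _anova_parts(gt: GroupedTrait):
    values = [vals for _, vals in gt.groups]
    k = len(values)
    ns = np.array([len(v) for v in values])
    N = int(ns.sum())
    means = np.array([v.mean() for v in values])
    grand = np.concatenate(values).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    return k, N, ns, means, ss_between, ss_within


def one_way_anova(gt: GroupedTrait) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA: (F, p).

    Zero pooled within-group variance with unequal means yields p = 0 (with
    a warning: the data are perfectly separated); with all-equal means it is
    degenerate and raises.
    """
    gt = gt.validated()
    k, N, ns, means, ssb, ssw = _anova_parts(gt)
    if ssw == 0.0:
        if ssb == 0.0:
            raise DegenerateDataError("all groups identical and constant")
        warnings.warn("zero within-group variance; p set to 0", stacklevel=2)
        return np.inf, 0.0
    ms_between = ssb / (k - 1)
    ms_within = ssw / (N - k)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, k - 1, N - k))
    return float(f), p


def tukey_kramer(gt: GroupedTrait, alpha: float = 0.05) -> frozenset:
    """Unordered group pairs significantly different at level ``alpha``."""
    gt = gt.validated()
    k, N, ns, means, ssb, ssw = _anova_parts(gt)
    labels = [label for label, _ in gt.groups]
    if ssw == 0.0:
        if ssb == 0.0:
            return frozenset()
        warnings.warn("zero within-group variance; all unequal pairs distinct",
                      stacklevel=2)
        return frozenset(
            frozenset((labels[i], labels[j]))
            for i, j in itertools.combinations(range(k), 2)
            if means[i] != means[j]
        )
    ms_within = ssw / (N - k)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, N - k))
    out = set()
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt((ms_within / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
        if abs(means[i] - means[j]) / se > q_crit:
            out.add(frozenset((labels[i], labels[j])))
    return frozenset(out)


def group_stats(gt: GroupedTrait, alpha: float = 0.05) -> GroupStats:
    """Summary + ANOVA + Tukey–Kramer in one record."""
    f, p = one_way_anova(gt)
    return GroupStats(
        trait_name=gt.trait_name,
        summary=summarize(gt),
        anova_f=f,
        anova_p=p,
        distinct_pairs=tukey_kramer(gt, alpha),
        alpha=alpha,
    )


def stats_tables(trait_table, group_col: str = "group", alpha: float = 0.05,
                 exclude: tuple = ("specimen", "qc_warnings")):
    """Run the full statistics stage on a trait table.

    ``trait_table`` is a pandas DataFrame with one row per specimen, a group
    label column and numeric trait columns.  Missing values (e.g. absent
    nipple geometry) are excluded listwise per trait.  Returns
    (summary_df, anova_df, pairs_df) mirroring the published presentation:
    mean ± SE per group, per-trait F and p, and explicit distinct pairs.
    """
    import pandas as pd

    trait_cols = [c for c in trait_table.columns
                  if c != group_col and c not in exclude
                  and pd.api.types.is_numeric_dtype(trait_table[c])]
    summary_rows, anova_rows, pair_rows = [], [], []
    for col in trait_cols:
        sub = trait_table[[group_col, col]].dropna()
        grouped = {g: vals[col].to_numpy(dtype=float)
                   for g, vals in sub.groupby(group_col, sort=True)}
        grouped = {g: v for g, v in grouped.items() if len(v) >= 2}
        if len(grouped) < 2:
            continue
        gt = GroupedTrait.from_dict(col, grouped)
        if all(np.ptp(v) == 0 for v in grouped.values()) and \
           len({v[0] for v in grouped.values()}) == 1:
            continue  # constant trait (e.g. NippleIdx all zero): nothing to test
        gs = group_stats(gt, alpha=alpha)
        for label, s in gs.summary.items():
            summary_rows.append({"trait": col, group_col: label, **s})
        anova_rows.append({"trait": col, "F": gs.anova_f, "p": gs.anova_p})
        for pair in sorted(tuple(sorted(p)) for p in gs.distinct_pairs):
            pair_rows.append({"trait": col, "group_1": pair[0], "group_2": pair[1]})
    return (pd.DataFrame(summary_rows), pd.DataFrame(anova_rows),
            pd.DataFrame(pair_rows))
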