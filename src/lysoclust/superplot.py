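"""Hierarchical "superplot" statistics over per-cell measurements.

Measurements come as rows (condition, experiment, cell, value): many cells
per independent experiment, several experiments per condition.  Summaries
follow the superplot convention — per-cell values are the small dots,
per-experiment means the large dots, and the condition mean is the
unweighted mean of experiment means.

The test battery mirrors common practice in the field: two-sided pooled
Student's t, one-way ANOVA, Tukey HSD (Tukey-Kramer for unbalanced groups)
for all-pairs comparisons, and Dunnett many-to-one comparisons.  Dunnett
familywise adjustment is computed by seeded Monte Carlo of the null
max-|t| statistic, so adjusted p-values are reproducible for a fixed seed
and their accuracy is bounded by the Monte-Carlo standard error.

Tests default to per-cell values (figure-legend n's are cell counts);
``level="experiment"`` aggregates to experiment means first, the
statistically conservative choice for hierarchical replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Zero variance makes the requested test statistic undefined."""


#: significance tiers: p < 0.05 (*), < 0.01 (**), < 0.001 (***), < 1e-4 (****)
_STAR_TIERS = (1e-4, 1e-3, 1e-2, 5e-2)


def stars(p: float) -> str:
    for i, cut in enumerate(_STAR_TIERS):
        if p < cut:
            return "*" * (4 - i)
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    pair: tuple[str, ...]
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjusted_p: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.adjusted_p < 0.05

    @property
    def stars(self) -> str:
        return stars(self.adjusted_p)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_superplot(table: pd.DataFrame,
                        level: str = "experiment") -> pd.DataFrame:
    """Summary means/SD/n at the cell or experiment level.

    ``level="experiment"``: one mean per (condition, experiment); the
    condition mean is the unweighted mean of experiment means and the SD is
    across experiments.  ``level="cell"``: condition mean and SD across all
    cells pooled.  An experiment-level SD over a single experiment is
    undefined and returned as NaN.
    """
    if level not in ("cell", "experiment"):
        raise ValueError("level must be 'cell' or 'experiment'")
    t = table.dropna(subset=["value"])
    if level == "cell":
        g = t.groupby("condition", sort=True)["value"]
        return g.agg(mean="mean", sd="std", n="count").reset_index()
    per_exp = (t.groupby(["condition", "experiment"], sort=True)["value"]
               .mean().rename("value").reset_index())
    g = per_exp.groupby("condition", sort=True)["value"]
    return g.agg(mean="mean", sd="std", n="count").reset_index()


def _groups_from_table(table: pd.DataFrame, level: str) -> dict[str, np.ndarray]:
    t = table.dropna(subset=["value"])
    if level == "experiment":
        t = (t.groupby(["condition", "experiment"], sort=True)["value"]
             .mean().reset_index())
    return {str(c): g["value"].to_numpy(dtype=float)
            for c, g in t.groupby("condition", sort=True)}


# ---------------------------------------------------------------------------
# tests


def students_t(group_a, group_b, paired: bool = False) -> ComparisonResult:
    """Two-sided Student's t-test (pooled variance, or paired differences)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal n")
        d = a - b
        sd = d.std(ddof=1)
        df = a.size - 1
        if sd == 0:
            if d.mean() == 0:
                return ComparisonResult("paired t", ("a", "b"), 0.0, (df,),
                                        1.0, 1.0, note="zero variance")
            raise DegenerateDataError("zero-variance differences, nonzero mean")
        t = d.mean() / (sd / np.sqrt(a.size))
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            if a.mean() == b.mean():
                return ComparisonResult("t", ("a", "b"), 0.0, (df,), 1.0, 1.0,
                                        note="zero pooled variance")
            raise DegenerateDataError("zero pooled variance, unequal means")
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    name = "paired t" if paired else "t"
    return ComparisonResult(name, ("a", "b"), float(t), (float(df),),
                            float(p), float(p))


def _anova_decomposition(groups: dict[str, np.ndarray]
                         ) -> tuple[float, float, int, int, float]:
    ns = {k: len(v) for k, v in groups.items()}
    if len(groups) < 2 or min(ns.values()) < 2:
        raise ValueError("need >= 2 groups with n >= 2 each")
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(n * (groups[k].mean() - grand) ** 2 for k, n in ns.items())
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    msw = ssw / df_w
    return float(ssb), float(ssw), df_b, df_w, float(msw)


def one_way_anova(groups) -> ComparisonResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within."""
    groups = _as_group_dict(groups)
    ssb, ssw, df_b, df_w, msw = _anova_decomposition(groups)
    if msw == 0:
        if ssb == 0:
            return ComparisonResult("anova", tuple(groups), 0.0,
                                    (df_b, df_w), 1.0, 1.0,
                                    note="zero variance everywhere")
        return ComparisonResult("anova", tuple(groups), float("inf"),
                                (df_b, df_w), 0.0, 0.0,
                                note="zero within-group variance")
    f = (ssb / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return ComparisonResult("anova", tuple(groups), float(f),
                            (df_b, df_w), p, p)


def _as_group_dict(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"g{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def tukey_hsd(groups) -> list[ComparisonResult]:
    """All-pairs comparisons with studentized-range (Tukey-Kramer) adjustment."""
    groups = _as_group_dict(groups)
    ssb, ssw, df_b, df_w, msw = _anova_decomposition(groups)
    names = list(groups)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            diff = a.mean() - b.mean()
            if msw == 0:
                adj = 1.0 if diff == 0 else 0.0
                raw = adj
                q = 0.0 if diff == 0 else float("inf")
                note = "zero within-group variance"
            else:
                se = np.sqrt(msw / 2 * (1 / len(a) + 1 / len(b)))
                q = abs(diff) / se
                adj = float(sps.studentized_range.sf(q, len(names), df_w))
                raw = 2.0 * float(sps.t.sf(q / np.sqrt(2), df_w))
                note = ""
            out.append(ComparisonResult("tukey", (names[i], names[j]),
                                        float(q), (len(names), df_w),
                                        min(raw, 1.0), min(adj, 1.0), note))
    return out


def dunnett(control_group, treatment_groups, n_mc: int = 100_000,
            seed: int = 0) -> list[ComparisonResult]:
    """Many-to-one comparisons against a control, Dunnett-adjusted.

    The familywise adjustment is Monte Carlo: ``n_mc`` draws of the null
    max-|t| statistic (shared control noise and pooled-variance estimate),
    so adjusted p-values carry an MC standard error of roughly
    ``sqrt(p * (1 - p) / n_mc)`` and are reproducible for a fixed seed.
    """
    control = np.asarray(control_group, dtype=float)
    treatments = _as_group_dict(treatment_groups)
    if control.size < 2:
        raise ValueError("control needs n >= 2")
    if not treatments:
        raise ValueError("need at least one treatment group")
    groups = {"control": control, **treatments}
    ssb, ssw, df_b, df_w, msw = _anova_decomposition(groups)
    if msw == 0:
        raise DegenerateDataError("zero within-group variance")
    n0 = control.size
    names = list(treatments)
    t_obs = np.array([
        (treatments[k].mean() - control.mean())
        / np.sqrt(msw * (1 / len(treatments[k]) + 1 / n0)) for k in names])

    rng = np.random.default_rng(seed)
    k = len(names)
    z0 = rng.standard_normal(n_mc)
    zi = rng.standard_normal((n_mc, k))
    s = np.sqrt(rng.chisquare(df_w, n_mc) / df_w)  # shared variance estimate
    ni = np.array([len(treatments[kk]) for kk in names], dtype=float)
    tnull = (zi / np.sqrt(ni) - z0[:, None] / np.sqrt(n0)) \
        / (s[:, None] * np.sqrt(1 / ni + 1 / n0))
    max_abs = np.abs(tnull).max(axis=1)

    out = []
    for idx, name in enumerate(names):
        raw = 2.0 * float(sps.t.sf(abs(t_obs[idx]), df_w))
        adj = float(np.mean(max_abs >= abs(t_obs[idx])))
        out.append(ComparisonResult("dunnett", ("control", name),
                                    float(t_obs[idx]), (k, float(df_w)),
                                    raw, adj))
    return out


# ---------------------------------------------------------------------------
# table-level driver


def compare_conditions(table: pd.DataFrame, test: str = "anova-tukey",
                       control: str | None = None, level: str = "cell",
                       n_mc: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Run the requested test battery on a (condition, experiment, cell,
    value) table and return a tidy comparisons table."""
    groups = _groups_from_table(table, level)
    results: list[ComparisonResult]
    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly 2 conditions")
        (na, a), (nb, b) = groups.items()
        r = students_t(a, b)
        results = [ComparisonResult(r.test_name, (na, nb), r.statistic, r.df,
                                    r.p_value, r.adjusted_p, r.note)]
    elif test == "anova-tukey":
        results = [one_way_anova(groups)] + tukey_hsd(groups)
    elif test == "anova-dunnett":
        if control is None or control not in groups:
            raise ValueError("anova-dunnett requires a valid control name")
        treats = {k: v for k, v in groups.items() if k != control}
        base = dunnett(groups[control], treats, n_mc=n_mc, seed=seed)
        results = [one_way_anova(groups)] + [
            ComparisonResult(r.test_name, (control, r.pair[1]), r.statistic,
                             r.df, r.p_value, r.adjusted_p, r.note)
            for r in base]
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame([{
        "test": r.test_name, "pair": " vs ".join(r.pair), "statistic":
        r.statistic, "df": "/".join(f"{d:g}" for d in r.df), "p": r.p_value,
        "adj_p": r.adjusted_p, "stars": r.stars, "note": r.note,
    } for r in results])
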