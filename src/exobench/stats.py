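"""Condition-comparison statistics and subjective-score analysis.

EMG effort metrics (static RMS, iEMG) and questionnaire scores in small
ergonomics samples are typically non-normal, so the primary route is
nonparametric: Shapiro-Wilk screens normality, the independent-samples
Kruskal-Wallis test compares the device conditions, and Dunn's test with
Bonferroni correction locates the pairwise differences.  The global
discomfort scale, which tends to be normal, uses one-way ANOVA with Tukey's
HSD; a binary covariate (e.g., sex) is compared with the Mann-Whitney U.

Dunn's z statistics are computed from the pooled ranks with tie correction;
two-sided normal p values are multiplied by the number of pairs and clipped
at 1.  Omnibus tests are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "dunn_bonferroni",
    "anova_tukey",
    "mann_whitney",
    "kruskal_type1_rate",
    "build_comparison_report",
]


@dataclass
class ComparisonResult:
    """Omnibus statistic with optional adjusted pairwise p matrix."""

    method: str
    statistic: float
    pvalue: float
    group_names: list[str]
    group_sizes: list[int]
    pairwise: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        if self.pairwise is None:
            return []
        out = []
        names = list(self.pairwise.index)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.pairwise.loc[a, b] < alpha:
                    out.append((a, b))
        return out


def _as_groups(groups, names):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("names length must match number of groups")
    return arrays, list(names)


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); requires 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups, names=None) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p value."""
    arrays, names = _as_groups(groups, names)
    if len(arrays) < 2 or any(len(g) < 1 for g in arrays):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    if sum(len(g) for g in arrays) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return ComparisonResult(method="kruskal-wallis", statistic=float(h),
                            pvalue=float(p), group_names=names,
                            group_sizes=[len(g) for g in arrays])


def dunn_bonferroni(groups, names=None) -> pd.DataFrame:
    """Dunn's post hoc test with Bonferroni correction.

    Returns a symmetric matrix of adjusted two-sided p values (unit
    diagonal).  z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))
    with pooled-rank means R̄ and tie correction T = Σ(t³ − t)/(12(N − 1)).
    """
    arrays, names = _as_groups(groups, names)
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())
                     / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = k * (k - 1) // 2
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            if se == 0:
                p_adj = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
            mat[i, j] = mat[j, i] = p_adj
    return pd.DataFrame(mat, index=names, columns=names)


def anova_tukey(groups, names=None) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""
    arrays, names = _as_groups(groups, names)
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups, each with >= 2 observations")
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError("zero within-group variance everywhere")
    f, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    k = len(arrays)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                mat[i, j] = tk.pvalue[i, j]
    pairwise = pd.DataFrame(mat, index=names, columns=names)
    return ComparisonResult(method="anova-tukey", statistic=float(f),
                            pvalue=float(p), group_names=names,
                            group_sizes=[len(g) for g in arrays],
                            pairwise=pairwise)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U for two independent samples.

    Returns (U, p) with U reported for the first sample.  The p value is
    exact for small tie-free samples (n_a·n_b <= 400), otherwise the normal
    approximation with tie correction is used.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_type1_rate(n_sims: int = 1000, n_groups: int = 5,
                       n_per_group: int = 10, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Fraction of Kruskal-Wallis rejections under identical distributions.

    A calibration utility: with all groups drawn from the same distribution
    the rejection rate should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        groups = rng.standard_normal((n_groups, n_per_group))
        if kruskal_wallis(list(groups)).pvalue < alpha:
            rejections += 1
    return rejections / n_sims


# ---------------------------------------------------------------------------
# report over a tidy metrics table + subjective scores
# ---------------------------------------------------------------------------

def _descriptives(series_by_group: dict[str, np.ndarray]) -> dict:
    out = {}
    for name, vals in series_by_group.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[name] = {"median": float(med), "iqr": [float(q1), float(q3)],
                     "mean": float(np.mean(vals)), "n": int(len(vals))}
    return out


def _compare_conditions(groups: dict[str, np.ndarray], alpha: float) -> dict:
    names = list(groups)
    arrays = [groups[n] for n in names]
    entry: dict = {"conditions_present": names,
                   "descriptives": _descriptives(groups)}
    if sum(len(g) for g in arrays) < 3:
        entry["kruskal"] = None
        entry["significant_pairs"] = []
        return entry
    try:
        sw = [shapiro_wilk(g)[1] for g in arrays if len(g) >= 3]
        entry["shapiro_min_p"] = float(min(sw)) if sw else None
    except ValueError:
        entry["shapiro_min_p"] = None
    kw = kruskal_wallis(arrays, names)
    entry["kruskal"] = {"H": kw.statistic, "p": kw.pvalue}
    posthoc = dunn_bonferroni(arrays, names)
    entry["dunn_bonferroni"] = posthoc.to_dict()
    kw.pairwise = posthoc
    entry["significant_pairs"] = [list(p) for p in kw.significant_pairs(alpha)]
    return entry


def build_comparison_report(metrics: pd.DataFrame,
                            borg: pd.DataFrame | None = None,
                            global_vas: pd.DataFrame | None = None,
                            alpha: float = 0.05,
                            average_sides_tasks: tuple[str, ...] = ("Squat", "Stoop"),
                            ) -> dict:
    """Statistical comparison bundle over a tidy metric table.

    ``metrics`` columns: subject, condition, task, muscle, side, metric,
    value.  Per muscle × task the five conditions are compared with
    Kruskal-Wallis + Dunn-Bonferroni (sides averaged per subject for the
    sagittal tasks, kept separate for Asymmetric); missing conditions (e.g.,
    the Paexo-like device for Squat) are simply absent from that cell.  Borg
    scores use the same nonparametric route per task; the global VAS uses
    ANOVA + Tukey across conditions and Mann-Whitney across sexes.
    """
    report: dict = {"alpha": alpha, "emg": {}, "subjective": {}}
    for (task, metric), df_tm in metrics.groupby(["task", "metric"]):
        if task in average_sides_tasks:
            df_tm = (df_tm.groupby(["subject", "condition", "task", "muscle",
                                    "metric"], as_index=False)["value"].mean())
            df_tm["side"] = "avg"
        for (muscle, side), df_m in df_tm.groupby(["muscle", "side"]):
            groups = {c: g["value"].to_numpy()
                      for c, g in df_m.groupby("condition")}
            groups = {c: v for c, v in groups.items() if len(v) > 0}
            if len(groups) < 2:
                continue
            key = f"{task}/{metric}/{muscle}_{side}"
            report["emg"][key] = _compare_conditions(groups, alpha)

    if borg is not None:
        for task, df_t in borg.groupby("task"):
            groups = {c: g["borg"].to_numpy(dtype=float)
                      for c, g in df_t.groupby("condition")}
            if len(groups) >= 2:
                report["subjective"][f"borg/{task}"] = _compare_conditions(
                    groups, alpha)

    if global_vas is not None:
        groups = {c: g["vas"].to_numpy(dtype=float)
                  for c, g in global_vas.groupby("condition")}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            names = list(groups)
            try:
                res = anova_tukey([groups[n] for n in names], names)
                report["subjective"]["global_vas"] = {
                    "descriptives": _descriptives(groups),
                    "anova": {"F": res.statistic, "p": res.pvalue},
                    "tukey": res.pairwise.to_dict(),
                    "significant_pairs": [list(p) for p in
                                          res.significant_pairs(alpha)],
                }
            except ValueError as exc:
                report["subjective"]["global_vas"] = {"error": str(exc)}
        if "sex" in global_vas.columns:
            sexes = sorted(global_vas["sex"].unique())
            if len(sexes) == 2:
                u, p = mann_whitney(
                    global_vas.loc[global_vas["sex"] == sexes[0], "vas"],
                    global_vas.loc[global_vas["sex"] == sexes[1], "vas"])
                report["subjective"]["global_vas_by_sex"] = {
                    "groups": sexes, "U": u, "p": p}
    return report
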