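"""Group-comparison statistics for morphometry study tables.

For every morphometric parameter the stage runs, per group, a Lilliefors
normality test (Kolmogorov–Smirnov distance against a normal with
estimated mean and SD, p-value from a seeded Monte-Carlo null) and a
Grubbs outlier test; across groups Bartlett's homoscedasticity test,
one-way ANOVA with the η² effect size (labelled small/medium/large by
Cohen's benchmarks 0.01/0.06/0.14), and — only when the ANOVA is
significant — a Tukey HSD post-hoc comparison (Tukey–Kramer for unequal
group sizes).  Normality or variance violations are recorded but do not
switch the test; outliers are flagged, not removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ETA_SQUARED_BENCHMARKS = (("large", 0.14), ("medium", 0.06), ("small", 0.01))

STUDY_GROUPS = ("T1P", "T1B", "T1V", "T1C", "T2P", "T2B", "T2V", "T2C")


# ---------------------------------------------------------------------------
# Lilliefors

def _ks_distance_normal(x: np.ndarray) -> float:
    """Two-sided KS distance to N(mean(x), sd(x)) with estimated moments."""
    n = len(x)
    xs = np.sort(x)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: Lilliefors undefined")
    z = (xs - x.mean()) / sd
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_null(n: int, reps: int, seed: int) -> np.ndarray:
    key = (n, reps, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((reps, n))
        draws = np.sort(draws, axis=1)
        mean = draws.mean(axis=1, keepdims=True)
        sd = draws.std(axis=1, ddof=1, keepdims=True)
        z = (draws - mean) / sd
        cdf = sps.norm.cdf(z)
        i = np.arange(1, n + 1) / n
        d_plus = (i - cdf).max(axis=1)
        d_minus = (cdf - (i - 1 / n)).max(axis=1)
        _NULL_CACHE[key] = np.maximum(d_plus, d_minus)
    return _NULL_CACHE[key]


def lilliefors(sample, n_reps: int = 10000, seed: int = 12345
               ) -> tuple[float, float]:
    """Lilliefors normality test: (D statistic, Monte-Carlo p-value).

    The null distribution of D (KS distance with estimated mean/SD) is
    simulated once per sample size with a fixed seed and cached, making
    p-values reproducible and free of table interpolation.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("Lilliefors needs n >= 4")
    d = _ks_distance_normal(x)
    null = _lilliefors_null(len(x), n_reps, seed)
    p = (1 + int((null >= d).sum())) / (n_reps + 1)
    return d, float(p)


# ---------------------------------------------------------------------------
# Bartlett, ANOVA + eta squared, Tukey, Grubbs

def bartlett(groups) -> tuple[float, float]:
    """Bartlett's chi-square test of equal variances across groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
        if g.std(ddof=1) == 0:
            raise ValueError("zero variance group: Bartlett undefined")
    stat, p = sps.bartlett(*groups)
    return float(stat), float(p)


def eta_squared_label(eta2: float) -> str:
    for name, cut in ETA_SQUARED_BENCHMARKS:
        if eta2 >= cut:
            return name
    return "negligible"


def anova_eta(groups) -> tuple[float, float, float, str]:
    """One-way ANOVA with effect size: (F, p, eta_squared, label).

    η² = SS_between / SS_total; labels follow Cohen's benchmarks with each
    threshold acting as a lower bound (0.14 large, 0.06 medium, 0.01 small).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    all_x = np.concatenate(groups)
    k, n = len(groups), len(all_x)
    if n <= k:
        raise ValueError("need total n > number of groups")
    grand = all_x.mean()
    ss_total = float(((all_x - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("all observations identical: ANOVA undefined")
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    eta2 = ss_between / ss_total
    return float(f), p, float(eta2), eta_squared_label(eta2)


def tukey_hsd(groups, alpha: float = 0.05) -> np.ndarray:
    """Pairwise Tukey HSD p-value matrix (Tukey–Kramer for unequal n)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    res = sps.tukey_hsd(*groups)
    p = np.asarray(res.pvalue, dtype=float)
    np.fill_diagonal(p, 1.0)
    return p


def grubbs(sample, alpha: float = 0.05) -> int | None:
    """Two-sided Grubbs test, applied once; returns the outlier index or None.

    G = max |x_i − mean| / sd against the t-based critical value
    ((n−1)/√n)·sqrt(t²/(n−2+t²)) with t the 1 − α/(2n) quantile of
    Student's t with n−2 degrees of freedom.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("zero-variance sample: no outlier definable")
        return None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
    return i if g > crit else None


# ---------------------------------------------------------------------------
# study-level report

@dataclass
class ParameterStats:
    parameter: str
    groups: list[str]
    group_n: list[int]
    lilliefors_d: dict[str, float]
    lilliefors_p: dict[str, float]
    bartlett_stat: float | None
    bartlett_p: float | None
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    eta_squared: float
    effect_label: str
    tukey_p: list[list[float]] | None   # None when ANOVA is not significant
    grubbs_outliers: dict[str, int]     # group -> flagged row index


@dataclass
class StatsReport:
    alpha: float
    parameters: dict[str, ParameterStats] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "alpha": self.alpha,
            "skipped": self.skipped,
            "parameters": {k: asdict(v) for k, v in self.parameters.items()},
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_stats(study: pd.DataFrame, alpha: float = 0.05,
              parameters: list[str] | None = None,
              group_col: str = "group", seed: int = 12345) -> StatsReport:
    """Per-parameter group comparison over a study table.

    Expects one row per sample with a ``group`` column and numeric
    parameter columns.  Tukey HSD is run only when the ANOVA p-value is
    below ``alpha``.  Parameters with fewer than two usable groups are
    skipped with a log entry.
    """
    if parameters is None:
        parameters = [c for c in study.columns
                      if c not in (group_col, "sample_id")
                      and np.issubdtype(study[c].dtype, np.number)]
    report = StatsReport(alpha=alpha)
    for param in parameters:
        sub = study[[group_col, param]].dropna()
        names = sorted(sub[group_col].unique())
        groups = [sub.loc[sub[group_col] == g, param].to_numpy() for g in names]
        groups = [g for g in groups]
        usable = [(n, g) for n, g in zip(names, groups) if len(g) >= 2]
        if len(usable) < 2:
            logger.warning("parameter %s skipped: fewer than 2 usable groups", param)
            report.skipped.append(param)
            continue
        names = [n for n, _ in usable]
        groups = [g for _, g in usable]

        lillie_d, lillie_p = {}, {}
        grubbs_out = {}
        for name, g in zip(names, groups):
            if len(g) >= 4:
                try:
                    d, p = lilliefors(g, seed=seed)
                    lillie_d[name], lillie_p[name] = d, p
                except ValueError:
                    pass
            if len(g) >= 3:
                try:
                    idx = grubbs(g, alpha)
                except ValueError:
                    idx = None
                if idx is not None:
                    grubbs_out[name] = int(idx)
        try:
            b_stat, b_p = bartlett(groups)
        except ValueError as exc:
            logger.warning("parameter %s: Bartlett not computed: %s", param, exc)
            b_stat = b_p = None

        f, p, eta2, label = anova_eta(groups)
        tukey = None
        if p < alpha:
            tukey = tukey_hsd(groups, alpha).tolist()
        report.parameters[param] = ParameterStats(
            parameter=param, groups=names, group_n=[len(g) for g in groups],
            lilliefors_d=lillie_d, lilliefors_p=lillie_p,
            bartlett_stat=b_stat, bartlett_p=b_p,
            anova_f=f, anova_p=p,
            df_between=len(groups) - 1,
            df_within=sum(len(g) for g in groups) - len(groups),
            eta_squared=eta2, effect_label=label,
            tukey_p=tukey, grubbs_outliers=grubbs_out,
        )
    return report
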