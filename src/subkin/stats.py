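"""Group x frequency statistics for the tracking outcome measures.

The statistical battery mirrors standard practice for a mixed design with a
between factor (group: PwP / OC / YC) and a within factor (stimulus
frequency, 6 levels):

* mixed-design ANOVA with Mauchly's sphericity test and Greenhouse-Geisser
  correction of the within and interaction effects when violated;
* Holm-corrected pairwise post-hoc t-tests on participant means
  (averaged over frequency), with Cohen's d;
* per-participant linear regressions of each measure on frequency, with a
  one-sample t-test of the slopes against zero;
* a noncentral-t power computation for two-sample t-tests, used for
  sample-size planning.

The module exposes both the individual operations and a statsmodels-style
:class:`OutcomeModel` whose :meth:`~OutcomeModel.fit` returns an
:class:`OutcomeResults` bundling all of the above with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "aggregate",
    "slope_test",
    "mixed_anova",
    "posthoc_holm",
    "ttest_power_n",
    "cohens_d",
    "significance_band",
    "OutcomeModel",
    "OutcomeResults",
]

MAUCHLY_ALPHA = 0.05


def significance_band(p: float) -> str:
    """The reporting convention: significant below 0.05, trend below 0.1."""
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "trend"
    return "ns"


def aggregate(metrics: pd.DataFrame, by: str = "frequency") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average segment-level metrics per participant per ``by`` level.

    Returns ``(table, missing)`` where ``table`` has one row per participant
    x level and ``missing`` lists (participant, level) cells absent from the
    input. Participants with missing cells are flagged with a warning (they
    must be dropped for the repeated-measures ANOVA but can still enter the
    slope analysis).
    """
    value_cols = [
        c
        for c in metrics.columns
        if c
        not in ("participant_id", "group", "trial_index", by)
        and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    table = (
        metrics.groupby(["participant_id", "group", by], as_index=False)[value_cols]
        .mean()
        .sort_values(["group", "participant_id", by])
        .reset_index(drop=True)
    )
    levels = np.sort(metrics[by].unique())
    full = pd.MultiIndex.from_product(
        [table["participant_id"].unique(), levels], names=["participant_id", by]
    )
    have = pd.MultiIndex.from_frame(table[["participant_id", by]])
    missing_idx = full.difference(have)
    missing = pd.DataFrame(list(missing_idx), columns=["participant_id", by])
    if len(missing):
        warnings.warn(
            f"{len(missing)} missing participant x {by} cells; affected "
            "participants are excluded from the repeated-measures ANOVA",
            stacklevel=2,
        )
    return table, missing


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Cohen's d with pooled SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return np.nan
    return float((a.mean() - b.mean()) / sp)


@dataclass
class SlopeTestResult:
    slopes: pd.DataFrame  # participant_id, group, slope
    mean_slope: float
    t: float
    df: int
    p: float
    d: float


def slope_test(table: pd.DataFrame, metric: str, by: str = "frequency") -> SlopeTestResult:
    """Per-participant OLS slope of ``metric`` vs ``by``, tested against 0.

    The effect size is d = mean(slope) / SD(slope). Participants need at
    least two levels; a single level raises ``ValueError``.
    """
    rows = []
    for (pid, group), sub in table.groupby(["participant_id", "group"], sort=True):
        if sub[by].nunique() < 2:
            raise ValueError(f"participant {pid} has fewer than 2 {by} levels")
        slope = np.polyfit(sub[by].to_numpy(float), sub[metric].to_numpy(float), 1)[0]
        rows.append({"participant_id": pid, "group": group, "slope": slope})
    slopes = pd.DataFrame(rows)
    vals = slopes["slope"].to_numpy()
    sd = vals.std(ddof=1)
    if sd == 0:
        # degenerate: identical slopes; report an infinite t with d undefined
        t, p, d = (np.inf * np.sign(vals.mean()), 0.0, np.nan) if vals.mean() != 0 else (0.0, 1.0, np.nan)
    else:
        t, p = sps.ttest_1samp(vals, 0.0)
        d = vals.mean() / sd
    return SlopeTestResult(
        slopes=slopes,
        mean_slope=float(vals.mean()),
        t=float(t),
        df=len(vals) - 1,
        p=float(p),
        d=float(d),
    )


def mixed_anova(table: pd.DataFrame, metric: str, by: str = "frequency") -> pd.DataFrame:
    """Mixed-design ANOVA (between: group; within: ``by``).

    Requires a complete balanced design (every participant measured at every
    level). Returns a table with effects ``group``, ``frequency`` and
    ``interaction``; when Mauchly's test rejects sphericity (p < 0.05) the
    within and interaction effects carry Greenhouse-Geisser-corrected
    degrees of freedom and p-values.
    """
    counts = table.groupby("participant_id")[by].nunique()
    n_levels = table[by].nunique()
    if (counts != n_levels).any():
        bad = counts[counts != n_levels].index.tolist()
        raise ValueError(
            f"incomplete design for participants {bad}; drop them (see "
            "aggregate() missing-cell report) before the repeated-measures ANOVA"
        )
    aov = pg.mixed_anova(
        data=table,
        dv=metric,
        within=by,
        subject="participant_id",
        between="group",
        correction="auto",
    )
    aov = aov.set_index("Source")
    eps = aov.loc[by, "eps"] if "eps" in aov.columns else np.nan
    sphericity_ok = True
    if "p_spher" in aov.columns and np.isfinite(aov.loc[by].get("p_spher", np.nan)):
        sphericity_ok = bool(aov.loc[by, "p_spher"] >= MAUCHLY_ALPHA)
    rows = []
    for label, source in (("group", "group"), ("frequency", by), ("interaction", "Interaction")):
        F = float(aov.loc[source, "F"])
        df1 = float(aov.loc[source, "DF1"])
        df2 = float(aov.loc[source, "DF2"])
        p = float(aov.loc[source, "p_unc"])
        corrected = False
        if label in ("frequency", "interaction") and not sphericity_ok and np.isfinite(eps):
            df1, df2 = eps * df1, eps * df2
            p = float(sps.f.sf(F, df1, df2))
            corrected = True
        rows.append(
            {
                "effect": label,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "gg_corrected": corrected,
                "band": significance_band(p),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mauchly_ok"] = sphericity_ok
    out.attrs["eps"] = float(eps) if np.isfinite(eps) else 1.0
    return out


def posthoc_holm(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Holm-corrected pairwise group t-tests on participant means.

    Participant values are first averaged over frequencies (the main-effect
    level); each group pair gets a pooled-variance two-sample t-test, and
    the p-values are Holm step-down adjusted.
    """
    means = table.groupby(["participant_id", "group"], as_index=False)[metric].mean()
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for g1, g2 in combinations(groups, 2):
        a = means.loc[means["group"] == g1, metric].to_numpy()
        b = means.loc[means["group"] == g2, metric].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group {g1 if len(a) < 2 else g2} has n < 2")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean1": a.mean(),
                "mean2": b.mean(),
                "t": float(t),
                "df": len(a) + len(b) - 2,
                "p_raw": float(p),
                "d": cohens_d(a, b),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    out["band"] = out["p_holm"].map(significance_band)
    return out


def _power_two_sample(d: float, n: int, alpha: float) -> float:
    """Exact noncentral-t power of a two-sided two-sample t-test."""
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    p = float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    if not np.isfinite(p):  # scipy's noncentral t fails for very large nc
        p = float(sps.norm.sf(tcrit - nc) + sps.norm.cdf(-tcrit - nc))
    return p


def ttest_power_n(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    power: float = 0.95,
    alpha: float = 0.05,
) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    The effect size is |mean1 - mean2| over the pooled SD
    ``sqrt((sd1^2 + sd2^2)/2)``; power is evaluated with the noncentral-t
    distribution and the minimal integer n reaching the target is returned.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    effect = abs(mean1 - mean2)
    if effect == 0:
        raise ValueError("zero effect: target power unreachable")
    d = effect / np.sqrt((sd1**2 + sd2**2) / 2.0)
    try:
        n = TTestIndPower().solve_power(
            effect_size=d, power=power, alpha=alpha, ratio=1.0
        )
        n = float(np.atleast_1d(n)[0])
    except Exception:  # extreme effects can break the numeric solver
        n = np.nan
    n = max(2, int(np.ceil(n))) if np.isfinite(n) else 2
    while n > 2 and _power_two_sample(d, n - 1, alpha) >= power:
        n -= 1
    while _power_two_sample(d, n, alpha) < power:
        n += 1
    return n


@dataclass
class OutcomeResults:
    """Fitted statistics for one outcome measure.

    Carries the ANOVA table, the Holm-corrected pairwise contrasts, the
    per-participant slope test, and the participant x frequency table used.
    """

    metric: str
    table: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    slopes: SlopeTestResult
    n_dropped: int = 0

    def summary(self) -> str:
        lines = [f"Outcome: {self.metric}"]
        if self.n_dropped:
            lines.append(
                f"  ({self.n_dropped} participants dropped from the ANOVA: incomplete design)"
            )
        lines.append("  Mixed-design ANOVA (between: group, within: frequency)")
        for _, r in self.anova.iterrows():
            gg = " (GG)" if r["gg_corrected"] else ""
            lines.append(
                f"    {r['effect']:<12} F({r['df1']:.3f},{r['df2']:.3f}) = "
                f"{r['F']:.3f}, p = {r['p']:.4g}{gg} [{r['band']}]"
            )
        lines.append("  Post-hoc pairwise t-tests (Holm-corrected)")
        for _, r in self.posthoc.iterrows():
            lines.append(
                f"    {r['group1']} vs {r['group2']}: "
                f"{r['mean1']:.3f} vs {r['mean2']:.3f}, t({r['df']}) = {r['t']:.3f}, "
                f"p = {r['p_holm']:.4g}, d = {r['d']:.2f} [{r['band']}]"
            )
        s = self.slopes
        lines.append(
            f"  Slopes vs frequency: mean {s.mean_slope:.3f}/Hz, "
            f"t({s.df}) = {s.t:.2f}, p = {s.p:.4g}, d = {s.d:.2f}"
        )
        return "\n".join(lines)


class OutcomeModel:
    """Statsmodels-style front end to the statistical battery.

    Built from a segment- or cell-level metrics DataFrame; ``fit`` aggregates
    to participant x frequency cells, runs the mixed ANOVA (on the complete-
    design subset), the Holm post-hocs and the slope test, and returns an
    :class:`OutcomeResults`.
    """

    def __init__(self, metrics: pd.DataFrame, metric: str, by: str = "frequency"):
        if metric not in metrics.columns:
            raise ValueError(f"metric {metric!r} not in table")
        self.metrics = metrics
        self.metric = metric
        self.by = by

    @classmethod
    def from_dataframe(cls, metrics: pd.DataFrame, metric: str, by: str = "frequency"):
        return cls(metrics, metric, by)

    def fit(self) -> OutcomeResults:
        table, missing = aggregate(self.metrics, by=self.by)
        incomplete = set(missing["participant_id"]) if len(missing) else set()
        complete = table[~table["participant_id"].isin(incomplete)]
        anova = mixed_anova(complete, self.metric, by=self.by)
        posthoc = posthoc_holm(complete, self.metric)
        slopes = slope_test(table, self.metric, by=self.by)
        return OutcomeResults(
            metric=self.metric,
            table=table,
            anova=anova,
            posthoc=posthoc,
            slopes=slopes,
            n_dropped=len(incomplete),
        )
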