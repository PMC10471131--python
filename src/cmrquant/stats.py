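"""Group classification and the cohort statistical battery.

Covers the analysis applied to the primate cohort: rule-based
classification into healthy / HFpEF / HFrEF from echocardiographic
scalars, classical one-way ANOVA, age-adjusted ANCOVA (extra
sum-of-squares F test) with adjusted means at the grand-mean age, Pearson
and age-partial correlation, and nonparametric ROC analysis with the
Youden-index cutoff.

Classification thresholds (cynomolgus-specific):

* EF < 65%  ->  HFrEF.
* Otherwise HFpEF when at least two of three diastolic criteria hold:
  (1) E'/A' or E/A ratio < 0.8 or > 3; (2) septal E' < 7 cm/s;
  (3) E/E' > 10.
* Otherwise healthy.

p-values are reported raw and two-sided; no multiple-testing correction is
applied (the report carries the count of tests performed instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

EF_HFREF_THRESHOLD = 65.0  # percent
SEPTAL_EP_THRESHOLD = 7.0  # cm/s
E_EP_THRESHOLD = 10.0
RATIO_LOW, RATIO_HIGH = 0.8, 3.0


@dataclass(frozen=True)
class EchoRecord:
    """Echocardiographic scalars of one subject."""

    ef_pct: float
    e_a: float
    ep_ap: float
    septal_ep: float  # cm/s
    e_ep: float

    def __post_init__(self) -> None:
        vals = (self.ef_pct, self.e_a, self.ep_ap, self.septal_ep, self.e_ep)
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ValueError("echo record has missing or non-finite fields")
        if not 0 < self.ef_pct < 100:
            raise ValueError("EF must lie in (0, 100) percent")
        if self.e_a <= 0 or self.ep_ap <= 0 or self.e_ep <= 0:
            raise ValueError("Doppler ratios must be positive")


def diastolic_criteria(echo: EchoRecord) -> tuple[bool, bool, bool]:
    """The three diastolic-dysfunction criteria, evaluated individually."""

    def out_of_band(x: float) -> bool:
        return x < RATIO_LOW or x > RATIO_HIGH

    c1 = out_of_band(echo.ep_ap) or out_of_band(echo.e_a)
    c2 = echo.septal_ep < SEPTAL_EP_THRESHOLD
    c3 = echo.e_ep > E_EP_THRESHOLD
    return c1, c2, c3


def classify_subject(echo: EchoRecord) -> str:
    """Assign healthy / HFpEF / HFrEF from the echo record."""
    if echo.ef_pct < EF_HFREF_THRESHOLD:
        return "HFrEF"
    if sum(diastolic_criteria(echo)) >= 2:
        return "HFpEF"
    return "healthy"


def one_way_anova(values, group_labels) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Requires at least two groups with at least two subjects each.  When
    both the between- and within-group sums of squares vanish (all values
    identical) F is defined as 0 with p = 1; a zero within-group variance
    with real group differences gives F = inf, p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two subjects")
    n_total = len(values)
    k = len(groups)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


@dataclass
class AncovaResult:
    """Age-adjusted group comparison."""

    adjusted_means: dict[str, float]  # evaluated at the grand-mean covariate
    f_group: float
    p_group: float
    covariate_coef: float
    n: int


def ancova_age_adjust(values, group_labels, age) -> AncovaResult:
    """ANCOVA: value ~ group + age; group tested by the extra-SS (Type II) F.

    Adjusted group means are model predictions at the grand-mean age.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": np.asarray(group_labels).astype(str),
            "age": np.asarray(age, dtype=float),
        }
    ).dropna()
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    if df.groupby("group").size().min() < 2:
        raise ValueError("every group needs at least two subjects")
    if np.ptp(df["age"].to_numpy()) == 0:
        raise ValueError("age is constant; ANCOVA design is degenerate")
    model = smf.ols("value ~ C(group) + age", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_group = float(table.loc["C(group)", "F"])
    p_group = float(table.loc["C(group)", "PR(>F)"])
    mean_age = float(df["age"].mean())
    pred = model.predict(
        pd.DataFrame({"group": sorted(df["group"].unique()), "age": mean_age})
    )
    adjusted = dict(zip(sorted(df["group"].unique()), map(float, pred)))
    return AncovaResult(
        adjusted_means=adjusted,
        f_group=f_group,
        p_group=p_group,
        covariate_coef=float(model.params["age"]),
        n=len(df),
    )


def correlations(x, y, covariate=None):
    """Pearson correlation and, given a covariate, the partial correlation.

    Returns ``{"pearson": (r, p)}`` plus ``"partial": (r, p)`` when a
    covariate is supplied.  The partial correlation is computed by the
    residual method: x and y are each regressed on the covariate and the
    residuals correlated; its p uses a t test on n - 3 degrees of freedom.
    A constant covariate adjusts nothing and reduces to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must have nonzero variance")
    r, p = sps.pearsonr(x, y)
    out = {"pearson": (float(r), float(p))}
    if covariate is not None:
        z = np.asarray(covariate, dtype=float)
        n = len(x)
        if n < 4:
            raise ValueError("partial correlation needs n >= 4")
        if np.ptp(z) == 0:
            out["partial"] = out["pearson"]
            return out
        design = np.column_stack([np.ones(n), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        pr = float(np.corrcoef(rx, ry)[0, 1])
        dof = n - 3
        if dof > 0 and abs(pr) < 1.0:
            t = pr * np.sqrt(dof / (1.0 - pr**2))
            pp = float(2 * sps.t.sf(abs(t), dof))
        else:
            pp = 0.0 if abs(pr) >= 1.0 else float("nan")
        out["partial"] = (pr, pp)
    return out


@dataclass
class ROCResult:
    """Empirical ROC summary with the Youden-index operating point."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    orientation_note: str | None = None


def roc_youden(scores, binary_labels) -> ROCResult:
    """Empirical ROC of a score for a binary outcome; cutoff by Youden's J.

    Higher score is taken to indicate the positive (diseased) class; if the
    resulting AUC is below 0.5 the result carries a note rather than being
    silently flipped.  AUC uses midrank tie handling (the normalised
    Mann-Whitney U).  Ties in J are broken toward the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    # thresholds are descending; among tied J pick the lowest cutoff
    best = int(np.flatnonzero(j == j.max())[-1])
    cutoff = float(thr[best])
    note = None
    if auc < 0.5:
        note = "AUC < 0.5: score orientation is opposite the assumed direction"
    return ROCResult(
        auc=auc,
        cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden_j=float(j[best]),
        n_pos=n_pos,
        n_neg=n_neg,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        orientation_note=note,
    )


#: cohort variables summarised per group
REPORT_VARIABLES = [
    "age_years",
    "ecv_pct",
    "perf_rest",
    "perf_stress",
    "mpr",
    "ef_pct",
    "e_a",
    "ep_ap",
    "septal_ep",
    "e_ep",
]


def run_cohort_analysis(cohort: pd.DataFrame, adjust_age: bool = True) -> dict:
    """Full statistical report for a cohort table.

    Produces per-variable group means +/- SD, one-way ANOVA p (variables
    observed in >= 2 groups), age-adjusted ANCOVA p, ECV correlations with
    EF and the diastolic indices (plain and age-partial), and ECV ROC
    analyses for heart-failure-vs-healthy and HFrEF-vs-HFpEF.  Variables or
    contrasts whose data are missing are skipped with a log entry.  The
    report counts the hypothesis tests performed; p-values are raw.
    """
    df = cohort.copy()
    groups = list(pd.unique(df["group"]))
    report: dict = {"groups": {g: int((df["group"] == g).sum()) for g in groups}, "variables": {}}
    n_tests = 0

    for var in REPORT_VARIABLES:
        if var not in df:
            logger.info("variable %s absent from cohort; skipped", var)
            continue
        entry: dict = {"by_group": {}}
        for g in groups:
            vals = df.loc[df["group"] == g, var].dropna()
            entry["by_group"][g] = {
                "mean": float(vals.mean()) if len(vals) else None,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                "n": int(len(vals)),
            }
        sub = df[["group", var]].dropna()
        usable = sub.groupby("group").size()
        usable = usable[usable >= 2]
        if len(usable) >= 2:
            keep = sub[sub["group"].isin(usable.index)]
            f, p = one_way_anova(keep[var].to_numpy(), keep["group"].to_numpy())
            entry["anova"] = {"F": f, "p": p, "groups_used": list(usable.index)}
            n_tests += 1
            if adjust_age and var != "age_years":
                sub_age = df[["group", var, "age_years"]].dropna()
                sub_age = sub_age[sub_age["group"].isin(usable.index)]
                try:
                    anc = ancova_age_adjust(
                        sub_age[var].to_numpy(),
                        sub_age["group"].to_numpy(),
                        sub_age["age_years"].to_numpy(),
                    )
                    entry["ancova_age"] = {
                        "p": anc.p_group,
                        "F": anc.f_group,
                        "adjusted_means": anc.adjusted_means,
                    }
                    n_tests += 1
                except ValueError as exc:
                    logger.info("ANCOVA skipped for %s: %s", var, exc)
        else:
            logger.info("ANOVA skipped for %s: fewer than two usable groups", var)
        report["variables"][var] = entry

    # ECV correlations with function/diastolic indices
    report["correlations"] = {}
    for other in ("ef_pct", "ep_ap", "e_a", "septal_ep"):
        sub = df[["ecv_pct", other, "age_years"]].dropna()
        if len(sub) < 4 or sub[other].nunique() < 2 or sub["ecv_pct"].nunique() < 2:
            logger.info("correlation ecv~%s skipped: insufficient data", other)
            continue
        res = correlations(
            sub["ecv_pct"].to_numpy(),
            sub[other].to_numpy(),
            covariate=sub["age_years"].to_numpy() if adjust_age else None,
        )
        report["correlations"][f"ecv_vs_{other}"] = {
            k: {"r": v[0], "p": v[1]} for k, v in res.items()
        }
        n_tests += len(res)

    # ROC of ECV: pooled HF vs healthy, and HFrEF vs HFpEF
    report["roc"] = {}
    contrasts = {
        "HF_vs_healthy": (df["group"].isin(["HFpEF", "HFrEF"]), df["group"] == "healthy"),
        "HFrEF_vs_HFpEF": (df["group"] == "HFrEF", df["group"] == "HFpEF"),
    }
    for name, (pos, neg) in contrasts.items():
        sel = (pos | neg) & df["ecv_pct"].notna()
        if not (pos & sel).any() or not (neg & sel).any():
            logger.info("ROC %s skipped: a class is empty", name)
            continue
        res = roc_youden(df.loc[sel, "ecv_pct"].to_numpy(), pos[sel].to_numpy().astype(int))
        d = asdict(res)
        for arr_key in ("fpr", "tpr", "thresholds"):
            d[arr_key] = [float(v) for v in d[arr_key]]
        report["roc"][name] = d
        n_tests += 1

    report["n_tests_performed"] = n_tests
    report["multiple_testing_correction"] = "none"
    return report
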