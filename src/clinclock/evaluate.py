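"""Clock performance evaluation: quartile-stratified Kaplan-Meier survival with
log-rank tests, horizon-mortality ROC with paired AUC comparison (DeLong),
concordance, multiplicative-noise robustness, cross-clock binning, and the
two-arm longitudinal aging-rate contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .cohort import CohortTable


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quartile stratification / Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class StratumCurve:
    label: str
    n: int
    curve: pd.DataFrame  # columns: time, survival, at_risk


@dataclass
class StratificationResult:
    """Per age-bin quartile strata with KM curves and pairwise log-rank tests."""

    bins: list[tuple[float, float]]
    strata: dict[tuple[float, float], dict[str, StratumCurve]]
    logrank: pd.DataFrame  # bin_lo, bin_hi, comparison, statistic, p_value

    def tidy(self) -> pd.DataFrame:
        rows = []
        for b, groups in self.strata.items():
            for label, sc in groups.items():
                for _, r in sc.curve.iterrows():
                    rows.append({"bin_lo": b[0], "bin_hi": b[1],
                                 "stratum": label, "time": r["time"],
                                 "survival": r["survival"],
                                 "at_risk": r["at_risk"]})
        return pd.DataFrame(rows)


def _km_curve(time: np.ndarray, event: np.ndarray, label: str) -> StratumCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event, label=label)
    surv = kmf.survival_function_[label]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    curve = pd.DataFrame({"time": surv.index.to_numpy(float),
                          "survival": surv.to_numpy(float),
                          "at_risk": at_risk.to_numpy(float)})
    return StratumCurve(label=label, n=len(time), curve=curve)


def stratify_quartiles(
    cohort: CohortTable,
    score: pd.Series,
    age_bins: Sequence[tuple[float, float]] = ((45, 54), (55, 64),
                                               (65, 74), (75, 84)),
    mode: str = "score",
    by_sex: bool = False,
) -> StratificationResult:
    """Within each chronological-age bin, label bottom-quartile ("low"),
    top-quartile ("high") and middle strata of the score (or of score - CA in
    ``delta`` mode) and compare each extreme stratum to the middle by log-rank.

    Quartile cut points are computed within each age (and, optionally,
    age-sex) bin, not globally.
    """
    if mode not in ("score", "delta"):
        raise EvaluationError(f"unknown stratification mode {mode!r}")
    values = score - cohort.meta["chron_age"] if mode == "delta" else score
    if (cohort.meta["followup_time"] <= 0).all():
        raise EvaluationError("all follow-up times are zero; no curves to fit")

    strata: dict[tuple[float, float], dict[str, StratumCurve]] = {}
    tests = []
    for lo, hi in age_bins:
        in_bin = ((cohort.meta["chron_age"] >= lo)
                  & (cohort.meta["chron_age"] <= hi))
        if in_bin.sum() == 0:
            warnings.warn(f"age bin [{lo}, {hi}] is empty; skipped", UserWarning)
            continue
        if in_bin.sum() < 20:
            warnings.warn(f"age bin [{lo}, {hi}] has only {int(in_bin.sum())} "
                          "subjects", UserWarning)
        labels = pd.Series("middle", index=cohort.meta.index[in_bin])
        groups = ([("all", cohort.meta.index[in_bin])] if not by_sex else
                  [(s, cohort.meta.index[in_bin & (cohort.meta["sex"] == s)])
                   for s in ("male", "female")])
        for _, ids in groups:
            if len(ids) == 0:
                continue
            v = values.loc[ids]
            q25, q75 = v.quantile(0.25), v.quantile(0.75)
            labels.loc[ids[v <= q25]] = "low"
            labels.loc[ids[v >= q75]] = "high"
        bin_curves = {}
        for label in ("low", "middle", "high"):
            ids = labels.index[labels == label]
            if len(ids) == 0:
                continue
            bin_curves[label] = _km_curve(
                cohort.meta.loc[ids, "followup_time"].to_numpy(float),
                cohort.meta.loc[ids, "event"].to_numpy(int), label)
        strata[(lo, hi)] = bin_curves
        for a, bl in (("low", "middle"), ("high", "middle"), ("low", "high")):
            if a not in bin_curves or bl not in bin_curves:
                continue
            ia = labels.index[labels == a]
            ib = labels.index[labels == bl]
            res = logrank_test(
                cohort.meta.loc[ia, "followup_time"],
                cohort.meta.loc[ib, "followup_time"],
                event_observed_A=cohort.meta.loc[ia, "event"],
                event_observed_B=cohort.meta.loc[ib, "event"])
            tests.append({"bin_lo": lo, "bin_hi": hi,
                          "comparison": f"{a}_vs_{bl}",
                          "statistic": res.test_statistic,
                          "p_value": res.p_value})
    return StratificationResult(bins=list(strata), strata=strata,
                                logrank=pd.DataFrame(
                                    tests, columns=["bin_lo", "bin_hi",
                                                    "comparison", "statistic",
                                                    "p_value"]))


# ---------------------------------------------------------------------------
# horizon-mortality ROC with DeLong comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_cov(scores: np.ndarray, labels: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fast DeLong AUC estimates and covariance for k scores on shared labels.

    scores: k x n matrix; labels: n boolean (positive = event).
    """
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    if m == 0 or n == 0:
        raise EvaluationError("need both positive and negative labels")
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def delong_test(score_a: np.ndarray, score_b: np.ndarray,
                labels: np.ndarray) -> float:
    """Two-sided p-value for the paired difference in AUC between two scores."""
    if np.array_equal(score_a, score_b):
        return 1.0
    aucs, cov = _delong_auc_cov(np.vstack([score_a, score_b]),
                                labels.astype(bool))
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class RocResult:
    horizon: float
    n_used: int
    auc: dict[str, float]
    roc_points: dict[str, pd.DataFrame]
    pairwise_p: pd.DataFrame  # score_a, score_b, p_value

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"score": list(self.auc),
                             "auc": list(self.auc.values())})


def roc_mortality(
    cohort: CohortTable,
    scores: Mapping[str, pd.Series],
    horizon: float,
) -> RocResult:
    """ROC for death within ``horizon`` years; subjects censored before the
    horizon are excluded.  Pairwise AUC differences tested with DeLong."""
    from sklearn.metrics import roc_curve

    meta = cohort.meta
    died_within = (meta["event"] == 1) & (meta["followup_time"] <= horizon)
    usable = died_within | (meta["followup_time"] >= horizon)
    if usable.sum() == 0:
        raise EvaluationError("no subjects with usable follow-up at this horizon")
    labels = died_within[usable].to_numpy(bool)
    if labels.all() or not labels.any():
        raise EvaluationError("labels are single-class at this horizon")

    auc, points = {}, {}
    names = list(scores)
    mat = np.vstack([scores[n][usable].to_numpy(float) for n in names])
    aucs, _ = _delong_auc_cov(mat, labels)
    for i, n in enumerate(names):
        auc[n] = float(aucs[i])
        fpr, tpr, _ = roc_curve(labels, mat[i])
        points[n] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairs.append({"score_a": a, "score_b": b,
                          "p_value": delong_test(mat[i], mat[names.index(b)],
                                                 labels)})
    return RocResult(horizon=horizon, n_used=int(usable.sum()), auc=auc,
                     roc_points=points,
                     pairwise_p=pd.DataFrame(
                         pairs, columns=["score_a", "score_b", "p_value"]))


def concordance(cohort: CohortTable, score: pd.Series) -> float:
    """Harrell's C-index of a risk score against observed survival
    (higher score = higher risk = shorter survival)."""
    return float(concordance_index(
        cohort.meta["followup_time"], -score.loc[cohort.meta.index],
        event_observed=cohort.meta["event"]))


# ---------------------------------------------------------------------------
# noise robustness
# ---------------------------------------------------------------------------

@dataclass
class NoiseSensitivityResult:
    noise_sd_fraction: float
    n_replicates: int
    errors: dict[str, np.ndarray]   # per clock: flattened relative errors
    summary: pd.DataFrame           # clock, error_sd, lo95, hi95
    used_fallback: dict[str, bool] = field(default_factory=dict)


def noise_sensitivity(
    cohort: CohortTable,
    clocks: Mapping[str, Callable[[CohortTable], pd.Series]],
    noise_sd_fraction: float = 0.10,
    n_replicates: int = 20,
    seed: int = 0,
) -> NoiseSensitivityResult:
    """Multiplicative Gaussian measurement noise: every clinical parameter is
    scaled by (1 + eps), eps ~ N(0, noise_sd_fraction), per replicate; each
    clock is recomputed and the distribution of relative score errors
    summarized (sd and central 95% interval).

    Clocks whose unperturbed score touches zero fall back to absolute errors
    in years.
    """
    rng = np.random.default_rng(seed)
    base = {name: fn(cohort).to_numpy(float) for name, fn in clocks.items()}
    errors: dict[str, list[np.ndarray]] = {name: [] for name in clocks}
    fallback = {name: bool(np.any(np.abs(b) < 1e-9))
                for name, b in base.items()}
    for _ in range(n_replicates):
        noisy = cohort.copy()
        eps = rng.normal(0.0, noise_sd_fraction, size=noisy.X.shape)
        noisy.X = noisy.X * (1.0 + eps)
        for name, fn in clocks.items():
            pert = fn(noisy).to_numpy(float)
            if fallback[name]:
                errors[name].append(pert - base[name])
            else:
                errors[name].append((pert - base[name]) / base[name])
    flat = {name: np.concatenate(v) for name, v in errors.items()}
    rows = [{"clock": name,
             "error_sd": float(np.std(v, ddof=1)),
             "lo95": float(np.quantile(v, 0.025)),
             "hi95": float(np.quantile(v, 0.975))}
            for name, v in flat.items()]
    return NoiseSensitivityResult(
        noise_sd_fraction=noise_sd_fraction, n_replicates=n_replicates,
        errors=flat, summary=pd.DataFrame(rows), used_fallback=fallback)


# ---------------------------------------------------------------------------
# cross-clock binning
# ---------------------------------------------------------------------------

def cross_binning(
    cohort: CohortTable,
    score_a: pd.Series,
    score_b: pd.Series,
    bins_on_a: Sequence[tuple[float, float]],
) -> StratificationResult:
    """Bin subjects by ``score_a`` (instead of CA) and quartile-stratify each
    bin by the residual score_b - score_a, with log-rank tests as in
    ``stratify_quartiles``."""
    pseudo = cohort.copy()
    pseudo.meta = pseudo.meta.copy()
    pseudo.meta["chron_age"] = score_a.loc[pseudo.meta.index]
    residual = score_b - score_a
    return stratify_quartiles(pseudo, residual + pseudo.meta["chron_age"],
                              age_bins=bins_on_a, mode="delta")


# ---------------------------------------------------------------------------
# two-arm intervention aging-rate contrast
# ---------------------------------------------------------------------------

@dataclass
class AgingRateContrast:
    rates: pd.DataFrame        # arm, rate, ci_lo, ci_hi, n
    interaction_p: float | None


def aging_rate_contrast(
    trial: pd.DataFrame,
    ba_col: str = "bio_age",
) -> AgingRateContrast:
    """Per-arm biological-aging rate (years of BA per calendar year) from the
    change-from-baseline linear model, with 95% CIs; the arm difference is
    tested via the time x arm interaction term (two-way ANOVA on the linear
    model).

    ``trial`` is long-format with columns subject_id, arm, timepoint and the
    biological-age column ``ba_col``.
    """
    need = {"subject_id", "arm", "timepoint", ba_col}
    missing = need - set(trial.columns)
    if missing:
        raise EvaluationError(f"trial table lacks columns {sorted(missing)}")
    base = trial.loc[trial["timepoint"] == 0].set_index("subject_id")[ba_col]
    if base.isna().any() or len(base) == 0:
        raise EvaluationError("every subject needs a baseline (timepoint 0)")
    df = trial.copy()
    df["dba"] = df[ba_col].to_numpy(float) - base.reindex(
        df["subject_id"]).to_numpy(float)
    arms = sorted(df["arm"].unique())
    if df.groupby("arm")["timepoint"].nunique().min() < 2:
        raise EvaluationError("each arm needs at least two timepoints")

    rows = []
    if len(arms) == 1:
        fit = smf.ols("dba ~ timepoint", data=df).fit()
        ci = fit.conf_int().loc["timepoint"]
        rows.append({"arm": arms[0], "rate": float(fit.params["timepoint"]),
                     "ci_lo": float(ci[0]), "ci_hi": float(ci[1]),
                     "n": int(df.loc[df['timepoint'] == 0].shape[0])})
        return AgingRateContrast(rates=pd.DataFrame(rows), interaction_p=None)

    fit = smf.ols("dba ~ timepoint * C(arm)", data=df).fit()
    anova_tab = sm.stats.anova_lm(fit, typ=2)
    inter_row = [i for i in anova_tab.index if "timepoint:" in i][0]
    interaction_p = float(anova_tab.loc[inter_row, "PR(>F)"])
    ref = arms[0]
    for arm in arms:
        if arm == ref:
            contrast = "timepoint"
        else:
            contrast = f"timepoint + timepoint:C(arm)[T.{arm}]"
        t = fit.t_test(contrast)
        lo, hi = np.asarray(t.conf_int())[0]
        rows.append({"arm": arm, "rate": float(np.asarray(t.effect).ravel()[0]),
                     "ci_lo": float(lo), "ci_hi": float(hi),
                     "n": int(df.loc[(df["arm"] == arm)
                                     & (df["timepoint"] == 0)].shape[0])})
    return AgingRateContrast(rates=pd.DataFrame(rows),
                             interaction_p=interaction_p)
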