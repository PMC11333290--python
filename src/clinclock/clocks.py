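"""Mortality clocks: null (age-only) and PC-space Cox models, the
hazard-to-Gompertz-age conversion, stability-based sparse PC selection, and the
exact collapse of a PC clock into per-feature linear weights.

The central quantity is the mortality-rate doubling time (MRDT): under a
Gompertz law the log all-cause hazard rises linearly with age at slope b, so
hazard doubles every ln(2)/b years.  A subject whose predicted hazard is r
times the age/sex-expected hazard is therefore biologically older by

    delta_age = ln(r) / ln(2) * MRDT_sex   (years)

and biological age BA = CA + delta_age.  The log relative hazard of a subject
is referenced to the training cohort: ln(r) = (eta - eta_bar_sex)
- b_sex*(CA - mean_CA_sex), which makes the mean training delta_age zero per
sex by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import SEXES, CohortTable
from .pca import PCModel, project

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


class ClockError(ValueError):
    pass


# ---------------------------------------------------------------------------
# null (age-only) mortality model
# ---------------------------------------------------------------------------

@dataclass
class NullMortalityModel:
    """Sex-specific age-only proportional-hazards fit.

    ``b`` is the per-year log-hazard slope of chronological age; the
    mortality-rate doubling time is MRDT = ln(2)/b.  On realistic human
    cohorts MRDT falls around 5-15 years; values outside [2, 30] trigger a
    sanity warning, not an error.
    """

    b: dict[str, float]
    mrdt: dict[str, float]
    mean_ca: dict[str, float]

    def sexes(self) -> list[str]:
        return list(self.b)


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.Series:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[covariates + ["followup_time", "event"]],
                    duration_col="followup_time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise ClockError(
            "Cox fit failed (collinear or degenerate covariates); "
            "consider retaining fewer components") from exc
    return cph.params_


def fit_null_model(cohort: CohortTable) -> NullMortalityModel:
    """Fit per-sex Cox models with chronological age as the sole covariate."""
    b, mrdt, mean_ca = {}, {}, {}
    for sex in SEXES:
        sub = pd.concat([cohort.meta.loc[cohort.sex_mask(sex)]], axis=1)
        if sub.empty:
            continue
        n_events = int(sub["event"].sum())
        if n_events == 0:
            raise ClockError(f"no events for sex {sex!r}; cannot fit null model")
        if n_events < 30:
            warnings.warn(f"only {n_events} events for sex {sex!r}; "
                          "MRDT estimate will be unstable", UserWarning)
        params = _fit_cox(sub, ["chron_age"])
        slope = float(params["chron_age"])
        if slope <= 0:
            raise ClockError(f"age coefficient {slope:.4f} <= 0 for sex {sex!r}; "
                             "mortality must rise with age")
        b[sex] = slope
        mrdt[sex] = LN2 / slope
        mean_ca[sex] = float(sub["chron_age"].mean())
        if not 2.0 <= mrdt[sex] <= 30.0:
            warnings.warn(f"MRDT {mrdt[sex]:.1f} y for sex {sex!r} is outside "
                          "the plausible [2, 30] year range", UserWarning)
    if not b:
        raise ClockError("cohort contains no subjects")
    return NullMortalityModel(b=b, mrdt=mrdt, mean_ca=mean_ca)


# ---------------------------------------------------------------------------
# hazard-to-age conversion
# ---------------------------------------------------------------------------

def hazard_to_delta_age(log_relative_hazard, mrdt: float):
    """Convert a log relative hazard into years of age offset:
    delta_age = log(r)/log(2) * MRDT.  Linear and antisymmetric in log r."""
    if mrdt <= 0:
        raise ClockError("MRDT must be positive")
    lr = np.asarray(log_relative_hazard, dtype=float)
    if not np.all(np.isfinite(lr)):
        raise ClockError("log relative hazard must be finite")
    out = lr / LN2 * mrdt
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# PC-space Cox clock
# ---------------------------------------------------------------------------

@dataclass
class PCClockModel:
    """Per-sex Cox coefficients over [CA, PC1..PCm] with training centering.

    ``eta_bar`` is the training-cohort mean linear predictor per sex;
    together with the null model's age slope it defines each subject's log
    relative hazard and hence delta_age.
    """

    coefs: dict[str, pd.Series]
    eta_bar: dict[str, float]
    mean_ca: dict[str, float]
    pc_model: PCModel = field(repr=False)
    null_model: NullMortalityModel = field(repr=False)
    selected_pcs: list[str] | None = None

    @property
    def pc_names(self) -> list[str]:
        some = next(iter(self.coefs.values()))
        return [c for c in some.index if c != "chron_age"]


def fit_pc_cox(
    cohort: CohortTable,
    pc_model: PCModel,
    null_model: NullMortalityModel,
    selected_pcs: Sequence[str] | None = None,
) -> PCClockModel:
    """Fit per-sex Cox models on chronological age plus retained (or selected)
    PC scores; stores the training mean linear predictor per sex."""
    scores = project(pc_model, cohort)
    if selected_pcs is not None:
        unknown = [p for p in selected_pcs if p not in scores.columns]
        if unknown:
            raise ClockError(f"selected PCs not available: {unknown}")
        scores = scores[list(selected_pcs)]
    pc_cols = list(scores.columns)
    df = pd.concat([cohort.meta, scores], axis=1)
    coefs, eta_bar, mean_ca = {}, {}, {}
    for sex in SEXES:
        sub = df.loc[df["sex"] == sex]
        if sub.empty:
            continue
        params = _fit_cox(sub, ["chron_age"] + pc_cols)
        coefs[sex] = params
        covs = sub[["chron_age"] + pc_cols].to_numpy(float)
        eta_bar[sex] = float(np.mean(covs @ params.to_numpy()))
        mean_ca[sex] = float(sub["chron_age"].mean())
    if not coefs:
        raise ClockError("cohort contains no subjects")
    return PCClockModel(coefs=coefs, eta_bar=eta_bar, mean_ca=mean_ca,
                        pc_model=pc_model, null_model=null_model,
                        selected_pcs=list(selected_pcs) if selected_pcs else None)


def predict_biological_age(model: PCClockModel, cohort: CohortTable) -> pd.DataFrame:
    """Per-subject delta_age and BA = CA + delta_age.

    The log relative hazard references the training cohort per sex:
    (eta - eta_bar) - b*(CA - mean_CA); training mean delta_age is zero per
    sex by construction.  |delta_age| > 60 years triggers a sanity warning.
    """
    pcs = model.pc_names
    scores = project(model.pc_model, cohort)
    missing_sex = set(cohort.meta["sex"]) - set(model.coefs)
    if missing_sex:
        raise ClockError(f"model has no fit for sex(es) {sorted(missing_sex)}")
    out = pd.DataFrame(index=cohort.meta.index,
                       columns=["chron_age", "delta_age", "bio_age"], dtype=float)
    out["chron_age"] = cohort.meta["chron_age"]
    for sex, params in model.coefs.items():
        mask = (cohort.meta["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        covs = pd.concat([cohort.meta.loc[mask, ["chron_age"]],
                          scores.loc[mask, pcs]], axis=1)
        eta = covs.to_numpy(float) @ params.to_numpy()
        b = model.null_model.b[sex]
        log_rel = ((eta - model.eta_bar[sex])
                   - b * (cohort.meta.loc[mask, "chron_age"].to_numpy()
                          - model.mean_ca[sex]))
        delta = hazard_to_delta_age(log_rel, model.null_model.mrdt[sex])
        out.loc[mask, "delta_age"] = delta
    if (out["delta_age"].abs() > 60).any():
        warnings.warn("some |delta_age| exceed 60 years; check inputs",
                      UserWarning)
    out["bio_age"] = out["chron_age"] + out["delta_age"]
    return out


# ---------------------------------------------------------------------------
# stability-based sparse PC selection (regularized Cox)
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-penalty-mixing-value counts of non-zero PC weights over repeated
    cross-validated elastic-net Cox refits, plus the final stable PC set."""

    counts: dict[float, pd.Series]   # alpha -> per-PC count of non-zero weights
    n_iterations: int
    min_count: int
    selected: list[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "counts": {str(a): {k: int(v) for k, v in s.items()}
                       for a, s in self.counts.items()},
            "n_iterations": self.n_iterations,
            "min_count": self.min_count,
            "selected": self.selected,
            "seed": self.seed,
        }


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood (used for cross-validated deviance).

    Risk set of an event at time t is every subject with follow-up >= t; tied
    event times share the full tie-group risk set.
    """
    order = np.argsort(time, kind="stable")
    t, e, ev = time[order], eta[order], event[order] == 1
    # suffix logsumexp of eta: log of the risk-set hazard mass at each index
    suffix = np.logaddexp.accumulate(e[::-1])[::-1]
    first_of_group = np.searchsorted(t, t, side="left")
    denom = suffix[first_of_group]
    return float(np.sum(e[ev] - denom[ev]))


def select_pcs_regularized(
    cohort: CohortTable,
    pc_model: PCModel,
    alphas: Sequence[float] = (1.0, 0.75, 0.5),
    n_iterations: int = 100,
    folds: int = 10,
    min_count: int = 5,
    seed: int = 0,
    n_penalties: int = 30,
) -> SelectionReport:
    """Stability selection of PCs by repeated cross-validated elastic-net Cox.

    For each penalty-mixing value alpha, the penalized coefficient path is fit
    once on the full data (CA force-included via a zero penalty factor); each
    of ``n_iterations`` repeats shuffles the fold assignment, accumulates the
    Verweij-Van Houwelingen cross-validated partial-likelihood deviance along
    the path, and records which PCs carry non-zero weights at the
    deviance-minimizing penalty.  The final set keeps PCs seen at least
    ``min_count`` times under every alpha.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    scores = project(pc_model, cohort)
    pc_cols = list(scores.columns)
    X = np.column_stack([cohort.meta["chron_age"].to_numpy(float),
                         scores.to_numpy(float)])
    names = ["chron_age"] + pc_cols
    time = cohort.meta["followup_time"].to_numpy(float)
    event = cohort.meta["event"].to_numpy() == 1
    n = len(time)
    if n < folds:
        raise ClockError("fewer subjects than folds")
    if int(event.sum()) < folds:
        raise ClockError("fewer events than folds")
    y = Surv.from_arrays(event=event, time=time)
    penalty_factor = np.ones(X.shape[1])
    penalty_factor[0] = 0.0  # CA unpenalized

    rng = np.random.default_rng(seed)
    counts: dict[float, pd.Series] = {}
    for alpha in alphas:
        full = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, n_alphas=n_penalties, alpha_min_ratio=0.01,
            penalty_factor=penalty_factor, fit_baseline_model=False)
        full.fit(X, y)
        path = np.asarray(full.alphas_)
        coef_full = full.coef_  # p x len(path)
        tally = pd.Series(0, index=pc_cols, dtype=int)
        for _ in range(n_iterations):
            fold_id = rng.permutation(np.arange(n) % folds)
            cv_ll = np.zeros(len(path))
            n_contrib = np.zeros(len(path), dtype=int)
            for k in range(folds):
                tr = fold_id != k
                model_k = CoxnetSurvivalAnalysis(
                    l1_ratio=alpha, alphas=path,
                    penalty_factor=penalty_factor, fit_baseline_model=False)
                try:
                    model_k.fit(X[tr], y[tr])
                except ArithmeticError:
                    continue
                coef_k = model_k.coef_
                fitted = np.asarray(model_k.alphas_)
                # align fitted path with requested path (coxnet may stop early)
                col_of = {round(float(a), 12): i for i, a in enumerate(fitted)}
                for ai, a in enumerate(path):
                    ci = col_of.get(round(float(a), 12))
                    if ci is None:
                        continue
                    beta = coef_k[:, ci]
                    eta_all = X @ beta
                    cv_ll[ai] += (_breslow_loglik(eta_all, time, event)
                                  - _breslow_loglik(eta_all[tr], time[tr],
                                                    event[tr]))
                    n_contrib[ai] += 1
            # penalties not reached by every fold's path are not comparable
            cv_ll[n_contrib < folds] = -np.inf
            best = int(np.argmax(cv_ll))
            nonzero = np.flatnonzero(coef_full[1:, best] != 0.0)
            tally.iloc[nonzero] += 1
        counts[float(alpha)] = tally
    stable = [p for p in pc_cols
              if all(counts[float(a)][p] >= min_count for a in alphas)]
    logger.info("stability selection kept %d/%d PCs", len(stable), len(pc_cols))
    return SelectionReport(counts=counts, n_iterations=n_iterations,
                           min_count=min_count, selected=stable, seed=seed)


# ---------------------------------------------------------------------------
# collapse to per-feature linear weights
# ---------------------------------------------------------------------------

@dataclass
class LinearClockModel:
    """Exact per-feature linear re-parameterization of a PC clock.

    For each sex: BA = beta_CA*CA + sum_i beta_i*z_i + C0, where z_i is the
    i-th feature normalized with the training statistics.  Algebraically
    identical to the PC-path BA; weights are in years per normalized unit.
    """

    beta_ca: dict[str, float]
    weights: dict[str, pd.Series]   # per-sex, indexed by feature name
    intercept: dict[str, float]
    pc_model: PCModel = field(repr=False)

    def predict(self, cohort: CohortTable, *,
                zero_z_missing: bool = False) -> pd.DataFrame:
        """BA/delta_age from the linear form.  Features annotated zero-weight
        on the cohort contribute nothing; with ``zero_z_missing`` sporadically
        missing cells substitute a zero z-score."""
        norm = self.pc_model.normalization
        cols = self.pc_model.feature_names
        absent = [c for c in cols if c not in cohort.X.columns]
        hard = [c for c in absent if c not in cohort.zero_weight_features]
        if hard:
            raise ClockError(f"cohort lacks feature(s) {hard} without "
                             "zero-weight annotation")
        X = cohort.X.reindex(columns=cols)
        Z = norm.transform(X, cohort.meta["sex"])
        for c in absent:
            Z[c] = 0.0
        for c in set(cohort.zero_weight_features) & set(cols):
            Z[c] = 0.0
        if zero_z_missing:
            Z = Z.fillna(0.0)
        elif Z.isna().any().any():
            bad = Z.columns[Z.isna().any()].tolist()
            raise ClockError(f"missing cells in {bad}; enable zero_z_missing "
                             "or impute")
        out = pd.DataFrame(index=cohort.meta.index,
                           columns=["chron_age", "delta_age", "bio_age"],
                           dtype=float)
        out["chron_age"] = cohort.meta["chron_age"]
        for sex, w in self.weights.items():
            mask = (cohort.meta["sex"] == sex).to_numpy()
            if not mask.any():
                continue
            ca = cohort.meta.loc[mask, "chron_age"].to_numpy(float)
            ba = (self.beta_ca[sex] * ca
                  + Z.loc[mask, w.index].to_numpy(float) @ w.to_numpy()
                  + self.intercept[sex])
            out.loc[mask, "bio_age"] = ba
        out["delta_age"] = out["bio_age"] - out["chron_age"]
        return out

    def weights_frame(self) -> pd.DataFrame:
        """Tidy export of per-feature weights and normalization constants."""
        rows = []
        norm = self.pc_model.normalization
        for sex, w in self.weights.items():
            key = sex if norm.sex_specific else "pooled"
            for feat, beta in w.items():
                rows.append({
                    "sex": sex, "feature": feat, "weight_years_per_z": beta,
                    "center": float(norm.centers[key][feat]),
                    "scale": float(norm.scales[key][feat]),
                })
            rows.append({"sex": sex, "feature": "__chron_age__",
                         "weight_years_per_z": self.beta_ca[sex],
                         "center": 0.0, "scale": 1.0})
            rows.append({"sex": sex, "feature": "__intercept__",
                         "weight_years_per_z": self.intercept[sex],
                         "center": 0.0, "scale": 1.0})
        return pd.DataFrame(rows)


def collapse_to_linear(
    clock: PCClockModel,
    selection: SelectionReport | None = None,
    verify_cohort: CohortTable | None = None,
) -> LinearClockModel:
    """Fold normalization, projection and Cox weights into one linear form.

    Per sex: beta_i = (MRDT/ln2) * sum_j V_ij * beta_PCj;
    beta_CA = 1 + (MRDT/ln2)*(beta_CA_cox - b);
    C0 = (MRDT/ln2)*(b*mean_CA - eta_bar).  If ``verify_cohort`` is given the
    linear form is asserted to reproduce the PC-path BA to < 1e-8 years.
    """
    pcs = clock.pc_names
    if selection is not None:
        if set(selection.selected) != set(pcs):
            raise ClockError(
                "selection set does not match the clock's PC covariates; "
                "refit the PC Cox model on the selected set first")
    pc_idx = [int(p[2:]) - 1 for p in pcs]
    V = clock.pc_model.V[:, pc_idx]
    feats = clock.pc_model.feature_names
    beta_ca, weights, intercept = {}, {}, {}
    for sex, params in clock.coefs.items():
        mrdt = clock.null_model.mrdt[sex]
        b = clock.null_model.b[sex]
        scale = mrdt / LN2
        beta_pc = params[pcs].to_numpy(float)
        weights[sex] = pd.Series(scale * (V @ beta_pc), index=feats)
        beta_ca[sex] = 1.0 + scale * (float(params["chron_age"]) - b)
        intercept[sex] = scale * (b * clock.mean_ca[sex] - clock.eta_bar[sex])
    model = LinearClockModel(beta_ca=beta_ca, weights=weights,
                             intercept=intercept, pc_model=clock.pc_model)
    if verify_cohort is not None:
        ref = predict_biological_age(clock, verify_cohort)["bio_age"]
        lin = model.predict(verify_cohort)["bio_age"]
        err = float((ref - lin).abs().max())
        if err > 1e-8:
            raise ClockError(f"linear collapse mismatch: max |diff| {err:.2e} y")
    return model


def predict_trial(
    trial: pd.DataFrame,
    clock: "PCClockModel | LinearClockModel",
) -> pd.DataFrame:
    """Apply a clock to every (subject, timepoint) row of a long-format trial
    table; returns the table with a ``bio_age`` column appended.

    Follow-up metadata are irrelevant for prediction and filled with
    placeholders.
    """
    feats = clock.pc_model.feature_names
    missing = [f for f in feats if f not in trial.columns]
    if missing:
        raise ClockError(f"trial table lacks feature(s) {missing}")
    idx = pd.Index([f"{s}@{t}" for s, t in
                    zip(trial["subject_id"], trial["timepoint"])])
    meta = pd.DataFrame({
        "sex": trial["sex"].to_numpy(),
        "chron_age": trial["chron_age"].to_numpy(float),
        "followup_time": 1.0,
        "event": 0,
    }, index=idx)
    pseudo = CohortTable(meta=meta,
                         X=pd.DataFrame(trial[feats].to_numpy(float),
                                        index=idx, columns=feats))
    if isinstance(clock, LinearClockModel):
        ba = clock.predict(pseudo)["bio_age"]
    else:
        ba = predict_biological_age(clock, pseudo)["bio_age"]
    out = trial.copy()
    out["bio_age"] = ba.to_numpy()
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

BUNDLE_MAJOR = 1


def save_clock_bundle(path: str | Path, clock: PCClockModel,
                      linear: LinearClockModel | None = None,
                      selection: SelectionReport | None = None,
                      provenance: dict | None = None) -> None:
    """Versioned JSON bundle: PC model, null model, Cox clock, optional
    linear clock and selection report."""
    null = clock.null_model
    payload = {
        "bundle_version": f"{BUNDLE_MAJOR}.0",
        "pc_model": clock.pc_model.to_json(),
        "null_model": {"b": null.b, "mrdt": null.mrdt, "mean_ca": null.mean_ca},
        "pc_clock": {
            "coefs": {s: {k: float(v) for k, v in c.items()}
                      for s, c in clock.coefs.items()},
            "eta_bar": clock.eta_bar,
            "mean_ca": clock.mean_ca,
            "selected_pcs": clock.selected_pcs,
        },
        "linear_clock": None if linear is None else {
            "beta_ca": linear.beta_ca,
            "weights": {s: {k: float(v) for k, v in w.items()}
                        for s, w in linear.weights.items()},
            "intercept": linear.intercept,
        },
        "selection": None if selection is None else selection.to_dict(),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_clock_bundle(path: str | Path) -> tuple[PCClockModel,
                                                 LinearClockModel | None]:
    payload = json.loads(Path(path).read_text())
    major = int(str(payload.get("bundle_version", "0")).split(".")[0])
    if major > BUNDLE_MAJOR:
        raise ClockError(f"bundle version {payload['bundle_version']} is newer "
                         f"than supported major {BUNDLE_MAJOR}")
    pc_model = PCModel.from_json(payload["pc_model"])
    nm = payload["null_model"]
    null = NullMortalityModel(b=nm["b"], mrdt=nm["mrdt"], mean_ca=nm["mean_ca"])
    pcc = payload["pc_clock"]
    clock = PCClockModel(
        coefs={s: pd.Series(c) for s, c in pcc["coefs"].items()},
        eta_bar=pcc["eta_bar"], mean_ca=pcc["mean_ca"],
        pc_model=pc_model, null_model=null,
        selected_pcs=pcc.get("selected_pcs"))
    linear = None
    if payload.get("linear_clock"):
        lc = payload["linear_clock"]
        linear = LinearClockModel(
            beta_ca=lc["beta_ca"],
            weights={s: pd.Series(w) for s, w in lc["weights"].items()},
            intercept=lc["intercept"], pc_model=pc_model)
    return clock, linear
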