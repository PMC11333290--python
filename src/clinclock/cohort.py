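"""Cohort tables, codebooks, derived questionnaire indices and missingness filters.

A cohort is a subjects x features table of clinical parameters together with the
survival metadata (sex, chronological age, follow-up time, death indicator) needed
to train mortality-based aging clocks.  A codebook names every feature column,
declares its units and per-feature transform (identity or log), and carries
include / force-include flags mirroring the workflow of survey-derived clinical
datasets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: number of comorbidity questions contributing to the comorbidity index
N_COMORBIDITY_QUESTIONS = 22

META_ROLES = ("sex", "chron_age", "followup_time", "event")

_SEX_ALIASES = {
    "male": MALE, "m": MALE, "1": MALE,
    "female": FEMALE, "f": FEMALE, "2": FEMALE,
}
_EVENT_ALIASES = {
    "died": 1, "death": 1, "dead": 1, "1": 1, "true": 1,
    "censored": 0, "alive": 0, "0": 0, "false": 0,
}


class CohortError(ValueError):
    """Raised for contract violations in cohort construction or filtering."""


@dataclass(frozen=True)
class FeatureCodebook:
    """Per-feature metadata: human name, units, transform and inclusion flags."""

    table: pd.DataFrame  # indexed by feature name

    REQUIRED = ("human_name", "units", "transform", "include", "force_include")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise CohortError(f"codebook missing required columns: {missing}")
        bad = set(self.table["transform"]) - {"identity", "log"}
        if bad:
            raise CohortError(f"unknown transforms in codebook: {sorted(bad)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise CohortError(f"duplicate codebook entries: {dups}")

    @property
    def features(self) -> list[str]:
        roles = self.roles()
        return [n for n in self.table.index if n not in roles]

    def roles(self) -> dict[str, str]:
        """Map meta-column name -> role, read from an optional 'role' column."""
        if "role" not in self.table.columns:
            return {}
        out = {}
        for name, role in self.table["role"].items():
            if isinstance(role, str) and role in META_ROLES:
                out[name] = role
        return out

    def transform_of(self, feature: str) -> str:
        return str(self.table.loc[feature, "transform"])

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureCodebook":
        tab = pd.read_csv(path)
        if "name" not in tab.columns:
            raise CohortError(f"codebook {path} lacks a 'name' column")
        return cls(tab.set_index("name"))

    def to_csv(self, path: str | Path) -> None:
        self.table.rename_axis("name").reset_index().to_csv(path, index=False)


@dataclass
class CohortTable:
    """Subjects x clinical features plus per-subject survival metadata.

    ``meta`` holds sex, chron_age, followup_time (years) and event (1=died,
    0=censored), indexed by subject id; ``X`` holds the numeric feature matrix on
    the same index.  ``zero_weight_features`` carries harmonization annotations
    consumed at clock-prediction time.
    """

    meta: pd.DataFrame
    X: pd.DataFrame
    codebook: FeatureCodebook | None = None
    zero_weight_features: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        need = {"sex", "chron_age", "followup_time", "event"}
        missing = need - set(self.meta.columns)
        if missing:
            raise CohortError(f"cohort meta lacks columns: {sorted(missing)}")
        if not self.meta.index.equals(self.X.index):
            raise CohortError("meta and feature matrix must share a subject index")
        if (self.meta["chron_age"] <= 0).any():
            raise CohortError("chronological age must be positive")
        if (self.meta["followup_time"] < 0).any():
            raise CohortError("follow-up time must be non-negative")
        bad_sex = set(self.meta["sex"]) - set(SEXES)
        if bad_sex:
            raise CohortError(f"unknown sex values: {sorted(bad_sex)}")
        if not self.meta["event"].isin((0, 1)).all():
            raise CohortError("event must be 0 (censored) or 1 (died)")
        if self.X.columns.duplicated().any():
            raise CohortError("duplicate feature names")

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def sex_mask(self, sex: str) -> pd.Series:
        return self.meta["sex"] == sex

    def subset(self, ids: Iterable) -> "CohortTable":
        idx = self.meta.index.intersection(pd.Index(ids))
        return replace(self, meta=self.meta.loc[idx], X=self.X.loc[idx])

    def copy(self) -> "CohortTable":
        return replace(self, meta=self.meta.copy(), X=self.X.copy(),
                       zero_weight_features=set(self.zero_weight_features))

    def write_csv(self, path: str | Path) -> None:
        pd.concat([self.meta, self.X], axis=1).rename_axis("subject_id") \
            .reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class QuestionnaireAnswers:
    """Health-questionnaire responses feeding the three derived indices."""

    comorbidities: Sequence[bool] = ()
    general_health: str = "good-or-better"   # good-or-better | fair | poor
    health_vs_last_year: str = "same"        # better | same | worse
    healthcare_visits: int = 0
    cotinine: float = 0.0


def _coerce_sex(values: pd.Series) -> pd.Series:
    out = values.astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    if out.isna().any():
        bad = values[out.isna()].unique().tolist()
        raise CohortError(f"unrecognized sex values: {bad}")
    return out


def _coerce_event(values: pd.Series) -> pd.Series:
    out = values.astype(str).str.strip().str.lower().map(_EVENT_ALIASES)
    if out.isna().any():
        bad = values[out.isna()].unique().tolist()
        raise CohortError(f"unrecognized event values: {bad}")
    return out.astype(int)


def read_cohort(
    table_path: str | Path,
    codebook_path: str | Path,
    *,
    subject_col: str = "subject_id",
    sep: str = ",",
    time_unit: str = "years",
) -> CohortTable:
    """Read a delimited cohort table with its codebook, applying per-feature transforms.

    Every feature column must appear in the codebook; log-transform flags are
    applied here, before any normalization.  ``time_unit`` may be ``"years"`` or
    ``"months"`` (converted to years internally).
    """
    codebook = FeatureCodebook.read_csv(codebook_path)
    raw = pd.read_csv(table_path, sep=sep)
    if subject_col in raw.columns:
        raw = raw.set_index(subject_col)
    raw.index.name = "subject_id"

    roles = codebook.roles()
    colmap = {name: role for name, role in roles.items()}
    defaults = {r: r for r in META_ROLES}
    meta_cols = {}
    for name, role in colmap.items():
        if name in raw.columns:
            meta_cols[role] = name
    for role, default in defaults.items():
        meta_cols.setdefault(role, default)
    missing_meta = [c for c in meta_cols.values() if c not in raw.columns]
    if missing_meta:
        raise CohortError(f"cohort table lacks meta columns: {missing_meta}")

    meta = pd.DataFrame({
        "sex": _coerce_sex(raw[meta_cols["sex"]]),
        "chron_age": pd.to_numeric(raw[meta_cols["chron_age"]]),
        "followup_time": pd.to_numeric(raw[meta_cols["followup_time"]]),
        "event": _coerce_event(raw[meta_cols["event"]]),
    }, index=raw.index)
    if time_unit == "months":
        meta["followup_time"] = meta["followup_time"] / 12.0
    elif time_unit != "years":
        raise CohortError(f"unknown time unit {time_unit!r}")

    feat_cols = [c for c in raw.columns if c not in set(meta_cols.values())]
    uncovered = [c for c in feat_cols if c not in codebook.table.index]
    if uncovered:
        raise CohortError(f"feature column(s) not in codebook: {uncovered}")

    X = pd.DataFrame(index=raw.index)
    for col in feat_cols:
        try:
            vals = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()
                           & raw[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise CohortError(
                f"non-numeric value in feature {col!r} at subject {row!r}") from exc
        if codebook.transform_of(col) == "log":
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.log(vals)
        X[col] = vals

    logger.info("read cohort: %d subjects, %d features", len(X), X.shape[1])
    return CohortTable(meta=meta, X=X, codebook=codebook)


# ---------------------------------------------------------------------------
# derived questionnaire indices
# ---------------------------------------------------------------------------

def derive_comorbidity_index(answers: QuestionnaireAnswers) -> float:
    """Fraction of the 22 surveyed comorbid conditions reported (missing = absent)."""
    flags = list(answers.comorbidities)
    if len(flags) > N_COMORBIDITY_QUESTIONS:
        raise CohortError(
            f"at most {N_COMORBIDITY_QUESTIONS} comorbidity flags accepted")
    return float(sum(bool(f) for f in flags)) / N_COMORBIDITY_QUESTIONS


def derive_self_health_index(answers: QuestionnaireAnswers) -> float:
    """Self-rated health score: ((fair x 2) + (poor x 4)) x (1 - 0.5*better + worse).

    Declining health doubles the general-health penalty; reported recovery
    halves it.  Affirmative answers score 1, negative 0.
    """
    levels = {"good-or-better": (0, 0), "fair": (1, 0), "poor": (0, 1)}
    trends = {"better": (1, 0), "same": (0, 0), "worse": (0, 1)}
    if answers.general_health not in levels:
        raise CohortError(f"unknown general-health level {answers.general_health!r}")
    if answers.health_vs_last_year not in trends:
        raise CohortError(
            f"unknown health-trend level {answers.health_vs_last_year!r}")
    fair, poor = levels[answers.general_health]
    better, worse = trends[answers.health_vs_last_year]
    return (fair * 2 + poor * 4) * (1 - better * 0.5 + worse)


def derive_healthcare_use_index(answers: QuestionnaireAnswers) -> int:
    """Number of healthcare contacts over the past year, passed through unchanged."""
    n = answers.healthcare_visits
    if n < 0:
        raise CohortError("healthcare visit count cannot be negative")
    return int(n)


#: serum cotinine (ng/ml) cutoffs separating non / light / moderate / heavy smokers
SMOKING_CUTOFFS = (10.0, 100.0, 200.0)


def bin_smoking_status(cotinine: float) -> int:
    """Ordinal smoking status from serum cotinine: [0,10)->0, [10,100)->1,
    [100,200)->2, [200,inf)->3 (left-closed bins)."""
    c = np.asarray(cotinine, dtype=float)
    if np.any(c < 0):
        raise CohortError("cotinine cannot be negative")
    out = np.digitize(c, SMOKING_CUTOFFS, right=False)
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# missingness filtering
# ---------------------------------------------------------------------------

def filter_missing(
    cohort: CohortTable,
    feature_threshold: float = 0.10,
    force_keep: Iterable[str] = (),
) -> tuple[CohortTable, dict]:
    """Drop features missing in more than ``feature_threshold`` of subjects
    (unless force-kept), then drop subjects with any remaining missing cell.

    Returns the filtered cohort plus a removal report listing every dropped
    feature and subject with the reason.  Idempotent.
    """
    if not 0 < feature_threshold <= 1:
        raise CohortError("feature_threshold must lie in (0, 1]")
    force = set(force_keep)
    miss_frac = cohort.X.isna().mean()
    dropped_features = [
        {"feature": f, "missing_fraction": round(float(miss_frac[f]), 6),
         "reason": f"missing fraction {miss_frac[f]:.3f} > {feature_threshold}"}
        for f in cohort.X.columns
        if miss_frac[f] > feature_threshold and f not in force
    ]
    kept = [f for f in cohort.X.columns
            if not (miss_frac[f] > feature_threshold and f not in force)]
    X = cohort.X[kept]
    subj_missing = X.isna().any(axis=1)
    dropped_subjects = [
        {"subject": str(s),
         "reason": "missing " + ", ".join(X.columns[X.loc[s].isna()])}
        for s in X.index[subj_missing]
    ]
    if subj_missing.all() and len(X):
        raise CohortError(
            "all subjects have missing cells after feature filtering; "
            "consider imputation or a different threshold")
    keep_idx = X.index[~subj_missing]
    out = replace(cohort, meta=cohort.meta.loc[keep_idx], X=X.loc[keep_idx])
    report = {
        "feature_threshold": feature_threshold,
        "force_keep": sorted(force),
        "dropped_features": dropped_features,
        "dropped_subjects": dropped_subjects,
        "n_subjects_kept": int(len(keep_idx)),
        "n_features_kept": int(len(kept)),
    }
    logger.info("filter_missing: dropped %d features, %d subjects; kept %d x %d",
                len(dropped_features), len(dropped_subjects),
                report["n_subjects_kept"], report["n_features_kept"])
    return out, report


def write_removal_report(report: Mapping, path: str | Path) -> None:
    """Write the removal report as JSON plus a plain-text summary alongside."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2) + "\n")
    lines = [f"kept {report['n_subjects_kept']} subjects x "
             f"{report['n_features_kept']} features"]
    lines += [f"dropped feature {d['feature']}: {d['reason']}"
              for d in report["dropped_features"]]
    lines += [f"dropped subject {d['subject']}: {d['reason']}"
              for d in report["dropped_subjects"]]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cross-cohort harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionLimitSubstitute:
    """Replace values at/below an assay detection limit with a fixed substitute."""
    feature: str
    limit: float
    substitute_value: float


@dataclass(frozen=True)
class RatioRescale:
    """Multiply a feature by reference_mean / cohort_mean to re-center batch shifts.

    ``cohort_mean`` defaults to the external cohort's own mean of the feature
    (optionally over a healthy reference subset chosen by the caller upstream).
    """
    feature: str
    reference_mean: float
    cohort_mean: float | None = None


@dataclass(frozen=True)
class DropFeatureZeroWeight:
    """Annotate a feature as absent: clock prediction sets its weight to zero."""
    feature: str


HarmonizationRule = DetectionLimitSubstitute | RatioRescale | DropFeatureZeroWeight


def harmonize_external_cohort(
    cohort: CohortTable,
    rules: Sequence[HarmonizationRule],
) -> CohortTable:
    """Apply cross-cohort harmonization rules in order; returns a new cohort."""
    out = cohort.copy()
    for rule in rules:
        if rule.feature not in out.X.columns:
            raise CohortError(f"harmonization rule references unknown feature "
                              f"{rule.feature!r}")
        col = out.X[rule.feature]
        if isinstance(rule, DetectionLimitSubstitute):
            out.X[rule.feature] = col.where(col > rule.limit, rule.substitute_value)
        elif isinstance(rule, RatioRescale):
            denom = rule.cohort_mean if rule.cohort_mean is not None else col.mean()
            if denom == 0 or not math.isfinite(denom):
                raise CohortError(f"cannot ratio-rescale {rule.feature!r}: "
                                  f"cohort mean {denom}")
            out.X[rule.feature] = col * (rule.reference_mean / denom)
        elif isinstance(rule, DropFeatureZeroWeight):
            out.zero_weight_features.add(rule.feature)
        else:  # pragma: no cover - type guard
            raise CohortError(f"unknown harmonization rule {rule!r}")
    return out
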