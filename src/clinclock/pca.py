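"""Normalization, singular value decomposition and projection of cohort features.

Correlation-mode PCA: features are z-scored (training mean/sd, or robust
median/MAD statistics taken over a healthy reference subset) before the SVD of
the training matrix.  External cohorts are always normalized with the stored
training statistics and projected with the training right singular vectors —
never re-centered on themselves — so that every cohort lives in the same PC
coordinate system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import SEXES, CohortTable

SCHEMA_VERSION = "1"


class PCAError(ValueError):
    pass


@dataclass
class NormalizationModel:
    """Per-feature centering and scaling learned on training data.

    ``mode`` is ``"zscore"`` (mean/sd) or ``"reference_median_mad"``
    (median/MAD over a healthy reference subset).  Statistics are stored per
    sex when ``sex_specific`` and pooled otherwise; ``exempt`` features pass
    through unnormalized (center 0, scale 1), matching the convention that
    ordinal/index features such as smoking status and morbidity indices enter
    the model on their native scale.
    """

    mode: str
    centers: dict[str, pd.Series]  # key "pooled" or sex
    scales: dict[str, pd.Series]
    sex_specific: bool
    exempt: frozenset[str] = frozenset()

    @property
    def feature_names(self) -> list[str]:
        return list(next(iter(self.centers.values())).index)

    def _key(self, sex: str) -> str:
        return sex if self.sex_specific else "pooled"

    def transform(self, X: pd.DataFrame, sex: pd.Series) -> pd.DataFrame:
        cols = self.feature_names
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise PCAError(f"cohort lacks feature(s) {missing}")
        Z = pd.DataFrame(index=X.index, columns=cols, dtype=float)
        if self.sex_specific:
            for s in SEXES:
                mask = (sex == s).to_numpy()
                if not mask.any():
                    continue
                Z.loc[mask, cols] = (
                    (X.loc[mask, cols] - self.centers[s]) / self.scales[s])
        else:
            Z.loc[:, cols] = (X[cols] - self.centers["pooled"]) / self.scales["pooled"]
        return Z


def _mad(x: pd.Series) -> float:
    med = x.median()
    return float((x - med).abs().median())


def fit_normalization(
    cohort: CohortTable,
    mode: str = "zscore",
    reference_subset: Iterable | None = None,
    *,
    sex_specific: bool | None = None,
    exempt: Iterable[str] = (),
) -> NormalizationModel:
    """Learn normalization statistics on a training cohort.

    z-score mode uses the whole cohort (pooled by default); reference mode
    requires a healthy reference subject subset and is sex-specific by default.
    Zero-variance features are rejected by name.
    """
    if mode not in ("zscore", "reference_median_mad"):
        raise PCAError(f"unknown normalization mode {mode!r}")
    if mode == "reference_median_mad":
        if reference_subset is None:
            raise PCAError("reference_median_mad mode requires a reference subset")
        if sex_specific is None:
            sex_specific = True
    elif sex_specific is None:
        sex_specific = False

    exempt = frozenset(exempt)
    unknown = exempt - set(cohort.feature_names)
    if unknown:
        raise PCAError(f"exempt feature(s) not in cohort: {sorted(unknown)}")

    src = cohort if reference_subset is None else cohort.subset(reference_subset)
    if mode == "reference_median_mad":
        for s in SEXES:
            if sex_specific and (src.meta["sex"] == s).sum() < 2:
                raise PCAError(f"reference subset needs >= 2 subjects of sex {s}")

    def stats_for(X: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        if mode == "zscore":
            center, scale = X.mean(), X.std(ddof=1)
        else:
            center = X.median()
            scale = X.apply(_mad)
        for f in exempt:
            center[f], scale[f] = 0.0, 1.0
        zero = scale.index[(scale <= 0) | ~np.isfinite(scale)].tolist()
        if zero:
            raise PCAError(f"zero or undefined scale for feature(s) {zero}; "
                           "remove constant features before normalization")
        return center.astype(float), scale.astype(float)

    centers, scales = {}, {}
    if sex_specific:
        for s in SEXES:
            sub = src.X.loc[(src.meta["sex"] == s).to_numpy()]
            centers[s], scales[s] = stats_for(sub)
    else:
        centers["pooled"], scales["pooled"] = stats_for(src.X)
    return NormalizationModel(mode=mode, centers=centers, scales=scales,
                              sex_specific=sex_specific, exempt=exempt)


@dataclass
class PCModel:
    """Training normalization plus right singular vectors and spectrum.

    ``V`` is features x components with orthonormal columns; the sign of each
    column is fixed so its largest-magnitude loading is positive, making
    serialized models reproducible.  ``m`` is the retained component count.
    """

    normalization: NormalizationModel
    feature_names: list[str]
    V: np.ndarray
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    m: int
    n_train: int = 0

    def __post_init__(self) -> None:
        g = self.V.T @ self.V
        if np.max(np.abs(g - np.eye(g.shape[0]))) > 1e-8:
            raise PCAError("columns of V are not orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-10):
            raise PCAError("singular values must be non-increasing")
        if abs(self.variance_fractions.sum() - 1.0) > 1e-10:
            raise PCAError("variance fractions must sum to 1")
        if not 1 <= self.m <= self.V.shape[1]:
            raise PCAError("retained count m out of range")

    @property
    def pc_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.m)]

    def to_json(self, path: str | Path | None = None) -> dict:
        norm = self.normalization
        payload = {
            "schema_version": SCHEMA_VERSION,
            "sign_convention": "largest-loading-positive",
            "features": self.feature_names,
            "normalization": {
                "mode": norm.mode,
                "sex_specific": norm.sex_specific,
                "exempt": sorted(norm.exempt),
                "centers": {k: v.tolist() for k, v in norm.centers.items()},
                "scales": {k: v.tolist() for k, v in norm.scales.items()},
            },
            "V": self.V.tolist(),
            "singular_values": self.singular_values.tolist(),
            "m": self.m,
            "n_train": self.n_train,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload) + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "PCModel":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        feats = list(source["features"])
        idx = pd.Index(feats)
        norm = NormalizationModel(
            mode=source["normalization"]["mode"],
            sex_specific=source["normalization"]["sex_specific"],
            exempt=frozenset(source["normalization"]["exempt"]),
            centers={k: pd.Series(v, index=idx)
                     for k, v in source["normalization"]["centers"].items()},
            scales={k: pd.Series(v, index=idx)
                    for k, v in source["normalization"]["scales"].items()},
        )
        s = np.asarray(source["singular_values"], float)
        var_frac = s**2 / np.sum(s**2)
        return cls(normalization=norm, feature_names=feats,
                   V=np.asarray(source["V"], float), singular_values=s,
                   variance_fractions=var_frac, m=int(source["m"]),
                   n_train=int(source.get("n_train", 0)))


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each singular vector so its largest-|loading| entry is positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def fit_svd(cohort: CohortTable, normalization: NormalizationModel) -> PCModel:
    """SVD of the normalized training matrix; retains all components initially."""
    Z = normalization.transform(cohort.X, cohort.meta["sex"])
    if Z.isna().any().any():
        bad = Z.columns[Z.isna().any()].tolist()
        raise PCAError(f"missing cells in feature(s) {bad}; "
                       "filter or impute before fitting the SVD")
    if len(Z) < 2:
        raise PCAError("need at least 2 subjects for an SVD")
    _, s, Vt = np.linalg.svd(Z.to_numpy(float), full_matrices=False)
    V = _fix_signs(Vt.T)
    var_frac = s**2 / np.sum(s**2)
    return PCModel(normalization=normalization,
                   feature_names=list(Z.columns), V=V, singular_values=s,
                   variance_fractions=var_frac, m=V.shape[1], n_train=len(Z))


def select_components(model: PCModel, variance_target: float) -> int:
    """Smallest m whose cumulative explained-variance fraction reaches the
    target; stores and returns it."""
    if not 0 < variance_target <= 1:
        raise PCAError("variance target must lie in (0, 1]")
    cum = np.cumsum(model.variance_fractions)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(m, len(model.variance_fractions))
    model.m = m
    return m


def project(model: PCModel, cohort: CohortTable,
            n_components: int | None = None) -> pd.DataFrame:
    """Project a cohort into the training PC coordinate system (name-aligned).

    Features annotated ``zero_weight_features`` on the cohort may be absent:
    their normalized coordinate is taken as zero.
    """
    m = model.m if n_components is None else n_components
    cols = model.feature_names
    absent = [c for c in cols if c not in cohort.X.columns]
    not_ok = [c for c in absent if c not in cohort.zero_weight_features]
    if not_ok:
        raise PCAError(f"cohort lacks feature(s) {not_ok} and they carry no "
                       "zero-weight annotation")
    X = cohort.X.reindex(columns=cols)
    norm = model.normalization
    Z = norm.transform(X.fillna({c: np.nan for c in absent}), cohort.meta["sex"])
    for c in absent:
        Z[c] = 0.0
    for c in cohort.zero_weight_features & set(cols):
        Z[c] = 0.0
    scores = Z.to_numpy(float) @ model.V[:, :m]
    return pd.DataFrame(scores, index=cohort.X.index,
                        columns=[f"PC{i + 1}" for i in range(m)])


def impute_iterative_pca(
    cohort: CohortTable,
    n_components: int,
    max_iterations: int = 10_000,
    tolerance: float = 1e-6,
) -> CohortTable:
    """Fill missing cells by iterative low-rank reconstruction.

    Missing cells start at feature means; each iteration standardizes the
    current matrix, reconstructs it from its leading ``n_components`` singular
    vectors, and overwrites only the missing cells, until the largest absolute
    change falls below ``tolerance``.  Observed cells are never modified.
    """
    X = cohort.X.copy()
    mask = X.isna()
    if not mask.any().any():
        return cohort
    if n_components >= X.shape[1]:
        raise PCAError("n_components must be below the feature count")
    col_means = X.mean()
    X = X.fillna(col_means)
    M = mask.to_numpy()
    A = X.to_numpy(float)
    converged = False
    for _ in range(max_iterations):
        mu = A.mean(axis=0)
        sd = A.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (A - mu) / sd
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        Zr = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
        recon = Zr * sd + mu
        delta = np.max(np.abs(recon[M] - A[M])) if M.any() else 0.0
        A[M] = recon[M]
        if delta < tolerance:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("iterative PCA imputation did not converge within "
                      f"{max_iterations} iterations", RuntimeWarning)
    out = cohort.copy()
    out.X = pd.DataFrame(A, index=cohort.X.index, columns=cohort.X.columns)
    return out
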