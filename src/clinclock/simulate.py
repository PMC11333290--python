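"""Synthetic survival cohorts with known ground truth.

Emulates the structure of a cross-sectional clinical survey with linked
mortality follow-up: clinical features arise from a small number of latent
physiological factors (some coupled to age), all-cause mortality follows a
Gompertz hazard whose log-linear age slope sets the mortality-rate doubling
time (MRDT), and follow-up is administratively right-censored at a fixed
horizon.  A two-arm longitudinal trial generator emulates a caloric-restriction
style intervention with arm-specific biological-aging rates.

Because every subject's true log relative hazard is recorded, downstream
stages (SVD, Cox fits, hazard-to-age conversion, selection, evaluation) can be
tested for parameter recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import MALE, FEMALE, CohortTable, FeatureCodebook

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic clinical survival cohort.

    Defaults describe a mid-size survey cohort: ages uniform on 40-84 years,
    Gompertz slope b=0.0866/year (MRDT = ln2/b = 8 years, a typical human
    all-cause figure), hazard calibrated to give a realistic event fraction
    over a 20-year follow-up horizon, and three latent factors of which the
    first two carry mortality risk and the first tracks age.
    """

    n_subjects: int = 2000
    n_features: int = 20
    n_latent: int = 3
    loadings: np.ndarray | None = None       # features x latents; default random
    age_range: tuple[float, float] = (40.0, 84.0)
    gompertz_intercept: float = -9.8         # ln hazard extrapolated to age 0
    gompertz_slope: float = LN2 / 8.0        # per year of age
    latent_effects: Sequence[float] | None = None  # default (0.5, 0.3, 0, ...)
    age_coupling: Sequence[float] | None = None  # per-latent slope on scaled age
    noise_sd: float = 0.5
    censoring_horizon: float = 20.0
    feature_scale: float = 10.0              # clinical-range rescaling
    feature_offset: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.gompertz_slope <= 0:
            raise ValueError("Gompertz slope b must be positive")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.latent_effects is None:
            base = (0.5, 0.3)
            effects = tuple(base[:self.n_latent]) + (0.0,) * max(
                0, self.n_latent - len(base))
            object.__setattr__(self, "latent_effects", effects)
        if len(self.latent_effects) != self.n_latent:
            raise ValueError("latent_effects length must equal n_latent")
        if self.loadings is not None:
            L = np.asarray(self.loadings, float)
            if L.shape != (self.n_features, self.n_latent):
                raise ValueError("loadings must be n_features x n_latent")
            if not np.all(np.isfinite(L)):
                raise ValueError("loadings must be finite")

    @property
    def true_mrdt(self) -> float:
        return LN2 / self.gompertz_slope


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort: latent scores, true log relative
    hazard eta* per subject, and the generative MRDT."""

    latents: pd.DataFrame
    eta: pd.Series
    mrdt: float
    config: SyntheticConfig = field(repr=False)

    @property
    def true_delta_age(self) -> pd.Series:
        """Centered eta* converted to years on the generative MRDT scale."""
        eta_c = self.eta - self.eta.mean()
        return eta_c * self.mrdt / LN2

    def write_json(self, path: str | Path) -> None:
        payload = {
            "mrdt": self.mrdt,
            "eta": {str(k): float(v) for k, v in self.eta.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _default_loadings(config: SyntheticConfig) -> np.ndarray:
    """Default feature-latent loading matrix.

    Depends only on the problem shape (n_features, n_latent), never on the
    subject seed, so cohorts and trials drawn from the same configuration
    share one population structure.
    """
    if config.loadings is not None:
        return np.asarray(config.loadings, float)
    rng = np.random.default_rng(987_000 + 31 * config.n_features
                                + config.n_latent)
    # block-ish structure: each feature loads mainly on one latent
    L = rng.normal(0.0, 0.3, size=(config.n_features, config.n_latent))
    for i in range(config.n_features):
        L[i, i % config.n_latent] += rng.choice([-1.0, 1.0]) * 1.0
    return L


def sample_gompertz_times(
    rng: np.random.Generator,
    age0: np.ndarray,
    eta: np.ndarray,
    intercept: float,
    slope: float,
) -> np.ndarray:
    """Exact inverse-transform sampling of death times under
    h(t) = exp(intercept + slope*(age0 + t) + eta).

    The cumulative hazard H(t) = exp(intercept + eta + slope*age0)
    * (exp(slope*t) - 1)/slope inverts in closed form against a unit
    exponential deviate.
    """
    e = rng.exponential(size=len(age0))
    base = np.exp(intercept + eta + slope * age0)
    return np.log1p(slope * e / base) / slope


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Draw a cross-sectional cohort with latent-factor features and Gompertz
    mortality; returns the cohort plus its generative ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    sex = np.where(rng.random(n) < 0.5, MALE, FEMALE)
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    age_scaled = (age - (lo + hi) / 2.0) / ((hi - lo) / 4.0)

    Z = rng.standard_normal((n, config.n_latent))
    if config.age_coupling is not None:
        coupling = np.asarray(config.age_coupling, float)
        Z = Z + np.outer(age_scaled, coupling)

    effects = np.asarray(config.latent_effects, float)
    eta = Z @ effects

    L = _default_loadings(config)
    F = Z @ L.T + rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    F = F * config.feature_scale + config.feature_offset

    t_death = sample_gompertz_times(
        rng, age, eta, config.gompertz_intercept, config.gompertz_slope)
    died = t_death <= config.censoring_horizon
    followup = np.where(died, t_death, config.censoring_horizon)
    followup = np.maximum(followup, 1e-6)  # Cox fitters require positive times

    ids = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    meta = pd.DataFrame({
        "sex": sex,
        "chron_age": age,
        "followup_time": followup,
        "event": died.astype(int),
    }, index=ids)
    feat_names = [f"feat_{j:03d}" for j in range(config.n_features)]
    X = pd.DataFrame(F, index=ids, columns=feat_names)

    codebook = FeatureCodebook(pd.DataFrame({
        "human_name": feat_names,
        "units": ["a.u."] * config.n_features,
        "transform": ["identity"] * config.n_features,
        "include": [True] * config.n_features,
        "force_include": [False] * config.n_features,
    }, index=pd.Index(feat_names, name="name")))

    truth = SyntheticTruth(
        latents=pd.DataFrame(Z, index=ids,
                             columns=[f"latent_{j}" for j in range(config.n_latent)]),
        eta=pd.Series(eta, index=ids, name="eta"),
        mrdt=config.true_mrdt,
        config=config,
    )
    return CohortTable(meta=meta, X=X, codebook=codebook), truth


def generate_trial(
    config: SyntheticConfig,
    arm_effects: dict[str, float],
    timepoints: Sequence[float],
    n_per_arm: dict[str, int],
    *,
    heterogeneity_sd: float = 0.0,
    measurement_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Two-arm (or multi-arm) longitudinal trial with arm-specific true
    biological-aging rates (years of biological age per calendar year).

    An arm rate of 1 is ordinary calendar aging (biological age keeps pace
    with chronological age); rates above/below 1 are accelerated/slowed aging.
    Per subject the realized rate is ``arm rate + N(0, heterogeneity_sd)``;
    since chronological age itself advances one year per year, the latent
    factors drift along the mortality-effect direction by the *excess*
    (rate - 1) so that true biological age changes by rate * t in total.
    Features are re-measured with fresh noise at every timepoint.  Returns a
    long-format table (subject, arm, sex, timepoint, true_ba_change, features).
    """
    tp = list(timepoints)
    if len(tp) < 2 or 0.0 not in tp:
        raise ValueError("need at least two timepoints including 0")
    if len(set(tp)) != len(tp):
        raise ValueError("duplicate timepoints")
    if set(arm_effects) != set(n_per_arm):
        raise ValueError("arm_effects and n_per_arm must name the same arms")

    rng = np.random.default_rng(config.seed)
    effects = np.asarray(config.latent_effects, float)
    norm2 = float(effects @ effects)
    if norm2 == 0:
        direction = np.zeros_like(effects)
    else:
        direction = effects / norm2  # drift d*direction moves eta by d
    b = config.gompertz_slope
    noise_sd = (config.noise_sd if measurement_noise_sd is None
                else measurement_noise_sd)
    L = _default_loadings(config)

    rows = []
    sid = 0
    for arm in sorted(arm_effects):
        rate = arm_effects[arm]
        for _ in range(n_per_arm[arm]):
            subj = f"T{sid:05d}"
            sid += 1
            sex = MALE if rng.random() < 0.5 else FEMALE
            age0 = rng.uniform(*config.age_range)
            z0 = rng.standard_normal(config.n_latent)
            subj_rate = rate + (rng.normal(0.0, heterogeneity_sd)
                                if heterogeneity_sd > 0 else 0.0)
            for t in tp:
                # excess over calendar aging: eta change of b*(rate-1)*t gives
                # a total true-BA change of rate*t once CA advances by t
                z_t = z0 + direction * (b * (subj_rate - 1.0) * t)
                feats = (z_t @ L.T
                         + rng.normal(0.0, noise_sd, size=config.n_features))
                feats = feats * config.feature_scale + config.feature_offset
                row = {
                    "subject_id": subj, "arm": arm, "timepoint": float(t),
                    "sex": sex, "chron_age": age0 + t,
                    "true_ba_change": subj_rate * t,
                }
                row.update({f"feat_{j:03d}": feats[j]
                            for j in range(config.n_features)})
                rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: CohortTable, truth: SyntheticTruth,
                 table_path: str | Path, codebook_path: str | Path,
                 truth_path: str | Path | None = None) -> None:
    """Write a generated cohort in the CSV + codebook dialect ``read_cohort`` reads."""
    cohort.write_csv(table_path)
    if cohort.codebook is not None:
        cohort.codebook.to_csv(codebook_path)
    if truth_path is not None:
        truth.write_json(truth_path)
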