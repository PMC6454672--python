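"""Synthetic screening-cohort generator.

The real screening cohort (a multi-center, multi-district follow-up of
middle-aged adults with eight questionnaire risk factors and a 4-year
first-ever-stroke outcome) is not publicly deposited.  This module generates
cohorts with the same statistical structure so the cleaning and estimation
machinery can be exercised against a known ground truth:

* 7 districts x urban/rural = 14 groups, several screening centers per group;
* eight binary risk factors with configurable prevalences and optional
  pairwise association (sequential conditional-Bernoulli scheme, calibrated
  so the configured marginal prevalences hold exactly);
* a 4-year incident-stroke outcome drawn from either a logistic model
  (baseline log-odds plus per-factor increments and optional pairwise
  interactions) or an explicit per-pattern lookup table;
* injectable outlier centers (a center whose positive rate for one factor is
  shifted by a multiplier) for testing the Dixon screen;
* prior-stroke, lost-to-follow-up and data-error flags drawn independently
  of the outcome.

``true_conditional_incidence`` returns the exact model-implied
P(stroke | pattern) by enumerating the 2^8 factor joint distribution — the
oracle that parameter-recovery tests compare estimates against.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .factors import BOOL_COLUMNS, COHORT_COLUMNS, DISTRICTS, FACTORS, validate_factor_names
from .patterns import FactorPattern


class ConfigError(ValueError):
    """A cohort configuration field is invalid; the message names the field."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value}")
    return value


@dataclass
class LogisticOutcome:
    """Logistic 4-year stroke risk: baseline log-odds + per-factor increments.

    ``increments`` maps factor name -> log-odds increment; missing factors get
    0.  ``interactions`` maps a factor pair -> extra log-odds when both are
    positive.  The intercept is ``logit(baseline_incidence)``.
    """

    increments: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        validate_factor_names(self.increments.keys())
        for pair in self.interactions:
            validate_factor_names(pair)
            if len(pair) != 2:
                raise ConfigError(f"interaction key must be a factor pair, got {pair!r}")

    def probabilities(self, X: np.ndarray, baseline: float) -> np.ndarray:
        """P(stroke | factors) for each row of the 0/1 matrix ``X`` (canonical order)."""
        if baseline <= 0.0:
            eta = np.full(X.shape[0], -np.inf)
        else:
            eta = np.full(X.shape[0], logit(baseline))
        for j, f in enumerate(FACTORS):
            beta = self.increments.get(f, 0.0)
            if beta:
                eta = eta + beta * X[:, j]
        for (f1, f2), gamma in self.interactions.items():
            if gamma:
                i, j = FACTORS.index(f1), FACTORS.index(f2)
                eta = eta + gamma * (X[:, i] * X[:, j])
        return expit(eta)


@dataclass
class LookupOutcome:
    """Explicit P(stroke | exact 8-factor pattern); unlisted patterns fall back to baseline."""

    table: dict[tuple[str, ...], float] = field(default_factory=dict)

    def validate(self) -> None:
        for pattern, p in self.table.items():
            validate_factor_names(pattern)
            _check_prob(f"lookup probability for {pattern!r}", p)

    def probabilities(self, X: np.ndarray, baseline: float) -> np.ndarray:
        probs = np.full(256, baseline)
        for pattern, p in self.table.items():
            idx = sum(1 << FACTORS.index(f) for f in pattern)
            probs[idx] = p
        codes = X.astype(np.int64) @ (1 << np.arange(8))
        return probs[codes]


# Default study conditions: factor prevalences and log-odds increments chosen
# as plausible values for a Chinese middle-aged (40-59) screening population,
# giving combination-conditional 4-year incidences on the order 0.006-0.2
# above a 0.0070 no-factor baseline.
DEFAULT_PREVALENCES: dict[str, float] = {
    "hypertension": 0.25,
    "atrial_fibrillation": 0.01,
    "smoking": 0.25,
    "dyslipidemia": 0.30,
    "diabetes": 0.08,
    "lack_of_exercise": 0.20,
    "overweight": 0.25,
    "family_history": 0.05,
}

DEFAULT_INCREMENTS: dict[str, float] = {
    "hypertension": 1.15,
    "atrial_fibrillation": 1.10,
    "smoking": 0.10,
    "dyslipidemia": 0.25,
    "diabetes": 0.85,
    "lack_of_exercise": 0.60,
    "overweight": 0.55,
    "family_history": 0.50,
}

#: Incident-case subtype mix (cerebral infarction / hemorrhage / TIA).
SUBTYPE_PROPORTIONS: tuple[float, float, float] = (0.503, 0.091, 0.406)


@dataclass
class CohortConfig:
    """Everything needed to simulate one screening cohort, including its seed."""

    n_people: int = 48007
    districts: tuple[str, ...] = DISTRICTS
    centers_per_group: int = 10
    factor_prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    factor_dependence: dict[tuple[str, str], float] = field(default_factory=dict)
    outcome_model: LogisticOutcome | LookupOutcome = field(
        default_factory=lambda: LogisticOutcome(dict(DEFAULT_INCREMENTS))
    )
    baseline_incidence: float = 0.0070
    prior_stroke_rate: float = 0.03
    lost_followup_rate: float = 0.0181
    error_rate: float = 0.005
    outlier_centers: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_people, (int, np.integer)) or self.n_people <= 0:
            raise ConfigError(f"n_people must be a positive integer, got {self.n_people!r}")
        if len(self.districts) == 0:
            raise ConfigError("districts must be a non-empty list")
        if len(self.districts) != 7:
            raise ConfigError(
                f"districts must list exactly 7 labels (x urban/rural = 14 groups), got {len(self.districts)}"
            )
        if self.centers_per_group <= 0:
            raise ConfigError(f"centers_per_group must be positive, got {self.centers_per_group}")
        if set(self.factor_prevalences) != set(FACTORS):
            missing = set(FACTORS) - set(self.factor_prevalences)
            extra = set(self.factor_prevalences) - set(FACTORS)
            raise ConfigError(
                f"factor_prevalences must cover exactly the 8 factors; missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        for f, p in self.factor_prevalences.items():
            _check_prob(f"factor_prevalences[{f}]", p)
        for pair in self.factor_dependence:
            validate_factor_names(pair)
        self.outcome_model.validate()
        _check_prob("baseline_incidence", self.baseline_incidence)
        _check_prob("prior_stroke_rate", self.prior_stroke_rate)
        _check_prob("lost_followup_rate", self.lost_followup_rate)
        _check_prob("error_rate", self.error_rate)
        for center, f, mult in self.outlier_centers:
            validate_factor_names([f])
            if mult < 0:
                raise ConfigError(f"outlier multiplier for center {center} must be >= 0, got {mult}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        model = self.outcome_model
        if isinstance(model, LogisticOutcome):
            model_d = {
                "kind": "logistic",
                "increments": dict(model.increments),
                "interactions": {";".join(k): v for k, v in model.interactions.items()},
            }
        else:
            model_d = {"kind": "lookup", "table": {";".join(k): v for k, v in model.table.items()}}
        return {
            "n_people": int(self.n_people),
            "districts": list(self.districts),
            "centers_per_group": int(self.centers_per_group),
            "factor_prevalences": dict(self.factor_prevalences),
            "factor_dependence": {";".join(k): v for k, v in self.factor_dependence.items()},
            "outcome_model": model_d,
            "baseline_incidence": self.baseline_incidence,
            "prior_stroke_rate": self.prior_stroke_rate,
            "lost_followup_rate": self.lost_followup_rate,
            "error_rate": self.error_rate,
            "outlier_centers": [list(t) for t in self.outlier_centers],
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        model_d = d.pop("outcome_model", None)
        if model_d is None:
            model = LogisticOutcome(dict(DEFAULT_INCREMENTS))
        elif model_d.get("kind") == "lookup":
            model = LookupOutcome({tuple(k.split(";")) if k else (): v for k, v in model_d.get("table", {}).items()})
        else:
            model = LogisticOutcome(
                increments=dict(model_d.get("increments", {})),
                interactions={tuple(k.split(";")): v for k, v in model_d.get("interactions", {}).items()},
            )
        dep = {tuple(k.split(";")): v for k, v in d.pop("factor_dependence", {}).items()}
        outliers = [tuple(t) for t in d.pop("outlier_centers", [])]
        cfg = cls(outcome_model=model, factor_dependence=dep, outlier_centers=outliers, **d)
        cfg.districts = tuple(cfg.districts)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- exact joint factor distribution ---------------------------------------

def _dependence_theta(config: CohortConfig) -> np.ndarray:
    """Pairwise association matrix theta[i, j] (log-odds), canonical indices."""
    theta = np.zeros((8, 8))
    for (f1, f2), t in config.factor_dependence.items():
        i, j = FACTORS.index(f1), FACTORS.index(f2)
        theta[i, j] = theta[j, i] = float(t)
    return theta


def _calibrated_bases(config: CohortConfig) -> np.ndarray:
    """Per-factor base log-odds for the sequential conditional-Bernoulli scheme.

    Factor j's conditional is sigmoid(base_j + sum_{i<j} theta_ij * x_i);
    base_j is solved so that the marginal prevalence equals the configured
    value exactly (given the joint distribution of the preceding factors).
    With all theta zero this reduces to base_j = logit(prevalence_j).
    """
    theta = _dependence_theta(config)
    prevs = np.array([config.factor_prevalences[f] for f in FACTORS])
    bases = np.zeros(8)
    # joint over prefixes, represented as probabilities of 2^j prefix patterns
    prefix_probs = np.array([1.0])
    prefix_patterns = np.zeros((1, 0))
    for j in range(8):
        p_target = prevs[j]
        if p_target in (0.0, 1.0):
            bases[j] = -np.inf if p_target == 0.0 else np.inf
            cond = np.full(len(prefix_probs), p_target)
        else:
            shift = prefix_patterns @ theta[:j, j] if j else np.zeros(1)

            def marginal(base):
                return float(prefix_probs @ expit(base + shift)) - p_target

            if np.allclose(shift, 0.0):
                bases[j] = logit(p_target)
            else:
                bases[j] = brentq(marginal, -40.0, 40.0, xtol=1e-12)
            cond = expit(bases[j] + shift)
        # extend prefix joint with factor j
        prefix_patterns = np.vstack(
            [np.hstack([prefix_patterns, np.zeros((len(prefix_probs), 1))]),
             np.hstack([prefix_patterns, np.ones((len(prefix_probs), 1))])]
        )
        prefix_probs = np.concatenate([prefix_probs * (1 - cond), prefix_probs * cond])
    return bases


def joint_factor_distribution(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint distribution over the 2^8 factor patterns.

    Returns ``(patterns, probs)``: a (256, 8) 0/1 matrix in canonical bit
    order and the matching probability vector (sums to 1).
    """
    theta = _dependence_theta(config)
    bases = _calibrated_bases(config)
    patterns = np.array(list(itertools.product([0, 1], repeat=8)))[:, ::-1]  # bit j = factor j
    probs = np.ones(256)
    for j in range(8):
        shift = patterns[:, :j] @ theta[:j, j]
        cond = expit(bases[j] + shift)
        probs = probs * np.where(patterns[:, j] == 1, cond, 1 - cond)
    return patterns, probs


def true_conditional_incidence(config: CohortConfig, pattern: FactorPattern) -> float:
    """Exact model-implied P(incident stroke | pattern) — no sampling.

    Sums the configured outcome model over the 2^8 factor joint distribution,
    restricted to the patterns consistent with ``pattern``'s semantics.
    Ground-truth oracle for parameter-recovery tests.
    """
    config.validate()
    patterns, probs = joint_factor_distribution(config)
    p_stroke = config.outcome_model.probabilities(patterns, config.baseline_incidence)
    mask = pattern.mask()
    if pattern.semantics == "exact":
        keep = np.all(patterns == np.array(mask, dtype=int), axis=1)
    else:
        keep = np.ones(256, dtype=bool)
        for j, named in enumerate(mask):
            if named:
                keep &= patterns[:, j] == 1
    w = probs[keep]
    if w.sum() == 0.0:
        raise ValueError(f"pattern {pattern.label()} has probability 0 under the configured factor distribution")
    return float(w @ p_stroke[keep] / w.sum())


# -- cohort generation ------------------------------------------------------

def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one screening cohort as a DataFrame (one row per person).

    Reproducible given ``config.seed``; factor marginals, outcome
    conditionals and injected outlier-center rates converge to the
    configured model as ``n_people`` grows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_people)

    # group & center assignment: uniform over the 14 groups, uniform within
    groups = [(d, u) for d in config.districts for u in (1, 0)]
    g_idx = rng.integers(0, len(groups), size=n)
    c_idx = rng.integers(0, config.centers_per_group, size=n)
    district = np.array([g[0] for g in groups])[g_idx]
    urban = np.array([g[1] for g in groups])[g_idx]
    center_id = np.array(
        [f"{d}_{'u' if u else 'r'}_c{c:02d}" for d, u, c in zip(district, urban, c_idx)]
    )

    age = rng.integers(40, 60, size=n)

    # factors: sequential conditional-Bernoulli, vectorised over people
    theta = _dependence_theta(config)
    bases = _calibrated_bases(config)
    outliers_by_factor: dict[str, list[tuple[str, float]]] = {}
    for center, f, mult in config.outlier_centers:
        outliers_by_factor.setdefault(f, []).append((center, mult))
    X = np.zeros((n, 8), dtype=np.int8)
    for j, f in enumerate(FACTORS):
        eta = bases[j] + (X[:, :j] @ theta[:j, j] if j else 0.0)
        p = expit(eta)
        for center, mult in outliers_by_factor.get(f, ()):  # outlier centers shift this factor's rate
            p = np.where(center_id == center, np.clip(p * mult, 0.0, 1.0), p)
        X[:, j] = rng.random(n) < p

    p_stroke = config.outcome_model.probabilities(X, config.baseline_incidence)
    incident = rng.random(n) < p_stroke

    subtype = np.full(n, "none", dtype=object)
    n_inc = int(incident.sum())
    if n_inc:
        subtype[incident] = rng.choice(
            ["cerebral_infarction", "cerebral_hemorrhage", "tia"],
            size=n_inc,
            p=np.array(SUBTYPE_PROPORTIONS) / sum(SUBTYPE_PROPORTIONS),
        )

    prior = rng.random(n) < config.prior_stroke_rate
    lost = rng.random(n) < config.lost_followup_rate
    error = rng.random(n) < config.error_rate
    # outcome is unknowable for people lost to follow-up
    incident = np.where(lost, False, incident)
    subtype = np.where(lost, "none", subtype)

    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "center_id": center_id,
            "district": district,
            "urban": urban.astype(bool),
            "age": age,
            **{f: X[:, j].astype(bool) for j, f in enumerate(FACTORS)},
            "prior_stroke": prior,
            "incident_stroke": incident.astype(bool),
            "stroke_subtype": subtype,
            "lost_to_followup": lost,
            "data_error": error,
        },
        columns=list(COHORT_COLUMNS),
    )
    return df


def case_mix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subtype counts and percentages among incident first-ever strokes."""
    cases = cohort[cohort["incident_stroke"].astype(bool)]
    counts = cases["stroke_subtype"].value_counts()
    counts = counts[counts.index != "none"]
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts.astype(int)})
    out["percent"] = (100.0 * out["count"] / total).round(1) if total else 0.0
    out.index.name = "stroke_subtype"
    return out


# -- CSV round trip ---------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a cohort CSV (booleans as 0/1) with the seed recorded in a header comment."""
    out = cohort.copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or any file with the same header)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df["age"] = df["age"].astype(int)
    return df
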