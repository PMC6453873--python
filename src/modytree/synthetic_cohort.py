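"""Synthetic four-group diabetes cohorts with realistic marker distributions.

No patient-level data accompany the study this package models, only group
summaries: means ± SD for roughly symmetric clinical variables and medians
with quartiles for the skewed biomarkers (hsCRP, 1,5-AG, C-peptide). The
simulator turns those summaries into sampling distributions:

* mean ± SD variables -> normal, truncated at per-variable plausibility
  bounds (BMI cannot be 3 kg/m², HbA1c cannot be negative);
* median (Q1, Q3) variables -> a *split lognormal*: ``exp(mu + sigma_lo·Z)``
  for ``Z < 0`` and ``exp(mu + sigma_hi·Z)`` for ``Z ≥ 0``. The two log-scale
  spreads are chosen so the law reproduces the printed median and both
  quartiles exactly (a single-sigma lognormal can only match a median plus a
  symmetric log-IQR);
* type 1 diabetes C-peptide -> a detection-floor mixture: with probability
  ``floor_prob`` the assay floor itself (the printed median and Q1 both equal
  0.01 ng/ml, forcing at least half the mass onto the floor), otherwise a
  lognormal tail anchored so the overall 75th percentile hits 0.10 ng/ml.

Markers are drawn independently within patient (the source summaries carry no
joint structure). Randomness flows from one root seed through per-(group,
variable) substreams, so adding a variable never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort, Group, Sex, Treatment, COLUMNS
from .exceptions import ConfigurationError

__all__ = [
    "GroupDistributionSpec",
    "SimulationConfig",
    "fit_lognormal_from_quantiles",
    "fit_split_lognormal_from_quantiles",
    "split_lognormal_ppf",
    "default_config",
    "simulate_cohort",
    "simulate_dataframe",
    "DEFAULT_GROUP_SIZES",
    "GROUP_ORDER",
]

#: canonical group order used for substream derivation and reporting
GROUP_ORDER: tuple[Group, ...] = (Group.HNF1A, Group.GCK, Group.T1D, Group.T2D)

DEFAULT_GROUP_SIZES: dict[Group, int] = {
    Group.HNF1A: 77,
    Group.GCK: 88,
    Group.T1D: 99,
    Group.T2D: 92,
}

_Z75 = float(stats.norm.ppf(0.75))

# ---------------------------------------------------------------------------
# study-group summary statistics (the simulation targets)
# ---------------------------------------------------------------------------

# mean ± SD variables, per group in GROUP_ORDER
_MEANSD: dict[str, dict[Group, tuple[float, float]]] = {
    "age": {
        Group.HNF1A: (38.8, 15.2),
        Group.GCK: (34.7, 15.2),
        Group.T1D: (29.1, 10.3),
        Group.T2D: (59.4, 10.2),
    },
    "diabetes_duration": {
        Group.HNF1A: (17.3, 10.2),
        Group.GCK: (26.2, 12.4),
        Group.T1D: (12.5, 8.0),
        Group.T2D: (6.5, 6.5),
    },
    "age_at_diagnosis": {
        Group.HNF1A: (23.1, 12.1),
        Group.GCK: (7.3, 7.3),
        Group.T1D: (16.6, 9.0),
        Group.T2D: (52.9, 10.7),
    },
    "bmi": {
        Group.HNF1A: (23.9, 4.2),
        Group.GCK: (23.7, 4.6),
        Group.T1D: (23.9, 2.7),
        Group.T2D: (30.3, 4.6),
    },
    "creatinine": {
        Group.HNF1A: (75.5, 15.9),
        Group.GCK: (74.0, 13.4),
        Group.T1D: (74.4, 13.4),
        Group.T2D: (82.7, 20.8),
    },
    "hba1c": {
        Group.HNF1A: (6.9, 1.4),
        Group.GCK: (6.3, 0.7),
        Group.T1D: (7.4, 1.1),
        Group.T2D: (6.8, 1.2),
    },
    "fasting_glucose": {
        Group.HNF1A: (6.8, 2.6),
        Group.GCK: (6.9, 1.3),
        Group.T1D: (8.1, 3.0),
        Group.T2D: (7.6, 1.9),
    },
}

# median (Q1, Q3) biomarkers, per group
_QUANTILES: dict[str, dict[Group, tuple[float, float, float]]] = {
    "hscrp": {
        Group.HNF1A: (0.51, 0.46, 0.66),
        Group.GCK: (0.76, 0.52, 1.55),
        Group.T1D: (0.75, 0.53, 1.41),
        Group.T2D: (1.33, 0.77, 2.50),
    },
    "ag15": {
        Group.HNF1A: (4.70, 2.78, 8.19),
        Group.GCK: (11.24, 6.54, 14.28),
        Group.T1D: (3.77, 1.94, 6.02),
        Group.T2D: (6.07, 3.75, 10.54),
    },
    "c_peptide": {
        Group.HNF1A: (1.45, 1.07, 1.80),
        Group.GCK: (1.43, 0.96, 1.80),
        # T1D uses the floor mixture instead (see default_config)
        Group.T2D: (2.78, 1.95, 3.55),
    },
}

_FEMALE_FRACTION: dict[Group, float] = {
    Group.HNF1A: 0.649,
    Group.GCK: 0.614,
    Group.T1D: 0.391,
    Group.T2D: 0.616,
}

# (insulin, non-insulin agents, diet only)
_TREATMENT_FRACTION: dict[Group, tuple[float, float, float]] = {
    Group.HNF1A: (0.35, 0.48, 0.17),
    Group.GCK: (0.06, 0.17, 0.77),
    Group.T1D: (1.00, 0.00, 0.00),
    Group.T2D: (0.17, 0.81, 0.02),
}

# truncation bounds for the normal family (also keep every draw positive)
_VAR_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (1.0, 110.0),
    "diabetes_duration": (0.1, 90.0),
    "age_at_diagnosis": (0.5, 100.0),
    "bmi": (10.0, 80.0),
    "creatinine": (10.0, 400.0),
    "hba1c": (3.0, 20.0),
    "fasting_glucose": (1.0, 40.0),
}

#: canonical variable order used for substream derivation
_VARIABLE_ORDER: tuple[str, ...] = (
    "sex",
    "age",
    "diabetes_duration",
    "age_at_diagnosis",
    "bmi",
    "creatinine",
    "hba1c",
    "fasting_glucose",
    "c_peptide",
    "hscrp",
    "ag15",
    "treatment",
)

#: (group, variable) pairs that the decision tree requires of every cohort
REQUIRED_TREE_VARIABLES: tuple[str, ...] = ("c_peptide", "bmi", "ag15", "hscrp", "fasting_glucose")


# ---------------------------------------------------------------------------
# quantile fitting
# ---------------------------------------------------------------------------

def _check_quartiles(median: float, q1: float, q3: float) -> None:
    if not (0 < q1 < median < q3):
        raise ValueError(
            f"quartiles must satisfy 0 < q1 < median < q3, got ({q1}, {median}, {q3})"
        )


def fit_lognormal_from_quantiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Fit a (single-sigma) lognormal from a median and quartiles.

    Returns ``(mu, sigma)`` on the log scale with ``mu = ln(median)`` and
    ``sigma = (ln q3 − ln q1) / (2 z_{0.75})``. The fitted law reproduces the
    median and the log-scale interquartile range exactly; the individual
    quartiles are reproduced exactly only when they are symmetric on the log
    scale (otherwise use :func:`fit_split_lognormal_from_quantiles`).
    """
    _check_quartiles(median, q1, q3)
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
    return mu, sigma


def fit_split_lognormal_from_quantiles(
    median: float, q1: float, q3: float
) -> tuple[float, float, float]:
    """Fit a split lognormal matching the median and both quartiles exactly.

    Returns ``(mu, sigma_lo, sigma_hi)``: draws are ``exp(mu + sigma_lo·Z)``
    for standard-normal ``Z < 0`` and ``exp(mu + sigma_hi·Z)`` otherwise.
    Reduces to the plain lognormal when the quartiles are log-symmetric.
    """
    _check_quartiles(median, q1, q3)
    mu = float(np.log(median))
    sigma_lo = float((mu - np.log(q1)) / _Z75)
    sigma_hi = float((np.log(q3) - mu) / _Z75)
    return mu, sigma_lo, sigma_hi


def split_lognormal_ppf(p, mu: float, sigma_lo: float, sigma_hi: float):
    """Quantile function of the split lognormal (closed form)."""
    p = np.asarray(p, dtype=float)
    z = stats.norm.ppf(p)
    sigma = np.where(z < 0, sigma_lo, sigma_hi)
    return np.exp(mu + sigma * z)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_FAMILIES = ("lognormal_quantile", "normal_meansd", "point_mass_floor_mixture")


@dataclass(frozen=True)
class GroupDistributionSpec:
    """Per-group, per-variable sampling distribution.

    ``params`` is family specific:

    * ``lognormal_quantile`` — ``median``, ``q1``, ``q3``;
    * ``normal_meansd`` — ``mean``, ``sd`` (optional ``lo``/``hi`` truncation);
    * ``point_mass_floor_mixture`` — ``floor``, ``floor_prob``, ``q75``
      (overall 75th percentile), ``tail_sigma`` (log-scale spread of the
      detectable tail).
    """

    group: Group
    variable: str
    family: str
    params: Mapping[str, float]
    floor: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        p = dict(self.params)
        if self.family == "lognormal_quantile":
            _check_quartiles(p["median"], p["q1"], p["q3"])
        elif self.family == "normal_meansd":
            if p["sd"] <= 0:
                raise ConfigurationError(f"sd must be > 0 for {self.variable}")
        else:  # point_mass_floor_mixture
            if not (0.0 <= p["floor_prob"] <= 1.0):
                raise ConfigurationError("floor_prob must lie in [0, 1]")
            if p["floor"] <= 0 or p.get("tail_sigma", 1.0) <= 0:
                raise ConfigurationError("floor and tail_sigma must be > 0")


@dataclass
class SimulationConfig:
    """Everything needed to draw one reproducible synthetic cohort."""

    group_sizes: dict[Group, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    specs: list[GroupDistributionSpec] = field(default_factory=list)
    seed: int = 0
    c_peptide_floor: float = 0.01
    female_fraction: dict[Group, float] = field(default_factory=lambda: dict(_FEMALE_FRACTION))
    treatment_fraction: dict[Group, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_TREATMENT_FRACTION)
    )

    def spec_for(self, group: Group, variable: str) -> GroupDistributionSpec:
        for s in self.specs:
            if s.group == group and s.variable == variable:
                return s
        raise ConfigurationError(f"no distribution spec for ({group.value}, {variable})")

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigurationError(f"group size for {g.value} must be >= 1")
        for g in self.group_sizes:
            for v in REQUIRED_TREE_VARIABLES:
                self.spec_for(g, v)  # raises if absent

    def digest(self) -> str:
        """Stable 12-hex digest of the configuration (for provenance blocks)."""
        return hashlib.sha256(
            json.dumps(config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def default_config(
    seed: int = 0,
    group_sizes: Mapping[Group, int] | None = None,
    t1d_floor_prob: float = 0.50,
    t1d_tail_sigma: float = 0.8,
    c_peptide_floor: float = 0.01,
) -> SimulationConfig:
    """The study-condition configuration: group sizes 77/88/99/92 and the
    published per-group summary statistics as distribution targets.

    ``t1d_floor_prob`` is the fraction of type 1 diabetes patients whose
    C-peptide sits at the detection floor; the printed median and Q1 both
    equal the floor, so it must be at least 0.5. The tail is anchored so the
    group's 75th percentile equals 0.10 ng/ml.
    """
    specs: list[GroupDistributionSpec] = []
    for var, per_group in _MEANSD.items():
        lo, hi = _VAR_BOUNDS[var]
        for g, (mean, sd) in per_group.items():
            specs.append(
                GroupDistributionSpec(
                    g, var, "normal_meansd", {"mean": mean, "sd": sd, "lo": lo, "hi": hi}
                )
            )
    for var, per_group in _QUANTILES.items():
        for g, (med, q1, q3) in per_group.items():
            specs.append(
                GroupDistributionSpec(
                    g, var, "lognormal_quantile", {"median": med, "q1": q1, "q3": q3}
                )
            )
    specs.append(
        GroupDistributionSpec(
            Group.T1D,
            "c_peptide",
            "point_mass_floor_mixture",
            {
                "floor": c_peptide_floor,
                "floor_prob": t1d_floor_prob,
                "q75": 0.10,
                "tail_sigma": t1d_tail_sigma,
            },
            floor=c_peptide_floor,
        )
    )
    cfg = SimulationConfig(
        group_sizes=dict(group_sizes) if group_sizes is not None else dict(DEFAULT_GROUP_SIZES),
        specs=specs,
        seed=int(seed),
        c_peptide_floor=c_peptide_floor,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _substream(seed: int, group: Group, variable: str) -> np.random.Generator:
    gi = GROUP_ORDER.index(group)
    vj = _VARIABLE_ORDER.index(variable)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(gi, vj)))


def _sample(spec: GroupDistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = dict(spec.params)
    if spec.family == "normal_meansd":
        mean, sd = p["mean"], p["sd"]
        lo = p.get("lo", 0.0)
        hi = p.get("hi", np.inf)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    if spec.family == "lognormal_quantile":
        mu, s_lo, s_hi = fit_split_lognormal_from_quantiles(p["median"], p["q1"], p["q3"])
        z = rng.standard_normal(n)
        sigma = np.where(z < 0, s_lo, s_hi)
        return np.exp(mu + sigma * z)
    # point_mass_floor_mixture
    floor, fp = p["floor"], p["floor_prob"]
    out = np.full(n, floor, dtype=float)
    tail = rng.random(n) >= fp
    n_tail = int(tail.sum())
    if n_tail and fp < 1.0:
        sigma = p.get("tail_sigma", 0.8)
        # anchor the overall 75th percentile: the tail must place its
        # (0.75 - fp)/(1 - fp) quantile at q75
        q75 = p.get("q75", 10 * floor)
        p_tail = (0.75 - fp) / (1.0 - fp)
        if 0.0 < p_tail < 1.0:
            mu = float(np.log(q75) - sigma * stats.norm.ppf(p_tail))
        else:
            mu = float(np.log(q75))
        draws = np.exp(mu + sigma * rng.standard_normal(n_tail))
        out[tail] = np.maximum(draws, floor)  # assay cannot report below floor
    return out


def simulate_dataframe(config: SimulationConfig) -> pd.DataFrame:
    """Draw a synthetic cohort as a data frame (vectorized; fast at large n)."""
    config.validate()
    frames = []
    for g in GROUP_ORDER:
        if g not in config.group_sizes:
            continue
        n = config.group_sizes[g]
        cols: dict[str, object] = {
            "id": [f"{g.value}-{i + 1:06d}" for i in range(n)],
            "group": g.value,
        }
        rng_sex = _substream(config.seed, g, "sex")
        fem = config.female_fraction.get(g, 0.5)
        cols["sex"] = np.where(rng_sex.random(n) < fem, Sex.F.value, Sex.M.value)
        for var in _MEANSD:
            spec = config.spec_for(g, var)
            cols[var] = _sample(spec, n, _substream(config.seed, g, var))
        for var in _QUANTILES:
            spec = config.spec_for(g, var)
            cols[var] = _sample(spec, n, _substream(config.seed, g, var))
        rng_tr = _substream(config.seed, g, "treatment")
        probs = np.asarray(config.treatment_fraction.get(g, (1 / 3, 1 / 3, 1 / 3)), dtype=float)
        probs = probs / probs.sum()
        choices = rng_tr.choice(3, size=n, p=probs)
        cols["treatment"] = np.array(
            [Treatment.INSULIN.value, Treatment.NON_INSULIN.value, Treatment.DIET.value]
        )[choices]
        frames.append(pd.DataFrame(cols, columns=list(COLUMNS)))
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a validated synthetic :class:`Cohort` (reproducible given the seed)."""
    df = simulate_dataframe(config)
    provenance = f"simulated(seed={config.seed}, config={config.digest()})"
    return Cohort.from_dataframe(df, provenance=provenance)


# ---------------------------------------------------------------------------
# JSON round-trip for configs
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "group_sizes": {g.value: n for g, n in config.group_sizes.items()},
        "seed": config.seed,
        "c_peptide_floor": config.c_peptide_floor,
        "female_fraction": {g.value: f for g, f in config.female_fraction.items()},
        "treatment_fraction": {g.value: list(t) for g, t in config.treatment_fraction.items()},
        "specs": [
            {
                "group": s.group.value,
                "variable": s.variable,
                "family": s.family,
                "params": dict(s.params),
                "floor": s.floor,
            }
            for s in config.specs
        ],
    }


def config_from_dict(d: Mapping) -> SimulationConfig:
    cfg = SimulationConfig(
        group_sizes={Group(g): int(n) for g, n in d["group_sizes"].items()},
        specs=[
            GroupDistributionSpec(
                Group(s["group"]), s["variable"], s["family"], dict(s["params"]), s.get("floor")
            )
            for s in d["specs"]
        ],
        seed=int(d.get("seed", 0)),
        c_peptide_floor=float(d.get("c_peptide_floor", 0.01)),
    )
    if "female_fraction" in d:
        cfg.female_fraction = {Group(g): float(f) for g, f in d["female_fraction"].items()}
    if "treatment_fraction" in d:
        cfg.treatment_fraction = {
            Group(g): tuple(t) for g, t in d["treatment_fraction"].items()
        }
    return cfg
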