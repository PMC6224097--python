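"""Population / analysis configuration.

`PopulationConfig` fully specifies the generative model for DHS-like
hierarchical birth histories: the sampling hierarchy (region > cluster >
household > woman > birth), target covariate margins, the log-rate outcome
model (fixed effects and random-effect covariances per outcome), the policy
roll-out, and the seed.  Defaults emulate the Burkina Faso DHS 2010 frame:
~550 clusters in 13 regions, ~32,000 live births over January 2000 -
December 2010, a delivery-fee subsidy starting January 2007 with a 0-3
month staggered district roll-out.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

#: canonical fixed-effect term names used by the generator and the model
BETA_TERMS = (
    "intercept", "time", "subsidy", "post_time",
    "rural",
    "wealth:poorer", "wealth:middle", "wealth:richer", "wealth:richest",
    "illiterate",
    "education:primary", "education:secondary+",
    "subsidy_x_rural",
    "multiple",
    "age:20-24", "age:25-29", "age:30-34", "age:35-39", "age:40-49",
    "order:2-4", "order:5+",
    "interval:<36",
    "worked",
    "newborn_female",
)

WEALTH_LEVELS = ("poorest", "poorer", "middle", "richer", "richest")
EDUCATION_LEVELS = ("none", "primary", "secondary+")
AGE_LEVELS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-49")
ORDER_LEVELS = ("first", "2-4", "5+")
INTERVAL_LEVELS = (">=36", "<36", "first")


def _default_margins() -> Dict[str, object]:
    return {
        "rural": 0.793,
        "wealth_quintile": [0.206, 0.213, 0.217, 0.214, 0.150],
        "education": [0.857, 0.099, 0.044],
        "literate": 0.121,
        "mother_age_group": [0.130, 0.281, 0.244, 0.182, 0.118, 0.045],
        "mother_worked": 0.809,
        "newborn_female": 0.488,
        "multiple_birth": 0.035,
        "preceding_interval_cat": [0.354, 0.453, 0.193],
    }


def _default_beta() -> Dict[str, Dict[str, float]]:
    # Facility-delivery coefficients follow the published rural/urban fee
    # subsidy estimates (urban stratum is the reference level of `rural`);
    # neonatal-mortality coefficients give a ~3.9% pre-period rate and a
    # modest immediate subsidy effect with a slowly widening slope change.
    delivery = {
        "intercept": -0.5405, "time": 0.003, "subsidy": 0.0386,
        "post_time": 0.0027, "rural": -0.3829, "subsidy_x_rural": 0.1002,
        "wealth:poorer": 0.1069, "wealth:middle": 0.1728,
        "wealth:richer": 0.2112, "wealth:richest": 0.2752,
        "illiterate": -0.0999, "multiple": 0.1136,
        "age:20-24": -0.0455, "age:25-29": -0.0662, "age:30-34": -0.0358,
        "age:35-39": -0.0223, "age:40-49": -0.0267,
        "order:2-4": -0.0811, "order:5+": -0.1244,
        "worked": 0.0948,
    }
    mortality = {
        "intercept": -3.56, "time": -0.004, "subsidy": -0.0726,
        "post_time": -0.0064, "rural": 0.20,
        "wealth:poorer": -0.05, "wealth:middle": -0.08,
        "wealth:richer": -0.12, "wealth:richest": -0.25,
        "illiterate": 0.10, "multiple": 1.00,
        "age:20-24": -0.10, "age:25-29": -0.15, "age:30-34": -0.10,
        "age:35-39": 0.00, "age:40-49": 0.15,
        "order:2-4": -0.15, "order:5+": 0.05,
        "interval:<36": 0.30, "newborn_female": -0.10,
    }
    return {"delivery": delivery, "mortality": mortality}


def _default_psi() -> Dict[str, Dict[str, float]]:
    # Cluster-level (intercept, subsidy, time) covariance per outcome.  The
    # intercept-subsidy correlation of -0.9 encodes the finding that
    # low-baseline clusters gained most from the subsidy.
    return {
        "delivery": {"psi11": 0.7682, "psi22": 0.0819, "psi33": 5e-05,
                     "corr_int_subsidy": -0.9, "corr_int_time": 0.0,
                     "corr_subsidy_time": 0.0, "level2_var": 0.0},
        "mortality": {"psi11": 0.30, "psi22": 0.05, "psi33": 1e-05,
                      "corr_int_subsidy": -0.5, "corr_int_time": 0.0,
                      "corr_subsidy_time": 0.0, "level2_var": 0.30},
    }


@dataclass
class PopulationConfig:
    n_regions: int = 13
    n_clusters: int = 550
    urban_fraction: float = 0.207
    households_per_cluster_mean: float = 15.0
    extra_women_per_household_mean: float = 0.25
    #: births per woman: 1 + NegBin(r, mu) truncated to {1..8} (median 3)
    births_nb_r: float = 2.0
    births_nb_mu: float = 2.3
    observation_window: Tuple[int, int] = (0, 131)
    subsidy_month: int = 84
    rollout_spread_months: int = 3
    covariate_margins: Dict[str, object] = field(default_factory=_default_margins)
    true_beta: Dict[str, Dict[str, float]] = field(default_factory=_default_beta)
    true_psi: Dict[str, Dict[str, float]] = field(default_factory=_default_psi)
    seasonal_multiplier: Optional[Sequence[float]] = None  # 12 values, None = flat
    twin_prob: float = 0.0178
    age_first_birth_mean: float = 19.0
    age_first_birth_sd: float = 3.5
    prior_parity_probs: Sequence[float] = (0.55, 0.09, 0.09, 0.09,
                                           0.07, 0.06, 0.05)
    mean_prior_interval_months: float = 34.0
    #: variance of an optional birth-level (level-1) log-normal frailty
    level1_frailty_var: Dict[str, float] = field(
        default_factory=lambda: {"delivery": 0.0, "mortality": 0.0})
    time_origin: Dict[str, int] = field(
        default_factory=lambda: {"delivery": 65, "mortality": 0})
    truncation_warn_fraction: float = 0.01
    seed: int = 0

    # ------------------------------------------------------------------
    def psi_matrix(self, outcome: str) -> np.ndarray:
        """Cluster-level 3x3 covariance (intercept, subsidy, time)."""
        p = self.true_psi[outcome]
        s = np.sqrt([p["psi11"], p["psi22"], p["psi33"]])
        c = np.array([
            [1.0, p["corr_int_subsidy"], p["corr_int_time"]],
            [p["corr_int_subsidy"], 1.0, p["corr_subsidy_time"]],
            [p["corr_int_time"], p["corr_subsidy_time"], 1.0],
        ])
        return c * np.outer(s, s)

    def validate(self) -> None:
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must lie in [0, 1]")
        m = self.covariate_margins
        for key in ("wealth_quintile", "education", "mother_age_group",
                    "preceding_interval_cat"):
            probs = np.asarray(m[key], dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"margins for {key} must be a probability "
                                 f"vector summing to 1 (got {probs})")
        for key in ("rural", "literate", "mother_worked", "newborn_female",
                    "multiple_birth"):
            p = float(m[key])
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"margin {key}={p} outside [0, 1]")
        lo, hi = self.observation_window
        if not (lo <= self.subsidy_month <= hi):
            raise ValueError("subsidy_month must lie inside observation_window")
        if self.rollout_spread_months < 0:
            raise ValueError("rollout_spread_months must be >= 0")
        for outcome in self.true_psi:
            psi = self.psi_matrix(outcome)
            ev = np.linalg.eigvalsh(psi)
            if ev.min() < -1e-10 * max(1.0, ev.max()):
                raise ValueError(
                    f"true_psi for {outcome!r} is not positive semi-definite")
            if self.true_psi[outcome].get("level2_var", 0.0) < 0:
                raise ValueError("level2_var must be >= 0")
        probs = np.asarray(self.prior_parity_probs, dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("prior_parity_probs must sum to 1")
        if self.seasonal_multiplier is not None:
            sm = np.asarray(self.seasonal_multiplier, dtype=float)
            if sm.shape != (12,) or np.any(sm <= 0):
                raise ValueError("seasonal_multiplier needs 12 positive values")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = copy.deepcopy(self.__dict__)
        d["observation_window"] = list(self.observation_window)
        d["prior_parity_probs"] = list(self.prior_parity_probs)
        if self.seasonal_multiplier is not None:
            d["seasonal_multiplier"] = list(self.seasonal_multiplier)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = copy.deepcopy(d)
        if "observation_window" in d:
            d["observation_window"] = tuple(d["observation_window"])
        base = cls()
        for key in ("covariate_margins", "true_beta", "true_psi",
                    "level1_frailty_var", "time_origin"):
            if key in d:
                merged = copy.deepcopy(getattr(base, key))
                for k, v in d[key].items():
                    if isinstance(v, dict) and isinstance(merged.get(k), dict):
                        merged[k].update(v)
                    else:
                        merged[k] = v
                d[key] = merged
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload.get("population", payload))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
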