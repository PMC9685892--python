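"""Seeded synthetic interhospital-transfer cohorts.

The motivating EHR cohort (adult critical-care transfers within one
health system; N = 8,893 episodes, 11.7% in-hospital mortality) cannot
be shared, so this module generates cohorts with the same published
marginal structure: a truncated-normal age distribution top-coded at 90,
the published sex/race mix, ~70 diagnosis indicators spread over the six
subcategories with per-subcategory mean counts near the published ones,
and a logistic in-hospital-death model with planted high-risk diagnosis
interactions whose carrier mortality exceeds 50%.

Generative model, per patient i:

* covariates: age_i ~ TruncNormal(mu, sigma, [21, 90]), rounded and
  top-coded; sex_i and race_i categorical;
* a single latent comorbidity-burden factor Z_i ~ N(0, 1);
* item presence: x_ij ~ Bernoulli(sigmoid(b_j + lambda_j Z_i
  + alpha_j (age_i - mu)/10)) — the shared burden loading lambda_j
  induces the positive co-occurrence that real multimorbid cohorts show;
* death: y_i ~ Bernoulli(sigmoid(beta_0 + sum_j beta_j x_ij
  + sum_S gamma_S prod_{j in S} x_ij + covariate terms)), with beta_0
  calibrated by bisection so that the cohort mortality hits its target.

The planted interaction terms gamma_S are what the downstream rule
mining is expected to recover.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .code_mapping import (
    SUBCATEGORIES,
    IndicatorMatrix,
    MappingTable,
    build_indicators,
    item_name,
    map_records,
)

logger = logging.getLogger("ihtminer")

#: Discharge dispositions and their published cohort proportions
#: (survivor categories are renormalized over the non-death mass when
#: sampling survivors).
DISPOSITION_PROBS: dict[str, float] = {
    "Home": 4683 / 8893,
    "Died": 1041 / 8893,
    "Home care": 828 / 8893,
    "Nursing facility": 1566 / 8893,
    "Other facility": 677 / 8893,
    "Other": 98 / 8893,
}

# Independent child-stream tags so calibration probes and the cohort draw
# never share random state.
_CALIB_STREAM = 101
_COHORT_STREAM = 202


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


class CalibrationError(RuntimeError):
    """Raised when intercept bisection cannot reach the target rate."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# Probabilists' Gauss-Hermite rule for integrating over the latent burden.
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(61)
_GH_W = _GH_W / _GH_W.sum()


@dataclass(frozen=True)
class CatalogItem:
    """One diagnosis indicator in the synthetic catalog.

    ``base_logit`` is the log-odds of presence at Z = 0 and mean age;
    ``loading`` (>= 0) scales the shared burden factor; ``age_loading``
    is log-odds per decade of age above the cohort mean.
    """

    concept: str
    subcategory: str
    base_logit: float
    loading: float = 0.0
    age_loading: float = 0.0

    def __post_init__(self) -> None:
        if self.subcategory not in SUBCATEGORIES:
            raise ConfigurationError(
                f"unknown subcategory {self.subcategory!r}; allowed: {SUBCATEGORIES}"
            )
        if self.loading < 0:
            raise ConfigurationError(f"{self.concept}: burden loading must be >= 0")

    @property
    def name(self) -> str:
        return item_name(self.subcategory, self.concept)


@dataclass(frozen=True)
class PlantedInteraction:
    """Extra death log-odds gamma for carriers of the full item set."""

    items: tuple[str, ...]
    gamma: float


@dataclass(frozen=True)
class CovariateEffects:
    """Death log-odds contributions of demographics.

    ``age_per_decade`` applies to (age - age_mean)/10; ``sex`` and
    ``race`` map non-reference levels to log-odds increments (absent
    levels contribute 0, so the reference level is whatever is omitted).
    """

    age_per_decade: float = 0.0
    sex: Mapping[str, float] = field(default_factory=dict)
    race: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    seed: int
    item_catalog: tuple[CatalogItem, ...]
    sex_probs: Mapping[str, float]
    race_probs: Mapping[str, float]
    outcome_main_effects: Mapping[str, float] = field(default_factory=dict)
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    target_mortality: float = 0.117
    age_mean: float = 63.5
    age_sd: float = 14.3
    age_min: int = 21
    age_topcode: int = 90

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not 0.0 < self.target_mortality < 1.0:
            raise ConfigurationError("target_mortality must lie in (0, 1)")
        for label, probs in (("sex_probs", self.sex_probs), ("race_probs", self.race_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{label} must sum to 1 (got {total!r})")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{label} must be non-negative")
        names = [it.name for it in self.item_catalog]
        if len(names) != len(set(names)):
            raise ConfigurationError("item names must be unique within the catalog")
        known = set(names)
        for eff in self.outcome_main_effects:
            if eff not in known:
                raise ConfigurationError(f"main effect on unknown item {eff!r}")
        for inter in self.planted_interactions:
            if not 2 <= len(inter.items) <= 4:
                raise ConfigurationError(
                    f"planted interaction {inter.items} must have 2-4 items"
                )
            unknown = set(inter.items) - known
            if unknown:
                raise ConfigurationError(
                    f"planted interaction references unknown items {sorted(unknown)}"
                )
        if not self.age_min <= self.age_topcode:
            raise ConfigurationError("age_min must not exceed age_topcode")

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.item_catalog]

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration (provenance)."""
        payload = {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "target_mortality": self.target_mortality,
            "age": [self.age_mean, self.age_sd, self.age_min, self.age_topcode],
            "sex_probs": dict(sorted(self.sex_probs.items())),
            "race_probs": dict(sorted(self.race_probs.items())),
            "catalog": [
                [it.concept, it.subcategory, it.base_logit, it.loading, it.age_loading]
                for it in self.item_catalog
            ],
            "main_effects": dict(sorted(self.outcome_main_effects.items())),
            "interactions": [
                [list(i.items), i.gamma] for i in self.planted_interactions
            ],
            "covariates": [
                self.covariate_effects.age_per_decade,
                dict(sorted(self.covariate_effects.sex.items())),
                dict(sorted(self.covariate_effects.race.items())),
            ],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def marginal_prevalence(base_logit: float, latent_sd: float) -> float:
    """E[sigmoid(b + s*Z)] for Z ~ N(0,1), by Gauss-Hermite quadrature."""
    if latent_sd == 0:
        return float(expit(base_logit))
    return float(np.dot(_GH_W, expit(base_logit + latent_sd * _GH_X)))


def base_logit_for_prevalence(
    prevalence: float, loading: float, age_loading: float = 0.0, age_sd_decades: float = 1.43
) -> float:
    """Invert the marginal prevalence for an item's base log-odds.

    The burden factor and the (approximately normal) age term are folded
    into one effective latent sd; the truncation of age makes this an
    approximation, good to a few tenths of a percent over the default
    age range.
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError("prevalence must lie in (0, 1)")
    s = float(np.hypot(loading, age_loading * age_sd_decades))
    lo, hi = logit(prevalence) - 6 * s - 1, logit(prevalence) + 6 * s + 1
    return float(brentq(lambda b: marginal_prevalence(b, s) - prevalence, lo, hi))


def _catalog_from_spec(entries: Sequence[Mapping], age_sd_decades: float) -> tuple[CatalogItem, ...]:
    items = []
    for entry in entries:
        loading = float(entry.get("loading", 0.0))
        age_loading = float(entry.get("age_loading", 0.0))
        if "base_logit" in entry:
            base = float(entry["base_logit"])
        elif "prevalence" in entry:
            base = base_logit_for_prevalence(
                float(entry["prevalence"]), loading, age_loading, age_sd_decades
            )
        else:
            raise ConfigurationError(
                f"catalog entry {entry.get('concept')!r} needs base_logit or prevalence"
            )
        items.append(
            CatalogItem(
                concept=str(entry["concept"]),
                subcategory=str(entry["subcategory"]),
                base_logit=base,
                loading=loading,
                age_loading=age_loading,
            )
        )
    return tuple(items)


def config_from_dict(spec: Mapping, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/dict spec."""
    spec = dict(spec)
    spec.update(overrides)
    age = spec.get("age", {})
    age_mean = float(age.get("mean", 63.5))
    age_sd = float(age.get("sd", 14.3))
    cov = spec.get("covariate_effects", {})
    return SimulationConfig(
        n_patients=int(spec["n_patients"]),
        seed=int(spec["seed"]),
        item_catalog=_catalog_from_spec(spec["catalog"], age_sd / 10.0),
        sex_probs=dict(spec["sex_probs"]),
        race_probs=dict(spec["race_probs"]),
        outcome_main_effects=dict(spec.get("outcome_main_effects", {})),
        planted_interactions=tuple(
            PlantedInteraction(tuple(e["items"]), float(e["gamma"]))
            for e in spec.get("planted_interactions", [])
        ),
        covariate_effects=CovariateEffects(
            age_per_decade=float(cov.get("age_per_decade", 0.0)),
            sex=dict(cov.get("sex", {})),
            race=dict(cov.get("race", {})),
        ),
        target_mortality=float(spec.get("target_mortality", 0.117)),
        age_mean=age_mean,
        age_sd=age_sd,
        age_min=int(age.get("min", 21)),
        age_topcode=int(age.get("topcode", 90)),
    )


def config_from_yaml(path: str | Path, **overrides) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    return config_from_dict(spec, **overrides)


def default_config(n_patients: int = 8893, seed: int = 0, **overrides) -> SimulationConfig:
    """The packaged default cohort configuration (data/default_cohort.yaml)."""
    ref = resources.files("ihtminer").joinpath("data/default_cohort.yaml")
    spec = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return config_from_dict(spec, n_patients=n_patients, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Generated cohort: demographics/outcome table plus 0/1 item matrix.

    ``demographics`` columns: patient_id (index), age, sex, race, died,
    disposition. ``items`` shares the same index with one int8 column
    per catalog item.
    """

    demographics: pd.DataFrame
    items: pd.DataFrame
    seed: int
    config_hash: str

    def __post_init__(self) -> None:
        died = self.demographics["died"]
        if len(died) and not (self.demographics.loc[died == 1, "disposition"] == "Died").all():
            raise ValueError("death must imply disposition 'Died'")

    @property
    def n(self) -> int:
        return len(self.demographics)

    @property
    def death_rate(self) -> float:
        return float(self.demographics["died"].mean()) if self.n else float("nan")

    def to_indicator_matrix(self) -> IndicatorMatrix:
        """Direct view of the cohort as the downstream indicator matrix."""
        demo = self.demographics
        return IndicatorMatrix(
            items=self.items.reindex(columns=sorted(self.items.columns)),
            died=demo["died"].to_numpy(),
            age=demo["age"].to_numpy(),
            sex=demo["sex"].to_numpy(),
            race=demo["race"].to_numpy(),
        )

    def write_csvs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "demographics": out / "demographics.csv",
            "items": out / "item_matrix.csv",
        }
        self.demographics.to_csv(paths["demographics"], index_label="patient_id")
        self.items.to_csv(paths["items"], index_label="patient_id")
        return paths


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _draw_covariates(config: SimulationConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_topcode - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    age = np.clip(np.rint(age), config.age_min, config.age_topcode).astype(int)
    sex_levels = sorted(config.sex_probs)
    race_levels = sorted(config.race_probs)
    sex = rng.choice(sex_levels, size=n, p=[config.sex_probs[k] for k in sex_levels])
    race = rng.choice(race_levels, size=n, p=[config.race_probs[k] for k in race_levels])
    return pd.DataFrame({"age": age, "sex": sex, "race": race})


def _draw_items(
    config: SimulationConfig, covariates: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(covariates)
    burden = rng.standard_normal(n)
    decades = (covariates["age"].to_numpy() - config.age_mean) / 10.0
    cols = {}
    for it in config.item_catalog:
        p = expit(it.base_logit + it.loading * burden + it.age_loading * decades)
        cols[it.name] = (rng.random(n) < p).astype(np.int8)
    return pd.DataFrame(cols, index=covariates.index)


def _death_linear_predictor(
    config: SimulationConfig, items: pd.DataFrame, covariates: pd.DataFrame
) -> np.ndarray:
    """Death log-odds without the intercept."""
    eta = np.zeros(len(items))
    for name, beta in config.outcome_main_effects.items():
        eta += beta * items[name].to_numpy()
    for inter in config.planted_interactions:
        carrier = np.ones(len(items), dtype=bool)
        for name in inter.items:
            carrier &= items[name].to_numpy(dtype=bool)
        eta += inter.gamma * carrier
    eff = config.covariate_effects
    eta += eff.age_per_decade * (covariates["age"].to_numpy() - config.age_mean) / 10.0
    sex = covariates["sex"].to_numpy()
    for level, delta in eff.sex.items():
        eta += delta * (sex == level)
    race = covariates["race"].to_numpy()
    for level, delta in eff.race.items():
        eta += delta * (race == level)
    return eta


def _probe_sample(
    config: SimulationConfig, n_probe: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = _rng(config.seed, _CALIB_STREAM)
    cov = _draw_covariates(config, n_probe, rng)
    items = _draw_items(config, cov, rng)
    return cov, items


def calibrate_intercept(config: SimulationConfig, n_probe: int = 20_000) -> float:
    """Intercept beta_0 hitting the target mortality on a fixed probe sample.

    A probe sample of covariates and items is drawn from a dedicated seed
    stream; bisection then solves mean(sigmoid(beta_0 + eta_i)) = target.
    Deterministic given the config seed.
    """
    if not 0.001 < config.target_mortality < 0.999:
        raise ConfigurationError("target_mortality must lie in (0.001, 0.999)")
    if n_probe < 10_000:
        raise ConfigurationError("n_probe must be at least 10,000")
    if not config.item_catalog:
        raise ConfigurationError("item catalog is empty")
    cov, items = _probe_sample(config, n_probe)
    eta = _death_linear_predictor(config, items, cov)

    def achieved(b0: float) -> float:
        return float(expit(b0 + eta).mean())

    lo, hi = -30.0, 30.0
    f_lo, f_hi = achieved(lo) - config.target_mortality, achieved(hi) - config.target_mortality
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"target {config.target_mortality} outside achievable range "
            f"[{achieved(lo):.4f}, {achieved(hi):.4f}]"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if achieved(mid) < config.target_mortality:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    rate = achieved(b0)
    if abs(rate - config.target_mortality) > 0.002:
        raise CalibrationError(
            f"bisection did not converge: achieved rate {rate:.4f} "
            f"vs target {config.target_mortality:.4f}"
        )
    return b0


def model_implied_carrier_mortality(
    config: SimulationConfig,
    items_of_interest: Iterable[str],
    n_probe: int = 100_000,
    intercept: float | None = None,
) -> tuple[float, int]:
    """Average model death probability among probe carriers of an item set.

    Returns ``(mean probability, probe carrier count)``; this is the
    quantity the empirical confidence of a planted rule estimates.
    """
    if intercept is None:
        intercept = calibrate_intercept(config)
    rng = _rng(config.seed, _CALIB_STREAM + 1)
    cov = _draw_covariates(config, n_probe, rng)
    items = _draw_items(config, cov, rng)
    carrier = np.ones(n_probe, dtype=bool)
    for name in items_of_interest:
        carrier &= items[name].to_numpy(dtype=bool)
    if not carrier.any():
        raise CalibrationError("no probe carriers of the requested item set")
    p = expit(intercept + _death_linear_predictor(config, items, cov))
    return float(p[carrier].mean()), int(carrier.sum())


def solve_interaction_gamma(
    config: SimulationConfig,
    items_of_interest: tuple[str, ...],
    target_carrier_mortality: float,
    n_probe: int = 100_000,
    tol: float = 0.002,
) -> float:
    """Gamma for one planted interaction hitting a target carrier mortality.

    Each candidate gamma re-calibrates the intercept (the interaction
    shifts overall mortality too), so the returned value is consistent
    with the config's mortality target. Used to freeze catalog defaults.
    """

    def carrier_rate(gamma: float) -> float:
        inters = tuple(
            PlantedInteraction(i.items, gamma) if set(i.items) == set(items_of_interest) else i
            for i in config.planted_interactions
        )
        if not any(set(i.items) == set(items_of_interest) for i in inters):
            inters = inters + (PlantedInteraction(tuple(items_of_interest), gamma),)
        cfg = replace(config, planted_interactions=inters)
        rate, _ = model_implied_carrier_mortality(cfg, items_of_interest, n_probe)
        return rate

    lo, hi = -5.0, 8.0
    if not carrier_rate(lo) < target_carrier_mortality < carrier_rate(hi):
        raise CalibrationError("target carrier mortality outside achievable gamma range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if carrier_rate(mid) < target_carrier_mortality:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    gamma = 0.5 * (lo + hi)
    if abs(carrier_rate(gamma) - target_carrier_mortality) > max(tol, 0.01):
        raise CalibrationError("gamma bisection did not reach the target carrier mortality")
    return gamma


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort; bit-reproducible under identical config+seed."""
    if not config.item_catalog:
        raise ConfigurationError("item catalog is empty")
    n = config.n_patients
    ids = pd.Index([f"P{i:07d}" for i in range(n)], name="patient_id")
    if n == 0:
        demo = pd.DataFrame(
            columns=["age", "sex", "race", "died", "disposition"], index=ids
        )
        items = pd.DataFrame(columns=config.item_names, index=ids, dtype=np.int8)
        return SyntheticCohort(demo, items, config.seed, config.config_hash())

    intercept = calibrate_intercept(config)
    rng = _rng(config.seed, _COHORT_STREAM)
    cov = _draw_covariates(config, n, rng)
    cov.index = ids
    items = _draw_items(config, cov, rng)
    p_death = expit(intercept + _death_linear_predictor(config, items, cov))
    died = (rng.random(n) < p_death).astype(np.int8)

    survivor_levels = [k for k in DISPOSITION_PROBS if k != "Died"]
    mass = sum(DISPOSITION_PROBS[k] for k in survivor_levels)
    survivor_p = [DISPOSITION_PROBS[k] / mass for k in survivor_levels]
    disposition = np.where(
        died == 1, "Died", rng.choice(survivor_levels, size=n, p=survivor_p)
    )

    demo = cov.copy()
    demo["died"] = died
    demo["disposition"] = disposition
    logger.info(
        "generated cohort n=%d death_rate=%.4f intercept=%.4f config=%s seed=%d",
        n, float(died.mean()), intercept, config.config_hash(), config.seed,
    )
    return SyntheticCohort(demo, items, config.seed, config.config_hash())


# ---------------------------------------------------------------------------
# round-trip plumbing: cohort -> long-format records -> indicators
# ---------------------------------------------------------------------------


class UnmappedConceptError(ValueError):
    """A catalog item has no code in the mapping table."""

    def __init__(self, missing: Sequence[tuple[str, str]]):
        self.missing = list(missing)
        super().__init__(
            f"{len(self.missing)} catalog item(s) without a mapping code: "
            f"{self.missing[:10]}"
        )


def build_default_mapping(catalog: Sequence[CatalogItem]) -> MappingTable:
    """One synthetic ICD-10-style code per catalog item (bijective).

    Codes are synthetic placeholders (``SY<nn>.<n>``), not real ICD
    codes; bijectivity guarantees exact record round trips.
    """
    rows = []
    for idx, it in enumerate(catalog):
        code = f"SY{idx // 10:02d}.{idx % 10}"
        rows.append((code, "icd10", it.concept, it.subcategory, 1))
    frame = pd.DataFrame(
        rows, columns=["code", "code_system", "concept", "subcategory", "precedence"]
    )
    return MappingTable(frame)


# Deterministic provenance assignment by subcategory: admission-phase
# categories come from the referring encounter, the rest from receiving;
# billing-style categories are administrative.
_SOURCE_BY_SUBCAT = {
    "pdx": "clinical", "pl": "clinical", "cm": "clinical",
    "hx": "clinical", "dx": "administrative", "ddx": "administrative",
}
_PHASE_BY_SUBCAT = {
    "pdx": "referring", "hx": "referring", "pl": "receiving",
    "cm": "receiving", "dx": "receiving", "ddx": "receiving",
}


def cohort_to_records(
    cohort: SyntheticCohort, mapping: MappingTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit long-format diagnosis records plus the demographics table.

    Every present item becomes one record whose code maps back to that
    item; passing the output through ``map_records`` and
    ``build_indicators`` reproduces the cohort's item matrix exactly
    when the mapping is bijective (as ``build_default_mapping``'s is).
    Patients with zero items emit no records but stay in demographics.
    """
    lookup: dict[str, tuple[str, str]] = {}
    for row in mapping.frame.itertuples(index=False):
        name = item_name(row.subcategory, row.concept)
        lookup.setdefault(name, (row.code, row.code_system))
    missing = [name for name in cohort.items.columns if name not in lookup]
    if missing:
        for name in missing:
            logger.error("no mapping code for catalog item %s", name)
        raise UnmappedConceptError(
            [tuple(name.split("_", 1)) for name in missing]  # (subcategory, concept)
        )

    records = []
    mat = cohort.items.to_numpy(dtype=bool)
    cols = list(cohort.items.columns)
    for j, name in enumerate(cols):
        code, system = lookup[name]
        subcat = name.split("_", 1)[0]
        source = _SOURCE_BY_SUBCAT[subcat]
        phase = _PHASE_BY_SUBCAT[subcat]
        for pid in cohort.items.index[mat[:, j]]:
            records.append((pid, code, system, source, phase))
    records_df = pd.DataFrame(
        records, columns=["patient_id", "code", "code_system", "source", "phase"]
    ).sort_values(["patient_id", "code"], kind="stable").reset_index(drop=True)

    demographics = cohort.demographics.reset_index()[
        ["patient_id", "age", "sex", "race", "died", "disposition"]
    ]
    return records_df, demographics


def roundtrip_indicators(
    cohort: SyntheticCohort, mapping: MappingTable | None = None
) -> IndicatorMatrix:
    """Cohort -> records -> mapped items -> indicator matrix, end to end."""
    if mapping is None:
        names = list(cohort.items.columns)
        pseudo = [
            CatalogItem(concept=n.split("_", 1)[1], subcategory=n.split("_", 1)[0], base_logit=0.0)
            for n in names
        ]
        mapping = build_default_mapping(pseudo)
    records, demographics = cohort_to_records(cohort, mapping)
    item_sets, _ = map_records(records, mapping)
    return build_indicators(item_sets, demographics)
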