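"""Typed, validated inputs for the IPF anti-fibrotic cost-effectiveness model.

The model compares treatment strategies for idiopathic pulmonary fibrosis
(IPF) — symptom management alone versus the anti-fibrotic drugs pirfenidone
and nintedanib — on a quarterly-cycle Markov cohort whose health states are
percent-predicted forced vital capacity (FVC) bands.  Everything the model
consumes is data: six living FVC bands plus death (each with a utility and a
per-cycle decline probability), one record per treatment strategy (annual
drug cost plus odds-ratio modifiers for decline, mortality and
exacerbation), and a block of global quantities (cycle length, discount
rate, exacerbation risk, costs, disutilities).  The packaged
``base_case.yaml`` encodes the published 2020-USD US base case; any
alternative scenario is just another config file.

All monetary amounts are 2020 US dollars; utilities are on the usual 0
(death) to 1 (perfect health) scale; probabilities are per 3-month cycle
unless a field name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .baseline_survival import BaselineHazard

__all__ = [
    "BAND_LABELS",
    "DEATH_LABEL",
    "ConfigError",
    "Uncertain",
    "HealthState",
    "StrategyParams",
    "GlobalParams",
    "ModelInputs",
    "CycleCosts",
    "or_to_probability",
    "per_cycle_amounts",
    "load_config",
    "save_config",
    "default_config",
]

#: Living FVC bands, best lung function first.  Decline moves one band to the
#: right; decline out of the last band is death ("below 40% predicted FVC").
BAND_LABELS: tuple[str, ...] = (
    "90-110",
    "80-89.9",
    "70-79.9",
    "60-69.9",
    "50-59.9",
    "40-49.9",
)
DEATH_LABEL = "death"
STATE_LABELS: tuple[str, ...] = BAND_LABELS + (DEATH_LABEL,)


class ConfigError(ValueError):
    """A model input violates its declared range or structure."""


def _check(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {message}")


@dataclass(frozen=True)
class Uncertain:
    """A natural-scale (mean, sd) pair as printed in the source tables."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        _check(math.isfinite(self.mean), "mean", "must be finite")
        _check(math.isfinite(self.sd) and self.sd >= 0.0, "sd", "must be finite and >= 0")


def _as_uncertain(value, field_name: str) -> Uncertain:
    if isinstance(value, Uncertain):
        return value
    if isinstance(value, Mapping):
        try:
            return Uncertain(float(value["mean"]), float(value.get("sd", 0.0)))
        except KeyError as exc:
            raise ConfigError(f"{field_name}: missing sub-field {exc}") from None
    if isinstance(value, (int, float)):
        return Uncertain(float(value), 0.0)
    raise ConfigError(f"{field_name}: expected number or {{mean, sd}} mapping")


@dataclass(frozen=True)
class HealthState:
    """One %FVC band (or death) with its utility moments and decline risk.

    ``decline_prob`` is the probability, per 3-month cycle, that an
    untreated individual in this band drops to the next-worse band (or to
    death from the worst living band).
    """

    label: str
    fvc_low: float
    fvc_high: float
    utility_mean: float
    utility_sd: float
    decline_prob: float

    def __post_init__(self) -> None:
        _check(self.label in STATE_LABELS, "label", f"unknown state label {self.label!r}")
        _check(0.0 <= self.utility_mean <= 1.0, "utility_mean", "must lie in [0, 1]")
        _check(self.utility_sd >= 0.0, "utility_sd", "must be >= 0")
        _check(0.0 <= self.decline_prob <= 1.0, "decline_prob", "must lie in [0, 1]")
        _check(self.fvc_high >= self.fvc_low, "fvc_high", "band upper bound below lower bound")
        if self.label == DEATH_LABEL:
            _check(self.utility_mean == 0.0, "utility_mean", "death has utility 0")
            _check(self.decline_prob == 0.0, "decline_prob", "death cannot decline")

    @property
    def is_death(self) -> bool:
        return self.label == DEATH_LABEL


@dataclass(frozen=True)
class StrategyParams:
    """A treatment arm: annual drug cost and odds-ratio effect modifiers.

    Odds ratios multiply the baseline odds of lung-function decline, death
    and acute exacerbation each cycle (OR < 1 is protective).  Symptom
    management is simply the arm with all ORs equal to 1 and zero drug cost.
    """

    name: str
    annual_drug_cost: float
    or_decline: Uncertain = Uncertain(1.0)
    or_mortality: Uncertain = Uncertain(1.0)
    or_exacerbation: Uncertain = Uncertain(1.0)

    def __post_init__(self) -> None:
        _check(bool(self.name), "name", "must be non-empty")
        _check(
            math.isfinite(self.annual_drug_cost) and self.annual_drug_cost >= 0.0,
            "annual_drug_cost",
            "must be finite and >= 0",
        )
        for fname in ("or_decline", "or_mortality", "or_exacerbation"):
            object.__setattr__(self, fname, _as_uncertain(getattr(self, fname), fname))
            _check(getattr(self, fname).mean > 0.0, fname, "odds ratio must be > 0")

    @property
    def is_reference(self) -> bool:
        """True for a no-treatment arm (all ORs 1, no drug cost)."""
        return (
            self.annual_drug_cost == 0.0
            and self.or_decline.mean == 1.0
            and self.or_mortality.mean == 1.0
            and self.or_exacerbation.mean == 1.0
        )


@dataclass(frozen=True)
class GlobalParams:
    """Strategy-independent model quantities.

    Units: ``cycle_years`` in years (0.25 = quarterly cycles);
    ``discount_rate`` per year; ``wtp`` in USD per QALY; probabilities per
    cycle; costs in 2020 USD (annual costs are split evenly over the year's
    cycles); disutilities in utility units subtracted during exacerbation
    cycles.
    """

    cycle_years: float = 0.25
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    exacerbation_prob: float = 0.0197
    post_ae_mortality_multiplier: Uncertain = Uncertain(1.40, 0.20)
    ae_episode_cost: Uncertain = Uncertain(14_731.0, 4_026.0)
    annual_followup_cost: Uncertain = Uncertain(12_291.0, 710.0)
    disutility_first_cycle: Uncertain = Uncertain(0.140, 0.047)
    disutility_subsequent: Uncertain = Uncertain(0.078, 0.032)
    horizon_years: float | None = None
    psa_n: int = 10_000
    seed: int = 12345
    start_band: str = "80-89.9"

    def __post_init__(self) -> None:
        _check(self.cycle_years > 0.0, "cycle_years", "must be > 0")
        _check(0.0 <= self.discount_rate < 1.0, "discount_rate", "must lie in [0, 1)")
        _check(self.wtp >= 0.0, "wtp", "must be >= 0")
        _check(0.0 <= self.exacerbation_prob <= 1.0, "exacerbation_prob", "must lie in [0, 1]")
        for fname in (
            "post_ae_mortality_multiplier",
            "ae_episode_cost",
            "annual_followup_cost",
            "disutility_first_cycle",
            "disutility_subsequent",
        ):
            object.__setattr__(self, fname, _as_uncertain(getattr(self, fname), fname))
        _check(
            self.post_ae_mortality_multiplier.mean > 0.0,
            "post_ae_mortality_multiplier",
            "must be > 0",
        )
        _check(self.ae_episode_cost.mean >= 0.0, "ae_episode_cost", "must be >= 0")
        _check(self.annual_followup_cost.mean >= 0.0, "annual_followup_cost", "must be >= 0")
        for fname in ("disutility_first_cycle", "disutility_subsequent"):
            _check(0.0 <= getattr(self, fname).mean <= 1.0, fname, "must lie in [0, 1]")
        if self.horizon_years is not None:
            _check(self.horizon_years > 0.0, "horizon_years", "must be > 0 or null")
        _check(self.psa_n >= 1, "psa_n", "must be >= 1")
        _check(self.start_band in BAND_LABELS, "start_band", f"unknown band {self.start_band!r}")


@dataclass(frozen=True)
class ModelInputs:
    """A complete, validated parameter set for one model run."""

    states: tuple[HealthState, ...]
    strategies: tuple[StrategyParams, ...]
    globals: GlobalParams
    hazard: BaselineHazard | None = None
    followup_components: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "strategies", tuple(self.strategies))
        labels = tuple(s.label for s in self.states)
        _check(
            labels == STATE_LABELS,
            "states",
            f"expected the seven states {STATE_LABELS} in order, got {labels}",
        )
        fvc_highs = [s.fvc_high for s in self.states[:-1]]
        _check(
            all(a > b for a, b in zip(fvc_highs, fvc_highs[1:])),
            "states",
            "living bands must be ordered by strictly decreasing FVC",
        )
        _check(len(self.strategies) >= 1, "strategies", "need at least one strategy")
        names = [s.name for s in self.strategies]
        _check(len(set(names)) == len(names), "strategies", "duplicate strategy names")

    # -- convenience views used throughout the engine ---------------------

    @property
    def living_states(self) -> tuple[HealthState, ...]:
        return self.states[:-1]

    def utilities(self) -> np.ndarray:
        return np.array([s.utility_mean for s in self.living_states])

    def decline_probs(self) -> np.ndarray:
        return np.array([s.decline_prob for s in self.living_states])

    def start_band_index(self) -> int:
        return BAND_LABELS.index(self.globals.start_band)

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def reference_strategy(self) -> StrategyParams:
        """The no-treatment arm (all ORs 1, zero drug cost)."""
        for s in self.strategies:
            if s.is_reference:
                return s
        raise ConfigError("strategies: no reference arm (all ORs 1, drug cost 0) found")


# ---------------------------------------------------------------------------
# Operations


def or_to_probability(p_base: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a baseline probability on the odds scale.

    Returns ``OR*o / (1 + OR*o)`` with ``o = p/(1-p)``.  The identity
    ``or_to_probability(p, 1) == p`` holds for every p, and the map is
    strictly increasing in both arguments on the open domain.
    """
    if not (math.isfinite(p_base) and 0.0 <= p_base <= 1.0):
        raise ConfigError(f"p_base: must lie in [0, 1], got {p_base}")
    if not (math.isfinite(odds_ratio) and odds_ratio > 0.0):
        raise ConfigError(f"odds_ratio: must be finite and > 0, got {odds_ratio}")
    if p_base == 1.0:
        return 1.0
    odds = odds_ratio * p_base / (1.0 - p_base)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class CycleCosts:
    """Per-cycle cost bundle: recurring amounts plus the per-event AE cost."""

    drug: float
    followup: float
    ae_episode: float

    @property
    def recurring(self) -> float:
        return self.drug + self.followup


def per_cycle_amounts(g: GlobalParams, s: StrategyParams) -> CycleCosts:
    """Allocate annual costs evenly to cycles; AE cost stays per-event."""
    return CycleCosts(
        drug=s.annual_drug_cost * g.cycle_years,
        followup=g.annual_followup_cost.mean * g.cycle_years,
        ae_episode=g.ae_episode_cost.mean,
    )


# ---------------------------------------------------------------------------
# Config I/O (YAML)


def _state_from_dict(d: Mapping, idx: int) -> HealthState:
    try:
        return HealthState(
            label=str(d["label"]),
            fvc_low=float(d["fvc_low"]),
            fvc_high=float(d["fvc_high"]),
            utility_mean=float(d["utility_mean"]),
            utility_sd=float(d.get("utility_sd", 0.0)),
            decline_prob=float(d["decline_prob"]),
        )
    except KeyError as exc:
        raise ConfigError(f"states[{idx}]: missing field {exc}") from None


def _strategy_from_dict(d: Mapping, idx: int) -> StrategyParams:
    try:
        return StrategyParams(
            name=str(d["name"]),
            annual_drug_cost=float(d["annual_drug_cost"]),
            or_decline=_as_uncertain(d.get("or_decline", 1.0), "or_decline"),
            or_mortality=_as_uncertain(d.get("or_mortality", 1.0), "or_mortality"),
            or_exacerbation=_as_uncertain(d.get("or_exacerbation", 1.0), "or_exacerbation"),
        )
    except KeyError as exc:
        raise ConfigError(f"strategies[{idx}]: missing field {exc}") from None


_GLOBAL_UNCERTAIN_FIELDS = (
    "post_ae_mortality_multiplier",
    "ae_episode_cost",
    "annual_followup_cost",
    "disutility_first_cycle",
    "disutility_subsequent",
)


def inputs_from_dict(doc: Mapping) -> ModelInputs:
    """Build validated :class:`ModelInputs` from a parsed config mapping."""
    for section in ("global", "states", "strategies"):
        if section not in doc:
            raise ConfigError(f"{section}: missing config section")
    gdoc = dict(doc["global"])
    for fname in _GLOBAL_UNCERTAIN_FIELDS:
        if fname in gdoc:
            gdoc[fname] = _as_uncertain(gdoc[fname], fname)
    try:
        g = GlobalParams(**gdoc)
    except TypeError as exc:
        raise ConfigError(f"global: {exc}") from None
    states = tuple(_state_from_dict(d, i) for i, d in enumerate(doc["states"]))
    strategies = tuple(_strategy_from_dict(d, i) for i, d in enumerate(doc["strategies"]))
    hazard = None
    if doc.get("baseline_hazard") is not None:
        hazard = BaselineHazard.from_dict(doc["baseline_hazard"])
    followup = doc.get("followup_components")
    if followup is not None:
        followup = {str(k): float(v) for k, v in followup.items()}
    return ModelInputs(
        states=states,
        strategies=strategies,
        globals=g,
        hazard=hazard,
        followup_components=followup,
    )


def inputs_to_dict(inputs: ModelInputs) -> dict:
    """Inverse of :func:`inputs_from_dict`; load -> save -> load is identity."""

    def unc(u: Uncertain) -> dict:
        return {"mean": u.mean, "sd": u.sd}

    g = inputs.globals
    doc: dict = {
        "global": {
            "cycle_years": g.cycle_years,
            "discount_rate": g.discount_rate,
            "wtp": g.wtp,
            "exacerbation_prob": g.exacerbation_prob,
            "post_ae_mortality_multiplier": unc(g.post_ae_mortality_multiplier),
            "ae_episode_cost": unc(g.ae_episode_cost),
            "annual_followup_cost": unc(g.annual_followup_cost),
            "disutility_first_cycle": unc(g.disutility_first_cycle),
            "disutility_subsequent": unc(g.disutility_subsequent),
            "horizon_years": g.horizon_years,
            "psa_n": g.psa_n,
            "seed": g.seed,
            "start_band": g.start_band,
        },
        "states": [
            {
                "label": s.label,
                "fvc_low": s.fvc_low,
                "fvc_high": s.fvc_high,
                "utility_mean": s.utility_mean,
                "utility_sd": s.utility_sd,
                "decline_prob": s.decline_prob,
            }
            for s in inputs.states
        ],
        "strategies": [
            {
                "name": s.name,
                "annual_drug_cost": s.annual_drug_cost,
                "or_decline": unc(s.or_decline),
                "or_mortality": unc(s.or_mortality),
                "or_exacerbation": unc(s.or_exacerbation),
            }
            for s in inputs.strategies
        ],
    }
    if inputs.hazard is not None:
        doc["baseline_hazard"] = inputs.hazard.to_dict()
    if inputs.followup_components is not None:
        doc["followup_components"] = dict(inputs.followup_components)
    return doc


def load_config(path: str | Path) -> ModelInputs:
    """Load and validate a YAML (or JSON) model config."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config: {path} did not parse to a mapping")
    return inputs_from_dict(doc)


def save_config(inputs: ModelInputs, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(inputs_to_dict(inputs), fh, sort_keys=False)


def default_config() -> ModelInputs:
    """The packaged base case (2020 US data, calibrated baseline hazard)."""
    ref = resources.files("ipfcea").joinpath("data/base_case.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return inputs_from_dict(doc)
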