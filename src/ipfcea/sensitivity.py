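"""Uncertainty analyses: probabilistic sensitivity analysis and thresholds.

The probabilistic sensitivity analysis (PSA) redraws every uncertain input
from a moment-matched distribution — beta for quantities on [0, 1]
(utilities, disutilities), lognormal for positive quantities (odds ratios,
costs, the post-exacerbation mortality multiplier) — re-runs all strategies
with each joint draw, and summarizes the (cost, QALY) clouds as a
cost-effectiveness acceptability curve (CEAC: the fraction of draws in
which each strategy maximizes net monetary benefit at a given
willingness-to-pay) and frontier (CEAF: the strategy with maximal expected
NMB).  The one-way threshold search bisects a single parameter (typically
an annual drug price) to the value at which the WTP-chosen strategy
switches.

The baseline hazard is held fixed in the PSA: no uncertainty distribution
is available for it, and it is itself a calibrated synthetic quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cea
from .engine import lifetime_outcomes
from .parameters import ConfigError, ModelInputs, Uncertain

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "ThresholdResult",
    "moment_match",
    "sample_distribution",
    "table1_distributions",
    "apply_values",
    "run_psa",
    "ceac_ceaf",
    "threshold_search",
]

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampled model input: target path, family, natural-scale moments.

    Target paths: ``utility:<band>``, ``decline:<band>``,
    ``or_decline:<strategy>``, ``or_mortality:<strategy>``,
    ``or_exacerbation:<strategy>``, ``annual_drug_cost:<strategy>``, or a
    bare :class:`GlobalParams` field name such as ``ae_episode_cost``.
    """

    target: str
    family: str  # "beta" | "lognormal"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "lognormal"):
            raise ConfigError(f"{self.target}: unknown family {self.family!r}")
        if self.sd < 0.0:
            raise ConfigError(f"{self.target}: sd must be >= 0")
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ConfigError(f"{self.target}: beta mean must lie in [0, 1]")
        if self.family == "lognormal" and self.mean <= 0.0:
            raise ConfigError(f"{self.target}: lognormal mean must be > 0")


def moment_match(dist: ParameterDistribution) -> tuple[float, float] | None:
    """Native parameters reproducing the natural-scale (mean, sd).

    beta: (alpha, beta); lognormal: (mu, sigma) of log(X).  Returns None for
    a (near-)zero sd, which is treated as a point mass.
    """
    m, s = dist.mean, dist.sd
    if s <= _SD_FLOOR:
        return None
    if dist.family == "beta":
        if not (0.0 < m < 1.0):
            raise ConfigError(f"{dist.target}: beta mean must be strictly inside (0, 1)")
        if s * s >= m * (1.0 - m):
            raise ConfigError(
                f"{dist.target}: infeasible beta moments (sd^2 >= mean(1-mean))"
            )
        alpha = m * (m * (1.0 - m) / (s * s) - 1.0)
        beta = alpha * (1.0 - m) / m
        return (alpha, beta)
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return (mu, math.sqrt(sigma2))


def sample_distribution(
    dist: ParameterDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw from the moment-matched distribution (point mass if sd ~ 0)."""
    params = moment_match(dist)
    if params is None:
        return dist.mean if size is None else np.full(size, dist.mean)
    if dist.family == "beta":
        return rng.beta(*params, size=size)
    mu, sigma = params
    return rng.lognormal(mu, sigma, size=size)


def table1_distributions(inputs: ModelInputs) -> list[ParameterDistribution]:
    """The base-case uncertain inputs: utilities and disutilities (beta);
    ORs, costs and the post-AE mortality multiplier (lognormal).

    Inputs whose printed sd is zero (drug prices, the per-band decline
    probabilities, the baseline exacerbation probability) stay fixed.
    """
    g = inputs.globals
    ds: list[ParameterDistribution] = []
    for st in inputs.living_states:
        if st.utility_sd > 0.0:
            ds.append(ParameterDistribution(f"utility:{st.label}", "beta", st.utility_mean, st.utility_sd))
    for fname in ("disutility_first_cycle", "disutility_subsequent"):
        u: Uncertain = getattr(g, fname)
        if u.sd > 0.0:
            ds.append(ParameterDistribution(fname, "beta", u.mean, u.sd))
    for fname in ("post_ae_mortality_multiplier", "ae_episode_cost", "annual_followup_cost"):
        u = getattr(g, fname)
        if u.sd > 0.0:
            ds.append(ParameterDistribution(fname, "lognormal", u.mean, u.sd))
    for s in inputs.strategies:
        for fname in ("or_decline", "or_mortality", "or_exacerbation"):
            u = getattr(s, fname)
            if u.sd > 0.0:
                ds.append(ParameterDistribution(f"{fname}:{s.name}", "lognormal", u.mean, u.sd))
    return ds


_GLOBAL_UNCERTAIN = {
    "post_ae_mortality_multiplier",
    "ae_episode_cost",
    "annual_followup_cost",
    "disutility_first_cycle",
    "disutility_subsequent",
}
_GLOBAL_SCALAR = {"exacerbation_prob", "discount_rate", "wtp", "cycle_years"}
_STRATEGY_UNCERTAIN = {"or_decline", "or_mortality", "or_exacerbation"}


def apply_values(inputs: ModelInputs, values: Mapping[str, float]) -> ModelInputs:
    """Return a copy of ``inputs`` with the targeted values replaced.

    Only distribution *means* are moved (the sd describes sampling
    uncertainty, not the realized value).  Raises :class:`ConfigError` if a
    replaced value violates validation.
    """
    states = list(inputs.states)
    strategies = list(inputs.strategies)
    g = inputs.globals
    g_updates: dict[str, object] = {}
    for target, value in values.items():
        if ":" in target:
            kind, _, name = target.partition(":")
            if kind in ("utility", "decline"):
                idx = next(
                    (i for i, s in enumerate(states) if s.label == name), None
                )
                if idx is None:
                    raise ConfigError(f"{target}: unknown state label {name!r}")
                fld = "utility_mean" if kind == "utility" else "decline_prob"
                states[idx] = replace(states[idx], **{fld: float(value)})
            elif kind in _STRATEGY_UNCERTAIN or kind == "annual_drug_cost":
                idx = next(
                    (i for i, s in enumerate(strategies) if s.name == name), None
                )
                if idx is None:
                    raise ConfigError(f"{target}: unknown strategy {name!r}")
                if kind == "annual_drug_cost":
                    strategies[idx] = replace(strategies[idx], annual_drug_cost=float(value))
                else:
                    old: Uncertain = getattr(strategies[idx], kind)
                    strategies[idx] = replace(
                        strategies[idx], **{kind: Uncertain(float(value), old.sd)}
                    )
            else:
                raise ConfigError(f"unknown parameter path {target!r}")
        elif target in _GLOBAL_UNCERTAIN:
            old = getattr(g, target)
            g_updates[target] = Uncertain(float(value), old.sd)
        elif target in _GLOBAL_SCALAR:
            g_updates[target] = float(value)
        else:
            raise ConfigError(f"unknown parameter path {target!r}")
    if g_updates:
        g = replace(g, **g_updates)
    return replace(inputs, states=tuple(states), strategies=tuple(strategies), globals=g)


@dataclass(frozen=True)
class PSAResult:
    """Sampled (cost, QALY) pairs per strategy plus derived curves."""

    names: tuple[str, ...]
    costs: np.ndarray  # (n, n_strategies)
    qalys: np.ndarray  # (n, n_strategies)
    n: int
    seed: int | None
    n_rejected: int = 0
    wtp_grid: np.ndarray | None = None
    ceac: pd.DataFrame | None = None
    ceaf: pd.Series | None = None

    def samples_frame(self) -> pd.DataFrame:
        frames = []
        for j, name in enumerate(self.names):
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(self.n),
                        "strategy": name,
                        "cost": self.costs[:, j],
                        "qalys": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def with_curves(self, wtp_grid: Sequence[float]) -> "PSAResult":
        ceac, ceaf = ceac_ceaf(self, wtp_grid)
        return replace(self, wtp_grid=np.asarray(wtp_grid, dtype=float), ceac=ceac, ceaf=ceaf)


def run_psa(
    inputs: ModelInputs,
    n: int | None = None,
    seed: int | None = None,
    distributions: Sequence[ParameterDistribution] | None = None,
    max_reject_fraction: float = 0.10,
) -> PSAResult:
    """Joint parameter resampling with a full model re-run per draw.

    All distributions are sampled independently; each draw is applied to
    every strategy simultaneously (so, e.g., a low utility draw affects all
    arms alike).  Draws whose assembled parameter set fails validation are
    redrawn; more than ``max_reject_fraction`` rejections aborts.
    """
    g = inputs.globals
    if n is None:
        n = g.psa_n
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = g.seed
    if distributions is None:
        distributions = table1_distributions(inputs)
    rng = np.random.default_rng(seed)
    names = tuple(s.name for s in inputs.strategies)
    costs = np.empty((n, len(names)))
    qalys = np.empty((n, len(names)))
    n_rejected = 0
    for i in range(n):
        for _attempt in range(100):
            values = {d.target: float(sample_distribution(d, rng)) for d in distributions}
            try:
                draw_inputs = apply_values(inputs, values)
            except ConfigError:
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a valid parameter set in 100 attempts")
        for j, s in enumerate(draw_inputs.strategies):
            out = lifetime_outcomes(s, draw_inputs)
            costs[i, j] = out.cost
            qalys[i, j] = out.qalys
    if n_rejected > max_reject_fraction * n:
        raise RuntimeError(
            f"{n_rejected} rejected draws out of {n}: distribution misspecification?"
        )
    if n_rejected:
        logger.info("PSA: %d draws rejected and redrawn", n_rejected)
    return PSAResult(names=names, costs=costs, qalys=qalys, n=n, seed=seed, n_rejected=n_rejected)


def default_wtp_grid(wtp_max: float = 5_000_000.0, step: float = 50_000.0) -> np.ndarray:
    return np.arange(0.0, wtp_max + step / 2, step)


def ceac_ceaf(
    result: PSAResult, wtp_grid: Sequence[float]
) -> tuple[pd.DataFrame, pd.Series]:
    """Acceptability curve and frontier over a WTP grid.

    CEAC(s, w): fraction of draws in which s attains the maximal NMB at w,
    ties split equally, so rows sum to 1.  CEAF(w): the strategy with the
    highest *mean* NMB at w (first-listed strategy on an exact tie).
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wtp_grid must be a non-empty 1-D sequence")
    # nmb: (n, S, W)
    nmb = result.qalys[:, :, None] * grid[None, None, :] - result.costs[:, :, None]
    best = nmb.max(axis=1, keepdims=True)
    is_best = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
    shares = is_best / is_best.sum(axis=1, keepdims=True)
    ceac = pd.DataFrame(shares.mean(axis=0).T, index=grid, columns=list(result.names))
    ceac.index.name = "wtp"
    mean_nmb = nmb.mean(axis=0)  # (S, W)
    ceaf = pd.Series(
        [result.names[j] for j in mean_nmb.argmax(axis=0)], index=grid, name="ceaf"
    )
    ceaf.index.name = "wtp"
    return ceac, ceaf


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    wtp: float
    bracket: tuple[float, float]
    value: float | None  # None: no switch inside the bracket
    strategy_below: str
    strategy_above: str

    @property
    def found(self) -> bool:
        return self.value is not None


def _chosen_strategy(inputs: ModelInputs, wtp: float) -> str:
    outcomes = [lifetime_outcomes(s, inputs) for s in inputs.strategies]
    table = cea.wtp_verdict(cea.dominance_frontier(outcomes), wtp)
    assert table.chosen is not None
    return table.chosen


def threshold_search(
    inputs: ModelInputs,
    parameter: str,
    bracket: tuple[float, float],
    wtp: float | None = None,
    rel_tol: float = 1e-4,
    coarse_points: int = 17,
    chooser: Callable[[float], str] | None = None,
) -> ThresholdResult:
    """One-way threshold analysis: bisect a parameter to the strategy switch.

    A coarse scan first verifies the WTP-chosen strategy switches at most
    once over the bracket (the search's precondition); a single switch is
    then bisected to a relative tolerance of ``rel_tol`` on the parameter.
    """
    if wtp is None:
        wtp = inputs.globals.wtp
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    if chooser is None:
        chooser = lambda v: _chosen_strategy(apply_values(inputs, {parameter: v}), wtp)

    grid = np.linspace(lo, hi, max(coarse_points, 3))
    choices = [chooser(v) for v in grid]
    switches = [i for i in range(len(grid) - 1) if choices[i] != choices[i + 1]]
    if len(switches) > 1:
        raise RuntimeError(
            f"{parameter}: chosen strategy switches more than once over "
            f"[{lo}, {hi}] ({choices}); threshold is not unique"
        )
    if not switches:
        return ThresholdResult(parameter, wtp, (lo, hi), None, choices[0], choices[-1])

    a, b = float(grid[switches[0]]), float(grid[switches[0] + 1])
    choice_a, choice_b = choices[switches[0]], choices[switches[0] + 1]
    tol = rel_tol * max(abs(lo), abs(hi), 1.0)
    while b - a > tol:
        mid = 0.5 * (a + b)
        if chooser(mid) == choice_a:
            a = mid
        else:
            b = mid
    return ThresholdResult(
        parameter, wtp, (lo, hi), 0.5 * (a + b), choice_a, choice_b
    )
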