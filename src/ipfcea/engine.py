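"""Quarterly-cycle Markov cohort engine for the IPF model.

State space: six %FVC bands crossed with a binary "any prior acute
exacerbation" tracker flag, plus absorbing death — 13 compartments.  Each
cycle, every living compartment experiences, in order:

1. death, with probability ``or_to_probability(q0, OR_mort * m_AE)`` where
   ``q0`` is the baseline per-cycle death probability from the hazard and
   ``m_AE`` is the post-exacerbation mortality multiplier (1.40) for
   tracker-positive compartments;
2. among survivors, an acute exacerbation with probability
   ``or_to_probability(p_AE, OR_AE)``, which sets the tracker flag
   (a repeat event in a tracker-positive compartment re-incurs the episode
   cost and first-cycle disutility but changes no state);
3. among survivors, one-band lung-function decline with the band's
   OR-adjusted probability; decline out of the worst band is death.

Lung function never improves and death is absorbing.  Costs and QALYs are
accrued with state-at-cycle-start accounting (no half-cycle correction) and
discounted by ``(1 + r)^(-cycle_index * cycle_years)``.

Two independent computational routes are provided: the cohort recursion
(:func:`run_cohort`, with an exact infinite-horizon linear solve as a fast
path for time-invariant hazards) and a per-individual microsimulation
(:func:`microsimulate`) used as a cross-validating oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline_survival import BaselineHazard
from .parameters import (
    BAND_LABELS,
    CycleCosts,
    GlobalParams,
    ModelInputs,
    StrategyParams,
    or_to_probability,
    per_cycle_amounts,
)

__all__ = [
    "N_BANDS",
    "N_COMP",
    "DEATH_IDX",
    "EngineError",
    "CohortState",
    "CycleEvents",
    "CohortTrace",
    "Outcome",
    "MicrosimResult",
    "transition",
    "accumulate_cycle",
    "run_cohort",
    "lifetime_outcomes",
    "microsimulate",
]

N_BANDS = 6
#: Compartments: bands 0..5 with no AE history, 6..11 with AE history, 12 death.
N_COMP = 2 * N_BANDS + 1
DEATH_IDX = N_COMP - 1

COMPARTMENT_LABELS: tuple[str, ...] = (
    tuple(f"{b}|noAE" for b in BAND_LABELS)
    + tuple(f"{b}|AE" for b in BAND_LABELS)
    + ("death",)
)

_EXTINCTION_TOL = 1e-9
_HARD_CAP_YEARS = 200.0


class EngineError(RuntimeError):
    """The cohort recursion produced an invalid state or failed to finish."""


@dataclass(frozen=True)
class CohortState:
    """Occupancy over the 13 compartments at the start of a cycle."""

    occupancy: np.ndarray
    cycle_index: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.shape != (N_COMP,):
            raise EngineError(f"occupancy must have shape ({N_COMP},), got {occ.shape}")
        if np.any(occ < -1e-15):
            raise EngineError("negative occupancy")
        if abs(occ.sum() - 1.0) > 1e-12:
            raise EngineError(f"occupancy sums to {occ.sum()!r}, expected 1")

    @property
    def living(self) -> float:
        return float(self.occupancy[:DEATH_IDX].sum())

    @classmethod
    def initial(cls, inputs: ModelInputs) -> "CohortState":
        occ = np.zeros(N_COMP)
        occ[inputs.start_band_index()] = 1.0
        return cls(occ, 0)


@dataclass(frozen=True)
class CycleEvents:
    """What happened during one cycle, resolved by band at cycle start.

    The three ``*_by_band`` vectors partition the living occupancy at cycle
    start into the disutility classes used for QALY accrual: individuals who
    exacerbate this cycle (first-cycle disutility, episode cost), those with
    prior AE history and no new event (subsequent-cycle disutility, whether
    or not they die this cycle), and everyone else (no disutility).
    """

    new_ae_by_band: np.ndarray
    history_by_band: np.ndarray
    none_by_band: np.ndarray
    deaths: float

    @property
    def new_ae_mass(self) -> float:
        return float(self.new_ae_by_band.sum())


@dataclass(frozen=True)
class _CycleProbs:
    """Per-cycle event probabilities for one strategy (possibly cached)."""

    qd_no: float
    qd_ae: float
    p_ae: float
    p_decline: np.ndarray  # (N_BANDS,) OR-adjusted


def _cycle_probs(
    inputs: ModelInputs,
    strategy: StrategyParams,
    hazard: BaselineHazard,
    cycle_index: int,
) -> _CycleProbs:
    g = inputs.globals
    q0 = hazard.cycle_death_prob(cycle_index, g.cycle_years)
    or_mort = strategy.or_mortality.mean
    m_ae = g.post_ae_mortality_multiplier.mean
    qd_no = or_to_probability(q0, or_mort)
    qd_ae = or_to_probability(q0, or_mort * m_ae)
    p_ae = or_to_probability(g.exacerbation_prob, strategy.or_exacerbation.mean)
    or_dec = strategy.or_decline.mean
    p_decline = np.array(
        [or_to_probability(p, or_dec) for p in inputs.decline_probs()]
    )
    for p in (qd_no, qd_ae, p_ae, *p_decline):
        if not (0.0 <= p <= 1.0):
            raise EngineError(f"computed probability {p} outside [0, 1]")
    return _CycleProbs(qd_no, qd_ae, p_ae, p_decline)


def _resolve_hazard(inputs: ModelInputs, hazard: BaselineHazard | None) -> BaselineHazard:
    h = hazard if hazard is not None else inputs.hazard
    if h is None:
        raise EngineError("no baseline hazard: pass one or calibrate the config first")
    return h


def transition(
    state: CohortState,
    strategy: StrategyParams,
    inputs: ModelInputs,
    hazard: BaselineHazard | None = None,
    _probs: _CycleProbs | None = None,
) -> tuple[CohortState, CycleEvents]:
    """Advance the cohort one cycle; also report the cycle's event masses."""
    pr = _probs if _probs is not None else _cycle_probs(
        inputs, strategy, _resolve_hazard(inputs, hazard), state.cycle_index
    )
    occ = state.occupancy
    no = occ[:N_BANDS]
    ae = occ[N_BANDS : 2 * N_BANDS]
    dead = occ[DEATH_IDX]

    s_no = no * (1.0 - pr.qd_no)
    s_ae = ae * (1.0 - pr.qd_ae)
    hazard_deaths = float(no.sum() * pr.qd_no + ae.sum() * pr.qd_ae)

    # exacerbation among survivors; tracker flag set (or already set)
    new_ae_by_band = pr.p_ae * (s_no + s_ae)
    a_no = s_no * (1.0 - pr.p_ae)
    a_ae = s_ae + s_no * pr.p_ae

    # one-band decline among survivors; out of the worst band -> death
    pd = pr.p_decline
    new_no = a_no * (1.0 - pd)
    new_no[1:] += a_no[:-1] * pd[:-1]
    new_ae = a_ae * (1.0 - pd)
    new_ae[1:] += a_ae[:-1] * pd[:-1]
    decline_deaths = float((a_no[-1] + a_ae[-1]) * pd[-1])

    new_occ = np.concatenate([new_no, new_ae, [dead + hazard_deaths + decline_deaths]])
    events = CycleEvents(
        new_ae_by_band=new_ae_by_band,
        history_by_band=ae - pr.p_ae * s_ae,
        none_by_band=no - pr.p_ae * s_no,
        deaths=hazard_deaths + decline_deaths,
    )
    return CohortState(new_occ, state.cycle_index + 1), events


def discount_factor(g: GlobalParams, cycle_index: int) -> float:
    return (1.0 + g.discount_rate) ** (-(cycle_index * g.cycle_years))


@dataclass(frozen=True)
class CycleAccrual:
    cost: float
    qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    life_years: float


def accumulate_cycle(
    state_before: CohortState,
    events: CycleEvents,
    strategy: StrategyParams,
    inputs: ModelInputs,
    cycle_index: int,
    costs: CycleCosts | None = None,
) -> CycleAccrual:
    """Costs and QALYs accrued during one cycle, discounted to time zero.

    Everyone alive at cycle start accrues the full cycle's recurring cost
    and utility (state-at-cycle-start accounting).  Utility per band is
    reduced by the first-cycle disutility for the newly exacerbating class
    and by the subsequent-cycle disutility for the prior-history class,
    floored at zero.  The AE episode cost is charged once per new event.
    """
    g = inputs.globals
    if costs is None:
        costs = per_cycle_amounts(g, strategy)
    occ = state_before.occupancy
    living = float(occ[:DEATH_IDX].sum())
    raw_cost = costs.recurring * living + costs.ae_episode * events.new_ae_mass

    u = inputs.utilities()
    d1 = g.disutility_first_cycle.mean
    d2 = g.disutility_subsequent.mean
    dt = g.cycle_years
    raw_qalys = dt * float(
        events.none_by_band @ u
        + events.new_ae_by_band @ np.maximum(u - d1, 0.0)
        + events.history_by_band @ np.maximum(u - d2, 0.0)
    )
    disc = discount_factor(g, cycle_index)
    return CycleAccrual(
        cost=disc * raw_cost,
        qalys=disc * raw_qalys,
        undiscounted_cost=raw_cost,
        undiscounted_qalys=raw_qalys,
        life_years=dt * living,
    )


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle record of a cohort run, with lifetime totals."""

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, N_COMP), row k = start of cycle k
    cost: np.ndarray  # (n_cycles,) discounted
    qalys: np.ndarray  # (n_cycles,) discounted
    undiscounted_cost: np.ndarray
    undiscounted_qalys: np.ndarray
    life_years: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.life_years.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        df = pd.DataFrame(self.occupancy[:n], columns=COMPARTMENT_LABELS)
        df.insert(0, "cycle", np.arange(n))
        df["discounted_cost"] = self.cost
        df["discounted_qalys"] = self.qalys
        return df


@dataclass(frozen=True)
class Outcome:
    """Lifetime discounted totals for one strategy."""

    name: str
    cost: float
    qalys: float
    life_years: float | None = None

    def as_tuple(self) -> tuple[str, float, float]:
        return (self.name, self.cost, self.qalys)


def run_cohort(
    strategy: StrategyParams,
    inputs: ModelInputs,
    hazard: BaselineHazard | None = None,
    horizon_years: float | None = None,
) -> CohortTrace:
    """Iterate the cohort until the horizon or extinction (living < 1e-9).

    With no horizon the run is lifetime; failure to (numerically) die out
    within 200 years raises :class:`EngineError`.
    """
    h = _resolve_hazard(inputs, hazard)
    g = inputs.globals
    if horizon_years is None:
        horizon_years = g.horizon_years
    cap_years = horizon_years if horizon_years is not None else _HARD_CAP_YEARS
    cap_cycles = int(math.ceil(cap_years / g.cycle_years - 1e-12))

    costs_bundle = per_cycle_amounts(g, strategy)
    cached = _cycle_probs(inputs, strategy, h, 0) if h.time_invariant else None

    state = CohortState.initial(inputs)
    occ_rows = [state.occupancy]
    cost, qalys, ucost, uqalys, ly = [], [], [], [], []
    for k in range(cap_cycles):
        if state.living < _EXTINCTION_TOL:
            break
        probs = cached if cached is not None else _cycle_probs(inputs, strategy, h, k)
        new_state, events = transition(state, strategy, inputs, h, _probs=probs)
        acc = accumulate_cycle(state, events, strategy, inputs, k, costs_bundle)
        cost.append(acc.cost)
        qalys.append(acc.qalys)
        ucost.append(acc.undiscounted_cost)
        uqalys.append(acc.undiscounted_qalys)
        ly.append(acc.life_years)
        state = new_state
        occ_rows.append(state.occupancy)
    else:
        if horizon_years is None and state.living >= _EXTINCTION_TOL:
            raise EngineError(
                f"cohort not extinct after {_HARD_CAP_YEARS} years "
                f"(living mass {state.living:.3e})"
            )
    return CohortTrace(
        strategy=strategy.name,
        occupancy=np.vstack(occ_rows),
        cost=np.array(cost),
        qalys=np.array(qalys),
        undiscounted_cost=np.array(ucost),
        undiscounted_qalys=np.array(uqalys),
        life_years=np.array(ly),
    )


def _living_kernel(pr: _CycleProbs) -> np.ndarray:
    """Living-to-living transition matrix T with x_{k+1} = T @ x_k (12x12)."""
    n = 2 * N_BANDS
    T = np.zeros((n, n))
    pd = pr.p_decline
    for b in range(N_BANDS):
        # from (b, noAE)
        s = 1.0 - pr.qd_no
        stay = s * (1.0 - pr.p_ae)
        flip = s * pr.p_ae
        if b < N_BANDS - 1:
            T[b, b] += stay * (1.0 - pd[b])
            T[b + 1, b] += stay * pd[b]
            T[N_BANDS + b, b] += flip * (1.0 - pd[b])
            T[N_BANDS + b + 1, b] += flip * pd[b]
        else:
            T[b, b] += stay * (1.0 - pd[b])
            T[N_BANDS + b, b] += flip * (1.0 - pd[b])
        # from (b, AE)
        s2 = 1.0 - pr.qd_ae
        if b < N_BANDS - 1:
            T[N_BANDS + b, N_BANDS + b] += s2 * (1.0 - pd[b])
            T[N_BANDS + b + 1, N_BANDS + b] += s2 * pd[b]
        else:
            T[N_BANDS + b, N_BANDS + b] += s2 * (1.0 - pd[b])
    return T


def _accrual_weights(
    inputs: ModelInputs, strategy: StrategyParams, pr: _CycleProbs
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-living-compartment expected (cost, qaly, life-year) accrual/cycle."""
    g = inputs.globals
    costs = per_cycle_amounts(g, strategy)
    u = inputs.utilities()
    d1 = g.disutility_first_cycle.mean
    d2 = g.disutility_subsequent.mean
    dt = g.cycle_years
    u1 = np.maximum(u - d1, 0.0)
    u2 = np.maximum(u - d2, 0.0)

    ae_no = (1.0 - pr.qd_no) * pr.p_ae  # P(new AE | start in noAE compartment)
    ae_ae = (1.0 - pr.qd_ae) * pr.p_ae
    w_cost = np.empty(2 * N_BANDS)
    w_qaly = np.empty(2 * N_BANDS)
    w_cost[:N_BANDS] = costs.recurring + costs.ae_episode * ae_no
    w_cost[N_BANDS:] = costs.recurring + costs.ae_episode * ae_ae
    w_qaly[:N_BANDS] = dt * ((1.0 - ae_no) * u + ae_no * u1)
    w_qaly[N_BANDS:] = dt * ((1.0 - ae_ae) * u2 + ae_ae * u1)
    w_ly = np.full(2 * N_BANDS, dt)
    return w_cost, w_qaly, w_ly


def lifetime_outcomes(
    strategy: StrategyParams,
    inputs: ModelInputs,
    hazard: BaselineHazard | None = None,
    method: str = "auto",
) -> Outcome:
    """Lifetime discounted (cost, QALYs) for one strategy.

    ``method='solve'`` evaluates the infinite-horizon geometric series
    exactly via ``w · (I - βT)^{-1} x0`` (valid for time-invariant hazards
    with no finite horizon); ``method='trace'`` sums the iterative cohort
    trace; ``'auto'`` picks the solve when applicable.
    """
    h = _resolve_hazard(inputs, hazard)
    g = inputs.globals
    solvable = h.time_invariant and g.horizon_years is None
    if method == "auto":
        method = "solve" if solvable else "trace"
    if method == "solve":
        if not solvable:
            raise EngineError("linear solve needs a time-invariant hazard and no horizon")
        pr = _cycle_probs(inputs, strategy, h, 0)
        T = _living_kernel(pr)
        beta = (1.0 + g.discount_rate) ** (-g.cycle_years)
        x0 = np.zeros(2 * N_BANDS)
        x0[inputs.start_band_index()] = 1.0
        w_cost, w_qaly, w_ly = _accrual_weights(inputs, strategy, pr)
        eye = np.eye(2 * N_BANDS)
        try:
            z = np.linalg.solve(eye - beta * T, x0)
            z_undisc = np.linalg.solve(eye - T, x0)
        except np.linalg.LinAlgError as exc:
            raise EngineError(f"lifetime solve failed (immortal cohort?): {exc}") from None
        if np.any(z < -1e-9) or np.any(z_undisc < -1e-9):
            raise EngineError("lifetime solve produced negative occupancy mass")
        return Outcome(
            name=strategy.name,
            cost=float(w_cost @ z),
            qalys=float(w_qaly @ z),
            life_years=float(w_ly @ z_undisc),
        )
    trace = run_cohort(strategy, inputs, h)
    return Outcome(
        name=strategy.name,
        cost=trace.total_cost,
        qalys=trace.total_qalys,
        life_years=trace.total_life_years,
    )


def run_all_strategies(
    inputs: ModelInputs, hazard: BaselineHazard | None = None, method: str = "auto"
) -> list[Outcome]:
    return [lifetime_outcomes(s, inputs, hazard, method) for s in inputs.strategies]


@dataclass(frozen=True)
class MicrosimResult:
    name: str
    n: int
    seed: int
    mean_cost: float
    mean_qalys: float
    se_cost: float
    se_qalys: float


def microsimulate(
    strategy: StrategyParams,
    inputs: ModelInputs,
    n_individuals: int,
    seed: int,
    hazard: BaselineHazard | None = None,
) -> MicrosimResult:
    """First-order Monte-Carlo walk of individuals through the same event tree.

    Serves as an independent oracle for the cohort recursion: with the same
    parameters, its mean lifetime cost and QALYs converge to the cohort
    totals.  Fully seeded; identical seeds give bit-identical results.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    h = _resolve_hazard(inputs, hazard)
    g = inputs.globals
    rng = np.random.default_rng(seed)
    costs = per_cycle_amounts(g, strategy)
    u = inputs.utilities()
    d1 = g.disutility_first_cycle.mean
    d2 = g.disutility_subsequent.mean
    dt = g.cycle_years
    cap_years = g.horizon_years if g.horizon_years is not None else _HARD_CAP_YEARS
    cap_cycles = int(math.ceil(cap_years / dt - 1e-12))
    cached = _cycle_probs(inputs, strategy, h, 0) if h.time_invariant else None

    band = np.full(n_individuals, inputs.start_band_index(), dtype=np.int64)
    hist = np.zeros(n_individuals, dtype=bool)
    alive = np.ones(n_individuals, dtype=bool)
    cost = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)

    for k in range(cap_cycles):
        ia = np.flatnonzero(alive)
        if ia.size == 0:
            break
        pr = cached if cached is not None else _cycle_probs(inputs, strategy, h, k)
        b = band[ia]
        hflag = hist[ia]
        qd = np.where(hflag, pr.qd_ae, pr.qd_no)
        died = rng.random(ia.size) < qd
        surv = ~died
        new_ae = np.zeros(ia.size, dtype=bool)
        new_ae[surv] = rng.random(int(surv.sum())) < pr.p_ae
        declined = np.zeros(ia.size, dtype=bool)
        declined[surv] = rng.random(int(surv.sum())) < pr.p_decline[b[surv]]

        disc = discount_factor(g, k)
        disutil = np.where(new_ae, d1, np.where(hflag, d2, 0.0))
        qaly[ia] += disc * dt * np.maximum(u[b] - disutil, 0.0)
        cost[ia] += disc * (costs.recurring + costs.ae_episode * new_ae)

        hist[ia[new_ae]] = True
        nb = b + declined
        fell_out = nb > N_BANDS - 1
        band[ia] = np.minimum(nb, N_BANDS - 1)
        alive[ia[died | fell_out]] = False

    return MicrosimResult(
        name=strategy.name,
        n=n_individuals,
        seed=seed,
        mean_cost=float(cost.mean()),
        mean_qalys=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / math.sqrt(n_individuals)) if n_individuals > 1 else 0.0,
        se_qalys=float(qaly.std(ddof=1) / math.sqrt(n_individuals)) if n_individuals > 1 else 0.0,
    )
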