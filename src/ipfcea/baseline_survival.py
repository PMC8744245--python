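"""Synthetic baseline mortality for the IPF cohort, with calibration.

The published analysis informed baseline (untreated) mortality from survival
curves of a network meta-analysis that are not reproduced in print.  This
module provides a parametric stand-in: a one- or two-parameter hazard
(exponential or Weibull) that yields a per-cycle death probability, plus a
calibration routine that tunes the hazard so the symptom-management arm of
the full model reproduces a target lifetime QALY figure.  Lifetime cost is
deliberately *not* fitted; how close it lands to the published figure is a
genuine out-of-sample consistency check.

The hazard is synthetic: it reproduces the published lifetime summaries by
construction, not the shape of the original survival curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

from scipy.optimize import bisect

__all__ = [
    "BaselineHazard",
    "CalibrationError",
    "CalibrationResult",
    "cycle_death_prob",
    "calibrate",
]

_FAMILIES = ("exponential", "weibull")


class CalibrationError(RuntimeError):
    """The calibration target cannot be reached inside the search bracket."""


@dataclass(frozen=True)
class BaselineHazard:
    """Parametric all-cause baseline hazard for an untreated IPF cohort.

    exponential: constant hazard ``rate_per_year`` (per year).
    weibull: S(t) = exp(-(t/scale_years)**shape); shape 1 reduces to the
    exponential with rate 1/scale_years.
    """

    family: str
    rate_per_year: float | None = None
    shape: float | None = None
    scale_years: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.family == "exponential":
            r = self.rate_per_year
            if r is None or not math.isfinite(r) or r < 0.0:
                raise ValueError("exponential hazard needs finite rate_per_year >= 0")
        else:
            k, lam = self.shape, self.scale_years
            if k is None or lam is None or not (math.isfinite(k) and math.isfinite(lam)):
                raise ValueError("weibull hazard needs finite shape and scale_years")
            if k <= 0.0 or lam <= 0.0:
                raise ValueError("weibull shape and scale_years must be > 0")

    @property
    def time_invariant(self) -> bool:
        """True when the per-cycle death probability does not depend on time."""
        return self.family == "exponential" or self.shape == 1.0

    def survival(self, t_years: float) -> float:
        if self.family == "exponential":
            return math.exp(-self.rate_per_year * t_years)
        return math.exp(-((t_years / self.scale_years) ** self.shape))

    def cycle_death_prob(self, cycle_index: int, cycle_years: float) -> float:
        """P(death within the cycle | alive at its start)."""
        if cycle_index < 0 or cycle_years <= 0.0:
            raise ValueError("cycle_index must be >= 0 and cycle_years > 0")
        t0 = cycle_index * cycle_years
        s0 = self.survival(t0)
        if s0 <= 0.0:
            return 1.0
        return 1.0 - self.survival(t0 + cycle_years) / s0

    def to_dict(self) -> dict:
        if self.family == "exponential":
            return {"family": self.family, "rate_per_year": self.rate_per_year}
        return {"family": self.family, "shape": self.shape, "scale_years": self.scale_years}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaselineHazard":
        return cls(
            family=str(d["family"]),
            rate_per_year=(None if d.get("rate_per_year") is None else float(d["rate_per_year"])),
            shape=(None if d.get("shape") is None else float(d["shape"])),
            scale_years=(None if d.get("scale_years") is None else float(d["scale_years"])),
        )


def cycle_death_prob(h: BaselineHazard, cycle_index: int, cycle_years: float) -> float:
    """Functional alias for :meth:`BaselineHazard.cycle_death_prob`."""
    return h.cycle_death_prob(cycle_index, cycle_years)


@dataclass(frozen=True)
class CalibrationResult:
    hazard: BaselineHazard
    achieved_qalys: float
    achieved_cost: float
    target_qalys: float
    target_cost: float | None = None

    @property
    def cost_relative_error(self) -> float | None:
        if self.target_cost is None or self.target_cost == 0.0:
            return None
        return (self.achieved_cost - self.target_cost) / self.target_cost


def calibrate(
    target_qalys: float,
    model_runner: Callable[[BaselineHazard], tuple[float, float]],
    *,
    target_cost: float | None = None,
    family: str = "exponential",
    shape: float = 1.0,
    bracket: tuple[float, float] = (1e-4, 10.0),
    rel_tol: float = 1e-6,
    qaly_tolerance: float = 0.005,
) -> CalibrationResult:
    """Find the hazard whose symptom-management QALYs hit ``target_qalys``.

    ``model_runner`` maps a hazard to the reference arm's (lifetime cost,
    lifetime QALYs) under otherwise base-case parameters.  Discounted QALYs
    are strictly decreasing in the hazard rate, so bisection on the rate
    (exponential) or on 1/scale with fixed shape (Weibull) is valid.
    ``target_cost``, when given, is recorded and reported alongside the fit
    but never used by the search.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")

    def make(rate: float) -> BaselineHazard:
        if family == "exponential":
            return BaselineHazard("exponential", rate_per_year=rate)
        return BaselineHazard("weibull", shape=shape, scale_years=1.0 / rate)

    def qaly_gap(rate: float) -> float:
        _, q = model_runner(make(rate))
        return q - target_qalys

    lo, hi = bracket
    f_lo, f_hi = qaly_gap(lo), qaly_gap(hi)
    if f_lo * f_hi > 0.0:
        raise CalibrationError(
            f"target {target_qalys} QALYs not bracketed on rate in [{lo}, {hi}]: "
            f"QALY gap {f_lo:+.4f} at {lo}, {f_hi:+.4f} at {hi}"
        )
    rate = bisect(qaly_gap, lo, hi, rtol=rel_tol, xtol=1e-12)
    hazard = make(rate)
    cost, qalys = model_runner(hazard)
    if abs(qalys - target_qalys) > qaly_tolerance * abs(target_qalys):
        raise CalibrationError(
            f"calibration stalled: achieved {qalys:.4f} QALYs vs target {target_qalys}"
        )
    return CalibrationResult(
        hazard=hazard,
        achieved_qalys=qalys,
        achieved_cost=cost,
        target_qalys=target_qalys,
        target_cost=target_cost,
    )
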