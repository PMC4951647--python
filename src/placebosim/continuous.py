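"""Continuous-time extension: within-trial pharmacodynamic time courses.

Real drugs act through a pharmacodynamic curve x(t) over a trial window of
duration T0, not a constant.  The continuous model keeps the discrete
error-driven recursion but applies it per time bin across trials, adds a
first-order low-pass (time constant tau, minutes) that shapes the reactive
output within a trial, and maintains a learned within-trial response
pattern y_P with confidence weights (w+, w-) updated by a bounded
potentiation/depression rule on pattern occurrence/non-occurrence.

Simulation uses a fine sampling step T_sample <= tau/20.  After repeated
identical active administrations the reactive component converges to a
tau-smoothed copy of the drug's response curve scaled toward
alpha/(1-alpha) ("reactive mimicking"); a subsequent placebo trial elicits
that reactive component alone, and further placebo trials extinguish it
geometrically with ratio alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter

from .discrete import ProtocolConfigError, acquisition_closed_form

__all__ = [
    "ContinuousParams",
    "TimeCourse",
    "PatternMemory",
    "ContinuousTrial",
    "ContinuousTrialResult",
    "ContinuousResult",
    "lowpass_expectation",
    "update_confidence",
    "expected_timecourse",
    "simulate_continuous",
    "discrete_consistency_check",
]


@dataclass(frozen=True)
class ContinuousParams:
    """Parameters of the continuous-time reactive model.

    Parameters
    ----------
    alpha
        Reactive efficiency (same semantics as the discrete model).
    tau
        Time constant of the low-pass expectation/response filter, minutes.
    T0
        Trial window duration, minutes.
    T_sample
        Simulation step, minutes; must satisfy T_sample <= tau/20.
    eta_plus, eta_minus
        Confidence potentiation rate per pattern occurrence and depression
        rate per non-occurrence, both in (0, 1].
    history_retention
        Across-trial memory of the per-bin outcome history in [0, 1):
        0 means the expectation history is the last trial's outcome (the
        discrete model's rule); larger values blend earlier trials in
        exponentially.
    """

    alpha: float
    tau: float
    T0: float
    T_sample: float
    eta_plus: float = 0.5
    eta_minus: float = 1.0
    history_retention: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ProtocolConfigError(f"tau must be > 0, got {self.tau}")
        if self.T0 <= 0:
            raise ProtocolConfigError(f"T0 must be > 0, got {self.T0}")
        if self.T_sample <= 0:
            raise ProtocolConfigError(f"T_sample must be > 0, got {self.T_sample}")
        if self.T_sample > self.tau / 20.0 + 1e-12:
            raise ProtocolConfigError(
                f"T_sample = {self.T_sample} violates the sampling rule "
                f"T_sample <= tau/20 = {self.tau / 20.0}"
            )
        for name in ("eta_plus", "eta_minus"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ProtocolConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.history_retention < 1.0:
            raise ProtocolConfigError(
                f"history_retention must be in [0, 1), got {self.history_retention}"
            )

    @property
    def n_bins(self) -> int:
        """Number of within-trial sample bins N = round(T0/T_sample)."""
        return int(round(self.T0 / self.T_sample))


@dataclass(frozen=True)
class TimeCourse:
    """A uniformly sampled function of time within a trial window.

    Values must be finite; NaN is permitted to mark quantities that are
    not computed (e.g. the error trace of a hidden administration).
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ProtocolConfigError("TimeCourse t and v must be 1-D of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ProtocolConfigError("TimeCourse grid must be uniform")
        if not np.all(np.isfinite(t)) or np.any(np.isinf(v)):
            raise ProtocolConfigError("TimeCourse values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else float("nan")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class PatternMemory:
    """Learned within-trial response pattern and its confidence weights.

    ``w_plus`` is the belief confidence that the learned pattern will
    occur on the next administration; ``w_minus = 1 - w_plus``.
    """

    y_P: np.ndarray
    w_plus: float = 0.0

    def __post_init__(self) -> None:
        y_P = np.asarray(self.y_P, dtype=float)
        object.__setattr__(self, "y_P", y_P)
        if not 0.0 <= self.w_plus <= 1.0:
            raise ProtocolConfigError(f"w_plus must be in [0, 1], got {self.w_plus}")

    @property
    def w_minus(self) -> float:
        return 1.0 - self.w_plus


@dataclass(frozen=True)
class ContinuousTrial:
    """One administration event with a within-trial stimulus curve.

    ``x_curve`` is the active pharmacodynamic magnitude per time bin
    (None or zeros for placebo).  Hidden trials deliver x_curve without
    triggering or updating the reactive machinery.
    """

    kind: Literal["active", "placebo", "hidden"] = "active"
    x_curve: np.ndarray | None = None


def _lowpass_coeff(dt: float, tau: float) -> float:
    return math.exp(-dt / tau)


def lowpass_expectation(history: TimeCourse, tau: float) -> TimeCourse:
    """First-order exponential low-pass of a sampled signal.

    Exact zero-order-hold discretization of an R-C first-order filter in
    its strictly causal form, out[k] = a*out[k-1] + (1-a)*in[k-1] with
    a = exp(-dt/tau) and zero initial state, so a unit step at t=0
    reaches 1 - e^{-t/tau} exactly on the grid.  Unit DC gain: a
    constant input converges to itself.
    """
    if tau <= 0:
        raise ProtocolConfigError(f"tau must be > 0, got {tau}")
    if len(history) == 0:
        return history
    out = _smooth(history.v, history.dt if len(history) >= 2 else 1.0, tau)
    return TimeCourse(t=history.t, v=out)


def _smooth(v: np.ndarray, dt: float, tau: float) -> np.ndarray:
    a = _lowpass_coeff(dt, tau)
    return lfilter([0.0, 1.0 - a], [1.0, -a], v)


def update_confidence(mem: PatternMemory, occurred: bool, params: ContinuousParams) -> PatternMemory:
    """Bounded Hebbian-style confidence update.

    Occurrence potentiates w+ toward 1 at rate eta_plus; non-occurrence
    depresses it toward 0 at rate eta_minus; w+ stays in [0, 1] and
    w- = 1 - w+ always.
    """
    if occurred:
        w = mem.w_plus + params.eta_plus * (1.0 - mem.w_plus)
    else:
        w = mem.w_plus * (1.0 - params.eta_minus)
    return PatternMemory(y_P=mem.y_P, w_plus=float(np.clip(w, 0.0, 1.0)))


def expected_timecourse(mem: PatternMemory, running_average: TimeCourse) -> TimeCourse:
    """Predicted within-trial outcome: w+ * y_P + w- * running average."""
    if mem.y_P.size != len(running_average):
        raise ProtocolConfigError(
            f"grid mismatch: pattern has {mem.y_P.size} bins, "
            f"running average has {len(running_average)}"
        )
    v = mem.w_plus * mem.y_P + mem.w_minus * running_average.v
    return TimeCourse(t=running_average.t, v=v)


@dataclass(frozen=True)
class ContinuousTrialResult:
    """Per-trial simulated time courses and the pattern-memory snapshot.

    ``reactive`` is the tau-smoothed reactive component (y - x); ``e`` is
    the per-bin prediction error driving the across-trial update.
    """

    index: int
    kind: str
    x: TimeCourse
    y: TimeCourse
    e: TimeCourse
    reactive: TimeCourse
    memory: PatternMemory


@dataclass(frozen=True)
class ContinuousResult:
    """Full simulation output."""

    trials: list[ContinuousTrialResult]
    params: ContinuousParams
    reactive_memory: np.ndarray  # final per-bin raw reactive memory r(b)

    def __len__(self) -> int:
        return len(self.trials)


def _time_grid(params: ContinuousParams) -> np.ndarray:
    return np.arange(params.n_bins) * params.T_sample


def simulate_continuous(
    protocol: Sequence[ContinuousTrial],
    params: ContinuousParams,
) -> ContinuousResult:
    """Simulate a sequence of administration trials in continuous time.

    Per time bin b the model keeps a reactive memory r(b) updated across
    trials by the discrete rule r(b) <- r(b) + alpha * e(b) with
    e(b) = y(b) - yhat(b); within a trial the reactive output is the
    tau-smoothed r (the reaction builds up from trial onset with the
    system's own time constant), so y(t) = x(t) + smooth_tau(r)(t).
    The expectation yhat blends the learned pattern y_P (weight w+) with
    the per-bin outcome history (weight w-); confidence updates once per
    trial (occurred = active administration).  Hidden trials deliver
    x(t) untouched by (and not touching) the reactive machinery.
    """
    if not protocol:
        raise ProtocolConfigError("protocol must contain at least one trial")
    N = params.n_bins
    t = _time_grid(params)
    zeros = np.zeros(N)

    r = np.zeros(N)  # per-bin reactive memory (raw, unsmoothed)
    history = np.zeros(N)  # per-bin outcome history (expectation source)
    mem = PatternMemory(y_P=np.zeros(N), w_plus=0.0)
    rho = params.history_retention

    results: list[ContinuousTrialResult] = []
    for n, trial in enumerate(protocol, start=1):
        if trial.kind not in ("active", "placebo", "hidden"):
            raise ProtocolConfigError(f"trial {n}: unknown kind {trial.kind!r}")
        if trial.x_curve is None:
            x = zeros
            if trial.kind in ("active", "hidden"):
                raise ProtocolConfigError(f"trial {n}: {trial.kind} trial requires x_curve")
        else:
            x = np.asarray(trial.x_curve, dtype=float)
            if x.shape != (N,):
                raise ProtocolConfigError(
                    f"trial {n}: x_curve has {x.shape} samples, expected ({N},)"
                )
            if trial.kind == "placebo" and np.any(x != 0.0):
                raise ProtocolConfigError(f"trial {n}: placebo trial must have zero x_curve")

        if trial.kind == "hidden":
            y = x.copy()
            results.append(
                ContinuousTrialResult(
                    index=n, kind=trial.kind,
                    x=TimeCourse(t, x), y=TimeCourse(t, y),
                    e=TimeCourse(t, np.full(N, np.nan)),
                    reactive=TimeCourse(t, zeros.copy()), memory=mem,
                )
            )
            continue

        reactive = _smooth(r, params.T_sample, params.tau)
        y = x + reactive
        yhat = mem.w_plus * mem.y_P + mem.w_minus * history
        e = y - yhat
        r = r + params.alpha * e
        history = rho * history + (1.0 - rho) * y

        occurred = trial.kind == "active"
        if occurred:
            mem = PatternMemory(y_P=y.copy(), w_plus=mem.w_plus)
        mem = update_confidence(mem, occurred, params)

        results.append(
            ContinuousTrialResult(
                index=n, kind=trial.kind,
                x=TimeCourse(t, x), y=TimeCourse(t, y),
                e=TimeCourse(t, e), reactive=TimeCourse(t, reactive),
                memory=mem,
            )
        )
    return ContinuousResult(trials=results, params=params, reactive_memory=r)


def plateau_value(tc: TimeCourse, fraction: float = 0.2) -> float:
    """Mean of the last ``fraction`` of a within-trial time course.

    For boxcar stimuli the filter transient has died out by the end of
    the window, so this estimates the trial's steady-state response.
    """
    k = max(1, int(round(fraction * len(tc))))
    return float(np.mean(tc.v[-k:]))


def discrete_consistency_check(
    x_const: float,
    alpha: float,
    tau: float,
    T0: float,
    n_trials: int,
    T_sample: float | None = None,
) -> float:
    """Max relative deviation of continuous plateaus from the discrete model.

    Runs ``n_trials`` active trials with a constant (boxcar) within-trial
    stimulus and compares each trial's plateau response with the discrete
    closed form y_n = x (1 - alpha^n)/(1 - alpha).  Requires
    tau <= T0/10 so the within-trial filter transient is negligible at
    the window end.  Returns the maximum relative deviation (contract:
    < 2%).
    """
    if tau > T0 / 10.0:
        raise ProtocolConfigError(f"tau = {tau} must be <= T0/10 = {T0 / 10.0}")
    if T_sample is None:
        T_sample = tau / 20.0
    params = ContinuousParams(alpha=alpha, tau=tau, T0=T0, T_sample=T_sample)
    boxcar = np.full(params.n_bins, float(x_const))
    protocol = [ContinuousTrial(kind="active", x_curve=boxcar) for _ in range(n_trials)]
    result = simulate_continuous(protocol, params)
    deviations = []
    for n, tr in enumerate(result.trials, start=1):
        expected, _, _ = acquisition_closed_form(x_const, alpha, n)
        plateau = plateau_value(tr.y)
        scale = max(abs(expected), abs(x_const), 1e-300)
        deviations.append(abs(plateau - expected) / scale)
    return float(max(deviations))
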