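"""Discrete trial-by-trial dynamics of the reactive system.

The model decomposes the response to an open substance administration into
an active pharmacological component ``x``, an implicitly learned reactive
component ``i_R`` (the unconscious placebo component), and additive
modulatory terms (cognitive contribution ``gamma``, misattributed response,
baseline drift ``b_n``).  The reactive component is updated by an
error-driven (prediction-error) rule with gain ``alpha``::

    y_n   = x_n + i_R,n + gamma_n + b_n + misattributed_n
    e_n   = y_n - expected_n
    i_R   <- i_R + alpha * e_n

with the default expectation rule "expected outcome = last experienced
outcome".  For a constant stimulus this yields the geometric acquisition
series y_n = x(1 + alpha + ... + alpha^(n-1)) and, after withdrawal of the
active component (placebo trials), geometric extinction y_n = x alpha^n/(1-alpha).
Stability requires 0 < |alpha| < 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InstabilityWarning",
    "InvalidStateError",
    "ProtocolConfigError",
    "ModelParams",
    "Trial",
    "TrialRecord",
    "State",
    "trial_step",
    "run_protocol",
    "records_to_frame",
    "acquisition_closed_form",
    "asymptotic_response",
    "extinction_closed_form",
    "run_cycle_protocol",
    "single_quantity_variant",
]

TrialKind = Literal["active", "placebo", "hidden", "virtual"]


class InstabilityWarning(UserWarning):
    """Raised when |alpha| >= 1: the reactive system has no asymptote."""


class InvalidStateError(ValueError):
    """Non-finite state or trial quantities."""


class ProtocolConfigError(ValueError):
    """A trial or protocol violates its construction invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the discrete reactive system.

    Parameters
    ----------
    alpha
        Reactive efficiency: gain of the error-driven update of ``i_R``.
        Any real value is accepted; ``stable`` is False for |alpha| >= 1.
    gamma_default
        Cognitive additive contribution applied to trials that do not set
        their own ``gamma`` (response units). Default 0.
    precision_factor
        Error-signal attenuation in [0, 1] applied on trials flagged
        ``error_blocked`` (1 = intact error computation, 0 = fully
        blocked).  Models a pharmacological degradation of the precision
        of the prediction-error signal.
    """

    alpha: float
    gamma_default: float = 0.0
    precision_factor: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise InvalidStateError("alpha must be finite")
        if not 0.0 <= self.precision_factor <= 1.0:
            raise ProtocolConfigError(
                f"precision_factor must be in [0, 1], got {self.precision_factor}"
            )

    @property
    def stable(self) -> bool:
        """True iff 0 < |alpha| < 1 (the stability condition)."""
        return 0.0 < abs(self.alpha) < 1.0


@dataclass(frozen=True)
class Trial:
    """One administration event.

    ``kind`` is one of ``active``, ``placebo``, ``hidden``, ``virtual``.
    Placebo and virtual trials carry no active magnitude (x = 0); virtual
    trials must set ``simulated_outcome`` (the cognitively inferred
    outcome).  Hidden trials deliver x pharmacologically but the
    administration is not perceived: the reactive response is neither
    triggered nor updated.
    """

    kind: TrialKind = "active"
    x: float = 0.0
    gamma: float | None = None
    misattributed: float = 0.0
    baseline_shift: float = 0.0
    error_blocked: bool = False
    simulated_outcome: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("active", "placebo", "hidden", "virtual"):
            raise ProtocolConfigError(f"unknown trial kind {self.kind!r}")
        if self.kind in ("placebo", "virtual") and self.x != 0.0:
            raise ProtocolConfigError(f"{self.kind} trial must have x = 0, got x={self.x}")
        if self.kind == "virtual" and self.simulated_outcome is None:
            raise ProtocolConfigError("virtual trial requires simulated_outcome")
        for name in ("x", "misattributed", "baseline_shift"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidStateError(f"trial field {name} must be finite")


@dataclass(frozen=True)
class State:
    """Carried learner state: reactive response and expected outcome."""

    i_R: float = 0.0
    expected: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.i_R) and math.isfinite(self.expected)):
            raise InvalidStateError("state must be finite")


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial realized quantities.

    ``e`` is the raw observable error y - expected (NaN on hidden trials,
    where no error is computed); ``i_R`` is the reactive response AFTER
    the trial's update.
    """

    index: int
    kind: TrialKind
    x: float
    gamma: float
    misattributed: float
    baseline_shift: float
    expected: float
    y: float
    e: float
    i_R: float


def trial_step(trial: Trial, state: State, params: ModelParams) -> tuple[TrialRecord, State]:
    """Advance the learner by one administration trial.

    Returns the realized :class:`TrialRecord` and the new :class:`State`.
    Active/placebo trials experience y = x + i_R + gamma + baseline_shift
    + misattributed, compute e = y - expected and update i_R by
    alpha * e (attenuated by ``precision_factor`` when the trial is
    error-blocked); hidden trials leave the learner untouched; virtual
    trials treat the simulated outcome as the experienced one.
    """
    gamma = params.gamma_default if trial.gamma is None else trial.gamma
    if not math.isfinite(gamma):
        raise InvalidStateError("gamma must be finite")

    if trial.kind == "hidden":
        y = trial.x + trial.baseline_shift
        record = TrialRecord(
            index=0, kind=trial.kind, x=trial.x, gamma=0.0,
            misattributed=0.0, baseline_shift=trial.baseline_shift,
            expected=state.expected, y=y, e=float("nan"), i_R=state.i_R,
        )
        return record, state

    if trial.kind == "virtual":
        y = float(trial.simulated_outcome)  # the inferred outcome is "experienced"
        if not math.isfinite(y):
            raise InvalidStateError("simulated_outcome must be finite")
        e = y - state.expected
        new_i_R = state.i_R + params.alpha * e
        record = TrialRecord(
            index=0, kind=trial.kind, x=0.0, gamma=gamma,
            misattributed=0.0, baseline_shift=0.0,
            expected=state.expected, y=y, e=e, i_R=new_i_R,
        )
        return record, State(i_R=new_i_R, expected=y)

    # open administration: active or placebo
    y = trial.x + state.i_R + gamma + trial.baseline_shift + trial.misattributed
    e = y - state.expected
    factor = params.precision_factor if trial.error_blocked else 1.0
    new_i_R = state.i_R + params.alpha * e * factor
    record = TrialRecord(
        index=0, kind=trial.kind, x=trial.x, gamma=gamma,
        misattributed=trial.misattributed, baseline_shift=trial.baseline_shift,
        expected=state.expected, y=y, e=e, i_R=new_i_R,
    )
    return record, State(i_R=new_i_R, expected=y)


def run_protocol(
    trials: Sequence[Trial] | Iterable[Trial],
    params: ModelParams,
    init_state: State = State(),
) -> list[TrialRecord]:
    """Fold :func:`trial_step` over an ordered trial list.

    Trial indices in the returned records are 1-based.  Emits an
    :class:`InstabilityWarning` when |alpha| >= 1 (the simulation still
    runs; the trace may diverge).
    """
    trials = list(trials)
    if not trials:
        raise ProtocolConfigError("protocol must contain at least one trial")
    if abs(params.alpha) >= 1.0:
        warnings.warn(
            f"|alpha| = {abs(params.alpha)} >= 1: reactive system is unstable, "
            "the response has no asymptote",
            InstabilityWarning,
            stacklevel=2,
        )
    records: list[TrialRecord] = []
    state = init_state
    for n, trial in enumerate(trials, start=1):
        try:
            record, state = trial_step(trial, state, params)
        except (InvalidStateError, ProtocolConfigError) as exc:
            raise type(exc)(f"trial {n}: {exc}") from exc
        records.append(replace(record, index=n))
    return records


_TRACE_COLUMNS = [
    "trial_index", "kind", "x", "gamma", "misattributed",
    "baseline_shift", "expected", "y", "e", "i_R",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records as a tidy DataFrame (one row per trial)."""
    return pd.DataFrame(
        {
            "trial_index": [r.index for r in records],
            "kind": [r.kind for r in records],
            "x": [r.x for r in records],
            "gamma": [r.gamma for r in records],
            "misattributed": [r.misattributed for r in records],
            "baseline_shift": [r.baseline_shift for r in records],
            "expected": [r.expected for r in records],
            "y": [r.y for r in records],
            "e": [r.e for r in records],
            "i_R": [r.i_R for r in records],
        },
        columns=_TRACE_COLUMNS,
    )


def acquisition_closed_form(x: float, alpha: float, n: int) -> tuple[float, float, float]:
    """Closed-form acquisition quantities at trial ``n`` (constant stimulus).

    Returns ``(y_n, i_R_n, e_n)`` with

    .. math:: y_n = x \\frac{1 - \\alpha^n}{1 - \\alpha}, \\quad
              i_{R,n} = y_n - x, \\quad e_n = \\alpha^{n-1} x

    using the limit forms y_n = n x for alpha = 1.  Note that i_R_n here
    is the reactive response elicited *during* trial n; the simulator's
    :class:`TrialRecord` stores the value after the trial's update,
    which equals i_R_{n+1}.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if alpha == 1.0:
        y = n * x
    else:
        y = x * (1.0 - alpha**n) / (1.0 - alpha)
    i_R = y - x
    e = alpha ** (n - 1) * x
    return y, i_R, e


def asymptotic_response(x: float, alpha: float) -> tuple[float, float]:
    """Asymptote of the acquisition series: ``(y_inf, i_R_inf)``.

    y_inf = x/(1-alpha) and i_R_inf = x*alpha/(1-alpha); requires the
    stability condition 0 < |alpha| < 1 (alpha = 0 is admitted and gives
    the trivial asymptote (x, 0)).
    """
    if abs(alpha) >= 1.0:
        raise InstabilityError(alpha)
    y_inf = x / (1.0 - alpha)
    return y_inf, y_inf - x


class InstabilityError(ValueError):
    """|alpha| >= 1: the geometric series has no limit."""

    def __init__(self, alpha: float):
        super().__init__(f"|alpha| = {abs(alpha)} >= 1: no asymptotic response exists")
        self.alpha = alpha


def extinction_closed_form(x_prior: float, alpha: float, n: int) -> float:
    """Placebo response at the n-th extinction trial after full acquisition.

    Starting from the asymptotic state (i_R = x*alpha/(1-alpha),
    expected = x/(1-alpha)), the n-th placebo trial yields

    .. math:: y_n = x \\frac{\\alpha^n}{1 - \\alpha}
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if abs(alpha) >= 1.0:
        raise InstabilityError(alpha)
    return x_prior * alpha**n / (1.0 - alpha)


def asymptotic_state(x: float, alpha: float) -> State:
    """Learner state at the acquisition asymptote for constant stimulus x."""
    y_inf, i_R_inf = asymptotic_response(x, alpha)
    return State(i_R=i_R_inf, expected=y_inf)


def run_cycle_protocol(
    x: float,
    alpha: float,
    n_active: int,
    n_blocked_placebo: int,
    n_cycles: int,
    params: ModelParams | None = None,
) -> tuple[list[TrialRecord], float]:
    """Resistant-to-extinction accumulation protocol.

    Each cycle consists of ``n_active`` open active trials followed by
    ``n_blocked_placebo`` placebo trials on which the error-signal
    computation is blocked (attenuated by ``params.precision_factor``;
    0 = perfect blocking).  During blocked placebo trials the expected
    outcome still tracks the experienced one, but the reactive response
    is not (or only partially) decremented, leaving behind a resistant
    reactive floor i_R0.  With perfect blocking and per-cycle convergence
    each cycle increments i_R0 by x*alpha/(1-alpha).

    Returns the full trial records and the final i_R0 (the reactive
    response remaining after the last blocked-placebo block).
    """
    if n_cycles < 0 or n_active < 0 or n_blocked_placebo < 0:
        raise ProtocolConfigError("cycle counts must be non-negative")
    if params is None:
        params = ModelParams(alpha=alpha, precision_factor=0.0)
    else:
        params = replace(params, alpha=alpha)
    trials: list[Trial] = []
    for _ in range(n_cycles):
        trials.extend(Trial(kind="active", x=x) for _ in range(n_active))
        trials.extend(
            Trial(kind="placebo", error_blocked=True) for _ in range(n_blocked_placebo)
        )
    if not trials:
        return [], 0.0
    records = run_protocol(trials, params)
    return records, records[-1].i_R


def single_quantity_variant(x: float, n: int) -> np.ndarray:
    """Outcome trace of the collapsed one-quantity model (reductio model).

    In this variant a single quantity serves as both the predicted
    outcome and the reactive response: each trial's outcome is the
    previous prediction plus the active effect, and the prediction then
    converges to (here: equals) the experienced outcome.  The trace grows
    without bound, y_n = n*x — the numerical face of the theorem that a
    stable reactive system must encode prediction and reactive response
    as two distinct quantities.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    y = np.empty(n, dtype=float)
    predicted = 0.0
    for k in range(n):
        y[k] = predicted + x
        predicted = y[k]  # prediction converges to the experienced outcome
    return y
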