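"""Synthetic fixtures: pharmacodynamic curves, noise, canned scenarios.

No external data are needed anywhere in the package: stimulus time courses
are generated as single-peak absorption/elimination (two-exponential)
curves emulating a hormone-release-like response, observation noise is
additive Gaussian with a mandatory seed, and the packaged demonstration
scenario reproduces the reference simulation conditions (150-min trial
window, 10-min filter time constant, alpha = 0.45, five active trials
followed by placebo).
"""

from __future__ import annotations

import math

import numpy as np

from .continuous import ContinuousParams, ContinuousTrial, TimeCourse
from .discrete import ModelParams, ProtocolConfigError, State, Trial, run_protocol

__all__ = [
    "pk_curve",
    "add_noise",
    "fig1_scenario",
    "acquisition_protocol",
    "extinction_protocol",
    "hidden_protocol",
    "noisy_acquisition_trace",
]

# Illustrative absorption/elimination rates: peak at ln(ka/ke)/(ka-ke) ~ 51 min
# inside a 150-min window.  Free choices; nothing in the model pins them.
DEFAULT_K_ABS = 0.03
DEFAULT_K_ELIM = 0.012


def pk_curve(
    dose: float,
    k_abs: float = DEFAULT_K_ABS,
    k_elim: float = DEFAULT_K_ELIM,
    T0: float = 150.0,
    T_sample: float = 0.5,
) -> TimeCourse:
    """Single-peak two-exponential pharmacodynamic stimulus curve.

    v(t) proportional to exp(-k_elim t) - exp(-k_abs t) (absorption rate
    k_abs, elimination rate k_elim, both 1/min), normalized so the peak
    equals ``dose``.  The curve starts at 0 and is non-negative over the
    window [0, T0).  Equal rates fall back to the limiting t*exp(-k t)
    form.
    """
    if k_abs <= 0 or k_elim <= 0:
        raise ProtocolConfigError("rate constants must be > 0")
    t = np.arange(0.0, T0, T_sample)
    if math.isclose(k_abs, k_elim, rel_tol=1e-12):
        v = t * np.exp(-k_abs * t)
    else:
        v = np.exp(-k_elim * t) - np.exp(-k_abs * t)
        if k_abs < k_elim:
            v = -v
    peak = float(np.max(v))
    if peak <= 0.0:
        raise ProtocolConfigError("curve has no peak inside the window")
    return TimeCourse(t=t, v=dose * v / peak)


def add_noise(trace, sigma: float, seed: int):
    """Additive i.i.d. Gaussian observation noise, seeded.

    Accepts a numpy array or a :class:`TimeCourse`; returns the same
    type.  ``sigma = 0`` returns the input values unchanged; a given
    seed always produces the same output.
    """
    if sigma < 0:
        raise ProtocolConfigError(f"sigma must be >= 0, got {sigma}")
    if seed is None:
        raise ProtocolConfigError("seed is mandatory for noisy generation")
    if isinstance(trace, TimeCourse):
        return TimeCourse(t=trace.t, v=add_noise(trace.v, sigma, seed))
    v = np.asarray(trace, dtype=float)
    if sigma == 0:
        return v.copy()
    rng = np.random.default_rng(seed)
    return v + rng.normal(0.0, sigma, size=v.shape)


def fig1_scenario(
    n_placebo: int = 3,
    dose: float = 1.0,
    T_sample: float = 0.5,
) -> tuple[list[ContinuousTrial], ContinuousParams]:
    """Packaged demonstration scenario: hormone-release-like responses.

    Five open active administrations of a single-peak stimulus curve
    followed by placebo trials, with T0 = 150 min, tau = 10 min,
    alpha = 0.45 and a sampling step of at most tau/20 = 0.5 min.
    Returns (protocol, params).
    """
    params = ContinuousParams(alpha=0.45, tau=10.0, T0=150.0, T_sample=T_sample)
    curve = pk_curve(dose=dose, T0=params.T0, T_sample=params.T_sample)
    protocol = [ContinuousTrial(kind="active", x_curve=curve.v) for _ in range(5)]
    protocol += [ContinuousTrial(kind="placebo") for _ in range(n_placebo)]
    return protocol, params


def acquisition_protocol(n_trials: int, x: float = 1.0) -> list[Trial]:
    """n open active trials with constant magnitude x."""
    return [Trial(kind="active", x=x) for _ in range(n_trials)]


def extinction_protocol(n_trials: int) -> list[Trial]:
    """n placebo trials (to be run from an acquired state)."""
    return [Trial(kind="placebo") for _ in range(n_trials)]


def hidden_protocol(n_trials: int, x: float = 1.0) -> list[Trial]:
    """n hidden (covert) administrations of magnitude x."""
    return [Trial(kind="hidden", x=x) for _ in range(n_trials)]


def noisy_acquisition_trace(
    x: float,
    alpha: float,
    n_trials: int,
    sigma: float,
    seed: int,
    init_state: State | None = None,
) -> np.ndarray:
    """Observed y trace of an open acquisition run with Gaussian noise.

    The noise is observational: it perturbs the recorded responses, not
    the learner's internal dynamics.
    """
    records = run_protocol(
        acquisition_protocol(n_trials, x=x),
        ModelParams(alpha=alpha),
        init_state or State(),
    )
    y = np.array([r.y for r in records])
    return add_noise(y, sigma, seed)
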