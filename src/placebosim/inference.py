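"""Estimation of the model's quantities from administration traces.

The measurement program: hidden (covert) administrations expose the pure
pharmacological response x, because no reactive response is triggered;
open acquisition or extinction traces expose the reactive efficiency
alpha through their geometric structure.  Noiseless traces admit exact
recovery by successive-difference (or successive-ratio) computations;
noisy traces are fit by bounded nonlinear least squares on the closed
forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "UnderdeterminedError",
    "Estimate",
    "estimate_x_from_hidden",
    "estimate_alpha",
    "estimate_alpha_from_extinction",
    "decompose_open_response",
    "estimate_from_trace",
]

_EXACT_RTOL = 1e-9
_ALPHA_BOUND = 0.999


class UnderdeterminedError(ValueError):
    """The trace carries no information about the requested parameter."""


@dataclass(frozen=True)
class Estimate:
    """A scalar parameter estimate with its uncertainty."""

    value: float
    stderr: float
    n: int
    method: str = ""


def estimate_x_from_hidden(hidden_y) -> Estimate:
    """Active pharmacological magnitude from hidden-administration responses.

    Hidden administrations do not trigger the reactive response, so each
    response equals x (plus observation noise): the estimate is the
    sample mean with its standard error (0 for a single trial).
    """
    y = np.asarray(hidden_y, dtype=float)
    if y.size == 0:
        raise UnderdeterminedError("need at least one hidden-trial response")
    stderr = float(np.std(y, ddof=1) / math.sqrt(y.size)) if y.size > 1 else 0.0
    return Estimate(value=float(np.mean(y)), stderr=stderr, n=int(y.size), method="mean")


def _acquisition_model(n: np.ndarray, x: float, alpha: float) -> np.ndarray:
    # y_n = x (1 - alpha^n) / (1 - alpha); bounds keep alpha away from 1
    return x * (1.0 - alpha**n) / (1.0 - alpha)


def estimate_alpha(acquisition_y, return_x: bool = False) -> Estimate | tuple[Estimate, Estimate]:
    """Reactive efficiency from an open acquisition trace (constant x).

    On a noiseless trace the ratio of successive differences
    (y_{n+1} - y_n)/(y_n - y_{n-1}) equals alpha exactly and is returned
    directly.  When the ratios are not mutually consistent (noise), the
    closed form y_n = x (1 - alpha^n)/(1 - alpha) is fit by bounded
    nonlinear least squares over (x, alpha) with |alpha| < 0.999.
    """
    y = np.asarray(acquisition_y, dtype=float)
    if y.size < 3:
        raise UnderdeterminedError(
            f"need >= 3 open acquisition trials, got {y.size}"
        )
    d = np.diff(y)
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.all(np.abs(d) <= _EXACT_RTOL * scale):
        # flat trace: either alpha = 0 (y = x throughout) or no signal at all
        if np.all(np.abs(y) <= _EXACT_RTOL):
            raise UnderdeterminedError("flat all-zero trace: alpha is unidentifiable")
        alpha_est = Estimate(value=0.0, stderr=0.0, n=int(y.size), method="ratio")
        x_est = Estimate(value=float(y[0]), stderr=0.0, n=int(y.size), method="ratio")
        return (alpha_est, x_est) if return_x else alpha_est

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = d[1:] / d[:-1]
    finite = np.isfinite(ratios)
    if finite.all() and ratios.size > 0:
        r0 = float(ratios[0])
        if np.all(np.abs(ratios - r0) <= _EXACT_RTOL * max(1.0, abs(r0))):
            # exact geometric structure -> noiseless fast path
            alpha_hat = r0
            x_hat = float(y[0]) if alpha_hat != 1.0 else float(d[0])
            alpha_est = Estimate(value=alpha_hat, stderr=0.0, n=int(y.size), method="ratio")
            x_est = Estimate(value=x_hat, stderr=0.0, n=int(y.size), method="ratio")
            return (alpha_est, x_est) if return_x else alpha_est

    alpha0 = float(np.clip(np.nanmedian(ratios[finite]) if finite.any() else 0.0,
                           -0.9, 0.9))
    x0 = float(y[0]) if y[0] != 0.0 else float(np.mean(y))
    n_idx = np.arange(1, y.size + 1, dtype=float)
    popt, pcov = optimize.curve_fit(
        _acquisition_model, n_idx, y,
        p0=[x0, alpha0],
        bounds=([-np.inf, -_ALPHA_BOUND], [np.inf, _ALPHA_BOUND]),
        maxfev=10000,
    )
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    alpha_est = Estimate(value=float(popt[1]), stderr=float(perr[1]),
                         n=int(y.size), method="least_squares")
    x_est = Estimate(value=float(popt[0]), stderr=float(perr[0]),
                     n=int(y.size), method="least_squares")
    return (alpha_est, x_est) if return_x else alpha_est


def estimate_alpha_from_extinction(extinction_y) -> Estimate:
    """Reactive efficiency from successive placebo-trial responses.

    Extinction is geometric, y_{n+1}/y_n = alpha.  On a noiseless trace
    the ratio is returned exactly (a zero response makes the ratio
    undefined and is an error); on a noisy trace ln|y_n| is regressed on
    n (slope = ln|alpha|), with the sign of alpha taken from the sign
    pattern of the successive ratios.
    """
    y = np.asarray(extinction_y, dtype=float)
    if y.size < 2:
        raise UnderdeterminedError(
            f"need >= 2 placebo-trial responses, got {y.size}"
        )
    if np.any(y == 0.0):
        if np.all(y == 0.0):
            raise UnderdeterminedError("all-zero extinction trace: alpha is unidentifiable")
        raise UnderdeterminedError("zero response in trace: successive ratio undefined")
    ratios = y[1:] / y[:-1]
    r0 = float(ratios[0])
    if np.all(np.abs(ratios - r0) <= _EXACT_RTOL * max(1.0, abs(r0))):
        return Estimate(value=r0, stderr=0.0, n=int(y.size), method="ratio")

    n_idx = np.arange(y.size, dtype=float)
    fit = stats.linregress(n_idx, np.log(np.abs(y)))
    magnitude = math.exp(fit.slope)
    sign = -1.0 if np.median(ratios) < 0 else 1.0
    stderr = magnitude * float(fit.stderr)  # delta method on exp(slope)
    return Estimate(value=sign * magnitude, stderr=stderr,
                    n=int(y.size), method="loglinear")


def decompose_open_response(open_y, x_hat: float) -> np.ndarray:
    """Reactive (placebo) component of open responses: i_R_n = y_n - x_hat.

    The open-minus-hidden difference is the psychological (placebo)
    component of the response, even though no placebo was given.
    """
    return np.asarray(open_y, dtype=float) - float(x_hat)


def estimate_from_trace(trace: pd.DataFrame) -> pd.DataFrame:
    """Estimate x and alpha from a simulator trace table.

    Expects the trace CSV schema of the discrete simulator (columns
    ``kind`` and ``y`` at minimum).  Hidden rows give x; active rows
    (the open acquisition run) give alpha; placebo rows give an
    extinction-based alpha when available.  Returns a tidy results table
    (parameter, estimate, stderr, n_trials, method, note).
    """
    if "kind" not in trace.columns or "y" not in trace.columns:
        raise ValueError("trace must have 'kind' and 'y' columns")
    rows = []
    hidden = trace.loc[trace["kind"] == "hidden", "y"].to_numpy(dtype=float)
    if hidden.size:
        est = estimate_x_from_hidden(hidden)
        rows.append(("x", est.value, est.stderr, est.n, est.method, ""))

    open_y = trace.loc[trace["kind"] == "active", "y"].to_numpy(dtype=float)
    if open_y.size >= 3:
        try:
            alpha_est, x_est = estimate_alpha(open_y, return_x=True)
            rows.append(("alpha", alpha_est.value, alpha_est.stderr,
                         alpha_est.n, alpha_est.method, "acquisition"))
            if not hidden.size:
                rows.append(("x", x_est.value, x_est.stderr, x_est.n,
                             x_est.method, "from acquisition fit"))
        except UnderdeterminedError as exc:
            rows.append(("alpha", float("nan"), float("nan"), int(open_y.size),
                         "", f"underdetermined: {exc}"))
    elif open_y.size:
        rows.append(("alpha", float("nan"), float("nan"), int(open_y.size),
                     "", "need >= 3 open acquisition trials"))

    placebo = trace.loc[trace["kind"] == "placebo", "y"].to_numpy(dtype=float)
    if placebo.size >= 2:
        try:
            est = estimate_alpha_from_extinction(placebo)
            rows.append(("alpha", est.value, est.stderr, est.n,
                         est.method, "extinction"))
        except UnderdeterminedError as exc:
            rows.append(("alpha", float("nan"), float("nan"), int(placebo.size),
                         "", f"underdetermined: {exc}"))

    if not rows:
        raise UnderdeterminedError("trace contains no estimable trials")
    return pd.DataFrame(
        rows, columns=["parameter", "estimate", "stderr", "n_trials", "method", "note"]
    )
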