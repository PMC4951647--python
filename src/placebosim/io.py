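"""Config parsing and trace I/O.

Protocol configurations are YAML (JSON works too, being a YAML subset):

.. code-block:: yaml

    mode: discrete              # or "continuous"
    seed: 7                     # mandatory whenever noise.sigma > 0
    params:
      alpha: 0.5
      gamma_default: 0.0       # discrete only
      precision_factor: 1.0    # discrete only
      # continuous adds: tau, T0, T_sample, eta_plus, eta_minus
    init: {i_r: 0.0, expected: 0.0}     # discrete, optional
    noise: {sigma: 0.0}                 # optional
    trials:
      - kind: active            # active | placebo | hidden | virtual
        x: 1.0                  # discrete magnitude
        repeat: 3               # optional repetition shorthand
        # discrete optional: gamma, misattributed, baseline_shift,
        #                    error_blocked, simulated_outcome
        # continuous instead of x, one of:
        # curve: {constant: 1.0}
        # curve: {pk: {dose: 1.0, k_abs: 0.03, k_elim: 0.012}}
        # curve: {file: relative/or/absolute.csv}   # two columns: time_min,value

Traces are plain CSV, comma-separated, '.' decimal, header row, UTF-8.
The discrete trace has one row per trial (columns trial_index, kind, x,
gamma, misattributed, baseline_shift, expected, y, e, i_R); the
continuous trace is long-format with one row per trial and time bin
(trial_index, time_min, x, y, e, i_R).
"""

from __future__ import annotations

import os
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .continuous import ContinuousParams, ContinuousResult, ContinuousTrial, TimeCourse
from .discrete import ModelParams, State, Trial, TrialRecord, records_to_frame

__all__ = [
    "ConfigError",
    "load_config",
    "build_discrete_setup",
    "build_continuous_setup",
    "write_discrete_trace",
    "write_continuous_trace",
    "read_trace",
    "write_timecourse",
    "read_timecourse",
]


class ConfigError(ValueError):
    """A config file violates the schema; names the offending field."""

    def __init__(self, field: str, message: str):
        super().__init__(f"config field '{field}': {message}")
        self.field = field


def load_config(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("<root>", "config must be a mapping")
    return config


def _require_mapping(config: dict, key: str, default: dict | None = None) -> dict:
    value = config.get(key, default if default is not None else {})
    if not isinstance(value, dict):
        raise ConfigError(key, "must be a mapping")
    return value


def _float_field(mapping: dict, key: str, context: str, default: float | None = None) -> float:
    if key not in mapping:
        if default is None:
            raise ConfigError(f"{context}.{key}", "is required")
        return default
    value = mapping[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{context}.{key}", f"must be a number, got {value!r}")
    return float(value)


def _noise_and_seed(config: dict) -> tuple[float, int | None]:
    noise = _require_mapping(config, "noise")
    sigma = _float_field(noise, "sigma", "noise", default=0.0)
    if sigma < 0:
        raise ConfigError("noise.sigma", "must be >= 0")
    seed = config.get("seed")
    if sigma > 0 and seed is None:
        raise ConfigError("seed", "required when noise.sigma > 0 (no silent defaults)")
    if seed is not None and not isinstance(seed, int):
        raise ConfigError("seed", "must be an integer")
    return sigma, seed


def _expand_trials(config: dict) -> list[dict]:
    trials = config.get("trials")
    if not isinstance(trials, list) or not trials:
        raise ConfigError("trials", "must be a non-empty list")
    expanded: list[tuple[int, dict]] = []
    for i, entry in enumerate(trials):
        if not isinstance(entry, dict):
            raise ConfigError(f"trials[{i}]", "must be a mapping")
        repeat = entry.get("repeat", 1)
        if not isinstance(repeat, int) or repeat < 1:
            raise ConfigError(f"trials[{i}].repeat", "must be a positive integer")
        expanded.extend((i, entry) for _ in range(repeat))
    return expanded


_DISCRETE_TRIAL_KEYS = {
    "kind", "x", "gamma", "misattributed", "baseline_shift",
    "error_blocked", "simulated_outcome", "repeat",
}


def build_discrete_setup(config: dict) -> tuple[ModelParams, list[Trial], State, float, int | None]:
    """Parse a discrete-mode config into runnable objects.

    Returns (params, trials, init_state, noise_sigma, seed).
    """
    pmap = _require_mapping(config, "params")
    params = ModelParams(
        alpha=_float_field(pmap, "alpha", "params"),
        gamma_default=_float_field(pmap, "gamma_default", "params", default=0.0),
        precision_factor=_float_field(pmap, "precision_factor", "params", default=1.0),
    )
    init = _require_mapping(config, "init")
    init_state = State(
        i_R=_float_field(init, "i_r", "init", default=0.0),
        expected=_float_field(init, "expected", "init", default=0.0),
    )
    sigma, seed = _noise_and_seed(config)
    trials: list[Trial] = []
    for i, entry in _expand_trials(config):
        unknown = set(entry) - _DISCRETE_TRIAL_KEYS
        if unknown:
            raise ConfigError(f"trials[{i}]", f"unknown keys {sorted(unknown)}")
        kind = entry.get("kind", "active")
        try:
            trials.append(
                Trial(
                    kind=kind,
                    x=_float_field(entry, "x", f"trials[{i}]", default=0.0),
                    gamma=(
                        _float_field(entry, "gamma", f"trials[{i}]")
                        if "gamma" in entry else None
                    ),
                    misattributed=_float_field(entry, "misattributed", f"trials[{i}]", default=0.0),
                    baseline_shift=_float_field(entry, "baseline_shift", f"trials[{i}]", default=0.0),
                    error_blocked=bool(entry.get("error_blocked", False)),
                    simulated_outcome=(
                        _float_field(entry, "simulated_outcome", f"trials[{i}]")
                        if "simulated_outcome" in entry else None
                    ),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"trials[{i}]", str(exc)) from exc
    return params, trials, init_state, sigma, seed


def _resolve_curve(entry: dict, i: int, params: ContinuousParams, base_dir: str) -> np.ndarray | None:
    from .synthetic import pk_curve  # local import to avoid a cycle

    if "curve" not in entry:
        return None
    spec = entry["curve"]
    if not isinstance(spec, dict) or len(spec) != 1:
        raise ConfigError(
            f"trials[{i}].curve", "must be a mapping with exactly one of constant/pk/file"
        )
    (key, value), = spec.items()
    if key == "constant":
        return np.full(params.n_bins, float(value))
    if key == "pk":
        if not isinstance(value, dict):
            raise ConfigError(f"trials[{i}].curve.pk", "must be a mapping")
        curve = pk_curve(
            dose=_float_field(value, "dose", f"trials[{i}].curve.pk"),
            k_abs=_float_field(value, "k_abs", f"trials[{i}].curve.pk", default=0.03),
            k_elim=_float_field(value, "k_elim", f"trials[{i}].curve.pk", default=0.012),
            T0=params.T0,
            T_sample=params.T_sample,
        )
        return curve.v
    if key == "file":
        path = value if os.path.isabs(str(value)) else os.path.join(base_dir, str(value))
        tc = read_timecourse(path)
        if len(tc) != params.n_bins:
            raise ConfigError(
                f"trials[{i}].curve.file",
                f"curve has {len(tc)} samples, expected {params.n_bins}",
            )
        return tc.v
    raise ConfigError(f"trials[{i}].curve", f"unknown curve source {key!r}")


def build_continuous_setup(
    config: dict, base_dir: str = "."
) -> tuple[ContinuousParams, list[ContinuousTrial], float, int | None]:
    """Parse a continuous-mode config into runnable objects."""
    pmap = _require_mapping(config, "params")
    params = ContinuousParams(
        alpha=_float_field(pmap, "alpha", "params"),
        tau=_float_field(pmap, "tau", "params"),
        T0=_float_field(pmap, "T0", "params"),
        T_sample=_float_field(pmap, "T_sample", "params"),
        eta_plus=_float_field(pmap, "eta_plus", "params", default=0.5),
        eta_minus=_float_field(pmap, "eta_minus", "params", default=1.0),
        history_retention=_float_field(pmap, "history_retention", "params", default=0.0),
    )
    sigma, seed = _noise_and_seed(config)
    protocol: list[ContinuousTrial] = []
    for i, entry in _expand_trials(config):
        kind = entry.get("kind", "active")
        curve = _resolve_curve(entry, i, params, base_dir)
        protocol.append(ContinuousTrial(kind=kind, x_curve=curve))
    return params, protocol, sigma, seed


def write_discrete_trace(records: Sequence[TrialRecord], path: str | os.PathLike) -> None:
    records_to_frame(records).to_csv(path, index=False)


def continuous_result_to_frame(result: ContinuousResult) -> pd.DataFrame:
    """Long-format table: one row per (trial, time bin)."""
    frames = []
    for tr in result.trials:
        frames.append(
            pd.DataFrame(
                {
                    "trial_index": tr.index,
                    "time_min": tr.y.t,
                    "x": tr.x.v,
                    "y": tr.y.v,
                    "e": tr.e.v,
                    "i_R": tr.reactive.v,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_continuous_trace(result: ContinuousResult, path: str | os.PathLike) -> None:
    continuous_result_to_frame(result).to_csv(path, index=False)


def read_trace(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_timecourse(tc: TimeCourse, path: str | os.PathLike) -> None:
    pd.DataFrame({"time_min": tc.t, "value": tc.v}).to_csv(path, index=False)


def read_timecourse(path: str | os.PathLike) -> TimeCourse:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ConfigError("curve file", f"{path} must have two columns (time_min, value)")
    return TimeCourse(t=df.iloc[:, 0].to_numpy(float), v=df.iloc[:, 1].to_numpy(float))
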