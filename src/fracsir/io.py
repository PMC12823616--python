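"""Configuration files, trajectory serialization and comparison tables.

Config dialect: flat keys with dotted sections, accepted as YAML or JSON.
Scenario keys: beta, gamma, delta, alpha, tau, N, T and history.{S,I,R}
as polynomial coefficient lists in constant-first order.  Solver keys
live under ``solver.`` (J, db_order, method, tol, max_iter, interp_order).
Unknown keys are errors, not warnings: a silent typo in a rate name would
invalidate a run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .collocation import SolverConfig
from .delay import HistorySet
from .model import SIRParameters, default_scenario, SCENARIO_VARIANTS

__all__ = ["ConfigError", "load_config", "scenario_from_config",
           "solver_config_from_config", "write_trajectory_csv",
           "read_trajectory_csv", "write_diagnostics", "write_sweep_csv",
           "compare_table"]

_SCENARIO_KEYS = {"beta", "gamma", "delta", "alpha", "tau", "N", "T"}
_HISTORY_KEYS = {"history.S", "history.I", "history.R"}
_SOLVER_KEYS = {"solver.J", "solver.db_order", "solver.method", "solver.tol",
                "solver.max_iter", "solver.interp_order", "solver.n_output"}
_META_KEYS = {"scenario", "variant"}


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


def load_config(path) -> dict:
    """Read a YAML/JSON config into a flat dotted-key dict, strictly."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "config" in raw and isinstance(raw["config"], dict):
        raw = raw["config"]  # diagnostics sidecar: re-run from its config echo
    flat = _flatten(raw)
    allowed = _SCENARIO_KEYS | _HISTORY_KEYS | _SOLVER_KEYS | _META_KEYS
    unknown = sorted(set(flat) - allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {unknown}; allowed: {sorted(allowed)}")
    return flat


def scenario_from_config(flat: dict) -> tuple[SIRParameters, HistorySet]:
    """Build parameters and histories from a flat config dict."""
    if flat.get("scenario") == "default":
        variant = flat.get("variant")
        if variant not in SCENARIO_VARIANTS:
            raise ConfigError(
                "the built-in scenario requires an explicit "
                f"variant, one of {SCENARIO_VARIANTS}: the published history "
                "functions and benchmark-table starting values disagree on "
                "which compartment starts at 70"
            )
        overrides = {k: float(flat[k]) for k in ("beta", "gamma", "delta", "alpha", "T")
                     if k in flat}
        return default_scenario(variant, **overrides)
    missing = sorted((_SCENARIO_KEYS | _HISTORY_KEYS) - set(flat))
    if missing:
        raise ConfigError(f"scenario config missing keys: {missing}")
    try:
        params = SIRParameters(beta=float(flat["beta"]), gamma=float(flat["gamma"]),
                               delta=float(flat["delta"]), alpha=float(flat["alpha"]),
                               tau=float(flat["tau"]), N=float(flat["N"]),
                               T=float(flat["T"]))
        histories = HistorySet.from_polynomials(flat["history.S"], flat["history.I"],
                                                flat["history.R"], tau=params.tau)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scenario values: {exc}") from exc
    return params, histories


def solver_config_from_config(flat: dict, **overrides) -> SolverConfig:
    kw = {}
    mapping = {"solver.J": "J", "solver.db_order": "db_order",
               "solver.method": "method", "solver.tol": "residual_tol",
               "solver.max_iter": "max_iter", "solver.interp_order": "interp_order",
               "solver.n_output": "n_output"}
    for src, dst in mapping.items():
        if src in flat:
            kw[dst] = flat[src]
    kw.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("J", "db_order", "max_iter", "interp_order", "n_output"):
        if key in kw:
            kw[key] = int(kw[key])
    if "residual_tol" in kw:
        kw["residual_tol"] = float(kw["residual_tol"])
    try:
        return SolverConfig(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid solver settings: {exc}") from exc


def write_trajectory_csv(path, trajectory, precision: int = 6) -> None:
    """CSV with columns t, S, I, R at fixed decimal precision."""
    df = pd.DataFrame({"t": trajectory.times, "S": trajectory.S,
                       "I": trajectory.I, "R": trajectory.R})
    df.to_csv(path, index=False, float_format=f"%.{precision}f")


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["t", "S", "I", "R"]
    if list(df.columns) != expected:
        raise ConfigError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_diagnostics(path, solution, config_echo: dict, solver_name: str) -> None:
    """JSON sidecar that fully determines the run."""
    payload = {
        "solver": solver_name,
        "config": config_echo,
        "iterations": int(getattr(solution, "iterations", 0)),
        "residual_norm": float(getattr(solution, "residual_norm", float("nan"))),
        "conservation": float(getattr(solution, "conservation", float("nan"))),
        "converged": bool(getattr(solution, "converged", True)),
        "diagnostics": _jsonable(getattr(solution, "diagnostics", {})),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_sweep_csv(path, results, parameter_name: str,
                    precision: int = 6) -> None:
    """Long-format CSV: (parameter value, t, S, I, R) per converged solve."""
    frames = []
    for value, sol in results:
        if isinstance(sol, Exception):
            continue
        frames.append(pd.DataFrame({parameter_name: value, "t": sol.times,
                                    "S": sol.S, "I": sol.I, "R": sol.R}))
    if not frames:
        raise ValueError("sweep produced no converged solutions")
    pd.concat(frames).to_csv(path, index=False, float_format=f"%.{precision}f")


def compare_table(solutions, times, precision: int = 4) -> pd.DataFrame:
    """Side-by-side compartment table at the requested times.

    ``solutions`` is a list of (name, trajectory) pairs sharing a horizon;
    each trajectory is interpolated at ``times``.  With two or more
    solvers a max-absolute-difference column is appended per compartment.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    for name, sol in solutions:
        if times.max() > sol.times[-1] + 1e-9 or times.min() < sol.times[0] - 1e-9:
            raise ValueError(f"requested time outside the horizon of {name!r}")
    data = {"t": np.round(times, precision)}
    per_comp = {c: [] for c in "SIR"}
    for name, sol in solutions:
        S, I, R = sol.sample(times)
        for comp, vals in zip("SIR", (S, I, R)):
            col = f"{comp}_{name}"
            data[col] = np.round(vals, precision)
            per_comp[comp].append(vals)
    if len(solutions) > 1:
        for comp in "SIR":
            stack = np.vstack(per_comp[comp])
            data[f"{comp}_maxdiff"] = np.round(stack.max(axis=0) - stack.min(axis=0),
                                               precision)
    return pd.DataFrame(data)


def format_table(df: pd.DataFrame, precision: int = 4) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.{precision}f}")
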