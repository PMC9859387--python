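"""Configuration loading and table serialization.

Configuration is a flat YAML (or JSON — valid JSON is valid YAML) mapping.
Tables are written twice: at full float precision (round-trippable) and in a
companion "printed" variant with population counts rounded to 2 decimals and
percentage errors to 4 significant figures, the conventional presentation
for these tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .experiments import ErrorTable
from .model import ModelParameters
from .solvers import METHODS, Trajectory

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "write_error_table",
    "write_trajectory",
    "read_error_table",
]

ANCHOR_CHOICES = ("printed_t5", "equilibrium_offset", "explicit")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults reproducing the canonical
    setup: one-year step, 20-year horizon, default parameters, t=5 anchor."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    method: str = "rk4"
    dt: float = 1.0
    t_end: float = 20.0
    anchor: str = "printed_t5"
    anchor_C: float | None = None
    anchor_N: float | None = None
    offset_C: float = 500.0
    offset_N: float = 500.0
    out_dir: str = "results"
    seed: int = 0
    rounding: str = "full"  # "full" | "printed"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method: unknown method {self.method!r}")
        if self.dt <= 0:
            raise ConfigError(f"dt: must be > 0, got {self.dt}")
        if self.anchor not in ANCHOR_CHOICES:
            raise ConfigError(f"anchor: must be one of {ANCHOR_CHOICES}")
        if self.anchor == "explicit" and (self.anchor_C is None or self.anchor_N is None):
            raise ConfigError("anchor_c/anchor_n: required when anchor is 'explicit'")
        if self.rounding not in ("full", "printed"):
            raise ConfigError(f"rounding: must be 'full' or 'printed', got {self.rounding!r}")


_PARAM_KEYS = ("lambda", "delta", "mu", "gamma", "nu", "incidence")
_SCALAR_KEYS = {
    "method": str,
    "dt": float,
    "t_end": float,
    "anchor": str,
    "anchor_c": float,
    "anchor_n": float,
    "offset_c": float,
    "offset_n": float,
    "out_dir": str,
    "seed": int,
    "rounding": str,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat key-value config file.

    An empty file yields the full-default configuration.  Unknown keys and
    invalid values raise :class:`ConfigError` naming the key; a missing file
    raises :class:`FileNotFoundError`; unparseable YAML raises
    :class:`yaml.YAMLError`.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    params_kwargs: dict[str, float] = {}
    fields: dict[str, object] = {}
    for key, value in raw.items():
        if key in _PARAM_KEYS:
            try:
                params_kwargs[key] = float(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: not a number ({value!r})") from exc
        elif key in _SCALAR_KEYS:
            try:
                fields[key] = _SCALAR_KEYS[key](value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: invalid value ({value!r})") from exc
        else:
            raise ConfigError(f"{key}: unknown configuration key")
    try:
        parameters = ModelParameters.from_dict(params_kwargs) if params_kwargs else ModelParameters()
    except ValueError as exc:
        # name the offending parameter key in the error
        raise ConfigError(str(exc).replace("lambda_", "lambda")) from exc
    rename = {"anchor_c": "anchor_C", "anchor_n": "anchor_N", "offset_c": "offset_C", "offset_n": "offset_N"}
    kwargs = {rename.get(k, k): v for k, v in fields.items()}
    return RunConfig(parameters=parameters, **kwargs)  # type: ignore[arg-type]


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to a flat YAML file (round-trips with load_config)."""
    data: dict[str, object] = dict(config.parameters.to_dict())
    for f in dataclasses.fields(RunConfig):
        if f.name == "parameters":
            continue
        value = getattr(config, f.name)
        if value is None:
            continue
        key = {"anchor_C": "anchor_c", "anchor_N": "anchor_n",
               "offset_C": "offset_c", "offset_N": "offset_n"}.get(f.name, f.name)
        data[key] = value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _printed_path(path: Path) -> Path:
    return path.with_name(path.stem + "_printed" + path.suffix)


def _fmt_pct(err: float) -> str:
    return "0.0000%" if err == 0 else f"{err:.4g}%"


def write_error_table(table: ErrorTable, path: str | Path) -> Path:
    """Write an error table as CSV, full precision plus a printed variant.

    The full-precision file carries the documented column schema
    (t, C_num, C_true, err_C_pct, N_num, N_true, err_N_pct) with a trailing
    average-error row; the ``*_printed`` companion rounds counts to 2
    decimals and errors to 4 significant figures.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = table.with_average_row()
    frame.to_csv(path, index=False)

    printed = frame.copy()
    for col in ("C_num", "C_true", "N_num", "N_true"):
        printed[col] = printed[col].map(lambda v: "" if pd.isna(v) else f"{v:,.2f}")
    for col in ("err_C_pct", "err_N_pct"):
        printed[col] = printed[col].map(lambda v: "" if pd.isna(v) else _fmt_pct(v))
    printed["t"] = printed["t"].map(lambda v: "Avg." if pd.isna(v) else f"{v:g}")
    printed.to_csv(_printed_path(path), index=False)
    return path


def read_error_table(path: str | Path) -> pd.DataFrame:
    """Read back a full-precision error-table CSV bit-exactly."""
    return pd.read_csv(path, float_precision="round_trip")


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as CSV (t, C, N, D, method, dt), full precision,
    plus a printed companion rounded to 2 decimals."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "t": traj.times,
            "C": traj.C,
            "N": traj.N,
            "D": traj.N - traj.C,
            "method": traj.method,
            "dt": traj.dt,
        }
    )
    frame.to_csv(path, index=False)
    printed = frame.copy()
    for col in ("C", "N", "D"):
        printed[col] = printed[col].map(lambda v: f"{v:,.2f}")
    printed.to_csv(_printed_path(path), index=False)
    return path
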