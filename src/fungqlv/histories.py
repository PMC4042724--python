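"""Deformation/load histories on uniform time grids, fixtures, and I/O.

Histories are sampled on a uniform grid t_0 = 0 < t_1 < ... < t_N with the
identity (or zero-load) pre-history for t < 0.  A step imposed at t = 0 is
represented by its t = 0+ value at the first node; the integrated-by-parts
form of the QLV law then carries the jump through the instantaneous term.

The protocol generator produces the ramp-hold(-release) and smooth test
shapes used throughout the examples and tests, emulating the kind of
slowly varying stretch and load programmes applied to soft-tissue
specimens (ramp over ~1 s to a stretch of ~1.5 against a relaxation time
of 1 s, then hold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .materials import MaterialModel
from .relaxation import ReducedRelaxation

__all__ = [
    "UniaxialHistory",
    "DiagonalHistory",
    "StressHistory",
    "ProtocolSpec",
    "generate_history",
    "read_history",
    "write_history",
    "load_material",
    "load_relaxation",
    "load_config",
]

_GRID_RTOL = 1e-12


def check_uniform_grid(times: np.ndarray) -> float:
    """Validate a uniform grid starting at 0; return the step."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("a history needs a one-dimensional, non-empty time grid")
    if abs(times[0]) > 0.0:
        raise ValueError("the first node must be at t = 0")
    if times.size == 1:
        return 0.0
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    dt = times[-1] / (times.size - 1)
    if np.max(np.abs(steps - dt)) > _GRID_RTOL * max(dt, 1.0):
        raise ValueError("time grid must be uniform")
    return float(dt)


@dataclass(frozen=True)
class UniaxialHistory:
    """Imposed axial stretch lambda(t) on a uniform grid (identity pre-history)."""

    times: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        check_uniform_grid(times)
        if lam.shape != times.shape:
            raise ValueError("lambda history must match the time grid")
        if np.any(lam <= 0):
            raise ValueError("stretches must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "lam", lam)

    @property
    def dt(self) -> float:
        return check_uniform_grid(self.times)

    def incompressible_diagonal(self) -> "DiagonalHistory":
        lat = self.lam ** -0.5
        return DiagonalHistory(self.times, np.stack([self.lam, lat, lat], axis=1))


@dataclass(frozen=True)
class DiagonalHistory:
    """Principal-stretch history (N, 3) for a diagonal deformation gradient."""

    times: np.ndarray
    stretches: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        s = np.asarray(self.stretches, dtype=float)
        check_uniform_grid(times)
        if s.shape != (times.size, 3):
            raise ValueError("stretches must have shape (n_nodes, 3)")
        if np.any(s <= 0):
            raise ValueError("stretches must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stretches", s)

    @property
    def dt(self) -> float:
        return check_uniform_grid(self.times)


@dataclass(frozen=True)
class StressHistory:
    """Axial Cauchy stress history; optionally the full diagonal (N, 3)."""

    times: np.ndarray
    T: np.ndarray
    diagonal: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        T = np.asarray(self.T, dtype=float)
        check_uniform_grid(times)
        if T.shape != times.shape:
            raise ValueError("stress history must match the time grid")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "T", T)
        if self.diagonal is not None:
            d = np.asarray(self.diagonal, dtype=float)
            if d.shape != (times.size, 3):
                raise ValueError("diagonal stress must have shape (n_nodes, 3)")
            object.__setattr__(self, "diagonal", d)

    @property
    def dt(self) -> float:
        return check_uniform_grid(self.times)


PROTOCOL_KINDS = ("step", "ramp_hold", "ramp_hold_release", "smooth_pulse", "random_smooth")


@dataclass(frozen=True)
class ProtocolSpec:
    """Recipe for a canonical test history.

    ``amplitude`` is the increment above rest (stretch 1 + amplitude, or a
    stress of ``amplitude`` in units of mu).  Ramp and hold times are in
    seconds; the grid has ``n_nodes`` nodes and ends at
    ``ramp_time + hold_time`` (+ another ramp and hold for the release
    kinds).  ``seed`` only affects ``random_smooth``.
    """

    kind: str
    amplitude: float = 0.5
    ramp_time: float = 1.0
    hold_time: float = 1.0
    n_nodes: int = 201
    seed: int = 0
    stress: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol {self.kind!r}; choose from {PROTOCOL_KINDS}")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.ramp_time <= 0 or self.hold_time < 0:
            raise ValueError("ramp_time must be positive and hold_time nonnegative")
        if not self.stress and self.amplitude <= -1.0:
            raise ValueError("amplitude would drive the stretch non-positive")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """C^1 ramp 0 -> 1 on [0, 1] (cosine shape, zero end slopes)."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def generate_history(spec: ProtocolSpec):
    """Build the history described by ``spec``.

    Returns a :class:`UniaxialHistory` (baseline stretch 1) or, when
    ``spec.stress`` is set, a :class:`StressHistory` (baseline 0).
    Deterministic given the spec (and seed).
    """
    tr, th, a = spec.ramp_time, spec.hold_time, spec.amplitude
    if spec.kind in ("ramp_hold_release", "smooth_pulse"):
        t_end = 2.0 * tr + 2.0 * th
    else:
        t_end = tr + th
    times = np.linspace(0.0, t_end, spec.n_nodes)

    if spec.kind == "step":
        profile = np.full(times.shape, a)
    elif spec.kind == "ramp_hold":
        profile = a * np.minimum(times / tr, 1.0)
    elif spec.kind == "ramp_hold_release":
        # up over tr, hold th, down over tr, rest at baseline
        up = np.minimum(times / tr, 1.0)
        down = np.clip((times - tr - th) / tr, 0.0, 1.0)
        profile = a * (up - down)
    elif spec.kind == "smooth_pulse":
        up = _smoothstep(times / tr)
        down = _smoothstep((times - tr - th) / tr)
        profile = a * (up - down)
    else:  # random_smooth
        rng = np.random.default_rng(spec.seed)
        n_modes = 4
        coef = rng.standard_normal(n_modes) / np.arange(1, n_modes + 1)
        phase = np.pi * times[:, None] * np.arange(1, n_modes + 1) / t_end
        raw = np.sin(phase) @ coef
        scale = np.max(np.abs(raw))
        profile = a * _smoothstep(times / tr) * raw / (scale if scale > 0 else 1.0)

    if spec.stress:
        return StressHistory(times, profile)
    lam = 1.0 + profile
    if np.any(lam <= 0):
        raise ValueError("amplitude drives the stretch non-positive")
    return UniaxialHistory(times, lam)


# ---------------------------------------------------------------------------
# CSV I/O: comma-separated, header row, '.' decimal.

def write_history(history, path) -> None:
    """Write a history to CSV (columns named by content)."""
    if isinstance(history, UniaxialHistory):
        df = pd.DataFrame({"time": history.times, "lambda": history.lam})
    elif isinstance(history, StressHistory):
        df = pd.DataFrame({"time": history.times, "T_over_mu": history.T})
        if history.diagonal is not None:
            for j in range(3):
                df[f"T{j + 1}{j + 1}_over_mu"] = history.diagonal[:, j]
    elif isinstance(history, DiagonalHistory):
        df = pd.DataFrame({"time": history.times,
                           "lambda1": history.stretches[:, 0],
                           "lambda2": history.stretches[:, 1],
                           "lambda3": history.stretches[:, 2]})
    else:
        raise TypeError(f"cannot write a {type(history).__name__}")
    df.to_csv(path, index=False)


def read_history(path, kind: str = "auto"):
    """Read a history CSV written by :func:`write_history` (or compatible).

    ``kind`` may be ``"stretch"``, ``"stress"``, ``"diagonal"`` or ``"auto"``
    (inferred from the column names).  The grid must be uniform and start
    at t = 0; parse failures name the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty history file") from exc
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError(f"{path}: a history needs a header plus >= 1 rows of >= 2 columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(np.argmax((bad | df[col].isna()).to_numpy())) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric or missing value in column "
                             f"{col!r} at line {line}")
    cols = [c.lower() for c in df.columns]
    if "time" not in cols:
        raise ValueError(f"{path}: missing 'time' column")
    times = df[df.columns[cols.index("time")]].to_numpy(dtype=float)
    try:
        check_uniform_grid(times)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc

    def col(name):
        return df[df.columns[cols.index(name)]].to_numpy(dtype=float)

    if kind == "auto":
        if "lambda1" in cols:
            kind = "diagonal"
        elif "lambda" in cols:
            kind = "stretch"
        else:
            kind = "stress"
    if kind == "stretch":
        if "lambda" not in cols:
            raise ValueError(f"{path}: missing 'lambda' column")
        return UniaxialHistory(times, col("lambda"))
    if kind == "diagonal":
        if not all(c in cols for c in ("lambda1", "lambda2", "lambda3")):
            raise ValueError(f"{path}: missing lambda1/lambda2/lambda3 columns")
        return DiagonalHistory(times, np.stack(
            [col("lambda1"), col("lambda2"), col("lambda3")], axis=1))
    if kind == "stress":
        name = "t_over_mu" if "t_over_mu" in cols else None
        if name is None:
            # fall back to the second column
            name = cols[1] if cols[0] == "time" else cols[0]
        return StressHistory(times, col(name))
    raise ValueError(f"unknown history kind {kind!r}")


# ---------------------------------------------------------------------------
# Configuration (YAML or JSON; JSON is a YAML subset).

def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def load_material(source) -> MaterialModel:
    """Build a :class:`MaterialModel` from a mapping or a YAML/JSON file.

    Keys: ``model`` (required), ``mu`` (default 1, i.e. stresses in units
    of mu), ``alpha``, ``gamma``, ``kappa``, ``Jm``.
    """
    data = source if isinstance(source, dict) else _load_mapping(source)
    if "material" in data:
        data = data["material"]
    if "model" not in data:
        raise ValueError("material config needs a 'model' key")
    kwargs = {"name": str(data["model"])}
    for key in ("mu", "alpha", "gamma", "kappa", "Jm"):
        if key in data and data[key] is not None:
            kwargs[key] = float(data[key])
    m = MaterialModel(**kwargs)
    if "incompressible" in data and bool(data["incompressible"]) != m.incompressible:
        raise ValueError(f"model {m.name!r} is "
                         f"{'in' if m.incompressible else ''}compressible by construction")
    return m


def load_relaxation(source, kind: str = "D") -> ReducedRelaxation:
    """Build a :class:`ReducedRelaxation` from a mapping or file.

    Keys: ``long_time_ratio`` and ``terms`` (list of ``{g, tau}``); a
    single-term shorthand ``tau`` is accepted.  Times in seconds.
    """
    data = source if isinstance(source, dict) else _load_mapping(source)
    ratio = float(data.get("long_time_ratio", 1.0))
    if "terms" in data and data["terms"]:
        terms = tuple((float(t["g"]), float(t["tau"])) for t in data["terms"])
        return ReducedRelaxation(ratio, terms, kind=str(data.get("kind", kind)))
    if "tau" in data and ratio < 1.0:
        return ReducedRelaxation.one_term(ratio, float(data["tau"]),
                                          kind=str(data.get("kind", kind)))
    return ReducedRelaxation(ratio, (), kind=str(data.get("kind", kind)))


def load_config(path):
    """Load a full run configuration: (material, D, H).

    The file may carry ``material``, ``relaxation`` (shear, D) and
    ``bulk_relaxation`` (H) sections; flat material keys are also accepted.
    When ``bulk_relaxation`` is absent, H defaults to the same parameters
    as D (a documented choice -- the volumetric relaxation is never
    specified by the underlying model catalog).
    """
    data = _load_mapping(path)
    material = load_material(data.get("material", data))
    relax = data.get("relaxation", {})
    D = load_relaxation(relax, kind="D")
    if "bulk_relaxation" in data:
        H = load_relaxation(data["bulk_relaxation"], kind="H")
    else:
        H = ReducedRelaxation(D.long_time_ratio, D.terms, kind="H")
    return material, D, H
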