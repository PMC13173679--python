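"""Model parameters, states, trajectories, and parameter-file I/O.

The model couples three state variables: blooming-plant density ``p``,
honeybee density ``h``, and the standing amount of honey ``n``.  Its
fifteen rate/capacity parameters are held in :class:`ModelParams`.
Parameter files come in two equivalent flavours: flat ``name = value``
text and a JSON object; both use the transliterated key names below
(``alpha1`` for the plants' benefit rate, ``gamma1`` for the plant
depletion rate, and so on).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

#: Canonical parameter order used by files, arrays, and reports.
PARAM_NAMES: tuple[str, ...] = (
    "r1", "k1", "alpha1", "w", "a", "b", "gamma1",
    "r2", "k2", "alpha2", "gamma2", "alpha3", "beta", "gamma3", "c",
)

# Parameters that must be strictly positive (capacities, growth rates,
# and the honey-loss rate, which divides several closed forms).
_STRICTLY_POSITIVE = frozenset({"r1", "k1", "r2", "k2", "gamma3"})


@dataclass(frozen=True)
class ModelParams:
    """The fifteen nonnegative rates and capacities of the model.

    Parameters
    ----------
    r1, k1, gamma1 : plant intrinsic growth rate, carrying capacity and
        depletion rate.
    alpha1 : benefit of honeybees to plants (pollination service).
    w : wind-flow level (dimensionless, >= 0).
    a : undepleted-equilibrium rate of the plant-bee interaction.
    b : intensity of bee competition for floral resources.
    r2, k2, gamma2 : honeybee intrinsic growth rate, carrying capacity
        and depletion rate.
    alpha2 : nutrient value of plants to bees.
    alpha3 : honey production rate; c : its half-saturation rate.
    beta : honey consumption rate by bees.
    gamma3 : natural honey-loss rate.
    """

    r1: float
    k1: float
    alpha1: float
    w: float
    a: float
    b: float
    gamma1: float
    r2: float
    k2: float
    alpha2: float
    gamma2: float
    alpha3: float
    beta: float
    gamma3: float
    c: float

    def __post_init__(self) -> None:
        problems = []
        for name in PARAM_NAMES:
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                problems.append(f"{name}={value!r} is not a number")
                continue
            object.__setattr__(self, name, value)
            if not math.isfinite(value):
                problems.append(f"{name}={value} is not finite")
            elif value < 0:
                problems.append(f"{name}={value} is negative")
            elif value == 0 and name in _STRICTLY_POSITIVE:
                problems.append(f"{name} must be strictly positive")
        if problems:
            raise ValueError("invalid model parameters: " + "; ".join(problems))

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])


@dataclass(frozen=True)
class State:
    """A point (p, h, n) in the nonnegative octant."""

    p: float
    h: float
    n: float

    def __post_init__(self) -> None:
        for name in ("p", "h", "n"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"state component {name}={value} outside the nonnegative octant"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.h, self.n])


def as_state_array(state: "State | Sequence[float] | np.ndarray") -> np.ndarray:
    """Coerce a State / length-3 sequence to a float array, no validation."""
    if isinstance(state, State):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"state must have exactly 3 components, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed solution: ``states[i]`` is (p, h, n) at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if states.ndim != 2 or states.shape[1] != 3:
            raise ValueError("states must have shape (n_times, 3)")
        if len(times) != len(states):
            raise ValueError("times and states must have equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def h(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def n(self) -> np.ndarray:
        return self.states[:, 2]

    def final_state(self) -> np.ndarray:
        return self.states[-1]


# ---------------------------------------------------------------------------
# Parameter file I/O


def _params_from_mapping(mapping: dict) -> ModelParams:
    keys = set(mapping)
    expected = set(PARAM_NAMES)
    problems = []
    for name in sorted(expected - keys):
        problems.append(f"missing key: {name}")
    for name in sorted(keys - expected):
        problems.append(f"unknown key: {name}")
    if problems:
        raise ValueError("bad parameter file: " + "; ".join(problems))
    return ModelParams(**{k: mapping[k] for k in PARAM_NAMES})


def parse_params_text(text: str) -> ModelParams:
    """Parse either a JSON object or flat ``name = value`` lines."""
    stripped = text.lstrip()
    if stripped.startswith("{"):
        mapping = json.loads(text)
        if not isinstance(mapping, dict):
            raise ValueError("JSON parameter file must contain a single object")
        return _params_from_mapping(mapping)
    mapping: dict[str, float] = {}
    problems = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            problems.append(f"line {lineno}: expected 'name = value', got {raw!r}")
            continue
        name, _, value = line.partition("=")
        name = name.strip()
        try:
            mapping[name] = float(value.strip())
        except ValueError:
            problems.append(f"line {lineno}: non-numeric value for {name}: {value.strip()!r}")
    if problems:
        raise ValueError("bad parameter file: " + "; ".join(problems))
    return _params_from_mapping(mapping)


def load_params(path) -> ModelParams:
    """Load a :class:`ModelParams` from a key-value or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_params_text(fh.read())


def save_params(params: ModelParams, path, fmt: str = "kv") -> None:
    """Write a parameter file (``fmt`` is ``"kv"`` or ``"json"``)."""
    if fmt == "json":
        text = json.dumps(params.as_dict(), indent=2) + "\n"
    elif fmt == "kv":
        text = "".join(f"{k} = {getattr(params, k)!r}\n" for k in PARAM_NAMES)
    else:
        raise ValueError(f"unknown parameter file format: {fmt!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def baseline_params() -> ModelParams:
    """The shipped baseline parameter set used throughout the docs/tests."""
    with resources.files("beebloom.data").joinpath("baseline.params").open(
        "r", encoding="utf-8"
    ) as fh:
        return parse_params_text(fh.read())
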