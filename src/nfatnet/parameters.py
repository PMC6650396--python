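"""Named kinetic constants with biological range metadata.

Ranges default by parameter-name prefix to the biologically plausible bounds
used for fitting and sampling: association rates ka in [1e-4, 1e4]
(nM^-1 min^-1), dissociation/first-order rates kd in [1e-4, 1e4] (min^-1),
catalytic rates kc in [1e-4, 1e5] (min^-1), maximal velocities V in
[1e-4, 1e4] (nM min^-1) and Michaelis/activation constants Km/Ka in
[1e-4, 1e5] (nM). Degradation constants (kdeg) are bounded to [1e-4, 1e-2]
min^-1, i.e. protein/transcript half-lives of roughly 1-115 h; basal
synthesis rates to [1e-6, 1e1] nM min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

DEFAULT_RANGES: tuple[tuple[str, tuple[float, float]], ...] = (
    ("ka_", (1e-4, 1e4)),
    ("kd_", (1e-4, 1e4)),
    ("kc_", (1e-4, 1e5)),
    ("V_", (1e-4, 1e4)),
    ("Km_", (1e-4, 1e5)),
    ("Ka_", (1e-4, 1e5)),
    ("kI_", (1e-4, 1e4)),
    ("kdeg_", (1e-4, 1e-2)),
    ("basal_", (1e-6, 1e1)),
)


def default_range(name: str) -> tuple[float, float]:
    for prefix, rng in DEFAULT_RANGES:
        if name.startswith(prefix):
            return rng
    return (1e-4, 1e4)


class ParameterError(KeyError):
    """A referenced kinetic constant is missing or out of range."""


@dataclass
class ParameterSet:
    """Ordered name -> value map, the unit of fitting, sampling and perturbation."""

    values: dict[str, float]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: str = "fitted"  # fitted | sampled | imported

    def __post_init__(self) -> None:
        for name in self.values:
            self.ranges.setdefault(name, default_range(name))
        for name, v in self.values.items():
            lo, hi = self.ranges[name]
            if not (v > 0 and np.isfinite(v)):
                raise ParameterError(f"{name} = {v}: constants must be positive and finite")
            if not (lo <= v <= hi):
                raise ParameterError(f"{name} = {v} outside range [{lo}, {hi}]")

    # -- basic access ----------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"missing parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def as_array(self, order: Iterable[str]) -> np.ndarray:
        return np.array([self[n] for n in order], dtype=float)

    def copy(self, provenance: str | None = None) -> "ParameterSet":
        return ParameterSet(
            dict(self.values), dict(self.ranges), provenance or self.provenance
        )

    # -- derived sets ----------------------------------------------------
    def scaled(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Multiply selected constants by factors, clipping into their ranges."""
        new = dict(self.values)
        for name, f in factors.items():
            if name not in new:
                raise ParameterError(f"cannot scale unknown parameter {name!r}")
            lo, hi = self.ranges[name]
            new[name] = float(np.clip(new[name] * f, lo, hi))
        return ParameterSet(new, dict(self.ranges), self.provenance)

    def jittered(self, spread: float, rng: np.random.Generator) -> "ParameterSet":
        """Every constant multiplied by an independent Uniform[1-spread, 1+spread] factor."""
        if spread < 0:
            raise ValueError("spread must be >= 0")
        new = {}
        for name, v in self.values.items():
            lo, hi = self.ranges[name]
            new[name] = float(np.clip(v * rng.uniform(1 - spread, 1 + spread), lo, hi))
        return ParameterSet(new, dict(self.ranges), "sampled")

    def log_uniform_sample(self, rng: np.random.Generator) -> "ParameterSet":
        """Independent log-uniform draw of every constant within its range."""
        new = {}
        for name in self.values:
            lo, hi = self.ranges[name]
            new[name] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        return ParameterSet(new, dict(self.ranges), "sampled")

    # -- log10 vector view (GA search space) -----------------------------
    def to_log_vector(self, free: Iterable[str]) -> np.ndarray:
        return np.log10(self.as_array(free))

    def with_log_vector(self, free: Iterable[str], x: np.ndarray) -> "ParameterSet":
        new = dict(self.values)
        for name, xi in zip(free, x):
            lo, hi = self.ranges[name]
            new[name] = float(np.clip(10.0**xi, lo, hi))
        return ParameterSet(new, dict(self.ranges), "fitted")

    def log_bounds(self, free: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        los, his = [], []
        for name in free:
            lo, hi = self.ranges[name]
            los.append(np.log10(lo))
            his.append(np.log10(hi))
        return np.array(los), np.array(his)
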