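"""Synthetic fixture data for calibration and parameter-recovery studies.

The fixture generator emulates the qualitative single-pulse response shapes
of the measured network components: phosphorylated TCR/MEK/ERK rise and
fall within minutes (peak at 5 min), NFAT activity peaks around an hour,
IL-2 (protein and mRNA) is a slow transient, while TNFa and CTLA-4 rise
slowly and stay up. Curves are differences of exponentials with an optional
sustained plateau, normalized to a maximum of 1, with multiplicative
Gaussian noise — deliberately smooth stand-ins, not digitized measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .calibration import CalibrationTarget
from .engine import find_baseline, simulate
from .network import NetworkModel
from .parameters import ParameterSet
from .stimulation import StimulusProtocol


@dataclass(frozen=True)
class ShapeSpec:
    """Double-exponential pulse: peak position, decay scale, plateau level."""

    peak_time_h: float
    decay_ratio: float = 6.0  # decay timescale / rise timescale
    sustained_fraction: float = 0.0  # 0 transient .. 1 fully sustained

    def __post_init__(self) -> None:
        if self.peak_time_h <= 0:
            raise ValueError("peak_time_h must be > 0")
        if not 0 <= self.sustained_fraction <= 1:
            raise ValueError("sustained_fraction must be in [0, 1]")


#: default shapes for the measured components after a single stimulation
DEFAULT_SHAPES: dict[str, ShapeSpec] = {
    "pTCR": ShapeSpec(peak_time_h=5 / 60),
    "pMEK": ShapeSpec(peak_time_h=5 / 60),
    "pERK": ShapeSpec(peak_time_h=5 / 60),
    "NFATnuc": ShapeSpec(peak_time_h=1.0),
    "IL2": ShapeSpec(peak_time_h=10.0, decay_ratio=2.5),
    "IL2mRNA": ShapeSpec(peak_time_h=6.0),
    "TNFa": ShapeSpec(peak_time_h=8.0, sustained_fraction=1.0),
    "CTLA4": ShapeSpec(peak_time_h=8.0, sustained_fraction=1.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    shapes: dict[str, ShapeSpec] = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    noise_sd: float = 0.05  # relative (multiplicative) noise
    seed: int = 0
    horizon_h: float = 48.0
    n_points: int = 25


def _pulse_shape(t: np.ndarray, spec: ShapeSpec) -> np.ndarray:
    """Normalized response curve with its continuous argmax at peak_time_h."""
    tau_d = spec.decay_ratio * spec.peak_time_h

    def peak_of(tau_r: float) -> float:
        return np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)

    tau_r = brentq(lambda x: peak_of(x) - spec.peak_time_h,
                   1e-6 * spec.peak_time_h, 0.999 * tau_d)
    pulse = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    pulse /= np.exp(-spec.peak_time_h / tau_d) - np.exp(-spec.peak_time_h / tau_r)
    rise = 1.0 - np.exp(-t / spec.peak_time_h)
    s = spec.sustained_fraction
    curve = (1.0 - s) * pulse + s * rise
    return curve / curve.max()


def fixture_grid(spec: FixtureSpec) -> np.ndarray:
    """Sampling times: dense over the first hour, geometric afterwards."""
    early = np.array([0.0, 2, 5, 10, 20, 30, 45, 60]) / 60.0
    late = np.geomspace(1.5, spec.horizon_h, max(spec.n_points - len(early), 4))
    peaks = [s.peak_time_h for s in spec.shapes.values()]
    return np.unique(np.concatenate([early, late, peaks]))


def generate_fixture_timecourses(spec: FixtureSpec = FixtureSpec()) -> list[CalibrationTarget]:
    """Fixture calibration targets, one per species in the spec, max-normalized."""
    rng = np.random.default_rng(spec.seed)
    t = fixture_grid(spec)
    targets = []
    for species, shape in spec.shapes.items():
        curve = _pulse_shape(t, shape)
        if spec.noise_sd > 0:
            curve = np.maximum(curve * (1.0 + spec.noise_sd * rng.standard_normal(len(t))), 0.0)
        targets.append(CalibrationTarget(species=species, times=t, values=curve))
    return targets


def targets_to_frame(targets: list[CalibrationTarget]) -> pd.DataFrame:
    rows = []
    for tg in targets:
        for t, v in zip(tg.times, tg.values):
            rows.append({"species": tg.species, "time_h": t, "value": v, "weight": tg.weight})
    return pd.DataFrame(rows)


def targets_from_frame(df: pd.DataFrame) -> list[CalibrationTarget]:
    out = []
    for species, grp in df.groupby("species", sort=False):
        out.append(
            CalibrationTarget(
                species=str(species),
                times=grp["time_h"].to_numpy(),
                values=grp["value"].to_numpy(),
                weight=float(grp["weight"].iloc[0]) if "weight" in grp else 1.0,
            )
        )
    return out


def generate_ground_truth(
    model: NetworkModel,
    true_params: ParameterSet,
    protocol: StimulusProtocol,
    noise_sd: float = 0.05,
    seed: int = 0,
    species: list[str] | None = None,
    times: np.ndarray | None = None,
) -> tuple[ParameterSet, list[CalibrationTarget]]:
    """Simulate the model at known parameters and return noisy sampled targets.

    The paired return (truth, targets) is the scoring surface for
    parameter-recovery tests of the calibration machinery.
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.unique(np.concatenate(
            [np.geomspace(0.1, protocol.horizon, 30), [protocol.horizon]]))
    baseline = find_baseline(model, true_params)
    traj = simulate(model, true_params, protocol, baseline=baseline)
    names = species if species is not None else list(model.species_names)
    targets = []
    for sp in names:
        clean = np.interp(times, traj.time_h, traj.series(sp))
        noisy = clean if noise_sd == 0 else np.maximum(
            clean * (1.0 + noise_sd * rng.standard_normal(len(times))), 0.0)
        targets.append(CalibrationTarget(species=sp, times=times, values=noisy))
    return true_params, targets
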