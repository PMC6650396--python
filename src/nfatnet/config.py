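"""Run configuration: model source, protocol, tolerances, seeds.

A :class:`RunConfig` can be built programmatically or loaded from a YAML
file; every field has a documented default, and the resolved configuration
is echoed into each run's log so that any result is reproducible from its
output directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class ProtocolConfig:
    amp1: float = 1.0  # primary pulse height, x nominal MHC strength
    amp2_fold: float = 1.0  # secondary amplitude = amp1 / amp2_fold
    interval_h: float = 48.0
    duration_h: float = 1.0
    horizon_h: float = 96.0
    cni_dose_nm: float = 0.0


@dataclass
class RunConfig:
    model: str = "full"  # full | reduced | path to an SBML file
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file {path} does not exist")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        proto = ProtocolConfig(**raw.pop("protocol", {}))
        cfg = cls(protocol=proto, **raw)
        if cfg.model not in ("full", "reduced") and not Path(cfg.model).exists():
            raise FileNotFoundError(f"model source {cfg.model!r} does not exist")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def build(self):
        """Resolve (model, params) from the configured source."""
        if self.model == "full":
            from .fullmodel import build_full_network, nominal_parameters

            return build_full_network(), nominal_parameters()
        if self.model == "reduced":
            from .reduced import build_reduced_network, reduced_nominal_parameters

            return build_reduced_network(), reduced_nominal_parameters()
        from .sbml import read_sbml

        model, params, unsupported = read_sbml(self.model)
        if unsupported:
            details = "; ".join(f"{u.path}: {u.detail}" for u in unsupported)
            raise ValueError(f"SBML import left unsupported constructs: {details}")
        return model, params

    def build_protocol(self):
        from .stimulation import make_cni_protocol, make_sequential_pulses

        p = self.protocol
        proto = make_sequential_pulses(p.amp1, p.amp1 / p.amp2_fold,
                                       interval=p.interval_h, duration=p.duration_h,
                                       horizon=p.horizon_h)
        if p.cni_dose_nm > 0:
            proto = make_cni_protocol(proto, p.cni_dose_nm)
        return proto
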