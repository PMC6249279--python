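"""Run configuration: one human-editable YAML file for all parameters.

Defaults are the reference study conditions: 78.26 nm PSF sigma, 3000
detected photons per activated emitter per frame, SPNR 0.2 / SGNR 0.3
um^2, a 2048x2048 nm field of 128 nm pixels, chain return probabilities
(0.5, 0.7, 0.8, 1), 250 emitters at 25 nm helix spacing, 30 mean
activations per emitter, duty-cycle sweep r00 = 0.98 .. 0.92.
Units are nm and photons throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .activation import ActivationChain
from .experiments import DEFAULT_R00_SWEEP
from .frames import FrameModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of a simulation/benchmark run."""

    # optics + noise + geometry
    sigma: float = 78.26
    mean_photons: float = 3000.0
    spnr: float = 0.2
    sgnr: float = 0.3
    frame_nm: tuple[float, float] = (2048.0, 2048.0)
    pixel_nm: tuple[float, float] = (128.0, 128.0)
    # activation chain
    r00: float = 0.92
    r01: float = 0.5
    r02: float = 0.7
    r03: float = 0.8
    r04: float = 1.0
    # experiment
    n_emitters: int = 250
    helix_spacing: float = 25.0
    target_activations: float = 30.0
    r00_sweep: tuple[float, ...] = DEFAULT_R00_SWEEP
    seed: int = 0

    def frame_model(self) -> FrameModel:
        return FrameModel(
            sigma=self.sigma,
            mean_photons=self.mean_photons,
            spnr=self.spnr,
            sgnr=self.sgnr,
            frame_nm=tuple(self.frame_nm),
            pixel_nm=tuple(self.pixel_nm),
        )

    def chain(self, r00: float | None = None) -> ActivationChain:
        return ActivationChain(
            r00=self.r00 if r00 is None else r00,
            r01=self.r01, r02=self.r02, r03=self.r03, r04=self.r04,
        )

    def chain_kwargs(self) -> dict:
        return {"r01": self.r01, "r02": self.r02, "r03": self.r03, "r04": self.r04}

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["frame_nm"] = list(self.frame_nm)
        data["pixel_nm"] = list(self.pixel_nm)
        data["r00_sweep"] = list(self.r00_sweep)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("frame_nm", "pixel_nm", "r00_sweep"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
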