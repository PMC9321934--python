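"""Run configuration: every stage parameter in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """All pipeline stage parameters plus the master seed.

    Round-trips losslessly through YAML (`to_yaml` / `from_yaml`).
    """

    # preprocess
    do_preprocess: bool = True
    target_dims: tuple[int, int, int] | None = None
    # segmentation
    pa_wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0)
    pa_noise_factor: float = 2.0
    strict_markers: bool = False
    background_margin: int = 0
    intensity_bias: float = 0.02
    # vessel enhancement
    tubeness_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    keep_fraction: float = 0.05
    d1_um: float = 10.0
    d2_um: float = 30.0
    # compartments
    keyslice_step: int = 50
    # morphometry
    box_sizes: tuple[int, ...] = (1, 2, 4, 8, 16)
    # statistics
    alpha: float = 0.05
    # master seed for any stochastic step (Lilliefors Monte-Carlo null)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if not self.d1_um < self.d2_um:
            raise ValueError("need d1_um < d2_um")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.keyslice_step < 1:
            raise ValueError("keyslice_step must be >= 1")
        if len(self.box_sizes) < 4:
            raise ValueError("need >= 4 box sizes")

    def to_yaml(self, path: str | None = None) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        """Load from a YAML string or file path."""
        import os

        if os.path.exists(source):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(source)
        tuple_fields = {f.name for f in fields(cls)
                        if "tuple" in str(f.type)}
        for k in list(d):
            if k in tuple_fields and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)
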