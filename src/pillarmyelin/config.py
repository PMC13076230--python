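"""Run configuration: a YAML-serialisable record of every knob a
quantification run depends on, written verbatim into each output
directory so any run is reproducible from (config, inputs) alone."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    """Configuration for quantification / simulation runs.

    Unset entries fall back to the package defaults at the point of
    use; CLI flags override file values.
    """

    inputs: list = field(default_factory=list)
    channel_roles: list = field(default_factory=lambda: ["PILLAR", "MBP", "NUCLEI"])
    # array / mold spec
    mold_diameter_um: float = 5.0
    interpillar_um: float = 10.0
    height_um: float = 22.0
    swelling_fraction: float = 0.26
    rows: int = 5
    cols: int = 5
    pixel_size_um: float = 0.25
    z_step_um: float = 2.0
    # scoring
    score_edges: list = field(default_factory=lambda: [0.05, 0.45, 0.95])
    gap_tolerance_deg: float = 18.0
    annulus_width_um: float = 2.0
    n_angular_bins: int = 72
    threshold: float | None = None  # None -> per-field Otsu
    base_exclusion_um: float = 4.0
    # probe constants (AFM runs)
    spring_constant_n_per_m: float = 0.1
    bead_radius_m: float = 12.5e-6
    poisson_ratio: float = 0.5
    # bookkeeping
    seed: int = 0
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        missing = [p for p in self.inputs if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")
        if len(self.channel_roles) != len(set(self.channel_roles)):
            raise ValidationError("channel roles must be unique")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, for output provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
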