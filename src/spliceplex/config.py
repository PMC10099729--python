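"""Run configuration with the study's standard thresholds as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, at their standard defaults:
    constitutive Ψ cut 0.97, expression filter TPM >= 1 with >= 10 event
    reads, high-complexity entropy 1.0 bits, differential splicing at
    |ΔΨ| >= 0.1 with posterior >= 0.85 in >= 5 stages, and entropy-dynamic
    selection at >= 0.5 bits change."""

    seed: int = 0
    psi_constitutive: float = 0.97
    min_tpm: float = 1.0
    min_reads: int = 10
    entropy_high: float = 1.0
    delta_psi: float = 0.1
    posterior_min: float = 0.85
    dev_min_stages: int = 5
    entropy_change: float = 0.5
    dyn_min_reads: int = 20
    dyn_min_tpm: float = 10.0
    max_paths: int = 128
    tissues: tuple[str, ...] = (
        "brain", "cerebellum", "heart", "liver", "kidney", "testis",
    )
    # testis develops earlier: its reference stage differs
    reference_stage: dict = field(default_factory=lambda: {"default": 0})

    def validate(self) -> None:
        if not 0 < self.psi_constitutive <= 1:
            raise ValueError("psi_constitutive must be in (0, 1]")
        if not 0 <= self.posterior_min <= 1:
            raise ValueError("posterior_min must be in [0, 1]")
        if self.delta_psi < 0 or self.entropy_change < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_reads < 0 or self.dev_min_stages < 1:
            raise ValueError("count thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "tissues" in data:
            data["tissues"] = tuple(data["tissues"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        return d
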