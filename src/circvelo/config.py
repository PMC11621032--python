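"""Run configuration with YAML round-trip.

One declarative object carries every tunable of the two-stage pipeline,
with defaults matching the standard settings (5,000 manifold steps, 10,000
velocity steps, learning rate decaying 0.03 -> 0.005, 500 posterior draws,
5-95% credible intervals, phase concentration 5).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    n_steps_manifold: int = 5000
    n_steps_velocity: int = 10000
    lr_start: float = 0.03
    lr_end: float = 0.005
    guide: str = "meanfield"  # meanfield | lrmn | mcmc
    model: str = "constant"  # constant | periodic
    n_harmonics: int = 1
    epsilon: float = 5.0
    gene_set: str | None = None  # small | medium | large | path | None
    min_mean_u: float = 0.1
    min_mean_s: float = 0.3
    n_posterior_samples: int = 500
    ci_lo: float = 5.0
    ci_hi: float = 95.0
    mean_half_life_hours: float = 1.0
    timescale_mode: str = "lifetime"  # lifetime | halflife
    early_stop: bool = False
    # simulation block
    sim_n_cells: int = 3000
    sim_n_genes: int = 300
    sim_omega: float = 0.4
    condition_column: str | None = None
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = yaml.safe_load(text) or {}
        return cls(**payload)
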