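"""Run configuration: every tunable with its default, strictly validated."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """All pipeline tunables. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # geometry
    spacing: float = 3.8
    include_radius: float = 7.6
    exclude_radius: float = 1.5
    cutoff: float = 8.5

    # energy model
    lambda_scale: float = 0.159
    e0: float = -2.27
    n_contacts: float | None = None  # override for the mean contact count

    # Hamiltonian weights
    A: float = 20.0
    w: float | None = None  # None: use p if set, else w = A
    p: float | None = None
    L0: int = 10
    D: int = 5
    ablate_E0: bool = False
    cluster_restarts: int = 20  # local-search restarts for the alphabet fit

    # solver
    solver: str = "sa"  # "sa" | "brute"
    n_runs: int = 50
    n_sweeps: int = 2000
    seed: int = 0

    # refinement stage
    refine_runs: int = 20
    refine_sweeps: int = 2000

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    if path is None:
        return RunConfig(**{k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig.from_yaml(Path(path).read_text())
    upd = {k: v for k, v in overrides.items() if v is not None}
    return cfg.model_copy(update=upd) if upd else cfg
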