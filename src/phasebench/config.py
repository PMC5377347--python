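"""Run configuration: a serializable description of a whole experiment.

A :class:`RunConfig` captures everything needed to reproduce a run —
phantom recipe, imaging regime(s), Fresnel number, fluence grid,
realization count, RAAR parameters, output directory and the base seed.
Configs round-trip through YAML, and every output file written by the CLI
embeds the config hash and base seed so results can be traced back.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .optics import na_requirement
from .phantoms import Phantom, make_bitmap_phantom, make_cell_phantom
from .retrieval import RAARConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    phantom_kind: str = "bitmap"          # "bitmap" | "cell"
    grid_size: int = 1024
    n_bits: int = 51
    block_size: int = 10
    fill_prob: float = 0.5
    max_phase: float = -1.0
    phantom_seed: int = 0

    regimes: tuple[str, ...] = ("nfh", "cdi")
    fresnel_number: float = 1e-3

    mu_min: float = 1.0
    mu_max: float = 2e4
    points_per_decade: int = 8
    n_realizations: int = 30

    raar: RAARConfig = field(default_factory=RAARConfig)

    saturation_tol: float = 0.01
    base_seed: int = 0
    outdir: str = "phasebench-out"

    def __post_init__(self) -> None:
        if isinstance(self.raar, dict):
            self.raar = RAARConfig(**self.raar)
        self.regimes = tuple(self.regimes)
        if not na_requirement(self.fresnel_number, self.grid_size):
            warnings.warn(
                f"Fr = {self.fresnel_number} < 1/N = {1 / self.grid_size:.2e}: "
                "the simulated NA does not support pixel-level resolution",
                stacklevel=2,
            )

    # -- phantom -----------------------------------------------------------
    def make_phantom(self) -> Phantom:
        if self.phantom_kind == "bitmap":
            return make_bitmap_phantom(
                n_bits_x=self.n_bits, block_size=self.block_size,
                grid_size=self.grid_size, fill_prob=self.fill_prob,
                seed=self.phantom_seed,
            )
        if self.phantom_kind == "cell":
            return make_cell_phantom(
                grid_size=self.grid_size, max_phase=self.max_phase,
                seed=self.phantom_seed,
            )
        raise ValueError(f"unknown phantom kind {self.phantom_kind!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["regimes"] = list(self.regimes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
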