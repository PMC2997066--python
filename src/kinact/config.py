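"""Configuration dataclasses for simulation, random walks and the pipeline.

Defaults follow the source analysis: 5% entropy window, 2x-SD background
cutoff, top-99.9-percentile correlation gate, 500 walks of 5 steps,
enrichment acceptance at p < 0.01 and a >= 15-seed term filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

from .errors import ConfigError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-tissue expression generator.

    The generator emulates the structure of a large curated expression
    corpus: many tissue classes with replicate samples, per-gene bimodal
    expression (a clipped-Gaussian background plus an active component
    shifted upwards by ``active_shift_sd`` background SDs in a random
    subset of tissues), correlated gene modules driven by a shared latent
    factor, completely-at-random missing values, and a small ontology
    annotating the module genes.
    """

    n_genes: int = 200
    n_tissues: int = 30
    samples_per_tissue: int = 20
    background_mean_range: Tuple[float, float] = (3.0, 6.0)
    background_sd_range: Tuple[float, float] = (0.3, 0.8)
    active_shift_sd: float = 8.0
    active_tissue_fraction: float = 1.0 / 6.0
    active_tissues_per_gene: Optional[int] = None  # exact count overrides the fraction
    n_modules: int = 4
    module_size: int = 10
    module_factor_sd: float = 1.5
    missing_rate: float = 0.05
    n_terms: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "samples_per_tissue": self.samples_per_tissue,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_terms": self.n_terms,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if self.samples_per_tissue < 2:
            raise ConfigError(
                "samples_per_tissue must be >= 2 (tissue medians are not robust otherwise)"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.active_shift_sd < 0:
            raise ConfigError("active_shift_sd must be >= 0")
        if not (0.0 <= self.active_tissue_fraction <= 1.0):
            raise ConfigError("active_tissue_fraction must lie in [0, 1]")
        if self.active_tissues_per_gene is not None and not (
            0 <= self.active_tissues_per_gene <= self.n_tissues
        ):
            raise ConfigError("active_tissues_per_gene must lie in [0, n_tissues]")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError(
                f"n_modules * module_size = {self.n_modules * self.module_size} "
                f"exceeds n_genes = {self.n_genes}"
            )
        lo, hi = self.background_mean_range
        if not (0 <= lo <= hi):
            raise ConfigError("background_mean_range must satisfy 0 <= lo <= hi")
        lo, hi = self.background_sd_range
        if not (0 < lo <= hi):
            raise ConfigError("background_sd_range must satisfy 0 < lo <= hi")
        if self.module_factor_sd < 0:
            raise ConfigError("module_factor_sd must be >= 0")
        if self.n_terms < self.n_modules + 1:
            raise ConfigError("n_terms must be >= n_modules + 1 (root plus one term per module)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the non-backtracking random-walk sampler."""

    n_walks: int = 500
    walk_length: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walks < 1:
            raise ConfigError("n_walks must be >= 1")
        if self.walk_length < 1:
            raise ConfigError("walk_length must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ActivityParams:
    """Entropy-window background-cutoff parameters."""

    window_frac: float = 0.05
    step_frac: float = 0.01
    sd_multiplier: float = 2.0
    reference_state: str = "healthy"

    def __post_init__(self) -> None:
        if not (0 < self.window_frac <= 1):
            raise ConfigError("window_frac must lie in (0, 1]")
        if not (0 < self.step_frac <= 1):
            raise ConfigError("step_frac must lie in (0, 1]")
        if self.sd_multiplier < 0:
            raise ConfigError("sd_multiplier must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)
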