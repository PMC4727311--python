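"""Scenario configuration: every simulation setting in one validated record.

A scenario fixes the mating design, population dimensions, trait
architecture, the models to run, and the master seed.  Configurations
round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .power import DEFAULT_ALPHAS
from .traits import CANONICAL_L_A

__all__ = ["ScenarioConfig"]

DESIGNS = ("DH-NAM", "BC-NAM", "RIL-NAM")


@dataclass
class ScenarioConfig:
    # mating design and population dimensions
    design: str = "BC-NAM"
    n_subpops: int = 10
    n_per_sub: int = 50
    size_sd: float = 0.0  # >0: unbalanced subpopulation sizes, constant total

    # founder source: synthetic unless files are given
    n_markers: int = 1000
    chrom_lengths_cm: dict[str, float] = field(
        default_factory=lambda: {f"C{i + 1}": 100.0 for i in range(10)}
    )
    divergence: float = 0.4
    founder_geno_file: str | None = None
    founder_map_file: str | None = None
    founder_panels_file: str | None = None

    # trait architecture
    n_qtl: int = 25
    geometric_a: float | None = None  # default: canonical pairing with n_qtl
    h2: float = 0.8
    n_qtl_int: int = 0
    n_bg: int = 0
    interaction_prop: float = 0.0

    # mapping and power
    models: tuple[str, ...] = ("S1", "S2", "J1", "J2")
    cofactor_method: str = "M1"
    segment_cm: float = 1.5
    exclusion_window_cm: float = 5.0
    alphas: tuple[float, ...] = DEFAULT_ALPHAS

    # orchestration
    n_runs: int = 25
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        for name in ("n_subpops", "n_per_sub", "n_markers", "n_qtl", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.size_sd < 0:
            raise ValueError("size_sd must be >= 0")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("heritability h2 must lie in (0, 1]")
        if not 0.0 <= self.interaction_prop < 1.0:
            raise ValueError("interaction_prop must lie in [0, 1)")
        if self.interaction_prop > 0 and (self.n_qtl_int < 1 or self.n_bg < 1):
            raise ValueError("interaction scenarios need n_qtl_int >= 1 and n_bg >= 1")
        if self.n_qtl_int > self.n_qtl:
            raise ValueError("n_qtl_int cannot exceed n_qtl")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        bad = [m for m in self.models if m not in ("S1", "S2", "J1", "J2")]
        if bad:
            raise ValueError(f"unknown model ids: {bad}")
        if self.cofactor_method not in ("M1", "M2"):
            raise ValueError("cofactor_method must be M1 or M2")
        if not all(0 < a < 1 for a in self.alphas):
            raise ValueError("alpha* levels must lie in (0, 1)")
        files = (self.founder_geno_file, self.founder_map_file)
        if any(files) and not all(files):
            raise ValueError("founder_geno_file and founder_map_file must be given together")
        if any(l <= 0 for l in self.chrom_lengths_cm.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def a(self) -> float:
        """Geometric ratio: explicit, or the canonical pairing with n_qtl."""
        if self.geometric_a is not None:
            return self.geometric_a
        if self.n_qtl in CANONICAL_L_A:
            return CANONICAL_L_A[self.n_qtl]
        raise ValueError(
            f"no canonical geometric ratio for {self.n_qtl} QTLs; set geometric_a"
        )

    @property
    def total_individuals(self) -> int:
        return self.n_subpops * self.n_per_sub

    # -- serialisation ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["models"] = list(self.models)
        d["alphas"] = [float(a) for a in self.alphas]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        if "models" in d:
            d["models"] = tuple(d["models"])
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        return cls(**d)
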