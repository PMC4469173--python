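"""Run configuration, validation and results serialization.

A :class:`RunConfig` gathers every knob of the pipeline with defaults that
reproduce the reference simulation settings (0.005 MeV transport cut-off,
0.05 cm tally shells, 250 um cluster radius, tumour-to-lung emission ratio
7, lung biological half-life 3 d).  Unknown keys and out-of-range values are
rejected with the offending field named.  Results are written as plain
comma-separated tables plus a manifest carrying the seed, package version
and a hash of the resolved configuration, so a rerun with the same manifest
reproduces the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "load_config", "write_results"]


class RunConfig(BaseModel):
    """Validated configuration for a dose run or a TCP/NTCP scan."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    # source / nuclide
    nuclide: str = "Y90"
    shape: str = "uniform"
    covering_fraction_per_cm2: float = Field(1e9, gt=0)
    n_atoms_per_no: float = Field(1.0, ge=0)
    n_a_grid: Optional[list[float]] = None
    uptake_delay_h: float = Field(0.0, ge=0)
    t_bio_tumour_days: float = Field(6.0, gt=0)
    t_bio_lung_days: float = Field(3.0, gt=0)
    tumour_to_lung_emission_ratio: float = Field(7.0, gt=0)
    centre_to_surface_ratio: float = Field(0.01, gt=0, le=1)
    include_lung_source: bool = True

    # geometry
    tumour_radius_cm: float = Field(0.5, gt=0)
    cluster_radius_cm: float = Field(0.025, gt=0)
    lung_thickness_cm: float = Field(4.0, ge=0)
    shell_thickness_cm: float = Field(0.05, gt=0)
    density_tumour_g_cm3: float = Field(1.06, gt=0)
    density_lung_g_cm3: float = Field(0.26, gt=0)
    lattice_registration: str = "origin"

    # transport
    n_histories: int = Field(20_000, ge=1000)
    n_histories_lung: Optional[int] = Field(None, ge=1000)
    seed: int = 42
    cutoff_mev: float = Field(0.005, gt=0)
    include_annihilation: bool = False

    # radiobiology / NTCP
    tcp_threshold: float = Field(0.99, gt=0, lt=1)
    lkb_td50_gy: float = Field(30.8, gt=0)
    lkb_m: float = Field(0.37, gt=0)
    seriality_s: float = Field(0.0061)
    tru_c: float = -0.98
    tru_v: float = Field(1.0, gt=0, le=1)

    @field_validator("nuclide")
    @classmethod
    def _known_nuclide(cls, v: str) -> str:
        from .decay import SUPPORTED_NUCLIDES

        if v not in SUPPORTED_NUCLIDES:
            raise ValueError(f"nuclide must be one of {SUPPORTED_NUCLIDES}, got {v!r}")
        return v

    @field_validator("shape")
    @classmethod
    def _known_shape(cls, v: str) -> str:
        if v not in ("uniform", "linear", "exponential"):
            raise ValueError(f"shape must be uniform/linear/exponential, got {v!r}")
        return v

    @field_validator("lattice_registration")
    @classmethod
    def _known_registration(cls, v: str) -> str:
        if v not in ("origin", "half"):
            raise ValueError(f"lattice_registration must be 'origin' or 'half', got {v!r}")
        return v

    @property
    def lambda_bio_tumour(self) -> float:
        """[1/h]"""
        return math.log(2.0) / (self.t_bio_tumour_days * 24.0)

    @property
    def lambda_bio_lung(self) -> float:
        """[1/h]"""
        return math.log(2.0) / (self.t_bio_lung_days * 24.0)

    @property
    def resolved_n_histories_lung(self) -> int:
        if self.n_histories_lung is not None:
            return self.n_histories_lung
        return max(2000, self.n_histories // 2)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML configuration file; an empty file yields full defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig(**data)


def write_results(tables: dict, out_dir, config: Optional[RunConfig] = None,
                  seed: Optional[int] = None) -> Path:
    """Write result tables as CSV plus a reproducibility manifest.

    ``tables`` maps file stems to pandas DataFrames (or dicts of scalars).
    Returns the manifest path.
    """
    import pandas as pd

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for stem, table in tables.items():
        path = out / f"{stem}.csv"
        if isinstance(table, pd.DataFrame):
            table.to_csv(path, index=False, float_format="%.10g")
        else:
            pd.DataFrame([table]).to_csv(path, index=False, float_format="%.10g")
        written[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_hash": config.config_hash() if config else None,
        "config": config.model_dump() if config else None,
        "files": written,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest_path
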