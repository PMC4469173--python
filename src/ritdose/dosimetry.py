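"""Absorbed-dose profiles and summary doses from energy tallies.

The per-shell absorbed dose is

    D(r) = 21.34 * E_tot(r) * (1/rho) * A / lambda_eff   [Gy],

with E_tot(r) the tallied energy density per decay [MeV/cm^3], rho the
medium density [g/cm^3], A the compartment activity [mCi] and lambda_eff
[1/h].  The 21.34 constant is not stored but derived from first principles
(decays per mCi.h times J/MeV times g/kg), so the Bq-based internal
conversion is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .geometry import ShellGrid, TissueModel, shell_index_of_radius
from .sources import ActivityReport, BQ_PER_MCI, SECONDS_PER_HOUR

__all__ = [
    "dose_rate_constant",
    "DoseProfile",
    "DoseSummary",
    "dose_profile",
    "combine_dose_profiles",
    "summarize_dose",
]

JOULE_PER_MEV = 1.602176634e-13
GRAM_PER_KG = 1000.0


def dose_rate_constant() -> float:
    """Gy per (MeV g^-1 per decay) per (mCi h): derived, not hard-coded.

    decays per mCi.h  x  J/MeV  x  g/kg  ~= 21.34.
    """
    return BQ_PER_MCI * SECONDS_PER_HOUR * JOULE_PER_MEV * GRAM_PER_KG


@dataclass(frozen=True)
class DoseProfile:
    """Per-shell absorbed dose [Gy] with provenance metadata."""

    grid: ShellGrid
    doses: np.ndarray  # [Gy]
    media: np.ndarray  # medium code per shell
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.doses < 0):
            raise ValueError("absorbed doses must be non-negative")
        if len(self.doses) != self.grid.n_shells:
            raise ValueError("dose array does not match the tally grid")

    def scaled(self, factor: float) -> "DoseProfile":
        """Dose scales linearly with cumulated activity (and with n_a)."""
        return DoseProfile(grid=self.grid, doses=self.doses * factor,
                           media=self.media, metadata=dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shell_index": np.arange(self.grid.n_shells),
                "r_inner_cm": self.grid.edges[:-1],
                "r_outer_cm": self.grid.edges[1:],
                "dose_Gy": self.doses,
                "medium": np.where(self.media == 0, "soft_tissue", "lung"),
            }
        )


@dataclass(frozen=True)
class DoseSummary:
    """Headline doses of one run [Gy]."""

    d_tot: float  # mass-weighted mean over tumour shells
    d_cent: float  # innermost shell
    d_surf: float  # shell containing the tumour surface (inner face)
    d_lung: Optional[float]  # mass-weighted mean over the lung shell

    def as_dict(self) -> dict:
        return {"D_tot_Gy": self.d_tot, "D_cent_Gy": self.d_cent,
                "D_surf_Gy": self.d_surf, "D_lung_Gy": self.d_lung}


def dose_profile(profile, activity: ActivityReport,
                 model: TissueModel, metadata: Optional[dict] = None) -> DoseProfile:
    """Apply the dose equation to one compartment's energy profile."""
    if profile.grid.n_shells != model.grid.n_shells:
        raise ValueError("energy profile and tissue model use different tally grids")
    rho = np.where(profile.media == 0, model.density_tumour, model.density_lung)
    a_mci = activity.total_activity_bq / BQ_PER_MCI
    doses = (dose_rate_constant() * profile.energy_density / rho
             * a_mci / activity.lambda_eff)
    meta = {"compartment": activity.compartment, "n_histories": profile.n_histories}
    meta.update(metadata or {})
    return DoseProfile(grid=profile.grid, doses=doses, media=profile.media,
                       metadata=meta)


def combine_dose_profiles(profiles: list[DoseProfile]) -> DoseProfile:
    """Sum dose contributions (e.g. tumour-source + lung-source runs)."""
    if not profiles:
        raise ValueError("nothing to combine")
    first = profiles[0]
    total = np.zeros_like(first.doses)
    for p in profiles:
        if p.grid.n_shells != first.grid.n_shells:
            raise ValueError("profiles use different tally grids")
        total = total + p.doses
    return DoseProfile(grid=first.grid, doses=total, media=first.media,
                       metadata={"combined_from": [dict(p.metadata) for p in profiles]})


def summarize_dose(dose: DoseProfile, model: TissueModel) -> DoseSummary:
    """D_tot, D_cent, D_surf and D_lung per their shell-wise definitions."""
    grid = dose.grid
    tumour_mask = grid.centres <= model.tumour_radius
    if not tumour_mask.any():
        raise ValueError("dose profile has no tumour shells")
    vols = grid.volumes
    d_tot = float(np.average(dose.doses[tumour_mask], weights=vols[tumour_mask]))
    d_cent = float(dose.doses[0])
    surf_idx = shell_index_of_radius(model.tumour_radius * (1 - 1e-9), grid)
    d_surf = float(dose.doses[surf_idx])
    lung_mask = ~tumour_mask
    if lung_mask.any() and model.lung_shell_thickness > 0:
        d_lung = float(np.average(dose.doses[lung_mask], weights=vols[lung_mask]))
    else:
        d_lung = None
    return DoseSummary(d_tot=d_tot, d_cent=d_cent, d_surf=d_surf, d_lung=d_lung)
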