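"""Full-pipeline scans over the number of radioactive atoms per nanoobject.

One Monte Carlo transport run per source compartment is performed at a
reference loading of one atom per nanoobject; absorbed dose is linear in
the cumulated activity, so every other grid point reuses the same energy
profile scaled by ``n_a`` (bit-equivalent to rerunning dosimetry).  BED,
TCP and the three NTCP models are re-evaluated per point because they are
non-linear in dose.  The minimal atom count for tumour control is the
real-valued crossing of the TCP threshold found by bisection; the two-day
uptake count applies the radioactive-decay factor exp(lambda_phys * 48 h)
to that real value before ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .decay import Radionuclide, load_radionuclide
from .dosimetry import DoseProfile, combine_dose_profiles, dose_profile, summarize_dose
from .geometry import TissueModel, build_tissue_model
from .ntcp import (LKBParams, SerialityParams, TRUParams, ntcp_lkb,
                   ntcp_relative_seriality, ntcp_tru)
from .radiobiology import (LUNG_PARAMS, TUMOUR_PARAMS, BiologicalParams,
                           bed_profile, cluster_kill_probability,
                           tumour_control_probability)
from .sources import SourceDistribution, radial_emission_weights, total_activity
from .transport import default_material_tables, run_transport

__all__ = [
    "ScanResult",
    "MinimalAtoms",
    "tcp_ntcp_curve",
    "minimal_atoms_for_control",
    "two_day_atom_count",
]

TWO_DAY_DELAY_H = 48.0


def two_day_atom_count(n_direct: float, nuclide: Radionuclide,
                       delay_h: float = TWO_DAY_DELAY_H) -> int:
    """Atoms per nanoobject needed when uptake takes ``delay_h`` hours.

    The direct-uptake count is inflated by the physical-decay factor
    exp(lambda_phys * delay) and then rounded up to an integer.
    """
    if n_direct < 0:
        raise ValueError("atom count must be non-negative")
    return int(math.ceil(n_direct * math.exp(nuclide.lambda_phys * delay_h)))


@dataclass(frozen=True)
class MinimalAtoms:
    """Minimal nanoobject loading for tumour control."""

    real: float  # real-valued threshold crossing
    direct: int  # ceil(real), direct uptake
    two_day: int  # ceil(real * exp(lambda_phys * 48 h))


@dataclass
class ScanResult:
    """TCP/NTCP curve over atoms per nanoobject, plus the reusable dose basis."""

    config: RunConfig
    nuclide: Radionuclide
    model: TissueModel = field(repr=False)
    unit_dose: DoseProfile = field(repr=False)  # combined dose at n_a = 1
    unit_activity_tumour_bq: float  # tumour activity at n_a = 1 [Bq]
    lambda_eff_tumour: float  # [1/h]
    lambda_eff_lung: float  # [1/h]
    tumour_bio: BiologicalParams
    lung_bio: BiologicalParams
    curve: Optional[pd.DataFrame] = None

    def dose_at(self, n_a: float) -> DoseProfile:
        return self.unit_dose.scaled(n_a)

    def evaluate(self, n_a: float) -> dict:
        """Dose summary, TCP and the three NTCPs at one loading."""
        dose = self.dose_at(n_a)
        summary = summarize_dose(dose, self.model)
        bed_t = bed_profile(dose.doses, self.tumour_bio, self.lambda_eff_tumour)
        tcp = tumour_control_probability(bed_t, self.model, self.tumour_bio).tcp

        cfg = self.config
        lung_mask = self.model.shell_media() == 1
        bed_l = bed_profile(dose.doses, self.lung_bio, self.lambda_eff_lung)
        n_cells_fsu = self.lung_bio.cells_per_cluster(self.model.cluster_radius)
        if lung_mask.any():
            vols = self.model.grid.volumes
            mean_lung_bed = float(np.average(bed_l.values[lung_mask],
                                             weights=vols[lung_mask]))
            p_fsu = float(cluster_kill_probability(mean_lung_bed, self.lung_bio,
                                                   n_cells_fsu))
            lkb = ntcp_lkb(summary.d_lung, LKBParams(cfg.lkb_td50_gy, cfg.lkb_m))
            ser = ntcp_relative_seriality(p_fsu, SerialityParams(cfg.seriality_s))
            tru_counts = self.model.lung_cluster_shell_counts()
            tru = ntcp_tru(bed_l, tru_counts, self.lung_bio,
                           TRUParams(cfg.tru_c, cfg.tru_v))
        else:
            lkb = ser = tru = float("nan")
        return {
            "n_a": n_a,
            "tcp": tcp,
            "ntcp_lkb": lkb,
            "ntcp_seriality": ser,
            "ntcp_tru": tru,
            **summary.as_dict(),
        }

    def tcp_at(self, n_a: float) -> float:
        dose = self.dose_at(n_a)
        bed_t = bed_profile(dose.doses, self.tumour_bio, self.lambda_eff_tumour)
        return tumour_control_probability(bed_t, self.model, self.tumour_bio).tcp


def tcp_ntcp_curve(config: RunConfig,
                   n_a_grid: Optional[Sequence[float]] = None) -> ScanResult:
    """Run the pipeline and tabulate TCP/NTCP over the atom-count grid."""
    grid = list(n_a_grid if n_a_grid is not None else (config.n_a_grid or []))
    if grid and any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("n_a grid must be strictly ascending")

    nuclide = load_radionuclide(config.nuclide)
    model = build_tissue_model(
        config.tumour_radius_cm,
        cluster_radius=config.cluster_radius_cm,
        lung_shell_thickness=config.lung_thickness_cm,
        density_tumour=config.density_tumour_g_cm3,
        density_lung=config.density_lung_g_cm3,
        shell_thickness=config.shell_thickness_cm,
        registration=config.lattice_registration,
    )
    weights = radial_emission_weights(
        model, config.shape,
        tumour_to_lung_emission_ratio=config.tumour_to_lung_emission_ratio,
        centre_to_surface_ratio=config.centre_to_surface_ratio,
    )
    tables = default_material_tables(model)

    source_unit = SourceDistribution(
        shape=config.shape,
        tumour_to_lung_emission_ratio=config.tumour_to_lung_emission_ratio,
        covering_fraction=config.covering_fraction_per_cm2,
        n_atoms_per_no=1.0,
        uptake_delay_h=config.uptake_delay_h,
        centre_to_surface_ratio=config.centre_to_surface_ratio,
        t_bio_tumour_days=config.t_bio_tumour_days,
        t_bio_lung_days=config.t_bio_lung_days,
    )

    act_t = total_activity(nuclide, model, source_unit, "tumour")
    prof_t = run_transport(
        nuclide, model, weights, config.n_histories, seed=config.seed,
        tables=tables, compartment="tumour", cutoff=config.cutoff_mev,
        include_annihilation=config.include_annihilation,
    )
    parts = [dose_profile(prof_t, act_t, model,
                          metadata={"nuclide": nuclide.name, "shape": config.shape})]
    act_l = total_activity(nuclide, model, source_unit, "lung")
    if config.include_lung_source and model.n_lung_clusters:
        prof_l = run_transport(
            nuclide, model, weights, config.resolved_n_histories_lung,
            seed=config.seed + 1, tables=tables, compartment="lung",
            cutoff=config.cutoff_mev,
            include_annihilation=config.include_annihilation,
        )
        parts.append(dose_profile(prof_l, act_l, model,
                                  metadata={"nuclide": nuclide.name,
                                            "shape": config.shape}))
    unit_dose = combine_dose_profiles(parts) if len(parts) > 1 else parts[0]

    tumour_bio = BiologicalParams(
        t_bio=config.t_bio_tumour_days, alpha_over_beta=TUMOUR_PARAMS.alpha_over_beta,
        mu=TUMOUR_PARAMS.mu, alpha=TUMOUR_PARAMS.alpha,
        cell_density=TUMOUR_PARAMS.cell_density,
    )
    lung_bio = BiologicalParams(
        t_bio=config.t_bio_lung_days, alpha_over_beta=LUNG_PARAMS.alpha_over_beta,
        mu=LUNG_PARAMS.mu, alpha=LUNG_PARAMS.alpha,
        cell_density=LUNG_PARAMS.cell_density,
    )

    result = ScanResult(
        config=config,
        nuclide=nuclide,
        model=model,
        unit_dose=unit_dose,
        unit_activity_tumour_bq=act_t.total_activity_bq,
        lambda_eff_tumour=act_t.lambda_eff,
        lambda_eff_lung=act_l.lambda_eff,
        tumour_bio=tumour_bio,
        lung_bio=lung_bio,
    )
    if grid:
        result.curve = pd.DataFrame([result.evaluate(n_a) for n_a in grid])
    return result


def minimal_atoms_for_control(result: ScanResult,
                              tcp_threshold: Optional[float] = None,
                              n_a_max: float = 1e9) -> MinimalAtoms:
    """Bisection on the dose-scaling relation for the TCP threshold crossing."""
    from scipy.optimize import brentq

    threshold = tcp_threshold if tcp_threshold is not None else result.config.tcp_threshold
    lo, hi = 1e-6, 1.0
    while result.tcp_at(hi) < threshold:
        lo, hi = hi, hi * 2.0
        if hi > n_a_max:
            raise ValueError(
                "insufficient activity range: TCP threshold "
                f"{threshold} not reached below n_a = {n_a_max:g}"
            )
    real = float(brentq(lambda n: result.tcp_at(n) - threshold, lo, hi,
                        xtol=1e-9, rtol=1e-12))
    return MinimalAtoms(
        real=real,
        direct=int(math.ceil(real)),
        two_day=two_day_atom_count(real, result.nuclide),
    )
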