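"""Simplified Monte Carlo energy-deposition engine on concentric shell tallies.

Decay positions are sampled on cluster surfaces proportionally to the
emission weights.  Electrons are transported by continuous slowing down
along straight sampled directions (no multiple scattering, no
bremsstrahlung): each path segment deposits S_lin * ds into the tally shell
containing the segment midpoint and tracks stop below the 0.005 MeV cut-off,
where the residual energy is deposited locally.  Photons are transported by
free-path sampling from the total attenuation coefficient; at each
interaction the energy-absorption fraction mu_en/mu of the current energy is
deposited at the interaction site (kerma approximation, secondary electrons
not tracked) and the remainder continues in a new isotropic direction until
cut-off or escape.  The medium of a step is the medium at its start point.

Tallies are per decay: one history is one disintegration, emitting its
electrons and photons with the tabulated multiplicities.  Statistical
uncertainty is estimated from batch means (>= 10 batches by default), and
escaped energy is tracked so that emitted = deposited + escaped closes to
within Monte Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .decay import Radionuclide, _sample_multiplicity
from .geometry import TissueModel, ShellGrid
from .materials import MaterialTable, MaterialTables, ENERGY_CUTOFF_MEV

__all__ = [
    "EnergyDepositionProfile",
    "run_transport",
    "estimate_required_histories",
    "default_material_tables",
]

ANNIHILATION_PHOTON_MEV = 0.51099895

_MAX_ELECTRON_STEPS = 4000
_MAX_PHOTON_INTERACTIONS = 500


def default_material_tables(model: TissueModel) -> MaterialTables:
    """Functional-fit tables matching the model's media."""
    return MaterialTables(
        soft_tissue=MaterialTable.from_functional_fits("soft_tissue",
                                                       model.density_tumour),
        lung=MaterialTable.from_functional_fits("lung", model.density_lung),
    )


@dataclass(frozen=True)
class EnergyDepositionProfile:
    """Per-shell energy density per decay, with batch-mean uncertainties."""

    grid: ShellGrid
    energy_density: np.ndarray  # [MeV/cm^3 per decay]
    se: np.ndarray  # standard error, same units
    media: np.ndarray  # medium code per shell (0 tumour, 1 lung)
    n_histories: int
    n_batches: int
    deposited_per_decay: float  # [MeV]
    escaped_per_decay: float  # [MeV]
    balance_se: float  # SE of deposited + escaped [MeV]
    emitted_per_decay: float  # analytic mean emitted energy [MeV]

    def __post_init__(self) -> None:
        if np.any(self.energy_density < 0):
            raise ValueError("energy densities must be non-negative")

    @property
    def escaped_fraction(self) -> float:
        return self.escaped_per_decay / self.emitted_per_decay

    @property
    def max_relative_se(self) -> float:
        """Largest relative SE among shells carrying energy."""
        mask = self.energy_density > 0
        if not mask.any():
            return 0.0
        return float(np.max(self.se[mask] / self.energy_density[mask]))

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per tally shell."""
        return pd.DataFrame(
            {
                "shell_index": np.arange(self.grid.n_shells),
                "r_inner_cm": self.grid.edges[:-1],
                "r_outer_cm": self.grid.edges[1:],
                "energy_MeV_per_cm3_per_decay": self.energy_density,
                "se": self.se,
                "medium": np.where(self.media == 0, "soft_tissue", "lung"),
            }
        )


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cost = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    sint = np.sqrt(1.0 - cost**2)
    return np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])


def _deposit(tally: np.ndarray, escaped: list, edges: np.ndarray,
             outer: float, r: np.ndarray, energy: np.ndarray) -> None:
    """Add ``energy`` at radii ``r`` to the shell tally (or to escape)."""
    inside = r < outer
    idx = np.searchsorted(edges, r[inside], side="right") - 1
    np.add.at(tally, idx, energy[inside])
    escaped[0] += float(energy[~inside].sum())


def _transport_electrons(
    pos: np.ndarray,
    energy: np.ndarray,
    rng: np.random.Generator,
    model: TissueModel,
    tables: MaterialTables,
    tally: np.ndarray,
    escaped: list,
    cutoff: float,
    max_step_cm: float,
    max_frac_eloss: float,
) -> Optional[np.ndarray]:
    """Straight-line CSDA transport; returns stop points (for annihilation)."""
    edges = model.grid.edges
    outer = model.grid.outer_radius
    rho = np.array([model.density_tumour, model.density_lung])
    direction = _isotropic_directions(rng, len(pos))
    pos = pos.copy()
    energy = energy.copy()
    stops: list[np.ndarray] = []

    # immediately-subcutoff electrons deposit at their origin
    r0 = np.linalg.norm(pos, axis=1)
    low = energy <= cutoff
    if low.any():
        _deposit(tally, escaped, edges, outer, r0[low], energy[low])
        stops.append(pos[low])
    keep = ~low
    pos, direction, energy = pos[keep], direction[keep], energy[keep]

    for _ in range(_MAX_ELECTRON_STEPS):
        if len(energy) == 0:
            break
        r = np.linalg.norm(pos, axis=1)
        med = model.medium_of_radius(r)
        s_mass = np.where(
            med == 0,
            tables.soft_tissue.stopping_power_at(energy),
            tables.lung.stopping_power_at(energy),
        )
        s_lin = s_mass * rho[med]  # [MeV/cm]
        ds = np.minimum(max_step_cm, max_frac_eloss * energy / s_lin)
        de = s_lin * ds
        finishing = energy - de <= cutoff
        de = np.where(finishing, energy, de)
        mid = pos + direction * (0.5 * ds)[:, None]
        _deposit(tally, escaped, edges, outer, np.linalg.norm(mid, axis=1), de)
        pos = pos + direction * ds[:, None]
        energy = energy - de
        r = np.linalg.norm(pos, axis=1)
        gone = finishing | (r >= outer)
        if gone.any():
            out = r[gone] >= outer
            # track energy leaving the geometry before slowing down
            escaped[0] += float(energy[gone][out].sum())
            stops.append(pos[gone][~out])
            keep = ~gone
            pos, direction, energy = pos[keep], direction[keep], energy[keep]
    if len(energy):  # pragma: no cover - safety net
        raise RuntimeError("electron transport failed to terminate")
    return np.concatenate(stops) if stops else np.empty((0, 3))


def _transport_photons(
    pos: np.ndarray,
    energy: np.ndarray,
    rng: np.random.Generator,
    model: TissueModel,
    tables: MaterialTables,
    tally: np.ndarray,
    escaped: list,
    cutoff: float,
) -> None:
    edges = model.grid.edges
    outer = model.grid.outer_radius
    rho = np.array([model.density_tumour, model.density_lung])
    direction = _isotropic_directions(rng, len(pos))
    pos = pos.copy()
    energy = energy.copy()

    for _ in range(_MAX_PHOTON_INTERACTIONS):
        if len(energy) == 0:
            break
        r = np.linalg.norm(pos, axis=1)
        med = model.medium_of_radius(r)
        mu_mass = np.where(
            med == 0,
            tables.soft_tissue.mu_rho_at(energy),
            tables.lung.mu_rho_at(energy),
        )
        f_abs = np.where(
            med == 0,
            tables.soft_tissue.mu_en_rho_at(energy) / tables.soft_tissue.mu_rho_at(energy),
            tables.lung.mu_en_rho_at(energy) / tables.lung.mu_rho_at(energy),
        )
        mu_lin = mu_mass * rho[med]
        path = rng.exponential(1.0 / mu_lin)
        pos = pos + direction * path[:, None]
        r = np.linalg.norm(pos, axis=1)
        out = r >= outer
        escaped[0] += float(energy[out].sum())
        inside = ~out
        pos, energy, f_abs = pos[inside], energy[inside], f_abs[inside]
        r = r[inside]
        dep = energy * f_abs
        _deposit(tally, escaped, edges, outer, r, dep)
        energy = energy - dep
        below = energy <= cutoff
        if below.any():
            _deposit(tally, escaped, edges, outer, r[below], energy[below])
        keep = ~below
        pos, energy = pos[keep], energy[keep]
        direction = _isotropic_directions(rng, len(energy))
    if len(energy):  # pragma: no cover - safety net
        raise RuntimeError("photon transport failed to terminate")


def run_transport(
    nuclide: Radionuclide,
    model: TissueModel,
    weights,
    n_histories: int,
    seed: int,
    tables: Optional[MaterialTables] = None,
    compartment: str = "tumour",
    origin_points: Optional[np.ndarray] = None,
    n_batches: int = 10,
    cutoff: float = ENERGY_CUTOFF_MEV,
    max_step_cm: float = 0.025,
    max_frac_eloss: float = 0.05,
    include_annihilation: bool = False,
    particles: str = "all",
) -> EnergyDepositionProfile:
    """Tally energy density per shell and per decay for one source compartment.

    Parameters
    ----------
    weights
        Emission weight per cluster of the chosen ``compartment`` (a
        :class:`~ritdose.sources.RadialWeights` is accepted), or ``None``
        for uniform weights.  Ignored when ``origin_points`` is given.
    origin_points
        Optional explicit decay origins, shape ``(k, 3)`` [cm]; decays are
        placed directly at these points (sampled uniformly among them),
        bypassing cluster-surface sampling.  Used for point-source checks.
    particles
        ``'all'`` (default), ``'electrons'`` or ``'photons'``: restrict the
        tally to one emission type, e.g. for beta absorbed fractions.
    """
    if particles not in ("all", "electrons", "photons"):
        raise ValueError("particles must be 'all', 'electrons' or 'photons'")
    if n_histories < 1000:
        raise ValueError("need at least 1e3 histories for batch statistics")
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    if compartment not in ("tumour", "lung"):
        raise ValueError("compartment must be 'tumour' or 'lung'")
    if tables is None:
        tables = default_material_tables(model)

    if origin_points is None:
        centres = (model.cluster_centres_tumour if compartment == "tumour"
                   else model.cluster_centres_lung)
        if len(centres) == 0:
            raise ValueError(f"tissue model has no {compartment} clusters")
        if weights is None:
            prob = None
        else:
            if hasattr(weights, "tumour"):
                w = weights.tumour if compartment == "tumour" else None
            else:
                w = np.asarray(weights, dtype=float)
            if w is None:
                prob = None  # lung weights are uniform by construction
            else:
                if len(w) != len(centres) or np.any(w < 0) or w.sum() <= 0:
                    raise ValueError("weights are not normalizable over the "
                                     f"{compartment} clusters")
                prob = w / w.sum()
    else:
        origin_points = np.atleast_2d(np.asarray(origin_points, dtype=float))
        prob = None

    rng = np.random.default_rng(seed)
    n_shells = model.grid.n_shells
    batch_edges = np.linspace(0, n_histories, n_batches + 1).astype(int)
    batch_density = np.zeros((n_batches, n_shells))
    batch_deposit = np.zeros(n_batches)
    batch_escape = np.zeros(n_batches)

    for b in range(n_batches):
        nb = int(batch_edges[b + 1] - batch_edges[b])
        tally = np.zeros(n_shells)
        escaped = [0.0]

        if origin_points is not None:
            idx = rng.integers(0, len(origin_points), nb)
            decay_pos = origin_points[idx]
        else:
            if prob is None:
                idx = rng.integers(0, len(centres), nb)
            else:
                idx = rng.choice(len(centres), size=nb, p=prob)
            decay_pos = centres[idx] + model.cluster_radius * _isotropic_directions(rng, nb)

        # electrons
        e_counts = _sample_multiplicity(rng, nuclide.p_e, nb) \
            if particles in ("all", "electrons") else np.zeros(nb, dtype=np.int64)
        n_e = int(e_counts.sum())
        if n_e:
            fracs = np.array([f for _, f in nuclide.beta_spectra]) / nuclide.p_e
            branch = rng.choice(len(nuclide.beta_spectra), size=n_e, p=fracs)
            e_energy = np.empty(n_e)
            for k, (spec, _) in enumerate(nuclide.beta_spectra):
                sel = branch == k
                if sel.any():
                    e_energy[sel] = spec.sample(rng, int(sel.sum()))
            e_pos = np.repeat(decay_pos, e_counts, axis=0)
            stops = _transport_electrons(
                e_pos, e_energy, rng, model, tables, tally, escaped,
                cutoff, max_step_cm, max_frac_eloss,
            )
            if include_annihilation and nuclide.is_positron_emitter and len(stops):
                ann_pos = np.repeat(stops, 2, axis=0)
                ann_e = np.full(len(ann_pos), ANNIHILATION_PHOTON_MEV)
                _transport_photons(ann_pos, ann_e, rng, model, tables, tally,
                                   escaped, cutoff)

        # photons
        for line in nuclide.gamma_lines if particles in ("all", "photons") else ():
            g_counts = _sample_multiplicity(rng, line.yield_, nb)
            n_g = int(g_counts.sum())
            if n_g:
                g_pos = np.repeat(decay_pos, g_counts, axis=0)
                g_energy = np.full(n_g, line.energy)
                _transport_photons(g_pos, g_energy, rng, model, tables, tally,
                                   escaped, cutoff)

        batch_density[b] = tally / nb / model.grid.volumes
        batch_deposit[b] = tally.sum() / nb
        batch_escape[b] = escaped[0] / nb

    mean_density = batch_density.mean(axis=0)
    se_density = batch_density.std(axis=0, ddof=1) / math.sqrt(n_batches)
    balance = batch_deposit + batch_escape
    if particles == "electrons":
        emitted = nuclide.mean_beta_energy_per_decay
    elif particles == "photons":
        emitted = nuclide.mean_gamma_energy_per_decay
    else:
        emitted = nuclide.mean_energy_per_decay
    if include_annihilation and nuclide.is_positron_emitter and particles != "photons":
        emitted = emitted + 2.0 * ANNIHILATION_PHOTON_MEV * nuclide.p_e
    return EnergyDepositionProfile(
        grid=model.grid,
        energy_density=mean_density,
        se=se_density,
        media=model.shell_media(),
        n_histories=n_histories,
        n_batches=n_batches,
        deposited_per_decay=float(batch_deposit.mean()),
        escaped_per_decay=float(batch_escape.mean()),
        balance_se=float(balance.std(ddof=1) / math.sqrt(n_batches)),
        emitted_per_decay=emitted,
    )


def estimate_required_histories(profile: EnergyDepositionProfile,
                                target_rel_se: float) -> int:
    """Histories needed for max per-shell relative SE <= target (1/sqrt(N) law)."""
    if target_rel_se <= 0:
        raise ValueError("target relative SE must be positive")
    if profile.n_batches < 2:
        raise ValueError("profile needs at least 2 batches")
    current = profile.max_relative_se
    if current <= target_rel_se or current == 0.0:
        return profile.n_histories
    return int(math.ceil(profile.n_histories * (current / target_rel_se) ** 2))
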