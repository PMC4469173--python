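"""Synthetic fixtures: material tables, toy geometries, randomized parameters.

Everything the pipeline consumes can be regenerated here deterministically,
so every stage is testable without any external download: interaction
tables from closed-form physics, miniature lattice tumours small enough for
brute-force TCP oracles, and randomized (but physiologically banded)
radiobiology parameter sets for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (DEFAULT_CLUSTER_RADIUS_CM, DEFAULT_DENSITY_LUNG,
                       DEFAULT_DENSITY_TUMOUR, TissueModel, _lattice_centres)
from .materials import MaterialTable, MaterialTables
from .radiobiology import LUNG_PARAMS, TUMOUR_PARAMS, BiologicalParams

__all__ = [
    "generate_material_tables",
    "generate_toy_tumour",
    "randomized_param_sets",
    "FixtureBundle",
    "generate_fixture_bundle",
]

_MEDIA = {"soft_tissue": DEFAULT_DENSITY_TUMOUR, "lung": DEFAULT_DENSITY_LUNG}


def generate_material_tables(medium: str) -> MaterialTable:
    """Stopping-power / attenuation tables for ``soft_tissue`` or ``lung``."""
    if medium not in _MEDIA:
        raise ValueError(f"medium must be one of {tuple(_MEDIA)}, got {medium!r}")
    return MaterialTable.from_functional_fits(medium, _MEDIA[medium])


def generate_toy_tumour(n_clusters: int, seed: int = 0,
                        cluster_radius: float = DEFAULT_CLUSTER_RADIUS_CM) -> TissueModel:
    """Miniature lattice tumour of ``n_clusters`` clusters, origin outward.

    Lattice sites are taken closest-first; ties at equal radius are broken
    by a seeded shuffle, so a fixed seed reproduces the layout exactly.
    The model carries no lung shell: it exists for brute-force TCP oracles
    where the full product over clusters is directly computable.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    spacing = 2.0 * cluster_radius
    # enough lattice shells to cover n_clusters sites
    max_r = spacing * (int(np.ceil((3.0 * n_clusters / (4.0 * np.pi)) ** (1 / 3))) + 2)
    pts = _lattice_centres(max_r, spacing, "origin")
    r2 = np.einsum("ij,ij->i", pts, pts)
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(len(pts)), np.round(r2 / spacing**2).astype(int)))
    chosen = pts[order[:n_clusters]]
    radius = float(np.linalg.norm(chosen, axis=1).max()) + cluster_radius
    return TissueModel(
        tumour_radius=max(radius, 2.001 * cluster_radius),
        cluster_radius=cluster_radius,
        lung_shell_thickness=0.0,
        density_tumour=DEFAULT_DENSITY_TUMOUR,
        density_lung=DEFAULT_DENSITY_LUNG,
        cluster_centres_tumour=chosen,
        cluster_centres_lung=np.empty((0, 3)),
    )


def randomized_param_sets(n: int, seed: int = 0) -> list[BiologicalParams]:
    """Random LQ parameter sets within physiologically anchored bands."""
    if n < 1:
        raise ValueError("need at least one parameter set")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n):
        sets.append(
            BiologicalParams(
                t_bio=rng.uniform(1.0, 10.0),
                alpha_over_beta=rng.uniform(1.0, 20.0),
                mu=rng.uniform(0.1, 3.0),
                alpha=rng.uniform(0.01, 1.0),
                cell_density=TUMOUR_PARAMS.cell_density,
            )
        )
    return sets


@dataclass(frozen=True)
class FixtureBundle:
    """Everything a pipeline test needs, regenerated from one seed."""

    seed: int
    materials: MaterialTables
    tumour_params: BiologicalParams
    lung_params: BiologicalParams
    toy_tumours: tuple[TissueModel, ...]
    random_params: tuple[BiologicalParams, ...]


def generate_fixture_bundle(seed: int = 0,
                            toy_sizes: tuple[int, ...] = (5, 27, 100)) -> FixtureBundle:
    return FixtureBundle(
        seed=seed,
        materials=MaterialTables(
            soft_tissue=generate_material_tables("soft_tissue"),
            lung=generate_material_tables("lung"),
        ),
        tumour_params=TUMOUR_PARAMS,
        lung_params=LUNG_PARAMS,
        toy_tumours=tuple(generate_toy_tumour(n, seed) for n in toy_sizes),
        random_params=tuple(randomized_param_sets(10, seed)),
    )
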