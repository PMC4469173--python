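"""Monte Carlo transport: conservation, determinism, convergence scaling."""

import numpy as np
import pytest

from ritdose.geometry import TissueModel, build_tissue_model
from ritdose.sources import radial_emission_weights
from ritdose.transport import (estimate_required_histories, run_transport)


def _bare_sphere(radius=3.0, density=1.06):
    """Homogeneous soft-tissue sphere with a single nominal cluster."""
    return TissueModel(
        tumour_radius=radius, cluster_radius=0.025, lung_shell_thickness=0.0,
        density_tumour=density, density_lung=0.26,
        cluster_centres_tumour=np.zeros((1, 3)),
        cluster_centres_lung=np.empty((0, 3)),
    )


def test_point_source_full_absorption(nuclides):
    """A central pure-beta source in a large sphere deposits everything."""
    prof = run_transport(nuclides["Y90"], _bare_sphere(), None, 20_000, seed=1,
                         origin_points=np.zeros((1, 3)))
    assert prof.escaped_per_decay == 0.0
    assert abs(prof.deposited_per_decay - prof.emitted_per_decay) < 3 * prof.balance_se


def test_deposition_confined_to_csda_range(nuclides, material_tables):
    """Beyond ~2x the endpoint CSDA range the deposit is negligible."""
    prof = run_transport(nuclides["Y90"], _bare_sphere(), None, 10_000, seed=2,
                         origin_points=np.zeros((1, 3)))
    endpoint = max(s.endpoint_energy for s, _ in nuclides["Y90"].beta_spectra)
    r_max = material_tables.soft_tissue.csda_range_at(endpoint) / 1.06  # cm
    shell_energy = prof.energy_density * prof.grid.volumes
    far = prof.grid.centres > 2 * r_max
    assert shell_energy[far].sum() < 0.01 * shell_energy.sum()


def test_determinism_under_fixed_seed(model05, nuclides):
    w = radial_emission_weights(model05, "uniform")
    a = run_transport(nuclides["Lu177"], model05, w, 3000, seed=9)
    b = run_transport(nuclides["Lu177"], model05, w, 3000, seed=9)
    assert np.array_equal(a.energy_density, b.energy_density)
    assert a.escaped_per_decay == b.escaped_per_decay


def test_energy_balance_with_photons(model05, nuclides):
    """Deposited + escaped equals emitted for a gamma-rich isotope."""
    w = radial_emission_weights(model05, "uniform")
    prof = run_transport(nuclides["I131"], model05, w, 10_000, seed=4)
    balance = prof.deposited_per_decay + prof.escaped_per_decay
    assert abs(balance - prof.emitted_per_decay) < 3 * prof.balance_se


def test_denser_medium_contracts_the_profile(nuclides):
    """Doubling density shrinks the radius enclosing 90% of the energy."""
    def r90(density):
        prof = run_transport(nuclides["Y90"], _bare_sphere(density=density), None,
                             10_000, seed=5, origin_points=np.zeros((1, 3)))
        e = prof.energy_density * prof.grid.volumes
        cum = np.cumsum(e) / e.sum()
        return prof.grid.centres[np.searchsorted(cum, 0.9)]

    assert r90(2.12) < r90(1.06)


def test_particle_filters_partition_the_tally(model05, nuclides):
    w = radial_emission_weights(model05, "uniform")
    full = run_transport(nuclides["Lu177"], model05, w, 4000, seed=6)
    beta = run_transport(nuclides["Lu177"], model05, w, 4000, seed=6,
                         particles="electrons")
    gamma = run_transport(nuclides["Lu177"], model05, w, 4000, seed=6,
                          particles="photons")
    assert beta.emitted_per_decay == pytest.approx(
        nuclides["Lu177"].mean_beta_energy_per_decay)
    assert gamma.emitted_per_decay == pytest.approx(
        nuclides["Lu177"].mean_gamma_energy_per_decay)
    total = beta.deposited_per_decay + gamma.deposited_per_decay
    assert total == pytest.approx(full.deposited_per_decay, rel=0.1)


def test_annihilation_toggle_adds_photon_energy(nuclides):
    base = run_transport(nuclides["I124"], _bare_sphere(), None, 5000, seed=7,
                         origin_points=np.zeros((1, 3)), particles="electrons")
    ann = run_transport(nuclides["I124"], _bare_sphere(), None, 5000, seed=7,
                        origin_points=np.zeros((1, 3)), particles="electrons",
                        include_annihilation=True)
    extra = 2 * 0.511 * nuclides["I124"].p_e
    assert ann.emitted_per_decay == pytest.approx(base.emitted_per_decay + extra,
                                                  rel=1e-3)
    assert (ann.deposited_per_decay + ann.escaped_per_decay
            > base.deposited_per_decay + base.escaped_per_decay)


def test_uniform_source_isotropy(model05, nuclides):
    """Two independent streams agree within a few SE on well-sampled shells."""
    w = radial_emission_weights(model05, "uniform")
    a = run_transport(nuclides["Y90"], model05, w, 20_000, seed=11)
    b = run_transport(nuclides["Y90"], model05, w, 20_000, seed=12)
    mask = (a.se > 0) & (b.se > 0) & (a.energy_density > 0.01 * a.energy_density.max())
    z = np.abs(a.energy_density[mask] - b.energy_density[mask]) / np.hypot(
        a.se[mask], b.se[mask])
    assert np.quantile(z, 0.95) < 4.0


class TestRequiredHistories:
    def _profile_with(self, n, max_rel):
        class P:
            n_histories = n
            n_batches = 10
            max_relative_se = max_rel
        return P()

    def test_inverse_square_root_law(self):
        assert estimate_required_histories(self._profile_with(10_000, 0.10), 0.05) \
            == pytest.approx(40_000, rel=1e-6)
        assert estimate_required_histories(self._profile_with(1000, 0.20), 0.05) \
            == pytest.approx(16_000, rel=1e-6)

    def test_already_converged_returns_current(self):
        assert estimate_required_histories(self._profile_with(5000, 0.03), 0.05) == 5000
        assert estimate_required_histories(self._profile_with(5000, 0.0), 0.05) == 5000


def test_input_validation(model05, nuclides):
    w = radial_emission_weights(model05, "uniform")
    with pytest.raises(ValueError, match="histories"):
        run_transport(nuclides["Y90"], model05, w, 10, seed=1)
    with pytest.raises(ValueError, match="normalizable"):
        run_transport(nuclides["Y90"], model05,
                      np.zeros(model05.n_tumour_clusters), 2000, seed=1)
    with pytest.raises(ValueError, match="particles"):
        run_transport(nuclides["Y90"], model05, w, 2000, seed=1, particles="muons")
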