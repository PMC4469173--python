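"""BED conversion, Poisson cluster kill and TCP products."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ritdose.geometry import shell_index
from ritdose.radiobiology import (LUNG_PARAMS, TUMOUR_PARAMS, BiologicalParams,
                                  bed_profile, cluster_kill_probability,
                                  minimum_uniform_dose_for_control,
                                  tumour_control_probability)
from ritdose.synthetic import generate_toy_tumour


def test_reference_parameter_sets():
    assert (TUMOUR_PARAMS.alpha_over_beta, TUMOUR_PARAMS.mu, TUMOUR_PARAMS.alpha) \
        == (10.0, 1.39, 0.35)
    assert (LUNG_PARAMS.t_bio, LUNG_PARAMS.alpha_over_beta, LUNG_PARAMS.mu,
            LUNG_PARAMS.alpha) == (3.0, 3.0, 0.46, 0.031)
    assert TUMOUR_PARAMS.cell_density == LUNG_PARAMS.cell_density == 9.5e7
    assert TUMOUR_PARAMS.lambda_bio == pytest.approx(math.log(2) / 144.0)


class TestBED:
    def test_closed_form_worked_example(self):
        # D = 55 Gy, lambda_eff for Y90 + 6 d biological clearance
        lam = math.log(2) / 64.1 + math.log(2) / 144.0
        bed = bed_profile(np.array([55.0]), TUMOUR_PARAMS, lam)
        expected = 55.0 + lam / (lam + 1.39) * 55.0**2 / 10.0
        assert bed.values[0] == pytest.approx(expected, rel=1e-12)
        assert bed.values[0] == pytest.approx(58.36, abs=0.01)

    def test_zero_dose_zero_bed(self):
        assert bed_profile(np.zeros(4), TUMOUR_PARAMS, 0.01).values.sum() == 0.0

    def test_fast_repair_limit_recovers_physical_dose(self):
        fast = BiologicalParams(t_bio=6, alpha_over_beta=10, mu=1e9, alpha=0.35,
                                cell_density=9.5e7)
        bed = bed_profile(np.array([40.0]), fast, 0.0156)
        assert bed.values[0] == pytest.approx(40.0, rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(d=st.floats(0, 500), lam=st.floats(1e-4, 0.1), mu=st.floats(0.1, 3.0),
           ab=st.floats(1.0, 20.0))
    def test_bed_dominates_dose(self, d, lam, mu, ab):
        p = BiologicalParams(t_bio=6, alpha_over_beta=ab, mu=mu, alpha=0.35,
                             cell_density=9.5e7)
        assert bed_profile(np.array([d]), p, lam).values[0] >= d

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            bed_profile(np.array([1.0]), TUMOUR_PARAMS, 0.0)


class TestClusterKill:
    def test_limits(self):
        n = 6218
        assert cluster_kill_probability(0.0, TUMOUR_PARAMS, n) \
            == pytest.approx(math.exp(-n))
        assert cluster_kill_probability(1e6, TUMOUR_PARAMS, n) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        # independent arithmetic: exp(-N exp(-alpha BED))
        val = cluster_kill_probability(48.4, TUMOUR_PARAMS, 6218)
        expected = math.exp(-6218 * math.exp(-0.35 * 48.4))
        assert val == pytest.approx(expected, rel=1e-14)

    def test_monotone_in_bed(self):
        beds = np.linspace(0, 100, 50)
        p = cluster_kill_probability(beds, TUMOUR_PARAMS, 6218)
        assert np.all(np.diff(p) >= 0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_kill_probability(10.0, TUMOUR_PARAMS, 0)


class TestTCP:
    def test_uniform_bed_algebraic_identity(self):
        toy = generate_toy_tumour(50, seed=1)
        bed = np.full(toy.grid.n_shells, 60.0)
        res = tumour_control_probability(bed, toy, TUMOUR_PARAMS)
        n_cells = TUMOUR_PARAMS.cells_per_cluster(toy.cluster_radius)
        p = cluster_kill_probability(60.0, TUMOUR_PARAMS, n_cells)
        assert res.tcp == pytest.approx(float(p) ** 50, rel=1e-12)

    def test_log_domain_reference_value(self):
        # p^n for p = 0.9999, n = 3701 clusters
        assert 0.9999 ** 3701 == pytest.approx(0.6906, abs=5e-4)

    def test_annihilation_by_cold_shell(self):
        toy = generate_toy_tumour(50, seed=1)
        bed = np.full(toy.grid.n_shells, 60.0)
        bed[0] = 0.0  # central clusters receive nothing -> certain survival
        res = tumour_control_probability(bed, toy, TUMOUR_PARAMS)
        assert res.tcp == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("n_clusters", [5, 27, 100])
    def test_matches_bruteforce_product(self, n_clusters):
        """Pipeline TCP == direct product over clusters on toy tumours."""
        toy = generate_toy_tumour(n_clusters, seed=4)
        rng = np.random.default_rng(100 + n_clusters)
        bed = rng.uniform(40.0, 70.0, toy.grid.n_shells)
        res = tumour_control_probability(bed, toy, TUMOUR_PARAMS)
        n_cells = TUMOUR_PARAMS.cells_per_cluster(toy.cluster_radius)
        idx = shell_index(toy.cluster_centres_tumour, toy.grid)
        brute = 1.0
        for i in idx:
            brute *= float(cluster_kill_probability(bed[i], TUMOUR_PARAMS, n_cells))
        assert res.tcp == pytest.approx(brute, rel=1e-12)
        assert res.cluster_counts.sum() == n_clusters

    def test_monotone_in_shell_bed(self):
        toy = generate_toy_tumour(30, seed=2)
        bed = np.full(toy.grid.n_shells, 55.0)
        base = tumour_control_probability(bed, toy, TUMOUR_PARAMS).tcp
        bed[0] += 5.0
        assert tumour_control_probability(bed, toy, TUMOUR_PARAMS).tcp >= base

    def test_incomplete_profile_rejected(self, model05):
        with pytest.raises(ValueError, match="cover"):
            tumour_control_probability(np.array([50.0]), model05, TUMOUR_PARAMS)


def test_minimum_uniform_dose_in_expected_band(model05):
    """Minimal uniform dose for control sits in the mid-50s of Gy."""
    lam = math.log(2) / 64.1 + math.log(2) / 144.0
    d = minimum_uniform_dose_for_control(model05, TUMOUR_PARAMS, lam)
    assert 45.0 <= d <= 65.0
    # at the crossing the TCP really is the threshold
    bed = bed_profile(np.full(model05.grid.n_shells, d), TUMOUR_PARAMS, lam)
    assert tumour_control_probability(bed, model05, TUMOUR_PARAMS).tcp \
        == pytest.approx(0.99, abs=1e-6)
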