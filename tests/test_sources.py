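"""Source distributions, activities and cumulated decays."""

import math

import numpy as np
import pytest

from ritdose.sources import (SourceDistribution, antibodies_per_cluster,
                             radial_emission_weights, total_activity)
from ritdose.synthetic import generate_toy_tumour


class TestAntibodiesPerCluster:
    def test_reference_value(self):
        # 4 pi (0.025)^2 x 1e9 / cm^2
        assert antibodies_per_cluster(1e9, 0.025) == pytest.approx(7.854e6, rel=1e-3)

    def test_linearity(self):
        with pytest.warns(UserWarning):
            ten_x = antibodies_per_cluster(1e11, 0.025)
        assert ten_x == pytest.approx(100 * antibodies_per_cluster(1e9, 0.025))

    def test_degenerate_inputs(self):
        assert antibodies_per_cluster(1e9, 0.0) == 0.0
        with pytest.raises(ValueError):
            antibodies_per_cluster(0.0, 0.025)


class TestActivity:
    def test_closed_form_on_known_cluster_count(self, nuclides):
        # A = lambda_phys n_u n_a n_mAb; the published worked value 87.32 kBq
        # corresponds to n_u = 3701 clusters at covering 1e9 /cm^2
        lam = nuclides["Y90"].lambda_phys / 3600.0
        a = lam * 3701 * 1.0 * antibodies_per_cluster(1e9, 0.025)
        assert a / 1e3 == pytest.approx(87.32, rel=2e-3)

    def test_activity_report_consistency(self, model05, nuclides):
        src = SourceDistribution(covering_fraction=1e9, n_atoms_per_no=1.0)
        rep = total_activity(nuclides["Y90"], model05, src)
        lam = nuclides["Y90"].lambda_phys / 3600.0
        expected = lam * model05.n_tumour_clusters * antibodies_per_cluster(1e9, 0.025)
        assert rep.total_activity_bq == pytest.approx(expected, rel=1e-12)
        assert rep.lambda_eff == pytest.approx(rep.lambda_phys + rep.lambda_bio)
        assert rep.cumulated_decays == pytest.approx(
            rep.total_activity_bq * 3600.0 / rep.lambda_eff, rel=1e-12
        )

    def test_zero_atoms_zero_activity(self, model05, nuclides):
        src = SourceDistribution(n_atoms_per_no=0.0)
        assert total_activity(nuclides["Y90"], model05, src).total_activity_bq == 0.0

    def test_uptake_delay_factor(self, model05, nuclides):
        # 48 h of physical decay before maximum accumulation (Re-188)
        direct = total_activity(nuclides["Re188"], model05, SourceDistribution())
        delayed = total_activity(
            nuclides["Re188"], model05, SourceDistribution(uptake_delay_h=48.0)
        )
        factor = delayed.total_activity_bq / direct.total_activity_bq
        assert factor == pytest.approx(math.exp(-math.log(2) * 48 / 16.9), rel=1e-12)
        assert factor == pytest.approx(0.1394, abs=5e-4)

    def test_linearity_in_loading_and_covering(self, model05, nuclides):
        base = total_activity(nuclides["Lu177"], model05, SourceDistribution())
        double = total_activity(
            nuclides["Lu177"], model05, SourceDistribution(n_atoms_per_no=2.0)
        )
        rich = total_activity(
            nuclides["Lu177"], model05, SourceDistribution(covering_fraction=2e9)
        )
        assert double.total_activity_bq == pytest.approx(2 * base.total_activity_bq)
        assert rich.total_activity_bq == pytest.approx(2 * base.total_activity_bq)

    def test_lung_compartment_scales_by_ratio(self, model05, nuclides):
        src = SourceDistribution()
        t = total_activity(nuclides["Y90"], model05, src, "tumour")
        l = total_activity(nuclides["Y90"], model05, src, "lung")
        per_t = t.total_activity_bq / model05.n_tumour_clusters
        per_l = l.total_activity_bq / model05.n_lung_clusters
        assert per_t / per_l == pytest.approx(7.0, rel=1e-12)
        # lung clears faster (3 d biological half-life)
        assert l.lambda_bio > t.lambda_bio


class TestRadialWeights:
    def test_uniform_ratio_exact(self, model05):
        w = radial_emission_weights(model05, "uniform")
        assert np.allclose(w.tumour, w.tumour[0])
        assert w.tumour[0] / w.lung == pytest.approx(7.0, rel=1e-12)

    def test_linear_ramp(self, model05):
        w = radial_emission_weights(model05, "linear")
        r = np.linalg.norm(model05.cluster_centres_tumour, axis=1)
        at_surface = w.tumour[np.argmax(r)]
        near_half = np.argmin(np.abs(r - model05.tumour_radius / 2))
        assert at_surface / w.tumour[near_half] == pytest.approx(
            r.max() / r[near_half], rel=1e-9
        )

    def test_exponential_monotone_with_configured_contrast(self, model05):
        w = radial_emission_weights(model05, "exponential",
                                    centre_to_surface_ratio=0.01)
        r = np.linalg.norm(model05.cluster_centres_tumour, axis=1)
        order = np.argsort(r)
        assert np.all(np.diff(w.tumour[order]) >= -1e-12)
        # centre-to-surface contrast follows the configured ratio
        contrast = w.tumour[order][0] / w.tumour[order][-1]
        expected = math.exp((r[order][0] - r[order][-1])
                            / (0.5 / math.log(100.0)))
        assert contrast == pytest.approx(expected, rel=1e-9)

    def test_mean_tumour_to_lung_ratio_all_shapes(self, model05):
        for shape in ("uniform", "linear", "exponential"):
            w = radial_emission_weights(model05, shape)
            assert w.tumour.mean() / w.lung == pytest.approx(7.0, rel=1e-12)
            assert np.all(w.tumour >= 0)

    def test_unknown_shape_rejected(self, model05):
        with pytest.raises(ValueError, match="shape"):
            radial_emission_weights(model05, "gaussian")
        with pytest.raises(ValueError, match="shape"):
            SourceDistribution(shape="gaussian")

    def test_probabilities_normalised_on_toy(self):
        toy = generate_toy_tumour(33, seed=1)
        w = radial_emission_weights(toy, "linear")
        assert w.tumour_probabilities().sum() == pytest.approx(1.0, rel=1e-12)
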