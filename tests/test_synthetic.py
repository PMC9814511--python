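"""Generative model: template geometry, condition effects, simulation."""

import numpy as np
import pytest

import gradientspace as gs
from gradientspace.errors import ConfigurationError, ValidationError
from gradientspace.synthetic import DEFAULT_CAP_LABELS


class TestMakeTemplate:
    def test_deterministic_and_seed_sensitive(self, scheme_small):
        a = gs.make_template(scheme_small, seed=5)
        b = gs.make_template(scheme_small, seed=5)
        c = gs.make_template(scheme_small, seed=6)
        np.testing.assert_array_equal(a.latent_coords, b.latent_coords)
        assert not np.array_equal(a.latent_coords, c.latent_coords)

    def test_axis_orderings(self, scheme400):
        tpl = gs.make_template(scheme400, seed=0)
        cen = tpl.network_centroids
        # unimodal-to-transmodal ordering on gradient 1
        assert cen["DMN"][0] > cen["VIS"][0]
        # visual vs somatomotor on gradient 2
        assert np.sign(cen["VIS"][1]) != np.sign(cen["SMN"][1])

    def test_latent_columns_roughly_centered(self, scheme400):
        tpl = gs.make_template(scheme400, seed=1)
        means = tpl.latent_coords.mean(axis=0)
        spread = tpl.latent_coords.std(axis=0)
        assert np.all(np.abs(means) < 0.15 * spread.max())

    def test_cluster_layout_sd_zero_puts_parcels_on_centroids(self, scheme_small):
        tpl = gs.make_template(scheme_small, within_network_sd=0.0, seed=0,
                               layout="cluster")
        for net in gs.NETWORKS:
            idx = scheme_small.indices_of(net)
            np.testing.assert_allclose(
                tpl.latent_coords[idx], np.tile(tpl.network_centroids[net], (idx.size, 1))
            )

    def test_missing_network_rejected(self):
        scheme = gs.ParcellationScheme(
            parcel_names=("a", "b"), networks=("VIS", "DMN"), hemispheres=("NA", "NA")
        )
        with pytest.raises(ConfigurationError):
            gs.make_template(scheme)


class TestApplyCondition:
    def test_identity_effect_is_identity(self, template_small):
        out = gs.apply_condition(template_small, gs.ConditionEffect())
        np.testing.assert_allclose(out.latent_coords, template_small.latent_coords)

    def test_compression_scales_axis_range_exactly(self, template_small):
        eff = gs.ConditionEffect(axis_compression=(0.5, 1, 1))
        out = gs.apply_condition(template_small, eff)
        for k, expected in [(0, 0.5), (1, 1.0), (2, 1.0)]:
            r0 = np.ptp(template_small.latent_coords[:, k])
            r1 = np.ptp(out.latent_coords[:, k])
            assert r1 / r0 == pytest.approx(expected, abs=1e-9)

    def test_compression_is_monotone_within_axis(self, template_small):
        eff = gs.ConditionEffect(axis_compression=(0.6, 1, 1))
        out = gs.apply_condition(template_small, eff)
        order0 = np.argsort(template_small.latent_coords[:, 0])
        x1 = out.latent_coords[order0, 0]
        assert np.all(np.diff(x1) >= -1e-12)

    def test_full_convergence_collapses_van_dmn(self, template_small):
        eff = gs.ConditionEffect(van_dmn_convergence=1.0)
        out = gs.apply_condition(template_small, eff)
        assert out.centroid_distance("VAN", "DMN") == pytest.approx(0.0, abs=1e-10)
        # other networks untouched
        for net in ("VIS", "SMN", "DAN", "LIM", "FPN"):
            idx = template_small.scheme.indices_of(net)
            np.testing.assert_allclose(
                out.latent_coords[idx], template_small.latent_coords[idx]
            )

    def test_half_convergence_halves_distance(self, template_small):
        eff = gs.ConditionEffect(van_dmn_convergence=0.5)
        out = gs.apply_condition(template_small, eff)
        assert out.centroid_distance("VAN", "DMN") == pytest.approx(
            0.5 * template_small.centroid_distance("VAN", "DMN")
        )

    @pytest.mark.parametrize("bad", [(0.0, 1, 1), (1.2, 1, 1), (-0.5, 1, 1)])
    def test_compression_bounds(self, bad):
        with pytest.raises(ValidationError):
            gs.ConditionEffect(axis_compression=bad)


class TestOccupancyFromGeometry:
    def test_beta_zero_is_identity(self, template_small):
        base = np.full(8, 1 / 8)
        eff = gs.ConditionEffect(van_dmn_convergence=0.5, cap_coupling_beta=0.0)
        np.testing.assert_allclose(
            gs.occupancy_from_geometry(template_small, eff, base), base
        )

    def test_convergence_raises_van_plus(self, template_small):
        base = np.full(8, 1 / 8)
        eff = gs.ConditionEffect(van_dmn_convergence=0.5, cap_coupling_beta=2.0)
        rates = gs.occupancy_from_geometry(template_small, eff, base)
        lab = list(DEFAULT_CAP_LABELS)
        assert rates[lab.index("VAN+")] > 1 / 8
        assert rates[lab.index("DMN+")] < 1 / 8
        assert rates[lab.index("DAN+")] < 1 / 8

    def test_output_is_simplex(self, template_small, rng):
        base = rng.dirichlet(np.ones(8))
        eff = gs.ConditionEffect(van_dmn_convergence=0.7, cap_coupling_beta=1.5)
        rates = gs.occupancy_from_geometry(template_small, eff, base)
        assert rates.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(rates >= 0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValidationError):
            gs.ConditionEffect(cap_coupling_beta=-1.0)


class TestSimulateSubject:
    def test_bit_identical_under_fixed_seed(self, template_small):
        caps = gs.default_cap_spec(template_small.scheme)
        a = gs.simulate_subject(template_small, caps, T=40, seed=9)
        b = gs.simulate_subject(template_small, caps, T=40, seed=9)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].params, b[1].params)
        np.testing.assert_array_equal(a[2], b[2])

    def test_identical_latent_coords_share_signal(self, scheme_small):
        tpl = gs.make_template(scheme_small, seed=0)
        coords = tpl.latent_coords.copy()
        coords[1] = coords[0]  # duplicate one parcel's coordinates
        from dataclasses import replace

        tpl2 = replace(tpl, latent_coords=coords)
        ts, _, _ = gs.simulate_subject(tpl2, None, T=3000, noise_sd=0.0, seed=1)
        r = np.corrcoef(ts.data[:, 0], ts.data[:, 1])[0, 1]
        assert r == pytest.approx(1.0, abs=0.01)

    def test_cap_label_frequencies_match_stationary_law(self, scheme_small):
        caps = gs.default_cap_spec(scheme_small, base_rates=None, stickiness=0.3)
        tpl = gs.make_template(scheme_small, seed=0)
        _, _, labels = gs.simulate_subject(tpl, caps, T=10_000, seed=4)
        freq = np.bincount(labels, minlength=caps.k) / labels.size
        pi = caps.stationary_distribution()
        np.testing.assert_allclose(freq, pi, atol=0.02)

    def test_non_stochastic_transition_matrix_rejected(self, scheme_small):
        caps = gs.default_cap_spec(scheme_small)
        from dataclasses import replace

        bad = caps.transition_matrix.copy()
        bad[0, 0] += 0.1
        with pytest.raises(ValidationError):
            replace(caps, transition_matrix=bad)

    def test_minimum_length_enforced(self, template_small):
        with pytest.raises(ValidationError):
            gs.simulate_subject(template_small, None, T=5)


class TestSimulateCohort:
    def test_paired_subjects_share_jitter(self, scheme_small):
        effects = {"BL": gs.ConditionEffect(), "X": gs.ConditionEffect()}
        cohort = gs.simulate_cohort(scheme_small, effects, n_subjects=3, paired=True,
                                    T=20, seed=0, caps=None)
        assert len(cohort.scans) == 6
        by_subject = {}
        for scan in cohort.scans:
            by_subject.setdefault(scan.subject_id, []).append(scan)
        for sid, scans in by_subject.items():
            np.testing.assert_allclose(
                scans[0].template.latent_coords, scans[1].template.latent_coords
            )

    def test_unpaired_jitters_are_independent(self, scheme_small):
        effects = {"BL": gs.ConditionEffect(), "X": gs.ConditionEffect()}
        corrs = []
        for seed in range(30):
            cohort = gs.simulate_cohort(scheme_small, effects, n_subjects=2,
                                        paired=False, T=20, seed=seed, caps=None)
            subj = cohort.by_condition("BL")[0].template.latent_coords
            other = cohort.by_condition("X")[0].template.latent_coords
            base = cohort.base_template.latent_coords
            da = (subj - base).ravel()
            db = (other - base).ravel()
            corrs.append(np.corrcoef(da, db)[0, 1])
        assert abs(np.mean(corrs)) < 0.15

    def test_cohort_size_and_validation(self, scheme_small):
        effects = {"BL": gs.ConditionEffect(), "PDS": gs.ConditionEffect()}
        cohort = gs.simulate_cohort(scheme_small, effects, n_subjects=26, T=20,
                                    seed=1, caps=None)
        assert len(cohort.scans) == 52
        with pytest.raises(ValidationError):
            gs.simulate_cohort(scheme_small, effects, n_subjects=1, T=20)
        with pytest.raises(ValidationError):
            gs.simulate_cohort(scheme_small, {}, n_subjects=4, T=20)


class TestDefaultCapSpec:
    def test_transition_rows_stochastic_and_stationary_matches_base(self, scheme_small):
        base = np.array([0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        caps = gs.default_cap_spec(scheme_small, base_rates=base, stickiness=0.6)
        np.testing.assert_allclose(caps.transition_matrix.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(caps.stationary_distribution(), base, atol=1e-10)

    def test_network_patterns_peak_on_their_network(self, scheme_small):
        caps = gs.default_cap_spec(scheme_small)
        for i, lab in enumerate(caps.labels):
            if lab in ("GN+", "GN-"):
                continue
            net = lab[:-1]
            idx = scheme_small.indices_of(net)
            on = caps.centroids[i, idx].mean()
            off = np.delete(caps.centroids[i], idx).mean()
            assert on > 0 > off
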