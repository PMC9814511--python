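"""Co-activation pattern derivation, assignment, and occurrence rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import gradientspace as gs
from gradientspace.cap import CapSet, _zscore_rows
from gradientspace.errors import DegenerateInputError, ValidationError


def planted_volumes(rng, n_per=40, P=60, k=3, noise=0.3):
    centroids = _zscore_rows(rng.normal(size=(k, P)))
    labels = np.repeat(np.arange(k), n_per)
    volumes = centroids[labels] + rng.normal(0, noise, size=(k * n_per, P))
    return volumes, centroids, labels


class TestDeriveCaps:
    def test_recovers_planted_centroids_with_hungarian_matching(self, rng):
        volumes, true_c, _ = planted_volumes(rng)
        caps = gs.derive_caps(volumes, k=3, n_restarts=10, seed=0)
        corr = np.corrcoef(np.vstack([caps.centroids, true_c]))[:3, 3:]
        row, col = linear_sum_assignment(-np.abs(corr))
        assert np.all(np.abs(corr[row, col]) > 0.99)

    def test_duplication_invariance(self, rng):
        volumes, _, _ = planted_volumes(rng)
        caps1 = gs.derive_caps(volumes, k=3, seed=1)
        caps2 = gs.derive_caps(np.vstack([volumes, volumes]), k=3, seed=1)
        corr = np.corrcoef(np.vstack([caps1.centroids, caps2.centroids]))[:3, 3:]
        row, col = linear_sum_assignment(-np.abs(corr))
        assert np.all(np.abs(corr[row, col]) > 0.9999)

    def test_deterministic_given_seed(self, rng):
        volumes, _, _ = planted_volumes(rng)
        a = gs.derive_caps(volumes, k=3, seed=42)
        b = gs.derive_caps(volumes, k=3, seed=42)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_k_exceeding_volumes_rejected(self, rng):
        with pytest.raises(ValidationError):
            gs.derive_caps(rng.normal(size=(4, 10)), k=5)


class TestAssignCaps:
    def _simple_caps(self, rng, k=4, P=30):
        return CapSet(
            centroids=_zscore_rows(rng.normal(size=(k, P))),
            labels=tuple(f"C{i}" for i in range(k)),
        )

    def test_volume_equal_to_centroid_gets_its_label(self, rng):
        caps = self._simple_caps(rng)
        data = np.vstack([caps.centroids[2], caps.centroids[0], caps.centroids[2]])
        ts = gs.ParcelTimeSeries(data=data, tr_seconds=2.0)
        asg = gs.assign_caps(ts, caps)
        np.testing.assert_array_equal(asg.per_volume_label, [2, 0, 2])

    def test_negated_global_pattern_maps_to_opposite(self, scheme_small, rng):
        spec = gs.default_cap_spec(scheme_small)
        caps = CapSet(centroids=spec.centroids, labels=spec.labels)
        # an anti-correlated copy of DMN+ must not be labeled DMN+
        v = -spec.centroids[spec.labels.index("DMN+")]
        noise = rng.normal(0, 1e-3, size=(2, scheme_small.n_parcels))
        ts = gs.ParcelTimeSeries(data=np.vstack([v, v]) + noise, tr_seconds=2.0)
        asg = gs.assign_caps(ts, caps)
        assert all(caps.labels[l] != "DMN+" for l in asg.per_volume_label)

    def test_occurrence_rate_is_count_ratio(self, rng):
        caps = self._simple_caps(rng, k=4)
        labels = np.array([0] * 50 + [1] * 100 + [3] * 50)
        data = caps.centroids[labels] + rng.normal(0, 0.05, size=(200, 30))
        ts = gs.ParcelTimeSeries(data=data, tr_seconds=2.0)
        asg = gs.assign_caps(ts, caps)
        np.testing.assert_allclose(asg.occurrence_rate, [0.25, 0.5, 0.0, 0.25])
        assert asg.rate("C1") == 0.5

    def test_censored_volumes_excluded_from_both_sides(self, rng):
        caps = self._simple_caps(rng, k=2)
        labels = np.array([0] * 10 + [1] * 10)
        data = caps.centroids[labels] + rng.normal(0, 0.05, size=(20, 30))
        mask = np.ones(20, dtype=bool)
        mask[:10] = False  # drop every C0 volume
        ts = gs.ParcelTimeSeries(data=data, tr_seconds=2.0, censor_mask=mask)
        asg = gs.assign_caps(ts, caps)
        np.testing.assert_allclose(asg.occurrence_rate, [0.0, 1.0])
        assert asg.per_volume_label.shape == (10,)

    def test_matches_bruteforce_per_volume_loop(self, rng):
        caps = self._simple_caps(rng, k=5, P=25)
        data = rng.normal(size=(40, 25))
        ts = gs.ParcelTimeSeries(data=data, tr_seconds=2.0)
        asg = gs.assign_caps(ts, caps, zscore_volumes=True)
        z = _zscore_rows(data)
        for t in range(40):
            sims = [np.corrcoef(z[t], c)[0, 1] for c in caps.centroids]
            assert asg.per_volume_label[t] == int(np.argmax(sims))

    def test_rates_form_simplex(self, rng):
        caps = self._simple_caps(rng)
        ts = gs.ParcelTimeSeries(data=rng.normal(size=(33, 30)), tr_seconds=2.0)
        asg = gs.assign_caps(ts, caps)
        assert asg.occurrence_rate.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((asg.per_volume_label >= 0) & (asg.per_volume_label < caps.k))


class TestGeometryDynamicsCorrelation:
    def test_constant_rate_flagged_as_ties(self, rng):
        n = 20
        distances = pd.DataFrame(
            {"DMN-VAN": rng.normal(size=n), "DMN-DAN": rng.normal(size=n),
             "DAN-VAN": rng.normal(size=n)}
        )
        rates = pd.DataFrame(
            {"VAN+": np.full(n, 0.2), "DAN+": rng.uniform(size=n),
             "DMN+": rng.uniform(size=n)}
        )
        out = gs.geometry_dynamics_correlation(distances, rates)
        van_rows = out[out["rate"] == "VAN+"]
        assert van_rows["all_ties"].all()
        assert (van_rows["tau_b"] == 0).all()
        assert len(out) == 9
        assert out.loc[~out["all_ties"], "p_fdr"].notna().all()

    def test_scan_mismatch_rejected(self, rng):
        d = pd.DataFrame({"DMN-VAN": rng.normal(size=12)})
        r = pd.DataFrame({"VAN+": rng.uniform(size=11)})
        with pytest.raises(ValidationError):
            gs.geometry_dynamics_correlation(d, r, distance_pairs=("DMN-VAN",),
                                             rate_labels=("VAN+",))

    def test_planted_coupling_has_expected_signs(self, scheme_small):
        """With occupancy coupled to VAN-DMN convergence, the VAN+ rate
        falls with distance and the DMN+ rate rises with it."""
        spec = gs.default_cap_spec(scheme_small)
        base = gs.make_template(scheme_small, seed=2)
        pi0 = spec.stationary_distribution()
        rows_d, rows_r = [], []
        rng = np.random.default_rng(0)
        for _ in range(40):
            gamma = rng.uniform(0, 0.8)
            eff = gs.ConditionEffect(van_dmn_convergence=gamma, cap_coupling_beta=2.0)
            pi = gs.occupancy_from_geometry(base, eff, pi0, spec.labels)
            tpl_c = gs.apply_condition(base, eff)
            rows_d.append({"DMN-VAN": tpl_c.centroid_distance("VAN", "DMN")})
            rows_r.append(dict(zip(spec.labels, pi)))
        out = gs.geometry_dynamics_correlation(
            pd.DataFrame(rows_d), pd.DataFrame(rows_r),
            distance_pairs=("DMN-VAN",), rate_labels=("VAN+", "DMN+", "DAN+"),
        )
        tau = dict(zip(out["rate"], out["tau_b"]))
        assert tau["VAN+"] < 0
        assert tau["DMN+"] > 0
        assert tau["DAN+"] > 0
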