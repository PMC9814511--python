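"""Pre-registered simulation studies exercising the whole pipeline.

Each function runs one self-contained study at fixed, documented
conditions - the same conditions the package's validation suite uses -
and returns its summary quantities.  The studies cover: spectral
correctness of the embedding against a dense oracle, recovery of the
planted latent geometry, detection power and axis specificity for a
planted gradient-1 compression, type-I calibration on null cohorts,
the sign structure of the geometry/CAP-dynamics coupling, and agreement
of the JZS Bayes factor with a Monte-Carlo marginal-likelihood oracle.

Problem sizes: power and recovery studies run the full 400-parcel
scheme with 26 paired subjects and 120-volume scans (4 min at TR 2 s);
the null-calibration study uses a proportional 300-parcel scheme and 16
paired subjects per cohort so that hundreds of replicate cohorts fit in
a routine validation run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import orthogonal_procrustes

from .cap import CapSet
from .connectivity import AffinityMatrix, correlation_to_fisher_z, cosine_affinity, sparsify_rows
from .embedding import align_cohort, diffusion_map
from .geometry import network_geometry
from .io import RunConfig, default_scheme, small_scheme
from .pipeline import cohort_metrics, embed_scan, healthy_reference
from .stats import compare_conditions, jzs_bf10, kendall_tau_b
from .synthetic import (
    ConditionEffect,
    apply_condition,
    default_cap_spec,
    make_template,
    occupancy_from_geometry,
    perturb_template,
    population_correlation,
    simulate_cohort,
    simulate_subject,
)
from .cap import assign_caps


# ---------------------------------------------------------------------------
# spectral oracle


def random_affinity(rng: np.random.Generator, p: int) -> AffinityMatrix:
    raw = rng.uniform(0, 1, size=(p, p))
    a = 0.2 + 0.8 * (raw + raw.T) / 2
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(a)


def spectral_oracle_worst_correlation(
    n_matrices: int = 50, n_components: int = 5, seed: int = 0
) -> float:
    """Worst per-component |corr| between the diffusion map and a dense
    eigendecomposition of the row-normalized operator, over random
    connected affinities with P <= 30."""
    rng = np.random.default_rng(seed)
    worst = 1.0
    for _ in range(n_matrices):
        p = int(rng.integers(8, 31))
        a = random_affinity(rng, p)
        emb = diffusion_map(a, n_components=n_components, alpha=0.5)
        A = a.values
        d = A.sum(axis=1)
        w = A / np.outer(d**0.5, d**0.5)
        pr = w / w.sum(axis=1, keepdims=True)
        evals, evecs = np.linalg.eig(pr)
        order = np.argsort(-evals.real)
        evecs = evecs.real[:, order][:, 1 : n_components + 1]
        for k in range(n_components):
            c = abs(np.corrcoef(emb.gradients[:, k], evecs[:, k])[0, 1])
            worst = min(worst, c)
    return worst


# ---------------------------------------------------------------------------
# latent-geometry recovery


def procrustes_disparity(grads: np.ndarray, latent: np.ndarray) -> float:
    """Normalized residual after per-axis standardization and orthogonal
    Procrustes of the embedding onto the planted coordinates."""
    A = (grads - grads.mean(0)) / grads.std(0)
    B = (latent - latent.mean(0)) / latent.std(0)
    R, _ = orthogonal_procrustes(A, B)
    return float(np.sum((A @ R - B) ** 2) / np.sum(B**2))


def latent_recovery_disparity(seed: int = 0, config: RunConfig | None = None) -> float:
    """Noise-free recoverability: embed the population correlation of a
    400-parcel template through the default pipeline and measure the
    Procrustes disparity of the first three gradients against the
    planted latent coordinates."""
    config = config or RunConfig()
    scheme = default_scheme()
    tpl = make_template(scheme, seed=seed)
    z = correlation_to_fisher_z(population_correlation(tpl))
    emb = diffusion_map(
        cosine_affinity(sparsify_rows(z, config.sparsity)),
        n_components=config.n_components,
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
    )
    return procrustes_disparity(emb.gradients[:, :3], tpl.latent_coords)


# ---------------------------------------------------------------------------
# compression detection power / specificity


def compression_detection(
    n_replicates: int = 50,
    n_subjects: int = 26,
    c1: float = 0.6,
    T: int = 120,
    seed: int = 0,
) -> dict:
    """Paired cohorts with a planted gradient-1 compression.

    For each replicate cohort the gradient-range contrasts are tested
    with the JZS Bayes factor; returns detection counts (BF10 > 10) per
    gradient and the mean gradient-1 range ratio.
    """
    scheme = default_scheme()
    config = RunConfig()
    effects = {
        "BL": ConditionEffect(),
        "CMP": ConditionEffect(axis_compression=(c1, 1.0, 1.0)),
    }
    hits = {"range_G1": 0, "range_G2": 0, "range_G3": 0}
    ratios = []
    for i in range(n_replicates):
        cohort = simulate_cohort(
            scheme, effects, n_subjects=n_subjects, paired=True, T=T,
            seed=seed + i, caps=None, spike_rate_per_minute=0.0,
        )
        ref = healthy_reference(cohort.base_template, config, T=T)
        metrics, _, _ = cohort_metrics(cohort, config, scheme, reference=ref)
        res = compare_conditions(
            metrics, test="CMP", control="BL", design="paired",
            metric_filter=list(hits),
        )
        for r in res.itertuples():
            if r.bf10 > 10:
                hits[r.metric] += 1
        mr = metrics.groupby(["metric", "condition"])["value"].mean()
        ratios.append(mr["range_G1"]["CMP"] / mr["range_G1"]["BL"])
    return {
        "n_replicates": n_replicates,
        "bf10_gt_10": hits,
        "mean_range_g1_ratio": float(np.mean(ratios)),
    }


# ---------------------------------------------------------------------------
# null calibration


def null_calibration(
    n_cohorts: int = 200,
    n_subjects: int = 16,
    n_parcels: int = 300,
    T: int = 120,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the full pipeline on null cohorts (identical
    generative conditions).  Returns the per-metric rejection rate of
    the classical paired t test at the nominal level."""
    scheme = small_scheme(n_parcels)
    config = RunConfig()
    effects = {"A": ConditionEffect(), "B": ConditionEffect()}
    rej: dict[str, list[bool]] = {}
    for i in range(n_cohorts):
        cohort = simulate_cohort(
            scheme, effects, n_subjects=n_subjects, paired=True, T=T,
            seed=seed + i, caps=None, spike_rate_per_minute=0.0,
        )
        ref = healthy_reference(cohort.base_template, config, T=T)
        metrics, _, _ = cohort_metrics(cohort, config, scheme, reference=ref)
        res = compare_conditions(metrics, test="B", control="A", design="paired")
        for r in res.itertuples():
            name = r.metric if not r.networks else f"{r.metric}:{r.networks}"
            rej.setdefault(name, []).append(r.p_two_tailed < alpha_level)
    return {name: float(np.mean(v)) for name, v in rej.items()}


# ---------------------------------------------------------------------------
# geometry / CAP-dynamics coupling


def coupling_taus(
    n_scans: int = 60,
    T: int = 120,
    beta: float = 2.0,
    max_convergence: float = 0.8,
    seed: int = 0,
) -> tuple[float, float]:
    """One coupling cohort: scans with varying VAN-DMN convergence and
    occupancy coupled to the geometry.  Returns Kendall tau-b of the
    recovered DMN-VAN distance against the VAN+ and DMN+ occurrence
    rates (expected negative and positive, respectively)."""
    scheme = default_scheme()
    config = RunConfig()
    cap_spec = default_cap_spec(scheme)
    cap_set = CapSet(centroids=cap_spec.centroids, labels=cap_spec.labels)
    rng = np.random.default_rng(seed)
    base = make_template(scheme, seed=seed)
    pi0 = cap_spec.stationary_distribution()
    scans, rates = [], []
    for _ in range(n_scans):
        gamma = rng.uniform(0.0, max_convergence)
        eff = ConditionEffect(van_dmn_convergence=gamma, cap_coupling_beta=beta)
        tpl = perturb_template(base, 0.1, rng)
        tpl_c = apply_condition(tpl, eff)
        pi = occupancy_from_geometry(tpl, eff, pi0, cap_spec.labels)
        spec_i = replace(
            cap_spec,
            transition_matrix=0.5 * np.eye(cap_spec.k) + 0.5 * np.tile(pi, (cap_spec.k, 1)),
        )
        ts, _, _ = simulate_subject(
            tpl_c, spec_i, T=T, seed=int(rng.integers(2**31 - 1)),
            spike_rate_per_minute=0.0,
        )
        scans.append(ts)
        asg = assign_caps(ts, cap_set)
        rates.append(dict(zip(cap_set.labels, asg.occurrence_rate)))
    ref = healthy_reference(base, config, T=T)
    dists = []
    for ts in scans:
        emb = align_cohort([embed_scan(ts, config)], ref)[0]
        dists.append(network_geometry(emb, scheme).distance("DMN", "VAN"))
    df = pd.DataFrame(rates)
    tau_van, _ = kendall_tau_b(np.asarray(dists), df["VAN+"].to_numpy())
    tau_dmn, _ = kendall_tau_b(np.asarray(dists), df["DMN+"].to_numpy())
    return float(tau_van), float(tau_dmn)


# ---------------------------------------------------------------------------
# Bayes-factor oracle


def bf_oracle_max_relative_error(
    t_grid=(0.0, 1.0, 2.0, 3.0, 5.0),
    n_grid=(12, 23, 26),
    n_draws: int = 10**6,
    rscale: float = 0.707,
    seed: int = 0,
) -> float:
    """Largest relative deviation between the quadrature JZS Bayes factor
    and a prior-draw Monte-Carlo estimate of the marginal likelihood."""
    rng = np.random.default_rng(seed)
    delta = sps.cauchy.rvs(scale=rscale, size=n_draws, random_state=rng)
    worst = 0.0
    for n in n_grid:
        ncp = delta * np.sqrt(n)
        for t in t_grid:
            m1 = sps.nct.pdf(t, n - 1, ncp).mean()
            bf_mc = m1 / sps.t.pdf(t, n - 1)
            bf = jzs_bf10(t, n, rscale=rscale)
            worst = max(worst, abs(bf - bf_mc) / bf_mc)
    return worst


# ---------------------------------------------------------------------------
# variance explained (descriptive)


def gradient_variance_summary(
    n_scans: int = 12, T: int = 120, seed: int = 0
) -> dict:
    """Mean variance explained by the first three gradients over a small
    healthy cohort (share of the retained 10-component spectrum)."""
    scheme = default_scheme()
    config = RunConfig()
    rng = np.random.default_rng(seed)
    base = make_template(scheme, seed=seed)
    shares = []
    for _ in range(n_scans):
        tpl = perturb_template(base, 0.1, rng)
        ts, _, _ = simulate_subject(
            tpl, None, T=T, seed=int(rng.integers(2**31 - 1)), spike_rate_per_minute=0.0
        )
        emb = embed_scan(ts, config)
        shares.append(emb.variance_explained[:3])
    shares = np.asarray(shares)
    return {
        "top3_percent": float(shares.sum(axis=1).mean() * 100),
        "g1_percent": float(shares[:, 0].mean() * 100),
        "g2_percent": float(shares[:, 1].mean() * 100),
        "g3_percent": float(shares[:, 2].mean() * 100),
    }
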