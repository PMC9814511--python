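"""End-to-end orchestration: scans -> connectivity -> aligned embeddings
-> geometry metrics -> CAP dynamics -> group statistics.

The stage order is fixed: preprocess (optional for already-clean synthetic
data), per-scan connectivity, an external condition-independent reference
embedding, per-scan embeddings aligned to that reference,
geometry metrics, CAP assignment, and finally condition contrasts.  The
``sweep`` helper reruns the whole chain over a grid of sparsity or alpha
values with a constant seed, mirroring the usual robustness checks.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cap import CapSet, assign_caps
from .connectivity import compute_fc, cosine_affinity, sparsify_rows
from .embedding import EmbeddingResult, align_cohort, diffusion_map
from .errors import ValidationError
from .geometry import network_geometry
from .io import ParcellationScheme, ParcelTimeSeries, RunConfig, write_json, write_table
from .preprocess import preprocess_scan
from .stats import compare_conditions
from .synthetic import Cohort


def trim_scan(ts: ParcelTimeSeries, duration_seconds: float) -> ParcelTimeSeries:
    """Keep ``floor(duration / tr)`` volumes from scan onset.

    The censor mask is trimmed consistently.  Trimming to the full scan
    length is the identity.
    """
    n_keep = math.floor(duration_seconds / ts.tr_seconds)
    if n_keep > ts.n_volumes:
        raise ValidationError(
            f"requested {duration_seconds} s = {n_keep} volumes, scan has {ts.n_volumes}"
        )
    return ParcelTimeSeries(
        data=ts.data[:n_keep].copy(),
        tr_seconds=ts.tr_seconds,
        censor_mask=ts.censor_mask[:n_keep].copy(),
        subject_id=ts.subject_id,
        condition_id=ts.condition_id,
    )


def embed_scan(ts: ParcelTimeSeries, config: RunConfig) -> EmbeddingResult:
    """Connectivity -> sparsify -> affinity -> diffusion map for one scan."""
    fc = compute_fc(ts)
    sp = sparsify_rows(fc, config.sparsity)
    aff = cosine_affinity(sp)
    return diffusion_map(
        aff,
        n_components=config.n_components,
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
    )


def reference_embedding(
    scans: list[ParcelTimeSeries], config: RunConfig
) -> EmbeddingResult:
    """Embedding of the group-average connectivity matrix of ``scans``.

    Used as the common Procrustes target so individual embeddings become
    comparable despite eigenvector sign/rotation ambiguity.
    """
    if not scans:
        raise ValidationError("need at least one scan for the reference")
    z = np.mean([compute_fc(ts).values for ts in scans], axis=0)
    from .connectivity import ConnectivityMatrix

    sp = sparsify_rows(ConnectivityMatrix(values=z, kind="fisher_z"), config.sparsity)
    return diffusion_map(
        cosine_affinity(sp),
        n_components=config.n_components,
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
    )


def template_reference(template, config: RunConfig) -> EmbeddingResult:
    """Reference embedding from a template's noise-free population
    connectivity (useful for recoverability analyses on population
    matrices; for aligning noisy scan embeddings prefer
    :func:`healthy_reference`, whose spectral statistics match real
    scans)."""
    from .connectivity import correlation_to_fisher_z
    from .synthetic import population_correlation

    z = correlation_to_fisher_z(population_correlation(template))
    sp = sparsify_rows(z, config.sparsity)
    return diffusion_map(
        cosine_affinity(sp),
        n_components=config.n_components,
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
    )


def healthy_reference(
    template,
    config: RunConfig,
    n_scans: int = 12,
    T: int = 120,
    tr: float = 2.0,
    noise_sd: float = 2.0,
    subject_sd_fraction: float = 0.1,
    seed: int = 915_874,
) -> EmbeddingResult:
    """External reference: pooled-average connectivity of an independent
    simulated healthy cohort.

    This mirrors aligning to gradients from an independent
    healthy-population dataset: the reference scans are drawn from the
    same population template but are not part of any analyzed cohort, so
    no condition is favored (a within-cohort baseline reference biases
    contrasts toward the baseline) and the canonical gradient order is
    pinned by healthy data (a pooled all-condition reference lets strong
    effects reorder the gradient labels).
    """
    from .synthetic import perturb_template, simulate_subject

    rng = np.random.default_rng(seed)
    scans = []
    for _ in range(n_scans):
        tpl = perturb_template(template, subject_sd_fraction, rng)
        ts, _, _ = simulate_subject(
            tpl, None, T=T, tr=tr, noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)), spike_rate_per_minute=0.0,
        )
        scans.append(ts)
    return reference_embedding(scans, config)


def cohort_metrics(
    cohort: Cohort,
    config: RunConfig,
    scheme: ParcellationScheme,
    do_preprocess: bool = False,
    cap_set: CapSet | None = None,
    reference: EmbeddingResult | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict[str, EmbeddingResult]]:
    """Per-scan aligned embeddings, geometry metrics, and CAP rates.

    ``reference`` is the common Procrustes target.  When None it defaults
    to :func:`healthy_reference` built from the cohort's base template
    (the synthetic analog of an independent healthy-population gradient
    set): a reference must not be built from one condition's scans, which
    would systematically favor that condition, and a pooled within-cohort
    reference would let strong condition effects reorder the gradient
    labels.

    Returns ``(metrics, cap_rates, embeddings)`` where ``metrics`` is the
    tidy table consumed by :func:`gradientspace.stats.compare_conditions`
    and ``cap_rates`` (scan-indexed occurrence rates) is None when no CAP
    set is supplied.
    """
    prepared: list[tuple[str, str, ParcelTimeSeries]] = []
    for scan in cohort.scans:
        ts = scan.timeseries
        if do_preprocess:
            ts, _ = preprocess_scan(
                ts,
                scan.motion,
                fd_threshold_mm=config.fd_threshold_mm,
                gsr=config.gsr,
                passband=config.passband_hz,
            )
        prepared.append((scan.subject_id, scan.condition_id, ts))

    ref = reference if reference is not None else healthy_reference(
        cohort.base_template, config
    )
    embeddings: dict[str, EmbeddingResult] = {}
    records: list[dict] = []
    rate_rows: list[dict] = []
    for sid, cond, ts in prepared:
        emb = embed_scan(ts, config)
        emb = align_cohort([emb], ref)[0]
        key = f"{sid}:{cond}"
        embeddings[key] = emb
        gm = network_geometry(
            emb,
            scheme,
            squared=config.eccentricity_squared,
            n_gradients=config.n_gradients_for_geometry,
        )
        records.extend(gm.to_records(subject_id=sid, condition_id=cond))
        if cap_set is not None:
            asg = assign_caps(ts, cap_set)
            row = {"scan": key, "subject": sid, "condition": cond}
            row.update(dict(zip(cap_set.labels, asg.occurrence_rate)))
            rate_rows.append(row)
    metrics = pd.DataFrame.from_records(records)
    rates = pd.DataFrame(rate_rows).set_index("scan") if rate_rows else None
    return metrics, rates, embeddings


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    package_version: str = "0.1.0"
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        write_json(self.__dict__, path)


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    cohort: Cohort,
    scheme: ParcellationScheme,
    out_dir: str | Path,
    baseline_condition: str | None = None,
    do_preprocess: bool = True,
    cap_set: CapSet | None = None,
    design: str | None = None,
) -> RunManifest:
    """Run every stage on a cohort and write all artifacts to ``out_dir``.

    Emits the tidy metrics TSV, CAP occurrence rates (when a CAP set is
    given), condition contrasts against the baseline, and a JSON manifest
    listing outputs, per-stage timing, and input digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**config.__dict__, "passband_hz": list(config.passband_hz)},
        seed=config.rng_seed,
    )
    for scan in cohort.scans:
        manifest.input_digests[f"{scan.subject_id}:{scan.condition_id}"] = _digest(
            scan.timeseries.data
        )

    t0 = time.perf_counter()
    metrics, rates, _ = cohort_metrics(
        cohort, config, scheme, do_preprocess=do_preprocess, cap_set=cap_set
    )
    manifest.stage_seconds["metrics"] = round(time.perf_counter() - t0, 3)
    metrics_path = out / "metrics.tsv"
    write_table(metrics.to_dict("records"), metrics_path)
    manifest.outputs["metrics"] = str(metrics_path)

    if rates is not None:
        rates_path = out / "cap_rates.tsv"
        rates.reset_index().to_csv(rates_path, sep="\t", index=False, float_format="%.12g")
        manifest.outputs["cap_rates"] = str(rates_path)

    conditions = list(dict.fromkeys(s.condition_id for s in cohort.scans))
    base = baseline_condition or conditions[0]
    if design is None:
        design = "paired" if cohort.paired else "independent"
    t0 = time.perf_counter()
    all_contrasts = []
    for cond in conditions:
        if cond == base:
            continue
        res = compare_conditions(metrics, test=cond, control=base, design=design)
        res.insert(0, "contrast", f"{cond}_vs_{base}")
        all_contrasts.append(res)
    if all_contrasts:
        stats_df = pd.concat(all_contrasts, ignore_index=True)
        stats_path = out / "contrasts.tsv"
        stats_df.to_csv(stats_path, sep="\t", index=False, float_format="%.12g")
        manifest.outputs["contrasts"] = str(stats_path)
    manifest.stage_seconds["stats"] = round(time.perf_counter() - t0, 3)

    manifest.save(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def sweep(
    config: RunConfig,
    cohort: Cohort,
    scheme: ParcellationScheme,
    parameter: str,
    values: list[float],
    do_preprocess: bool = False,
) -> pd.DataFrame:
    """Recompute the tidy metrics table for each value of ``sparsity`` or
    ``alpha``, concatenated with a sweep-value column."""
    if parameter not in {"sparsity", "alpha"}:
        raise ValidationError("parameter must be 'sparsity' or 'alpha'")
    if not values:
        raise ValidationError("empty sweep value list")
    for v in values:  # validate everything before any run
        RunConfig(**{**config.__dict__, parameter: v})
    frames = []
    for v in values:
        cfg = RunConfig(**{**config.__dict__, parameter: v})
        metrics, _, _ = cohort_metrics(cohort, cfg, scheme, do_preprocess=do_preprocess)
        metrics.insert(0, parameter, v)
        frames.append(metrics)
    return pd.concat(frames, ignore_index=True)
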