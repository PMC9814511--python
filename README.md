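# gradientspace

Cortical connectivity gradients, gradient-space geometry, and
co-activation pattern (CAP) dynamics for parcellated resting-state fMRI
— the analysis stack used to ask whether depressed or altered states of
consciousness (sedation, anesthesia, disorders of consciousness,
psychiatric conditions) degrade specific macroscale gradients of the
functional connectome.

## What it computes

From a time × parcels matrix (400 cortical areas, 7 canonical networks)
per scan:

1. **Preprocessing** — frame censoring at FD > 0.4 mm (frame + previous
   frame), OLS removal of drift, motion + derivatives, optional WM/CSF
   and global signal, band-pass 0.01–0.1 Hz by spectral regression,
   per-parcel standardization.
2. **Connectivity** — Pearson FC, Fisher z, top-10% row sparsification,
   normalized cosine-angle affinity
   `a_ij = 1 − arccos(cos(z_i, z_j))/π`.
3. **Gradients** — diffusion-map embedding of the affinity
   (α = 0.5, t = 0 with damped `λ/(1−λ)` scaling), variance explained
   over the retained spectrum, orthogonal Procrustes alignment of every
   scan to an external healthy reference.
4. **Geometry** — per-gradient range (max − min loading), global
   dispersion `Σ_p ‖u_p − ū‖²`, network eccentricity and pairwise
   network-centroid distances in the 3-D gradient space.
5. **CAP dynamics** — per-volume assignment to eight pattern centroids
   by spatial correlation, per-scan occurrence rates, Kendall tau-b
   coupling between network distances and occurrence rates.
6. **Inference** — paired/independent Student t, JZS Bayes factor
   (Cauchy 0.707 prior on the standardized effect; BF10 with posterior
   median and 95% credible interval), Jeffreys-style evidence bins,
   BH-FDR per dataset, Wilcoxon/Mann–Whitney rank tests.

A first-class synthetic-cohort generator plants a known 3-axis latent
gradient geometry (axis compression, VAN–DMN convergence, Markov CAP
dynamics coupled to the geometry, motion spikes) so every stage can be
validated against ground truth.  See `docs/methods.md` for the models
and design choices.

## Worked example

Simulate a paired cohort of 12 subjects in which the "sedation"
condition compresses gradient 1 to 60% of its range and pulls VAN and
DMN 40% toward each other, then test the gradient-space metrics:

```python
import gradientspace as gs

scheme = gs.default_scheme()                 # 400 parcels, 7 networks
cfg = gs.RunConfig()                         # sparsity .9, alpha .5, FD .4 mm, ...
effects = {
    "BL":  gs.ConditionEffect(),
    "PDS": gs.ConditionEffect(axis_compression=(0.6, 1.0, 1.0),
                              van_dmn_convergence=0.4),
}
cohort = gs.simulate_cohort(scheme, effects, n_subjects=12, paired=True,
                            T=120, seed=7, caps=None)
ref = gs.pipeline.healthy_reference(cohort.base_template, cfg)
metrics, _, _ = gs.cohort_metrics(cohort, cfg, scheme, reference=ref)
res = gs.compare_conditions(metrics, test="PDS", control="BL", design="paired",
                            metric_filter=["range_G1", "range_G2",
                                           "range_G3", "dispersion"])
print(res[["metric", "t", "df", "p_fdr", "bf10",
           "posterior_median_delta", "evidence_label"]].round(3).to_string(index=False))
```

```
    metric       t   df  p_fdr      bf10  posterior_median_delta evidence_label
  range_G1 -11.311 11.0  0.000 65948.501                  -2.971       decisive
  range_G2   2.615 11.0  0.024     2.930                   0.633      anecdotal
  range_G3  -3.626 11.0  0.005    12.584                  -0.897         strong
dispersion -11.121 11.0  0.000 56519.691                  -2.920       decisive
```

The planted gradient-1 compression is detected decisively
(BF10 ≈ 6.6·10⁴, posterior median standardized effect −2.97), dispersion
falls with it, and the untouched gradient 2 stays at anecdotal evidence.
The mean DMN–VAN centroid distance drops from 0.0070 (baseline) to
0.0026 under the planted convergence — the geometry the CAP-coupling
analysis then correlates with VAN+/DMN+ occurrence rates.

A command-line interface mirrors the library
(`gradientspace simulate | preprocess | connectivity | gradient |
metrics | cap | stats | run | sweep`).

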