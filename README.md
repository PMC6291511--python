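# plimst

Phase-lag-index connectivity, minimum-spanning-tree topology and permutation
inference for resting-state source-space MEG/EEG.

## The problem

Comparing brain networks between groups (for example patients with amnestic
mild cognitive impairment versus healthy controls) is easily biased by
differences in overall connectivity strength, edge density or arbitrary
thresholds. This package implements a pipeline that sidesteps those biases:

1. **Spectral decomposition** — ROI time series are band-pass filtered
   (zero-phase Butterworth) into the five canonical bands: delta (0.5–4 Hz),
   theta (4–8), alpha (8–13), beta (13–30), gamma (30–48), and segmented
   into 10 epochs of 8 s at 512 Hz.
2. **Phase lag index (PLI)** — for each ROI pair and epoch,
   `PLI = |⟨sign(sin ΔΦ(t_k))⟩|` with ΔΦ the instantaneous (Hilbert) phase
   difference; insensitive to volume conduction because zero-lag coupling
   contributes nothing. Per-epoch matrices are merged by arithmetic average.
3. **Minimum spanning tree (MST)** — Kruskal's algorithm on distances 1/PLI
   extracts the N-node, (N−1)-link backbone, on which global (leaf fraction
   L/M, tree hierarchy Th = L/(2·M·BC_max), degree divergence κ = ⟨k²⟩/⟨k⟩)
   and nodal (degree, betweenness centrality, eccentricity) metrics are
   computed without any threshold choice.
4. **Group inference** — two-sided label-permutation tests (10,000 reshuffles
   by default, exhaustive when feasible) with Benjamini–Hochberg FDR across
   the 3 global metrics and, separately, across ROIs per nodal metric and
   band; link-level permutation and MST-inclusion chi-square follow-ups;
   Pearson correlations of nodal metrics with clinical scores within one
   designated group.

Because real source-space recordings of this kind are rarely shared, the
package ships a first-class synthetic-cohort generator: phase-lagged
narrow-band carriers with controllable coupling strength, planted hub
effects, and clinical scores with a prescribed correlation to any metric.
See `docs/methods.md` for the model and its design choices.

## Worked example

```python
import plimst as pm

# a 30-ROI cohort of 16+16 subjects; group B carries a theta-band hub at ROI 7
spec = pm.CouplingSpec(n_rois=30)
cohort = pm.generate_cohort(spec, n_per_group=16,
                            planted_effect=pm.PlantedEffect(7), master_seed=11)
subjects = (
    [(s, "A", ts) for s, ts in zip(cohort.subject_ids["A"], cohort.group_a)]
    + [(s, "B", ts) for s, ts in zip(cohort.subject_ids["B"], cohort.group_b)]
)
res = pm.run_pipeline(subjects, pm.PipelineConfig(n_perm=2000, seed=3))
bc = res.nodal_tests[("theta", "betweenness_centrality")]
top = max(bc, key=lambda r: abs(r.observed_diff))
print(top.metric_id, round(top.observed_diff, 3), round(top.p_fdr, 4))
```

prints

```
betweenness_centrality:ROI07 -0.504 0.015
```

— the planted hub is recovered as the strongest nodal betweenness
difference (group A minus group B is negative: the hub is *more* central in
group B), significant after FDR across the 30 ROIs. The same run shows no
significant global metric differences in a matched null cohort and no
planted-ROI effects outside the theta band.

The same pipeline is scriptable from the shell:

```bash
plimst simulate --n-rois 30 --n-per-group 16 --planted-roi 7 --seed 11 --out cohort/
plimst run-all --manifest cohort/manifest.json --seed 3 --out results/
plimst links --manifest cohort/manifest.json --node ROI07 --band theta --out links.tsv
```

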