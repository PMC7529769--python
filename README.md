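# seasonomics

Seasonality analysis for longitudinal multiomics cohorts.

Cohort studies that sample the same subjects repeatedly over several
years — transcripts, proteins, metabolites, cytokines, clinical labs,
gut and nasal microbiota — can ask a question calendar seasons cannot
answer: *when, in the data themselves, does human biology change over
the year, and does it change differently in different clinical groups?*
`seasonomics` packages the statistical machinery for that question:

1. **Per-analyte seasonality.** Each analyte `y` is modeled as

   `y ~ group + BMI + s(day)` with a subject random intercept,

   where `s(day)` is a penalized **cyclic cubic regression spline** on
   the day-of-year circle (the fit at day 365 wraps smoothly into day
   1, continuous up to the second derivative). Subject baselines enter
   as ridge-penalized indicator coefficients — the penalized-regression
   form of a Gaussian random intercept — and the smoothing and
   shrinkage parameters are chosen by GCV, keeping every fit a
   deterministic linear solve. Seasonality is called by a likelihood
   ratio test of the smooth (`p ≤ 0.05`), with 95% bands computed as
   fit ± 1.96 × coefficient-propagated SD.

2. **Pattern discovery.** The standardized fitted annual curves of the
   significant analytes are clustered with **fuzzy C-means**
   (minimizing Σ uᵢⱼᵐ ‖xᵢ − cⱼ‖², fuzzifier m = 2, seeded restarts);
   the number of patterns k is chosen by the **average silhouette
   width** of the hardened partition over k = 2..10, with
   within-cluster dispersion reported for the elbow view. External
   streams (clinical labs, meteorology, pollen counts) are *projected*:
   their membership against the fixed centroids scores each stream's
   affinity to every pattern on a 0..1 scale.

3. **Interval-wise group differences.** For insulin-resistant (IR) vs
   insulin-sensitive (IS) subjects, group-specific cyclic-spline curves
   are compared interval by interval with the studentized area
   statistic

   `stat[t,t+1] = (A¹[t,t+1] − A²[t,t+1]) / √( ((SE¹ₜ+SE¹ₜ₊₁)/2)² + ((SE²ₜ+SE²ₜ₊₁)/2)² )`,

   referred to a pooled permutation null built by shuffling subject
   group labels B times: `p[t,t+1]` is the pooled fraction of the
   B × (T−1) null statistics more extreme in the observed direction.
   BH adjustment across a feature's intervals and an adjusted-p < α/2
   rule yield significant intervals and a global / partial / none call.

4. **Microbiome richness.** Chao1 richness
   (`S_obs + F1(F1−1)/(2(F2+1))` bias-corrected, classic
   `S_obs + F1²/(2F2)` available) at any taxonomic level, fed through
   the same seasonal model and summarized as a winter-vs-summer fitted
   contrast.

A **synthetic cohort generator** emulates the study design — quarterly
visits spread uniformly over multiple years, subject baselines, two
seasonal archetypes (late-April peak; December peak with a March–July
trough), IR/IS differential windows, winter-boosted taxon counts — with
per-feature ground truth, so every stage is testable without access to
cohort data.

## Worked example

`examples/03_discover_patterns.py` simulates 100 analytes, half from
each seasonal archetype (SNR 3, phase jitter ≤ 15 days, 40 subjects ×
12 visits), fits the seasonal model per analyte and scans k:

```
silhouette by k: {2: 0.876, 3: 0.777, 4: 0.612, 5: 0.599, 6: 0.551,
                  7: 0.505, 8: 0.464, 9: 0.469, 10: 0.433}
chosen k = 2
pattern 1: peak day 351, trough day 167
pattern 2: peak day 115, trough day 297
PC1+PC2 explain 99% of curve variance
```

The silhouette is maximal at k = 2 and the centroid peaks land in
mid-December (day 351) and late April (day 115) — the two major
seasonal patterns. `examples/05_ir_is_intervals.py` injects an IR
elevation confined to days 120–210 and recovers it:

```
classification: partial
significant day ranges: [(129, 201)]
10/51 intervals with BH-adjusted p < alpha/2 = 0.025
```

and `examples/06_microbiome_richness.py` shows the richness analysis
(winter − summer fitted Chao1 contrast +20.8 genera, seasonality
p ≈ 0) on counts generated with a 1.5× winter richness boost. The
remaining examples cover simulation, the per-analyte seasonality scan
and membership projection of external streams.

A thin CLI mirrors the library
(`seasonomics simulate | seasonality | cluster | project | differential
| diversity | run`); `seasonomics run --config cfg.yaml` executes the
whole pipeline and writes TSV tables plus a `manifest.json` with
seeds, row counts and output checksums (same config + seed ⇒ identical
checksums).

## Layout

```
src/seasonomics/   cohort, basis, seasonal, clustering, intervals,
                   diversity, pipeline, cli, io
examples/          one narrative script per capability
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    model and design notes
```
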