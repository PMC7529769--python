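"""Simulate a desk-scale longitudinal multiomics cohort.

Generates 40 subjects followed for 3 years with ~quarterly visits,
a 200-feature analyte panel (two seasonal archetypes, a twice-a-year
shape, IR/IS-differential features, nulls) and a per-visit taxon count
table with higher winter richness, then prints what was made.
"""

import seasonomics as so

design = so.CohortDesign(n_subjects=40, n_years=3, visits_per_year=4, seed=42)
visits = so.generate_visits(design)
long, truth = so.generate_features(design, so.default_feature_panel(200), visits)
counts, taxonomy = so.generate_taxon_counts(design, visits)

print(f"visits:   {len(visits)} rows, {visits.subject_id.nunique()} subjects, "
      f"{(visits.group == 'IR').sum()} IR visit-rows")
print(f"analytes: {truth.feature_id.nunique()} features -> {len(long)} measurements")
print("feature kinds:", truth.kind.value_counts().to_dict())
print(f"taxa:     {counts.shape[1]} taxa x {counts.shape[0]} samples, "
      f"depth {counts.iloc[0].sum()} reads/sample")
# The kind counts are the ground truth downstream stages try to recover:
# seasonal_p1/p2 features should cluster into two patterns, differential
# features should show an IR-vs-IS window, nulls should stay quiet.
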