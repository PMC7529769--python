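"""Project external data streams onto learned seasonal patterns.

External streams (think clinical labs, air temperature, pollen counts)
are not re-clustered: their standardized annual curves get fuzzy
membership values against the fixed centroids, scoring each stream's
affinity to every pattern on a 0..1 scale.
"""

import numpy as np

import seasonomics as so

# learn the two patterns from an omics panel
design = so.CohortDesign(seed=3)
panel = [so.FeatureSpec(f"f{i:03d}",
                        kind="seasonal_p1" if i % 2 else "seasonal_p2",
                        amplitude=3.0)
         for i in range(60)]
long, _ = so.generate_features(design, panel)
_, fits = so.fit_table(long)
curves = so.standardize_curves(fits)
model = so.fuzzy_cmeans(curves, k=2, m=2.0, seed=3)

# synthetic external streams with known phase
days = np.arange(1, 366, dtype=float)
streams = {
    "air_temperature": np.cos(2 * np.pi * (days - 200) / 365),   # summer peak
    "spring_bloom": np.asarray(so.archetype_curve(1, days)),     # late April
    "winter_humidity": np.asarray(so.archetype_curve(2, days)),  # December
}
for name, curve in streams.items():
    u = so.project_membership(so.standardize_curve(curve), model)
    best = int(np.argmax(u)) + 1
    print(f"{name:16s} membership " +
          " ".join(f"{x:.3f}" for x in u) + f"  -> pattern {best}")
# A membership near 1 means the stream's annual shape matches that
# pattern's centroid; values near 0.5 mean it sits between the two.
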