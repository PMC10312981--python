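"""Radial distribution function and delta-CDF on a clustered point pattern.

Macrophages are scattered within 15 um of T-cells over a uniform tumor-cell
background. The observed near-range density exceeds the label-permutation
expectation, giving a positive delta-CDF (colocalization).
"""

import numpy as np

from cisa import (
    AnalysisConfig,
    cohort_delta_cdf_test,
    delta_cdf,
    generate_point_pattern,
    permutation_expected,
    radial_density,
)

cfg = AnalysisConfig()
rng = np.random.default_rng(12)
values = []
for s in range(6):
    table = generate_point_pattern(
        "clustered", (1000.0, 1000.0), rng=rng,
        parent_intensity_per_mm2=40.0, offspring_mean=5.0,
        offspring_radius_um=15.0, background_intensity_per_mm2=100.0,
    )
    res = radial_density(table, "T-cell", "macrophage", config=cfg)
    expected = permutation_expected(table, "T-cell", "macrophage",
                                    config=cfg, rng=rng)
    d = delta_cdf(res.observed, expected, sample_id=f"s{s}",
                  target_type="macrophage")
    values.append(d.delta_cdf)
    near = res.observed[:15].mean() * 1e6
    far = res.observed[30:].mean() * 1e6
    print(f"sample {s}: density <15um = {near:7.1f} /mm^2, "
          f">30um = {far:6.1f} /mm^2, delta-CDF = {d.delta_cdf:+.2f}")

test = cohort_delta_cdf_test(values)
print(f"\ncohort delta-CDF mean = {test['mean']:.3f}, "
      f"one-sided t-test p = {test['p_value']:.2e}")
# Positive delta-CDF means target mass sits at shorter distances than the
# permutation null allows: T-cells and macrophages colocalize.
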