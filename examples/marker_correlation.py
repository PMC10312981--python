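"""Contact-aware vs pixel-wise marker correlation on co-polarized markers.

CD3 and CD8 are enriched together at each contact (coupling rho = 0.8) but
carry independent pixel noise. Scoring at the contact interface recovers the
coupling; pooling raw pixels dilutes it.
"""

import numpy as np

from cisa import (
    AnalysisConfig,
    all_contacts,
    cisa_correlation,
    compare_methods,
    pixelwise_correlation,
    score_contacts,
)
from cisa.synthetic import SyntheticConfig, generate_tissue

acfg = AnalysisConfig()
cisa_rs, pixel_rs = [], []
for s in range(8):
    cfg = SyntheticConfig(
        n_pairs=25, markers=("CD3", "CD8"),
        polarization_factor=2.0, polarization_log2_sd=0.6, comarker_rho=0.8,
        membrane_base_intensity=60.0, cytoplasm_base_intensity=60.0,
        noise_kind="gaussian", background_noise_sd=12.0, rng_seed=100 + s,
    )
    image, mask, table, _ = generate_tissue(cfg)
    recs = all_contacts(mask, table, acfg, "T-cell", "APC")
    sa = score_contacts(image, recs, "CD3", table, sample_id=f"s{s}",
                        target_type="APC")
    sb = score_contacts(image, recs, "CD8", table, sample_id=f"s{s}",
                        target_type="APC")
    (rc,) = cisa_correlation(sa, sb)
    rp = pixelwise_correlation(image, mask, table, "T-cell", "CD3", "CD8",
                               sample_id=f"s{s}")
    rc.sample_id = rp.sample_id = f"s{s}"
    cisa_rs.append(rc)
    pixel_rs.append(rp)
    print(f"sample {s}: r(contact-aware) = {rc.r:+.3f}   r(pixel-wise) = {rp.r:+.3f}")

test = compare_methods(cisa_rs, pixel_rs)
print(f"\npaired t-test: mean difference = {test['mean_diff']:+.3f}, "
      f"p = {test['p_value']:.2e} (n = {test['n']})")
# The contact-aware coefficients sit well above the pixel-wise ones in every
# sample: the co-recruitment signal lives at the interface, not in bulk pixels.
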