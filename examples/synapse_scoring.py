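"""Score immune-synapse strength on a synthetic tissue with known truth.

Generates disk-shaped T-cell/APC pairs whose contact-facing membrane CD3 is
enriched 2-fold (so the true synapse strength is log2(2) = 1), scores every
contact, and compares the per-sample mean against the seed-and-grow null.
"""

import numpy as np

from cisa import (
    AnalysisConfig,
    aggregate_sample,
    all_contacts,
    null_synapse_model,
    score_contacts,
    stratify_by_synapse,
)
from cisa.synthetic import SyntheticConfig, generate_tissue

cfg = SyntheticConfig(
    n_pairs=60,
    polarization_factor=2.0,
    membrane_base_intensity=25.0,
    cytoplasm_base_intensity=5.0,
    noise_kind="poisson",
    rng_seed=4,
)
image, mask, table, truth = generate_tissue(cfg)
acfg = AnalysisConfig()

records = all_contacts(mask, table, acfg, reference_type="T-cell", target_type="APC")
scores = score_contacts(image, records, "CD3", table,
                        sample_id="demo", target_type="APC")
(summary,) = aggregate_sample(scores, ref_type="T-cell")

ref_ids = sorted({r.ref_id for r in records})
null_value = null_synapse_model(image, mask, ref_ids, "CD3", acfg, seed=4)

group = stratify_by_synapse([summary])[0]
print(f"contacts scored:        {summary.n_contacts}")
print(f"mean synapse strength:  {summary.sigma_bar:.4f}  (truth: log2(2) = 1)")
print(f"null model mean:        {null_value:.4f}  (expected: ~0)")
print(f"patient group (sigma>0 rule): {group}  (1 = synapse-forming)")
# A mean sigma near 1 against a null near 0 shows CD3 is polarized toward
# the contacting APCs well beyond segmentation-driven artifacts.
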