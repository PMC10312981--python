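# cisa — computational immune synapse analysis

`cisa` quantifies whether membrane proteins polarize toward cell–cell
contact interfaces in multiplexed tissue images (imaging mass cytometry or
multiplexed fluorescence), for researchers studying T-cell interactions in
the tumor microenvironment from segmented single-cell imaging data.

## The statistic

For a reference T-cell in contact with a neighbor, the **synapse strength**
is the log-ratio of mean marker intensity on the contacting versus
non-contacting membrane:

```
sigma = log2( mean(I, contact membrane px) / mean(I, noncontact membrane px) )
```

The membrane is the 2-px internal boundary of the cell mask (1 px for IMC);
the contact interface is where the neighbor's mask, dilated with a radius-2
diamond element, intersects that membrane. When a T-cell touches several
neighbors of the same type, the noncontact pool excludes all of that type's
interfaces. `sigma > 0` means the marker (e.g. CD3, a T-cell-receptor
proxy) is enriched toward the neighbor — an immunological synapse.
Supporting machinery:

- **IMC zero handling** — sparse ion counts give zero means; these are
  filled in with a per-sample background noise term, and a contact mean of
  0 with a noncontact mean below that noise yields `sigma = 0`.
- **Seed-and-grow null** — random contiguous ≥15-px membrane regions scored
  as if they were contacts (5 regions per cell, 100 iterations of sample
  averages) control for segmentation-driven artifacts.
- **Contact-aware correlation** — Pearson r between two markers' sigma
  values over matched contacts, versus the contact-naive pixel-wise
  baseline pooled over whole cell areas.
- **Radial distribution function** — target-cell density per 1-µm distance
  bin out to 100 µm around reference cells, annulus-normalized (not divided
  by overall density) with analytic rectangular-window edge correction, and
  **delta-CDF**: the summed difference between observed and
  label-permutation-expected cumulative distance distributions (positive =
  colocalization).
- **Adaptive annotation** — four-class Multi-Otsu tumor/stroma masks,
  exact 1D two-means cell labeling, and upper-quartile cytoplasmic calls of
  antigen-loaded macrophages.
- **Synthetic tissue generator** — packed cells with membrane-localized
  markers and known contact-directed enrichment `f` (true
  `sigma = log2 f`), Poisson/clustered point patterns, and two-compartment
  images, so everything is testable end-to-end without data downloads.

## Worked example

```bash
python examples/synapse_scoring.py
```

```
contacts scored:        60
mean synapse strength:  0.9440  (truth: log2(2) = 1)
null model mean:        -0.0064  (expected: ~0)
patient group (sigma>0 rule): 1  (1 = synapse-forming)
```

A synthetic tissue is generated with 60 T-cell/APC pairs whose
contact-facing membrane CD3 is enriched 2-fold under Poisson count noise.
The pipeline recovers a mean sigma near the true `log2(2) = 1`, while
randomly seeded membrane regions score near 0 — the enrichment is at the
contact, not an artifact of the masks. The `sigma > 0` rule is the grouping
used to stratify patients by synapse formation. The other scripts in
`examples/` demonstrate marker correlation, the RDF/delta-CDF statistics,
and tumor/stroma annotation the same way.

A thin CLI mirrors the library for shell pipelines
(`cisa simulate|segment|classify|contacts|synapse|correlate|rdf`; see
`cisa --help`).

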