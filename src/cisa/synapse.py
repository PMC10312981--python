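"""Synapse strength sigma, its IMC noise adjustment, and the seed-and-grow null.

sigma is the log2 ratio of mean marker intensity on the membrane pixels in
contact with a neighbor over the mean on the remaining membrane. Positive
sigma means the marker is polarized toward the neighbor. IMC ion counts are
sparse, so zero means are filled in with a per-sample background noise term;
when the contact mean is 0 and the noncontact mean is below that noise level
the score is set to 0 outright.

The null model scores randomly seeded contiguous membrane regions as if they
were contacts, averaging 5 seeded regions per cell, cells within a sample,
and 100 iterations of sample averages.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import all_contacts, extract_membrane
from .model import (
    AnalysisConfig,
    CellTable,
    ContactRecord,
    LabelMask,
    MarkerImage,
    NoiseTerm,
    SampleSynapseSummary,
    SynapseScore,
)

__all__ = [
    "synapse_strength",
    "estimate_noise_term",
    "seed_and_grow",
    "null_synapse_model",
    "aggregate_sample",
    "stratify_by_synapse",
    "score_contacts",
]


def _sigma_from_means(
    contact_mean: float,
    noncontact_mean: float,
    noise: Optional[NoiseTerm],
    modality: str,
) -> tuple[float, str, bool, bool, bool]:
    """Apply the zero-handling rules; returns
    (sigma, mode, fillin_contact, fillin_noncontact, excluded)."""
    if modality == "imc" and noise is not None:
        if contact_mean == 0.0 and noncontact_mean < noise.value:
            return 0.0, "zero_rule", False, False, False
        fc = contact_mean == 0.0
        fn = noncontact_mean == 0.0
        c = noise.value if fc else contact_mean
        n = noise.value if fn else noncontact_mean
        if c == 0.0 or n == 0.0:  # noise term itself zero
            return math.nan, "imc_noise_adjusted", fc, fn, True
        mode = "imc_noise_adjusted" if (fc or fn) else "standard"
        return math.log2(c / n), mode, fc, fn, False
    if contact_mean == 0.0 or noncontact_mean == 0.0:
        return math.nan, "standard", False, False, True
    return math.log2(contact_mean / noncontact_mean), "standard", False, False, False


def synapse_strength(
    image: MarkerImage,
    record: ContactRecord,
    marker: str,
    noise: Optional[NoiseTerm] = None,
    modality: Optional[str] = None,
) -> SynapseScore:
    """Score one contact: sigma = log2(contact mean / noncontact mean).

    An empty contact or noncontact set yields an excluded score, as does a
    zero mean outside IMC mode (the fill-in rule is IMC-specific).
    """
    modality = modality or image.modality
    chan = image[marker]
    if record.n_contact == 0 or record.n_noncontact == 0 or record.no_noncontact:
        return SynapseScore(
            record.ref_id, record.neighbor_id, marker, math.nan, excluded=True
        )
    c_mean = float(chan[record.contact_px].mean())
    n_mean = float(chan[record.noncontact_px].mean())
    sigma, mode, fc, fn, excl = _sigma_from_means(c_mean, n_mean, noise, modality)
    return SynapseScore(
        record.ref_id,
        record.neighbor_id,
        marker,
        sigma,
        mode=mode,
        fillin_contact=fc,
        fillin_noncontact=fn,
        excluded=excl,
    )


def estimate_noise_term(
    image: MarkerImage,
    mask: LabelMask,
    cell_table: CellTable,
    marker: str,
    reference_types: Sequence[str],
    sample_id: Optional[str] = None,
) -> NoiseTerm:
    """Background marker level: mean over all pixels of non-reference cells."""
    ref_set = set(reference_types)
    keep_ids = [
        int(cid)
        for cid, types in zip(cell_table.df["cell_id"], cell_table.df["types"])
        if not (types & ref_set)
    ]
    if not keep_ids:
        raise ValueError("noise term undefined: no non-reference cells")
    sel = np.isin(mask.labels, keep_ids) & (mask.labels > 0)
    value = float(image[marker][sel].mean())
    return NoiseTerm(sample_id=sample_id, marker=marker, value=value)


def _membrane_adjacency(rr: np.ndarray, cc: np.ndarray) -> list[np.ndarray]:
    """8-connected adjacency lists over a membrane pixel set."""
    n = rr.size
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rr, cc))}
    adj: list[np.ndarray] = []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i in range(n):
        r, c = int(rr[i]), int(cc[i])
        nbrs = [index[(r + dr, c + dc)] for dr, dc in offsets if (r + dr, c + dc) in index]
        adj.append(np.array(nbrs, dtype=np.intp))
    return adj


def seed_and_grow(
    membrane_px: tuple[np.ndarray, np.ndarray],
    min_size: int = 15,
    rng: Optional[np.random.Generator] = None,
    adjacency: Optional[list[np.ndarray]] = None,
) -> np.ndarray:
    """Grow a random contiguous membrane region of at least ``min_size`` px.

    A uniformly random seed pixel is expanded over 8-connected membrane
    neighbors, drawing uniformly from the current frontier, until the region
    reaches ``min_size``. Returns indices into the membrane pixel arrays.
    Membranes smaller than ``min_size`` are returned whole (caller treats the
    cell as ineligible).
    """
    rng = rng if rng is not None else np.random.default_rng()
    rr, cc = membrane_px
    n = rr.size
    if n <= min_size:
        return np.arange(n, dtype=np.intp)
    if adjacency is None:
        adjacency = _membrane_adjacency(rr, cc)
    seed = int(rng.integers(n))
    in_region = np.zeros(n, bool)
    in_frontier = np.zeros(n, bool)
    in_region[seed] = True
    region = [seed]
    frontier: list[int] = []
    for j in adjacency[seed]:
        if not in_frontier[j]:
            in_frontier[j] = True
            frontier.append(int(j))
    while len(region) < min_size and frontier:
        k = int(rng.integers(len(frontier)))
        pix = frontier[k]
        frontier[k] = frontier[-1]
        frontier.pop()
        in_frontier[pix] = False
        if in_region[pix]:
            continue
        in_region[pix] = True
        region.append(pix)
        for j in adjacency[pix]:
            if not in_region[j] and not in_frontier[j]:
                in_frontier[j] = True
                frontier.append(int(j))
    return np.array(region, dtype=np.intp)


def null_synapse_model(
    image: MarkerImage,
    mask: LabelMask,
    cell_ids: Iterable[int],
    marker: str,
    config: Optional[AnalysisConfig] = None,
    noise: Optional[NoiseTerm] = None,
    seed: Optional[int] = None,
) -> float:
    """Seed-and-grow null synapse value for a set of in-contact cells.

    Per iteration, each eligible cell contributes the mean sigma of
    ``null_seeds_per_cell`` random regions (region as contact, rest of the
    membrane as noncontact); the sample average over cells is the iteration
    value, and the final null value is the mean of ``null_iterations``
    iteration values. Cells whose membrane is smaller than
    ``null_min_region_px`` are skipped. Reproducible for a given seed
    independent of iteration order (one RNG stream per cell and iteration).
    """
    config = config or AnalysisConfig()
    if seed is None:
        seed = config.rng_seed
    chan = image[marker]
    cells = []
    for cid in cell_ids:
        mem = extract_membrane(mask, int(cid), config.membrane_width_px)
        if mem[0].size < config.null_min_region_px:
            continue
        values = chan[mem]
        adj = _membrane_adjacency(*mem)
        cells.append((int(cid), values, adj, mem))
    if not cells:
        raise ValueError("null model undefined: no eligible cells")

    iter_means = np.empty(config.null_iterations)
    for it in range(config.null_iterations):
        cell_vals = []
        for cid, values, adj, mem in cells:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(cid), it])
            )
            sigmas = []
            for _ in range(config.null_seeds_per_cell):
                idx = seed_and_grow(
                    mem, config.null_min_region_px, rng, adjacency=adj
                )
                sel = np.zeros(values.size, bool)
                sel[idx] = True
                c_mean = float(values[sel].mean())
                rest = values[~sel]
                if rest.size == 0:
                    continue
                n_mean = float(rest.mean())
                s, _, _, _, excl = _sigma_from_means(
                    c_mean, n_mean, noise, image.modality
                )
                if not excl:
                    sigmas.append(s)
            if sigmas:
                cell_vals.append(float(np.mean(sigmas)))
        if not cell_vals:
            raise ValueError("null model undefined: no scorable cells")
        iter_means[it] = float(np.mean(cell_vals))
    return float(iter_means.mean())


def score_contacts(
    image: MarkerImage,
    records: Sequence[ContactRecord],
    marker: str,
    cell_table: Optional[CellTable] = None,
    noise: Optional[NoiseTerm] = None,
    sample_id: Optional[str] = None,
    target_type: Optional[str] = None,
) -> list[SynapseScore]:
    """Score a batch of contact records, attaching sample/region metadata."""
    region_by_id = {}
    if cell_table is not None:
        region_by_id = dict(
            zip(cell_table.df["cell_id"], cell_table.df["region"])
        )
    out = []
    for rec in records:
        s = synapse_strength(image, rec, marker, noise=noise)
        s.sample_id = sample_id
        s.target_type = target_type
        s.region = region_by_id.get(rec.ref_id, "none")
        out.append(s)
    return out


def aggregate_sample(
    scores: Sequence[SynapseScore],
    ref_type: str = "",
    marker: Optional[str] = None,
    null_values: Optional[dict] = None,
) -> list[SampleSynapseSummary]:
    """Mean sigma per (sample, marker, target type, region); excluded scores drop.

    Each contact of a reference cell with a distinct neighbor contributes one
    sigma, so one T-cell touching two same-type neighbors counts twice.
    """
    rows = [
        {
            "sample_id": s.sample_id,
            "marker": s.marker,
            "target_type": s.target_type or "",
            "region": s.region,
            "sigma": s.sigma,
        }
        for s in scores
        if not s.excluded and np.isfinite(s.sigma)
    ]
    if not rows:
        return []
    df = pd.DataFrame(rows)
    if marker is not None:
        df = df[df["marker"] == marker]
    grouped = df.groupby(
        ["sample_id", "marker", "target_type", "region"], dropna=False, sort=True
    )["sigma"]
    out = []
    for (sample_id, mk, tt, region), vals in grouped:
        key = (sample_id, mk, tt, region)
        out.append(
            SampleSynapseSummary(
                sample_id=sample_id,
                marker=mk,
                ref_type=ref_type,
                target_type=tt,
                region=region,
                sigma_bar=float(vals.mean()),
                n_contacts=int(vals.size),
                null_sigma_bar=(null_values or {}).get(key),
            )
        )
    return out


def stratify_by_synapse(
    summaries: Sequence[Optional[SampleSynapseSummary]],
) -> list[int]:
    """Patient grouping by the sigma>0 rule.

    Group 1: mean sigma > 0 (contact with a tendency to form synapses).
    Group 2: mean sigma <= 0, or no contact at all (a ``None`` entry).
    """
    groups = []
    for s in summaries:
        if s is not None and np.isfinite(s.sigma_bar) and s.sigma_bar > 0:
            groups.append(1)
        else:
            groups.append(2)
    return groups
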