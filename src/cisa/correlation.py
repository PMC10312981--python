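"""Correlating synapse scores between markers, and the pixel-wise baseline.

Contact-aware correlation pairs sigma values of two markers over the same
contacts; the contact-naive baseline correlates raw pixel intensities pooled
over whole cell areas of a type. Comparing the two per sample tests whether
scoring at the contact interface strengthens marker-marker relationships.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import CellTable, CorrelationResult, LabelMask, MarkerImage, SynapseScore

__all__ = [
    "cisa_correlation",
    "pixelwise_correlation",
    "compare_methods",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _match(scores_a, scores_b):
    by_key_b = {
        (s.sample_id, s.ref_id, s.neighbor_id): s
        for s in scores_b
        if not s.excluded and np.isfinite(s.sigma)
    }
    xs, ys, samples = [], [], []
    for sa in scores_a:
        if sa.excluded or not np.isfinite(sa.sigma):
            continue
        sb = by_key_b.get((sa.sample_id, sa.ref_id, sa.neighbor_id))
        if sb is None:
            continue
        xs.append(sa.sigma)
        ys.append(sb.sigma)
        samples.append(sa.sample_id)
    return np.array(xs), np.array(ys), samples


def cisa_correlation(
    scores_a: Sequence[SynapseScore],
    scores_b: Sequence[SynapseScore],
    by_sample: bool = False,
    cell_type: str = "",
) -> list[CorrelationResult]:
    """Pearson r of two markers' sigma values over matched contacts.

    Contacts are matched on (sample, reference cell, neighbor); excluded
    scores drop pairwise. ``by_sample=False`` pools all contacts into one
    coefficient; ``by_sample=True`` returns one coefficient per sample.
    Groups with fewer than two matched contacts are emitted as missing
    (``r`` is NaN).
    """
    xs, ys, samples = _match(scores_a, scores_b)
    marker_a = scores_a[0].marker if scores_a else ""
    marker_b = scores_b[0].marker if scores_b else ""
    if not by_sample:
        return [
            CorrelationResult(
                sample_id=None,
                marker_a=marker_a,
                marker_b=marker_b,
                cell_type=cell_type,
                method="cisa",
                r=_pearson(xs, ys),
                n=int(xs.size),
            )
        ]
    out = []
    for sid in sorted(set(samples), key=lambda s: (s is None, s)):
        sel = np.array([s == sid for s in samples])
        out.append(
            CorrelationResult(
                sample_id=sid,
                marker_a=marker_a,
                marker_b=marker_b,
                cell_type=cell_type,
                method="cisa",
                r=_pearson(xs[sel], ys[sel]),
                n=int(sel.sum()),
            )
        )
    return out


def pixelwise_correlation(
    image: MarkerImage,
    mask: LabelMask,
    cell_table: CellTable,
    cell_type: str,
    marker_a: str,
    marker_b: str,
    sample_id: Optional[str] = None,
) -> CorrelationResult:
    """Contact-naive Pearson r over all pixels of every cell of a type.

    Pools the complete cell areas (not membranes only). Zero variance in
    either marker yields a missing (NaN) coefficient.
    """
    ids = cell_table.of_type(cell_type)["cell_id"].to_numpy()
    if ids.size == 0:
        return CorrelationResult(
            sample_id, marker_a, marker_b, cell_type, "pixelwise", float("nan"), 0
        )
    sel = np.isin(mask.labels, ids)
    a = image[marker_a][sel]
    b = image[marker_b][sel]
    return CorrelationResult(
        sample_id=sample_id,
        marker_a=marker_a,
        marker_b=marker_b,
        cell_type=cell_type,
        method="pixelwise",
        r=_pearson(a, b),
        n=int(a.size),
    )


def compare_methods(
    cisa_per_sample: Sequence[CorrelationResult],
    pixelwise_per_sample: Sequence[CorrelationResult],
) -> dict:
    """Paired t-test of per-sample r(contact-aware) vs r(pixel-wise).

    Samples are matched on ``sample_id``; returns the mean difference,
    two-sided p, and a ``degenerate`` flag when the paired differences have
    zero variance (p is 1.0 for a zero mean difference, NaN otherwise).
    """
    pix = {c.sample_id: c.r for c in pixelwise_per_sample if np.isfinite(c.r)}
    diffs, cs, ps = [], [], []
    for c in cisa_per_sample:
        if c.sample_id in pix and np.isfinite(c.r):
            cs.append(c.r)
            ps.append(pix[c.sample_id])
            diffs.append(c.r - pix[c.sample_id])
    if len(diffs) < 3:
        raise ValueError("compare_methods needs at least 3 matched samples")
    diffs = np.array(diffs)
    mean_diff = float(diffs.mean())
    if np.std(diffs) == 0:
        return {
            "mean_diff": mean_diff,
            "p_value": 1.0 if mean_diff == 0 else float("nan"),
            "n": len(diffs),
            "degenerate": True,
        }
    t = stats.ttest_rel(cs, ps)
    return {
        "mean_diff": mean_diff,
        "p_value": float(t.pvalue),
        "t_statistic": float(t.statistic),
        "n": len(diffs),
        "degenerate": False,
    }
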