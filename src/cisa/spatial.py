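"""Radial distribution functions, a label-permutation null, and delta-CDF.

The RDF here is the density of target cells per 1 um distance bin around
reference cells (cells per square um), normalized per reference cell and by
annulus area but deliberately *not* by the overall point density, so curves
read as true local densities. Counts near image borders are divided by the
in-window fraction of each annulus (analytic for rectangular windows), the
standard unbiased border correction.

The expected curve permutes cell-type labels among each reference cell's
<=100 um neighbors while keeping distances fixed. Delta-CDF sums the
per-bin differences of the observed and expected cumulative distance
distributions; positive values mean observed mass sits at shorter distances
(colocalization).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .model import (
    AnalysisConfig,
    CellTable,
    DeltaCDFResult,
    RDFResult,
    RegionMasks,
)

__all__ = [
    "disk_rectangle_area",
    "annulus_window_fraction",
    "radial_density",
    "permutation_expected",
    "rdf_with_null",
    "delta_cdf",
    "cohort_delta_cdf_test",
    "region_density",
]


def _quadrant_area(a: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Area of a radius-r disk at the origin inside [0,a]x[0,b], a,b >= 0."""
    a = np.minimum(a, r)
    b = np.minimum(b, r)
    inside = a * a + b * b <= r * r
    out = np.where(inside, a * b, 0.0)
    xb = np.sqrt(np.maximum(r * r - b * b, 0.0))
    safe_r = np.where(r > 0, r, 1.0)

    def _F(x):
        return 0.5 * (
            x * np.sqrt(np.maximum(r * r - x * x, 0.0))
            + r * r * np.arcsin(np.clip(x / safe_r, -1.0, 1.0))
        )

    curved = xb * b + _F(a) - _F(xb)
    return np.where(inside | (r == 0), out, curved)


def disk_rectangle_area(
    r, cx, cy, width: float, height: float
) -> np.ndarray:
    """Exact area of disk(center (cx, cy), radius r) inside [0,W]x[0,H].

    All of ``r``, ``cx``, ``cy`` broadcast.
    """
    r, cx, cy = np.broadcast_arrays(
        np.asarray(r, float), np.asarray(cx, float), np.asarray(cy, float)
    )

    def _I(a, b):
        return np.sign(a) * np.sign(b) * _quadrant_area(np.abs(a), np.abs(b), r)

    x0, x1 = -cx, width - cx
    y0, y1 = -cy, height - cy
    return _I(x1, y1) - _I(x0, y1) - _I(x1, y0) + _I(x0, y0)


def annulus_window_fraction(
    edges_um: np.ndarray, xy_um: np.ndarray, window_um: tuple[float, float]
) -> np.ndarray:
    """In-window area fraction of each annulus around each point.

    Returns (n_points, n_bins); fraction is (A(r+1) - A(r)) / annulus area.
    """
    W, H = window_um
    disk_areas = disk_rectangle_area(
        edges_um[None, :], xy_um[:, 0:1], xy_um[:, 1:2], W, H
    )
    in_areas = np.diff(disk_areas, axis=1)
    full = np.pi * np.diff(edges_um**2)
    return in_areas / full[None, :]


def _bin_edges(config: AnalysisConfig) -> np.ndarray:
    return np.arange(config.n_rdf_bins + 1, dtype=float) * config.rdf_bin_um


def _select_refs(cell_table: CellTable, reference_type: str, region):
    m = cell_table.has_type(reference_type)
    if region is not None:
        m &= (cell_table.df["region"] == region).to_numpy()
    return np.nonzero(m)[0]


def _weights(
    config, cell_table, ref_xy, edges, window_um, edge_correction
):
    """Per-(reference, bin) reciprocal annulus in-window fractions."""
    n_bins = len(edges) - 1
    if not edge_correction:
        return np.ones((len(ref_xy), n_bins))
    if window_um is None:
        window_um = cell_table.window_um
    if window_um is None:
        raise ValueError("edge correction needs a window_um (width, height)")
    frac = annulus_window_fraction(edges, ref_xy, window_um)
    w = np.zeros_like(frac)
    np.divide(1.0, frac, out=w, where=frac > 1e-12)
    return w


def radial_density(
    cell_table: CellTable,
    reference_type: str,
    target_type: str,
    region: Optional[str] = None,
    config: Optional[AnalysisConfig] = None,
    window_um: Optional[tuple[float, float]] = None,
    edge_correction: Optional[bool] = None,
) -> RDFResult:
    """Observed target-cell density per distance bin around reference cells.

    Counts target cells (the reference cell itself excluded) in half-open
    1 um annuli out to 100 um, edge-corrects, averages over reference cells
    and divides by the full annulus areas. ``region`` filters the reference
    cells only.
    """
    config = config or AnalysisConfig()
    if edge_correction is None:
        edge_correction = config.edge_correction
    edges = _bin_edges(config)
    n_bins = len(edges) - 1
    ref_idx = _select_refs(cell_table, reference_type, region)
    if ref_idx.size == 0:
        raise ValueError(f"no reference cells of type {reference_type!r}")
    xy = cell_table.xy_um
    tgt_mask = cell_table.has_type(target_type)
    ref_xy = xy[ref_idx]
    weights = _weights(config, cell_table, ref_xy, edges, window_um, edge_correction)

    tgt_idx = np.nonzero(tgt_mask)[0]
    acc = np.zeros(n_bins)
    if tgt_idx.size:
        tree = cKDTree(xy[tgt_idx])
        hits = tree.query_ball_point(ref_xy, r=float(edges[-1]))
        for i, hit in enumerate(hits):
            if not hit:
                continue
            cand = tgt_idx[np.asarray(hit)]
            cand = cand[cand != ref_idx[i]]
            if cand.size == 0:
                continue
            d = np.linalg.norm(xy[cand] - ref_xy[i], axis=1)
            b = np.floor(d / config.rdf_bin_um).astype(int)
            keep = b < n_bins
            np.add.at(acc, b[keep], weights[i, b[keep]])
    annulus = np.pi * np.diff(edges**2)
    observed = acc / ref_idx.size / annulus
    return RDFResult(
        reference_type=reference_type,
        target_type=target_type,
        region=region or "none",
        bin_edges_um=edges,
        observed=observed,
        expected=None,
        n_ref=int(ref_idx.size),
    )


def permutation_expected(
    cell_table: CellTable,
    reference_type: str,
    target_type: str,
    region: Optional[str] = None,
    config: Optional[AnalysisConfig] = None,
    rng: Optional[np.random.Generator] = None,
    window_um: Optional[tuple[float, float]] = None,
    edge_correction: Optional[bool] = None,
) -> np.ndarray:
    """Label-permutation expected RDF curve.

    For each reference cell, the type labels of all cells within 100 um
    (the reference itself keeps its label) are permuted uniformly while
    distances stay fixed; target counts are re-collected per bin, repeated
    ``n_permutations`` times and averaged, then normalized identically to
    the observed curve. The number of target labels within each reference's
    neighborhood is conserved by construction.
    """
    config = config or AnalysisConfig()
    if edge_correction is None:
        edge_correction = config.edge_correction
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    edges = _bin_edges(config)
    n_bins = len(edges) - 1
    ref_idx = _select_refs(cell_table, reference_type, region)
    if ref_idx.size == 0:
        raise ValueError(f"no reference cells of type {reference_type!r}")
    xy = cell_table.xy_um
    tgt_mask = cell_table.has_type(target_type)
    ref_xy = xy[ref_idx]
    weights = _weights(config, cell_table, ref_xy, edges, window_um, edge_correction)

    tree = cKDTree(xy)
    hits = tree.query_ball_point(ref_xy, r=float(edges[-1]))
    n_perm = config.n_permutations
    acc = np.zeros(n_bins)
    for i, hit in enumerate(hits):
        cand = np.sort(np.asarray(hit))  # fixed order: reproducible RNG stream
        cand = cand[cand != ref_idx[i]]
        if cand.size == 0:
            continue
        d = np.linalg.norm(xy[cand] - ref_xy[i], axis=1)
        b = np.floor(d / config.rdf_bin_um).astype(int)
        keep = b < n_bins
        cand, b = cand[keep], b[keep]
        if cand.size == 0:
            continue
        indicator = tgt_mask[cand]
        m = cand.size
        # how many of n_perm random permutations place a target label at
        # each neighbor position
        perm_positions = np.argsort(rng.random((n_perm, m)), axis=1)
        held = indicator[perm_positions].sum(axis=0)
        np.add.at(acc, b, weights[i, b] * held)
    annulus = np.pi * np.diff(edges**2)
    return acc / n_perm / ref_idx.size / annulus


def rdf_with_null(
    cell_table: CellTable,
    reference_type: str,
    target_type: str,
    region: Optional[str] = None,
    config: Optional[AnalysisConfig] = None,
    rng: Optional[np.random.Generator] = None,
    window_um: Optional[tuple[float, float]] = None,
    edge_correction: Optional[bool] = None,
) -> RDFResult:
    """Observed curve together with the permutation-expected curve."""
    res = radial_density(
        cell_table, reference_type, target_type, region, config,
        window_um=window_um, edge_correction=edge_correction,
    )
    res.expected = permutation_expected(
        cell_table, reference_type, target_type, region, config,
        rng=rng, window_um=window_um, edge_correction=edge_correction,
    )
    return res


def delta_cdf(
    observed: np.ndarray,
    expected: np.ndarray,
    sample_id: Optional[str] = None,
    region: str = "none",
    target_type: str = "",
) -> Optional[DeltaCDFResult]:
    """Sum of per-bin differences of the observed and expected CDFs.

    Each curve is normalized to total mass 1 (pseudo-PDF), cumulated, and
    the differences summed over the 100 bins. Returns ``None`` when either
    curve has zero total mass.
    """
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    if observed.shape != expected.shape:
        raise ValueError("curve length mismatch")
    so, se = observed.sum(), expected.sum()
    if so <= 0 or se <= 0:
        return None
    cdf_o = np.cumsum(observed / so)
    cdf_e = np.cumsum(expected / se)
    return DeltaCDFResult(
        sample_id=sample_id,
        region=region,
        target_type=target_type,
        delta_cdf=float(np.sum(cdf_o - cdf_e)),
    )


def cohort_delta_cdf_test(values: Sequence[float]) -> dict:
    """One-sided (greater than 0) one-sample t-test on per-sample delta-CDF."""
    values = np.asarray([v for v in values if np.isfinite(v)], float)
    if values.size < 3:
        raise ValueError("cohort test needs at least 3 samples")
    mean = float(values.mean())
    if np.std(values) == 0:
        return {
            "mean": mean,
            "p_value": 0.0 if mean > 0 else 1.0,
            "n": int(values.size),
            "degenerate": True,
        }
    t = stats.ttest_1samp(values, 0.0, alternative="greater")
    return {
        "mean": mean,
        "p_value": float(t.pvalue),
        "t_statistic": float(t.statistic),
        "n": int(values.size),
        "degenerate": False,
    }


def region_density(
    cell_table: CellTable,
    region_masks: RegionMasks,
    type_label: str,
    pixel_size_um: float,
) -> dict:
    """Cells of a type per square millimetre of tumor and of stroma."""
    px_mm2 = (pixel_size_um / 1000.0) ** 2
    out = {}
    for name, mask in (("intratumor", region_masks.tumor), ("stroma", region_masks.stroma)):
        area_mm2 = float(mask.sum()) * px_mm2
        if area_mm2 == 0:
            raise ValueError(f"empty {name} region mask")
        sel = cell_table.of_type(type_label, region=name)
        out[name] = len(sel) / area_mm2
    return out
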