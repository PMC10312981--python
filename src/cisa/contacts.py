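"""Cell-membrane extraction and contact-interface geometry.

A cell's membrane is its internal boundary: the cell pixels within Chebyshev
(8-connected) distance ``width_px`` of any non-cell pixel, i.e.
``cell \\ erosion(cell, square of side 2*width+1)``. Pixels outside the image
count as non-cell, so border-touching cells keep a defined membrane.

A neighbor is in contact where its mask, dilated with an L1-ball (diamond)
structuring element of radius ``dilation_radius_px`` (default 2, wide enough
to bridge the neighbor's own 2-px membrane), intersects the reference cell's
membrane. When a reference cell touches several neighbors of the same type,
the noncontact pool excludes the union of all same-type contact interfaces.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .model import CellTable, ContactRecord, LabelMask, AnalysisConfig

__all__ = [
    "extract_membrane",
    "find_contacts",
    "apply_noncontact_exclusion",
    "contacts_for_reference",
    "all_contacts",
]


def _bbox_slices(mask: np.ndarray, pad: int) -> tuple[slice, slice]:
    rr, cc = np.nonzero(mask)
    r0 = max(int(rr.min()) - pad, 0)
    r1 = min(int(rr.max()) + pad + 1, mask.shape[0])
    c0 = max(int(cc.min()) - pad, 0)
    c1 = min(int(cc.max()) + pad + 1, mask.shape[1])
    return slice(r0, r1), slice(c0, c1)


def extract_membrane(
    mask: LabelMask, cell_id: int, width_px: int, connectivity: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the ``width_px``-wide internal boundary of a cell.

    Cells thinner than ``2*width_px`` are all membrane. ``connectivity``
    selects the erosion element: 8 (square, default) or 4 (diamond).
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    cell = mask.labels == cell_id
    if not cell.any():
        raise KeyError(f"cell id {cell_id} not present in mask")
    sl = _bbox_slices(cell, pad=1)
    sub = cell[sl]
    structure = (
        np.ones((3, 3), bool)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    interior = ndimage.binary_erosion(
        sub, structure=structure, iterations=width_px, border_value=0
    )
    membrane = sub & ~interior
    rr, cc = np.nonzero(membrane)
    return rr + sl[0].start, cc + sl[1].start


def _diamond(radius: int) -> np.ndarray:
    n = 2 * radius + 1
    rr, cc = np.mgrid[:n, :n]
    return (np.abs(rr - radius) + np.abs(cc - radius)) <= radius


def _touches_border(shape, rr, cc) -> bool:
    return bool(
        (rr == 0).any()
        or (cc == 0).any()
        or (rr == shape[0] - 1).any()
        or (cc == shape[1] - 1).any()
    )


def find_contacts(
    mask: LabelMask,
    ref_id: int,
    neighbor_ids: Iterable[int],
    cell_table: Optional[CellTable] = None,
    config: Optional[AnalysisConfig] = None,
    membrane_px: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> list[ContactRecord]:
    """Contact records of one reference cell against candidate neighbors.

    Emits a record only where the dilated neighbor intersects the reference
    membrane. ``noncontact_px`` is initially ``membrane \\ contact`` per
    record; apply :func:`apply_noncontact_exclusion` to pool same-type
    exclusions before scoring.
    """
    config = config or AnalysisConfig()
    if membrane_px is None:
        membrane_px = extract_membrane(mask, ref_id, config.membrane_width_px)
    mem_r, mem_c = membrane_px
    shape = mask.shape
    mem_flat = mem_r.astype(np.int64) * shape[1] + mem_c
    order = np.argsort(mem_flat)
    mem_flat_sorted = mem_flat[order]
    structure = _diamond(config.dilation_radius_px)
    border = _touches_border(shape, mem_r, mem_c)

    records = []
    for nb in neighbor_ids:
        if nb == ref_id:
            continue
        nb_mask = mask.labels == nb
        if not nb_mask.any():
            raise KeyError(f"neighbor id {nb} not present in mask")
        sl = _bbox_slices(nb_mask, pad=config.dilation_radius_px)
        dil = ndimage.binary_dilation(nb_mask[sl], structure=structure)
        full = np.zeros(shape, bool)
        full[sl] = dil
        hit = full[mem_r, mem_c]
        if not hit.any():
            continue
        contact = (mem_r[hit], mem_c[hit])
        keep = ~hit
        noncontact = (mem_r[keep], mem_c[keep])
        types = (
            cell_table.types_of(nb) if cell_table is not None else frozenset()
        )
        records.append(
            ContactRecord(
                ref_id=ref_id,
                neighbor_id=int(nb),
                neighbor_types=types,
                contact_px=contact,
                noncontact_px=noncontact,
                membrane_px=(mem_r, mem_c),
                touches_border=border,
            )
        )
    return records


def apply_noncontact_exclusion(
    records: Sequence[ContactRecord], target_type: Optional[str] = None
) -> list[ContactRecord]:
    """Pool the same-type contact exclusion across one reference cell.

    For the given target type, every record against a neighbor of that type
    gets ``noncontact_px = membrane \\ union(contact_px over all neighbors of
    that type)``. Contacts with neighbors of other types are not removed.
    With ``target_type=None`` each record's own types are used in turn
    (a record appears once per held neighbor type when types differ).
    """
    if not records:
        return []
    ref_ids = {r.ref_id for r in records}
    if len(ref_ids) != 1:
        raise ValueError("records must belong to a single reference cell")
    mem_r, mem_c = records[0].membrane_px
    shape_cols = int(max(mem_c.max(), max(r.contact_px[1].max() for r in records))) + 1
    mem_flat = mem_r.astype(np.int64) * shape_cols + mem_c

    if target_type is not None:
        type_pool = [target_type]
    else:
        type_pool = sorted({t for r in records for t in r.neighbor_types})
        if not type_pool:
            type_pool = [None]

    out = []
    for t in type_pool:
        if t is None:
            group = list(records)
        else:
            group = [r for r in records if t in r.neighbor_types]
        if not group:
            continue
        union_flat = np.unique(
            np.concatenate(
                [r.contact_px[0].astype(np.int64) * shape_cols + r.contact_px[1] for r in group]
            )
        )
        keep = ~np.isin(mem_flat, union_flat)
        noncontact = (mem_r[keep], mem_c[keep])
        empty = noncontact[0].size == 0
        for r in group:
            out.append(
                ContactRecord(
                    ref_id=r.ref_id,
                    neighbor_id=r.neighbor_id,
                    neighbor_types=r.neighbor_types,
                    contact_px=r.contact_px,
                    noncontact_px=noncontact,
                    membrane_px=r.membrane_px,
                    touches_border=r.touches_border,
                    no_noncontact=empty,
                )
            )
    return out


def _neighbor_candidates(
    mask: LabelMask, ref_id: int, membrane_px, radius: int
) -> np.ndarray:
    """Labels whose pixels come within L1 distance ``radius`` of the membrane."""
    rr, cc = membrane_px
    shape = mask.shape
    box = np.zeros(shape, bool)
    box[rr, cc] = True
    sl = _bbox_slices(box, pad=radius)
    dil = ndimage.binary_dilation(box[sl], structure=_diamond(radius))
    labs = np.unique(mask.labels[sl][dil])
    return labs[(labs > 0) & (labs != ref_id)]


def contacts_for_reference(
    mask: LabelMask,
    ref_id: int,
    cell_table: Optional[CellTable] = None,
    config: Optional[AnalysisConfig] = None,
    target_type: Optional[str] = None,
) -> list[ContactRecord]:
    """All contact records of one reference cell, with same-type exclusion."""
    config = config or AnalysisConfig()
    membrane = extract_membrane(mask, ref_id, config.membrane_width_px)
    cand = _neighbor_candidates(mask, ref_id, membrane, config.dilation_radius_px)
    recs = find_contacts(
        mask, ref_id, cand, cell_table, config, membrane_px=membrane
    )
    return apply_noncontact_exclusion(recs, target_type=target_type)


def all_contacts(
    mask: LabelMask,
    cell_table: CellTable,
    config: Optional[AnalysisConfig] = None,
    reference_type: Optional[str] = None,
    target_type: Optional[str] = None,
) -> list[ContactRecord]:
    """Contact records for every reference cell of ``reference_type``.

    Records against neighbors lacking ``target_type`` (when given) are
    dropped after the exclusion step.
    """
    config = config or AnalysisConfig()
    if reference_type is None:
        ref_ids = cell_table.cell_ids
    else:
        ref_ids = cell_table.of_type(reference_type)["cell_id"].to_numpy()
    out = []
    for ref_id in ref_ids:
        recs = contacts_for_reference(
            mask, int(ref_id), cell_table, config, target_type=target_type
        )
        if target_type is not None:
            recs = [r for r in recs if target_type in r.neighbor_types]
        out.extend(recs)
    return out
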