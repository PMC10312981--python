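"""Synthetic tissue, point-pattern and two-compartment image generators.

These generators provide ground truth for every analysis stage: packed
disk-shaped cells with membrane-localized markers and designated contacting
pairs whose contact-facing membrane intensity is multiplied by a known
factor ``f`` (so the expected synapse strength is ``log2(f)``); homogeneous
Poisson and clustered point patterns for radial-distribution calibration;
and two-compartment tumor/leukocyte images for segmentation recovery.

The contact-facing polarization zone uses the same diamond-dilation rule as
the analyzer, so in the noiseless case the measured sigma equals ``log2(f)``
exactly rather than approximately. Noise is additive Gaussian clipped at 0,
or Poisson counts (mimicking ion-count sparsity, including exact-zero
pixels), selected by ``noise_kind``. No attempt is made to simulate
realistic tissue morphology, point-spread functions, or spectral spillover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import extract_membrane, find_contacts
from .model import AnalysisConfig, CellTable, LabelMask, MarkerImage, RegionMasks

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_tissue",
    "generate_point_pattern",
    "generate_two_compartment_image",
]

REF_TYPE = "T-cell"
NEIGHBOR_TYPE = "APC"
OTHER_TYPE = "other"


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a generated tissue.

    ``polarization_factor`` multiplies the reference cell's contact-facing
    membrane pixels (f >= 1; expected sigma = log2 f).
    ``polarization_log2_sd`` adds per-contact lognormal variation around
    log2(f), and ``comarker_rho`` couples that variation between the first
    two markers for co-polarization tests.
    """

    n_pairs: int = 40
    n_other: int = 10
    markers: tuple[str, ...] = ("CD3",)
    pixel_size_um: float = 1.0
    cell_radius_px: tuple[int, int] = (6, 9)
    polarization_factor: float = 2.0
    polarization_log2_sd: float = 0.0
    comarker_rho: float = 0.0
    membrane_base_intensity: float = 100.0
    cytoplasm_base_intensity: float = 20.0
    other_cell_intensity: float = 10.0
    noise_kind: str = "none"  # none | gaussian | poisson
    background_noise_sd: float = 0.0
    modality: str = "fluorescence"
    membrane_width_px: int = 2
    dilation_radius_px: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.polarization_factor < 1:
            raise ValueError("polarization_factor must be >= 1")
        if self.noise_kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if not (-1.0 <= self.comarker_rho <= 1.0):
            raise ValueError("comarker_rho must be in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Designated contacts with their true per-marker log2 polarization."""

    pairs: pd.DataFrame  # ref_id, neighbor_id, marker, true_log2_polarization
    cell_types: dict = field(default_factory=dict)

    def true_log2(self, ref_id: int, neighbor_id: int, marker: str) -> float:
        sel = self.pairs[
            (self.pairs.ref_id == ref_id)
            & (self.pairs.neighbor_id == neighbor_id)
            & (self.pairs.marker == marker)
        ]
        if sel.empty:
            raise KeyError((ref_id, neighbor_id, marker))
        return float(sel.true_log2_polarization.iloc[0])


def _disk_offsets(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    sel = yy**2 + xx**2 <= radius**2
    return np.stack([yy[sel], xx[sel]], axis=1)


def _place_pair(
    cy: int, cx: int, r1: int, r2: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Neighbor center tangent to (cy, cx) such that the rasterized disks are
    disjoint and within L1 reach 2 of each other (guaranteed contact)."""
    d1 = _disk_offsets(r1)
    d2 = _disk_offsets(r2)
    for attempt in range(30):
        if attempt < 29:
            theta = rng.uniform(0, 2 * np.pi)
            d = r1 + r2 + 1
            ny = int(round(cy + d * np.sin(theta)))
            nx = int(round(cx + d * np.cos(theta)))
        else:  # axis-aligned fallback always satisfies both conditions
            ny, nx = cy, cx + r1 + r2 + 1
        p1 = d1 + (cy, cx)
        p2 = d2 + (ny, nx)
        l1 = np.abs(p1[:, None, :] - p2[None, :, :]).sum(axis=2)
        if l1.min() == 0:  # overlapping rasterizations
            continue
        if l1.min() <= 2:
            return ny, nx
    raise RuntimeError("pair placement failed")


def _paint_disk(labels: np.ndarray, cy: int, cx: int, radius: int, value: int):
    H, W = labels.shape
    r0, r1 = max(cy - radius, 0), min(cy + radius + 1, H)
    c0, c1 = max(cx - radius, 0), min(cx + radius + 1, W)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    labels[r0:r1, c0:c1][disk] = value


def generate_tissue(
    config: SyntheticConfig,
) -> tuple[MarkerImage, LabelMask, CellTable, SyntheticTruth]:
    """Tissue of tangent reference/neighbor disk pairs plus isolated cells.

    Pairs are laid out on a jittered grid with the neighbor placed tangent
    to its reference cell (1 px gap, bridged by the contact dilation), so
    every designated pair is in contact in the generated mask; extra
    isolated cells of a third type support background-noise estimation.
    Deterministic for a given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    rmin, rmax = config.cell_radius_px
    # grid pitch: a tangent pair plus jitter spans at most 3*rmax+4 from its
    # site center; this pitch keeps >=4 px clearance between sites
    site = 6 * rmax + 12
    n_sites = config.n_pairs + config.n_other
    n_col = int(np.ceil(np.sqrt(n_sites)))
    n_row = int(np.ceil(n_sites / n_col))
    H, W = n_row * site, n_col * site
    labels = np.zeros((H, W), np.int32)

    records = []
    next_id = 1
    pair_ids = []
    for k in range(n_sites):
        gy, gx = divmod(k, n_col)
        cy0, cx0 = gy * site + site // 2, gx * site + site // 2
        jitter = rng.integers(-3, 4, size=2)
        cy, cx = int(cy0 + jitter[0]), int(cx0 + jitter[1])
        if k < config.n_pairs:
            r1 = int(rng.integers(rmin, rmax + 1))
            r2 = int(rng.integers(rmin, rmax + 1))
            ny, nx = _place_pair(cy, cx, r1, r2, rng)
            ref_id, nb_id = next_id, next_id + 1
            next_id += 2
            _paint_disk(labels, cy, cx, r1, ref_id)
            _paint_disk(labels, ny, nx, r2, nb_id)
            records.append((ref_id, cx, cy, REF_TYPE))
            records.append((nb_id, nx, ny, NEIGHBOR_TYPE))
            pair_ids.append((ref_id, nb_id))
        else:
            r1 = int(rng.integers(rmin, rmax + 1))
            cid = next_id
            next_id += 1
            _paint_disk(labels, cy, cx, r1, cid)
            records.append((cid, cx, cy, OTHER_TYPE))
    mask = LabelMask(labels)

    # verify the designated-pair invariant before painting intensities
    geom = AnalysisConfig(
        membrane_width_px=config.membrane_width_px,
        dilation_radius_px=config.dilation_radius_px,
    )
    contact_zones = {}
    for ref_id, nb_id in pair_ids:
        recs = find_contacts(mask, ref_id, [nb_id], config=geom)
        if not recs:
            raise RuntimeError(
                f"designated pair ({ref_id},{nb_id}) not in contact; "
                "lower cell density or radii"
            )
        contact_zones[(ref_id, nb_id)] = recs[0]

    # per-contact polarization factors, optionally coupled across markers
    n_markers = len(config.markers)
    base_log2 = np.log2(config.polarization_factor)
    z = np.zeros((len(pair_ids), n_markers))
    if config.polarization_log2_sd > 0:
        shared = rng.normal(size=len(pair_ids))
        for j in range(n_markers):
            if j == 0 or config.comarker_rho == 0:
                own = shared if j == 0 else rng.normal(size=len(pair_ids))
            else:
                own = config.comarker_rho * shared + np.sqrt(
                    1 - config.comarker_rho**2
                ) * rng.normal(size=len(pair_ids))
            z[:, j] = config.polarization_log2_sd * own
    log2_factors = base_log2 + z

    channels = {}
    membranes = {}
    for cid, _, _, ctype in records:
        if ctype in (REF_TYPE, NEIGHBOR_TYPE):
            membranes[cid] = extract_membrane(mask, cid, config.membrane_width_px)
    truth_rows = []
    for j, marker in enumerate(config.markers):
        chan = np.zeros((H, W))
        for cid, _, _, ctype in records:
            sel = labels == cid
            if ctype == OTHER_TYPE:
                chan[sel] = config.other_cell_intensity
            else:
                chan[sel] = config.cytoplasm_base_intensity
                chan[membranes[cid]] = config.membrane_base_intensity
        for p, (ref_id, nb_id) in enumerate(pair_ids):
            zone = contact_zones[(ref_id, nb_id)]
            chan[zone.contact_px] *= 2.0 ** log2_factors[p, j]
            truth_rows.append(
                {
                    "ref_id": ref_id,
                    "neighbor_id": nb_id,
                    "marker": marker,
                    "true_log2_polarization": log2_factors[p, j],
                }
            )
        if config.noise_kind == "gaussian" and config.background_noise_sd > 0:
            chan = np.clip(
                chan + rng.normal(0, config.background_noise_sd, chan.shape), 0, None
            )
        elif config.noise_kind == "poisson":
            chan = rng.poisson(chan).astype(float)
        channels[marker] = chan

    image = MarkerImage(
        channels, pixel_size_um=config.pixel_size_um, modality=config.modality
    )
    rows = []
    for cid, cx, cy, ctype in records:
        row = {
            "cell_id": cid,
            "x_um": cx * config.pixel_size_um,
            "y_um": cy * config.pixel_size_um,
            "types": frozenset([ctype]),
            "region": "none",
        }
        for marker in config.markers:
            row[f"mean_{marker}"] = float(channels[marker][labels == cid].mean())
        rows.append(row)
    table = CellTable(
        pd.DataFrame(rows),
        window_um=(W * config.pixel_size_um, H * config.pixel_size_um),
    )
    truth = SyntheticTruth(
        pairs=pd.DataFrame(truth_rows),
        cell_types={cid: ctype for cid, _, _, ctype in records},
    )
    return image, mask, table, truth


def generate_point_pattern(
    kind: str,
    window_um: tuple[float, float],
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    intensity_per_mm2: float = 100.0,
    type_proportions: Optional[dict] = None,
    parent_type: str = REF_TYPE,
    offspring_type: str = "macrophage",
    background_type: str = "tumor",
    parent_intensity_per_mm2: float = 50.0,
    offspring_mean: float = 5.0,
    offspring_radius_um: float = 15.0,
    background_intensity_per_mm2: float = 200.0,
) -> CellTable:
    """Homogeneous Poisson or clustered parent-offspring point pattern.

    ``poisson``: N ~ Poisson(intensity * area) points uniform in the window
    with independent type labels drawn from ``type_proportions``.
    ``clustered``: Poisson parents (``parent_type``) each scatter
    Poisson-many offspring (``offspring_type``) uniformly within
    ``offspring_radius_um``, over an independent uniform background of
    ``background_type`` cells, so offspring are enriched near parents.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    W, H = window_um
    area_mm2 = (W / 1000.0) * (H / 1000.0)
    rows = []
    cid = 1
    if kind == "poisson":
        props = type_proportions or {REF_TYPE: 0.5, "macrophage": 0.5}
        names = list(props)
        p = np.array([props[n] for n in names], float)
        p = p / p.sum()
        n = rng.poisson(intensity_per_mm2 * area_mm2)
        xy = rng.uniform([0, 0], [W, H], size=(n, 2))
        t_idx = rng.choice(len(names), size=n, p=p)
        for i in range(n):
            rows.append(
                {
                    "cell_id": cid,
                    "x_um": xy[i, 0],
                    "y_um": xy[i, 1],
                    "types": frozenset([names[t_idx[i]]]),
                    "region": "none",
                }
            )
            cid += 1
    elif kind == "clustered":
        n_bg = rng.poisson(background_intensity_per_mm2 * area_mm2)
        for x, y in rng.uniform([0, 0], [W, H], size=(n_bg, 2)):
            rows.append(
                {
                    "cell_id": cid,
                    "x_um": x,
                    "y_um": y,
                    "types": frozenset([background_type]),
                    "region": "none",
                }
            )
            cid += 1
        n_par = rng.poisson(parent_intensity_per_mm2 * area_mm2)
        parents = rng.uniform([0, 0], [W, H], size=(n_par, 2))
        for px, py in parents:
            rows.append(
                {
                    "cell_id": cid,
                    "x_um": px,
                    "y_um": py,
                    "types": frozenset([parent_type]),
                    "region": "none",
                }
            )
            cid += 1
            for _ in range(rng.poisson(offspring_mean)):
                r = offspring_radius_um * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                ox = np.clip(px + r * np.cos(th), 0, W)
                oy = np.clip(py + r * np.sin(th), 0, H)
                rows.append(
                    {
                        "cell_id": cid,
                        "x_um": ox,
                        "y_um": oy,
                        "types": frozenset([offspring_type]),
                        "region": "none",
                    }
                )
                cid += 1
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    if not rows:
        df = pd.DataFrame(
            columns=["cell_id", "x_um", "y_um", "types", "region"]
        ).astype({"cell_id": int})
    else:
        df = pd.DataFrame(rows)
    return CellTable(df, window_um=window_um)


def generate_two_compartment_image(
    image_size_px: int = 400,
    tumor_radius_px: int = 90,
    tissue_radius_px: Optional[int] = None,
    tumor_channel: str = "Melanoma",
    leukocyte_channel: str = "CD45",
    background_level: float = 0.3,
    tissue_level: float = 3.0,
    foreground_level: float = 400.0,
    noise_sd_frac: float = 0.15,
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> tuple[MarkerImage, RegionMasks]:
    """Bright tumor blob inside a leukocyte-filled tissue disk, with truth.

    The tumor channel is bright inside the blob and faint over the rest of
    the tissue; the leukocyte channel is bright over the whole tissue disk.
    Gaussian noise proportional to the local level is added, and the
    Gaussian-blur transition pixels populate the low-intensity-foreground
    class of the four-class threshold model. True masks (tumor blob;
    stroma = tissue minus blob) are returned.
    """
    rng = np.random.default_rng(seed)
    S = image_size_px
    if tissue_radius_px is None:
        tissue_radius_px = int(0.45 * S)
    yy, xx = np.mgrid[:S, :S]
    c = S / 2.0
    tissue = (yy - c) ** 2 + (xx - c) ** 2 <= tissue_radius_px**2
    off = 0.12 * S
    tumor = (yy - (c - off)) ** 2 + (xx - (c - off)) ** 2 <= tumor_radius_px**2
    tumor &= tissue

    mel = np.full((S, S), background_level)
    mel[tissue] = tissue_level
    mel[tumor] = foreground_level
    cd45 = np.full((S, S), background_level)
    cd45[tissue] = foreground_level

    channels = {}
    for name, raw in ((tumor_channel, mel), (leukocyte_channel, cd45)):
        noisy = raw * (1.0 + noise_sd_frac * rng.normal(size=raw.shape))
        channels[name] = np.clip(noisy, 0, None)
    image = MarkerImage(channels, pixel_size_um=pixel_size_um)
    truth = RegionMasks(tumor=tumor, stroma=tissue & ~tumor)
    return image, truth
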