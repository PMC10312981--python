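"""Shared data model for multiplexed-image synapse analysis.

Conventions
-----------
Pixel rasters are 0-based, row-major ``(row, col)``; exported centroids are in
micrometres with ``x = col * pixel_size_um`` and ``y = row * pixel_size_um``.
Square pixels only. Intensities are carried as ``float64`` after load,
regardless of the on-disk bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MarkerImage",
    "LabelMask",
    "CellTable",
    "RegionMasks",
    "AnalysisConfig",
    "ContactRecord",
    "SynapseScore",
    "SampleSynapseSummary",
    "NoiseTerm",
    "CorrelationResult",
    "RDFResult",
    "DeltaCDFResult",
    "ThresholdModel",
]


@dataclass
class MarkerImage:
    """Named 2D intensity channels sharing one pixel grid.

    Parameters
    ----------
    channels
        Mapping of marker name to a 2D non-negative intensity raster
        (arbitrary units).
    pixel_size_um
        Micrometres per pixel (square pixels).
    modality
        ``"fluorescence"`` or ``"imc"``.
    log_transformed
        Set by :func:`cisa.io.imc_preprocess`; guards double application.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    modality: str = "fluorescence"
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.modality not in ("fluorescence", "imc"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.channels:
            raise ValueError("MarkerImage needs at least one channel")
        shapes = set()
        converted = {}
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=np.float64)
            if a.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(a < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            shapes.add(a.shape)
            converted[name] = a
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        self.channels = converted

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown marker {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class LabelMask:
    """Integer cell-instance mask; 0 is background, k>0 is cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.labels)
        if a.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(a == np.round(a)):
                raise ValueError("label mask must be integer valued")
            a = a.astype(np.int64)
        if a.min() < 0:
            raise ValueError("label mask has negative labels")
        self.labels = a.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def pixels(self, cell_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the cell's pixels; raises on an absent id."""
        rr, cc = np.nonzero(self.labels == cell_id)
        if rr.size == 0:
            raise KeyError(f"cell id {cell_id} not present in mask")
        return rr, cc


_TYPE_SEP = ";"


class CellTable:
    """Per-cell annotation table backed by a :class:`pandas.DataFrame`.

    Columns: ``cell_id`` (positive int, unique), ``x_um``/``y_um`` centroids,
    ``types`` (frozenset of labels; multi-label cells are retained and
    flagged ``multi_label``), ``region`` in {intratumor, stroma, none},
    ``mean_<marker>`` channel means, and optional boolean ``ki67`` and
    ``loaded`` flags plus a ``sample_id``.
    """

    REGIONS = ("intratumor", "stroma", "none")

    def __init__(
        self,
        df: pd.DataFrame,
        window_um: Optional[tuple[float, float]] = None,
    ):
        df = df.copy()
        if "cell_id" not in df.columns:
            raise ValueError("cell table needs a 'cell_id' column")
        ids = df["cell_id"].to_numpy()
        if np.any(ids <= 0):
            raise ValueError("cell ids must be positive")
        if len(np.unique(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise ValueError(f"duplicate cell id {dup}")
        if "types" not in df.columns:
            df["types"] = [frozenset()] * len(df)
        df["types"] = df["types"].map(_as_typeset)
        if "region" not in df.columns:
            df["region"] = "none"
        bad = set(df["region"].unique()) - set(self.REGIONS)
        if bad:
            raise ValueError(f"unknown regions {bad}")
        mean_cols = [c for c in df.columns if c.startswith("mean_")]
        for c in mean_cols:
            if (df[c].dropna() < 0).any():
                raise ValueError(f"negative channel mean in {c}")
        self.df = df.reset_index(drop=True)
        #: (width_um, height_um) of the analysis window, if known
        self.window_um = window_um

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy()

    @property
    def xy_um(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def types_of(self, cell_id: int) -> frozenset:
        row = self.df.loc[self.df["cell_id"] == cell_id]
        if row.empty:
            raise KeyError(f"cell id {cell_id} not in table")
        return row["types"].iloc[0]

    def has_type(self, type_label: str) -> np.ndarray:
        return self.df["types"].map(lambda s: type_label in s).to_numpy()

    def of_type(self, type_label: str, region: Optional[str] = None) -> pd.DataFrame:
        m = self.has_type(type_label)
        if region is not None:
            m &= (self.df["region"] == region).to_numpy()
        return self.df.loc[m]

    def validate_against(self, mask: LabelMask) -> None:
        present = set(mask.cell_ids.tolist())
        missing = set(self.cell_ids.tolist()) - present
        if missing:
            raise ValueError(f"cell ids absent from mask: {sorted(missing)[:10]}")

    def copy(self) -> "CellTable":
        return CellTable(self.df.copy(), window_um=self.window_um)


def _as_typeset(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(str(v) for v in value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    if not s:
        return frozenset()
    return frozenset(p.strip() for p in s.split(_TYPE_SEP) if p.strip())


def types_to_str(types: Iterable[str]) -> str:
    return _TYPE_SEP.join(sorted(types))


@dataclass
class RegionMasks:
    """Tumor and stroma binary rasters; stroma excludes tumor by construction."""

    tumor: np.ndarray
    stroma: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.stroma = np.asarray(self.stroma, dtype=bool)
        if self.tumor.shape != self.stroma.shape:
            raise ValueError("tumor/stroma shape mismatch")
        if np.any(self.tumor & self.stroma):
            raise ValueError("tumor and stroma masks overlap")


@dataclass
class AnalysisConfig:
    """Fixed constants of the synapse and radial-distribution analyses.

    Membrane width defaults to 2 px for fluorescence and 1 px for IMC
    (set explicitly or via :meth:`for_modality`).
    """

    membrane_width_px: int = 2
    dilation_radius_px: int = 2
    synapse_marker: str = "CD3"
    reference_types: tuple[str, ...] = ("T-cell",)
    target_types: tuple[str, ...] = ("macrophage",)
    rdf_max_um: float = 100.0
    rdf_bin_um: float = 1.0
    n_permutations: int = 100
    null_seeds_per_cell: int = 5
    null_min_region_px: int = 15
    null_iterations: int = 100
    edge_correction: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "membrane_width_px",
            "dilation_radius_px",
            "n_permutations",
            "null_seeds_per_cell",
            "null_min_region_px",
            "null_iterations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.membrane_width_px not in (1, 2):
            raise ValueError("membrane_width_px must be 1 or 2")
        n_bins = self.rdf_max_um / self.rdf_bin_um
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("rdf_max_um must be divisible by rdf_bin_um")
        self.reference_types = tuple(self.reference_types)
        self.target_types = tuple(self.target_types)

    @property
    def n_rdf_bins(self) -> int:
        return int(round(self.rdf_max_um / self.rdf_bin_um))

    @classmethod
    def for_modality(cls, modality: str, **kwargs) -> "AnalysisConfig":
        width = 1 if modality == "imc" else 2
        kwargs.setdefault("membrane_width_px", width)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


@dataclass
class ContactRecord:
    """One reference cell's membrane split against one neighbor.

    ``contact_px``/``noncontact_px``/``membrane_px`` are ``(rows, cols)``
    integer arrays. Records are only emitted for true contacts, so
    ``contact_px`` is nonempty and a subset of ``membrane_px``;
    ``noncontact_px`` is disjoint from the union of same-type contacts.
    """

    ref_id: int
    neighbor_id: int
    neighbor_types: frozenset
    contact_px: tuple[np.ndarray, np.ndarray]
    noncontact_px: tuple[np.ndarray, np.ndarray]
    membrane_px: tuple[np.ndarray, np.ndarray]
    touches_border: bool = False
    no_noncontact: bool = False

    @property
    def n_contact(self) -> int:
        return len(self.contact_px[0])

    @property
    def n_noncontact(self) -> int:
        return len(self.noncontact_px[0])


@dataclass
class SynapseScore:
    """Synapse strength sigma for one contact and marker.

    ``sigma = log2(mean over contact / mean over noncontact)``; mode records
    whether the IMC noise fill-in or the zero rule fired.
    """

    ref_id: int
    neighbor_id: int
    marker: str
    sigma: float
    mode: str = "standard"  # standard | imc_noise_adjusted | zero_rule
    fillin_contact: bool = False
    fillin_noncontact: bool = False
    excluded: bool = False
    target_type: Optional[str] = None
    sample_id: Optional[str] = None
    region: str = "none"


@dataclass
class SampleSynapseSummary:
    sample_id: Optional[str]
    marker: str
    ref_type: str
    target_type: str
    region: str
    sigma_bar: float
    n_contacts: int
    null_sigma_bar: Optional[float] = None


@dataclass
class NoiseTerm:
    """Per-sample background level of a marker in non-reference cells."""

    sample_id: Optional[str]
    marker: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("noise term must be >= 0")


@dataclass
class CorrelationResult:
    sample_id: Optional[str]
    marker_a: str
    marker_b: str
    cell_type: str
    method: str  # cisa | pixelwise
    r: float
    n: int


@dataclass
class RDFResult:
    """Distance-binned target-cell density around reference cells.

    ``observed``/``expected`` are densities in cells per square micrometre,
    annulus-normalized but deliberately not divided by the overall density.
    """

    reference_type: str
    target_type: str
    region: str
    bin_edges_um: np.ndarray
    observed: np.ndarray
    expected: Optional[np.ndarray]
    n_ref: int

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


@dataclass
class DeltaCDFResult:
    sample_id: Optional[str]
    region: str
    target_type: str
    delta_cdf: float


@dataclass
class ThresholdModel:
    """Adaptive intensity thresholds with the induced class means."""

    channel: str
    thresholds: np.ndarray
    class_means: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = t
        self.class_means = np.asarray(self.class_means, dtype=float)
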