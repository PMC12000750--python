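"""Domain containers and file input/output.

The unit of image analysis is the :class:`ImageStack`: a 4-D voxel array
ordered ``(channel, z, y, x)`` together with its physical voxel size and a
map from channel *roles* (``nuclei``, ``actin``, ``nascent``, ...) to channel
indices. All micron/voxel conversions go through ``voxel_size`` so that the
anisotropy of confocal stacks (z step much larger than the pixel pitch) is
handled in exactly one place.

Stacks are stored as OME-TIFF (axis metadata honored on read); tables are
plain CSV with a header row, comma separator, ``.`` decimal, UTF-8.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ChannelCountMismatchError,
    ConfigError,
    InvalidMeasurementError,
    NonNumericPixelError,
)

#: channel roles understood by the analysis modules
VALID_ROLES = frozenset(
    {"nuclei", "actin", "nascent", "collagen1", "collagen2", "live", "dead"}
)

#: default confocal voxel geometry in μm, ordered (dz, dy, dx):
#: 20X 0.8NA acquisition at 0.42 μm/pixel with a 2 μm z step.
DEFAULT_VOXEL_SIZE = (2.0, 0.42, 0.42)


@dataclass
class ImageStack:
    """Multi-channel 3-D voxel volume with physical metadata.

    Parameters
    ----------
    voxels
        4-D non-negative intensity array indexed ``(channel, z, y, x)``.
    voxel_size
        Physical voxel edge lengths ``(dz, dy, dx)`` in μm, all > 0.
    channel_roles
        Map role → channel index. Roles must be drawn from
        :data:`VALID_ROLES`; no two roles may share an index.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4-D (channel, z, y, x); got {self.voxels.ndim}-D"
            )
        if self.voxels.dtype.kind not in "uif":
            raise NonNumericPixelError(
                f"non-numeric pixel type {self.voxels.dtype}"
            )
        if self.voxels.size and float(np.min(self.voxels)) < 0:
            raise ValueError("voxel intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats; got {self.voxel_size}")
        n = self.voxels.shape[0]
        seen: dict[int, str] = {}
        for role, idx in self.channel_roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if not (0 <= int(idx) < n):
                raise ChannelCountMismatchError(
                    f"role {role!r} maps to channel {idx} but stack has {n} channels"
                )
            if idx in seen:
                raise ValueError(
                    f"roles {seen[idx]!r} and {role!r} share channel {idx}"
                )
            seen[int(idx)] = role

    # -- convenience -----------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return the 3-D ``(z, y, x)`` view for a named role."""
        try:
            idx = self.channel_roles[role]
        except KeyError:
            from .errors import MissingChannelError

            raise MissingChannelError(role) from None
        return self.voxels[idx]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR reading: target Ct paired with the housekeeping-gene Ct."""

    ct_reference: float
    ct_target: float
    gene: str = ""

    def __post_init__(self):
        for name in ("ct_reference", "ct_target"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(
                    f"{name} must be finite and > 0; got {v}"
                )


def relative_expression(m: QpcrMeasurement) -> float:
    """Relative mRNA expression as fold change over the housekeeping gene.

    Computed as ``2 ** (Ct_reference − Ct_target)``: a target amplifying
    earlier (lower Ct) than the reference is more abundant, giving a fold
    change above 1. Always strictly positive.
    """
    return float(2.0 ** (m.ct_reference - m.ct_target))


def qpcr_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Vectorised relative expression over a Ct table.

    Expects columns ``gene``, ``ct_reference``, ``ct_target``; returns the
    same rows with a ``fold_change`` column appended.
    """
    out = ct.copy()
    folds = [
        relative_expression(
            QpcrMeasurement(row.ct_reference, row.ct_target, str(row.gene))
        )
        for row in ct.itertuples()
    ]
    out["fold_change"] = folds
    return out


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, serialisable to/from JSON.

    Image-analysis fields are in μm or voxel counts; mechanics fields follow
    the Hertz-fit conventions (window in μm of indentation, Poisson ratio
    dimensionless); secretome fields act on the cytokine tables.
    """

    # imagequant
    threshold_method: str = "otsu"           # or "fixed"
    fixed_thresholds: dict = field(default_factory=dict)  # role -> intensity
    min_nucleus_volume_um3: float = 50.0
    nucleus_min_separation_um: float = 5.0   # watershed seed separation
    crop_pad_um: float = 10.0                # per-cell crop margin
    detection_min_voxels: int = 5            # nascent floor for "negative"
    min_object_volume_um3: float = 20.0      # live/dead counting floor
    collagen_min_overlap_voxels: int = 10
    # mechanics
    poisson_ratio: float = 0.5
    fit_window_um: tuple[float, float] = (1.0, 4.0)
    contact_baseline_fraction: float = 0.2
    contact_k_sd: float = 5.0
    # secretome
    variance_threshold: float = 0.9
    excluded_analytes: tuple[str, ...] = ("IL-1 beta", "TNF alpha")
    # diffusion
    saturation_threshold: float = 0.95
    # shared
    random_seed: int = 0

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold_method {self.threshold_method!r}")
        if self.min_nucleus_volume_um3 < 0:
            raise ConfigError("min_nucleus_volume_um3 must be >= 0")
        if self.crop_pad_um < 0:
            raise ConfigError("crop_pad_um must be >= 0")
        if self.detection_min_voxels < 0:
            raise ConfigError("detection_min_voxels must be >= 0")
        if not (0.0 <= self.poisson_ratio <= 0.5 + 1e-12):
            raise ConfigError("poisson_ratio must lie in [0, 0.5]")
        lo, hi = self.fit_window_um
        if not (0 <= lo < hi):
            raise ConfigError("fit_window_um must satisfy 0 <= lo < hi")
        self.fit_window_um = (float(lo), float(hi))
        if not (0 < self.contact_baseline_fraction < 1):
            raise ConfigError("contact_baseline_fraction must lie in (0, 1)")
        if not (0 < self.saturation_threshold <= 1):
            raise ConfigError("saturation_threshold must lie in (0, 1]")
        self.excluded_analytes = tuple(self.excluded_analytes)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = json.loads(text)
        for key in ("fit_window_um", "excluded_analytes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_AXIS_ALIASES = str.maketrans({"S": "C", "I": "Z", "Q": "Z"})


def read_image_stack(
    path: str | Path,
    channel_roles: dict[str, int] | None = None,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> ImageStack:
    """Read a multi-channel TIFF into an :class:`ImageStack`.

    Axis metadata (OME or ImageJ) is honored when present and the volume is
    reordered to ``(channel, z, y, x)``; intensities are preserved bit-exact.

    Raises
    ------
    FileNotFoundError
        if the file does not exist.
    ChannelCountMismatchError
        if the declared roles reference more channels than the file holds.
    NonNumericPixelError
        for non-integer, non-float pixel types.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channel_roles = dict(channel_roles or {})
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = np.asarray(series.asarray())
        axes = (series.axes or "").upper().translate(_AXIS_ALIASES)
    if data.dtype.kind not in "uif":
        raise NonNumericPixelError(f"non-numeric pixel type {data.dtype}")
    if len(axes) != data.ndim or any(a not in "CZYX" for a in axes):
        # fall back to positional interpretation
        axes = "CZYX"[-data.ndim:] if data.ndim <= 4 else ""
        if not axes:
            raise ValueError(f"cannot interpret {data.ndim}-D TIFF")
    # insert missing axes as singletons, then transpose to CZYX
    for a in "CZYX":
        if a not in axes:
            data = data[np.newaxis]
            axes = a + axes
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)
    n_chan = data.shape[0]
    if len(channel_roles) > n_chan or any(
        idx >= n_chan for idx in channel_roles.values()
    ):
        raise ChannelCountMismatchError(
            f"{len(channel_roles)} roles declared (max index "
            f"{max(channel_roles.values(), default=0)}) but file has {n_chan} channels"
        )
    return ImageStack(voxels=data, voxel_size=voxel_size, channel_roles=channel_roles)


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as OME-TIFF with explicit CZYX axis metadata."""
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a table in the package's single CSV dialect (comma, UTF-8)."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, encoding="utf-8")
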