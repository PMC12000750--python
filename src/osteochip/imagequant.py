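"""3-D single-cell image quantification.

The workflow mirrors nuclei-seeded single-cell analysis of confocal
z-stacks of hydrogel-embedded cells:

1. **segment_nuclei** — threshold the nuclei channel (Otsu by default),
   clean morphologically, split touching nuclei by distance-transform
   watershed, and filter by minimum volume. The resulting labels are the
   *seeds* for everything downstream.
2. **assign_cell_territories** — seeded watershed on the inverted combined
   actin + nascent intensity landscape assigns every foreground voxel to
   exactly one seed, limited to a padded per-cell crop region.
3. **extracellular_mask** — per cell, subtract the actin (cell-body) mask
   from the nascent-protein mask; what remains is newly deposited
   *pericellular* matrix.
4. **classify_cell** — cells with no detectable nascent signal are
   *negative*; with signal but an empty subtraction, *restricted*
   (intracellular only); with extracellular voxels, *secreting*.

Volumes are voxel counts × physical voxel volume (μm³). Mean intensity per
mask is reported alongside, but classification and all volume statistics
use volumes only. Live/dead viability counting and per-image collagen
positivity follow the same threshold + connected-component conventions
(26-connectivity throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import (
    InvariantViolationError,
    MissingChannelError,
    ShapeMismatchError,
    UndefinedFractionError,
)
from .io import AnalysisConfig, ImageStack

logger = logging.getLogger(__name__)

CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabelVolume:
    """3-D integer label array aligned to a stack's spatial grid.

    0 is background; objects are labeled with the contiguous set 1..K.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if self.labels.dtype.kind not in "iu":
            raise ValueError("labels must be integer")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def centroids_um(self) -> np.ndarray:
        """(K, 3) centroids in μm, ordered by label."""
        k = self.n_objects
        if k == 0:
            return np.empty((0, 3))
        cents = ndi.center_of_mass(
            np.ones_like(self.labels, dtype=np.uint8),
            self.labels,
            index=np.arange(1, k + 1),
        )
        return np.asarray(cents) * np.asarray(self.voxel_size)


def _channel_threshold(
    channel: np.ndarray, method: str = "otsu", fixed: float | None = None
) -> float:
    """Resolve the binarisation threshold for one channel."""
    if fixed is not None or method == "fixed":
        if fixed is None:
            raise ValueError("threshold_method 'fixed' requires a fixed value")
        return float(fixed)
    lo, hi = float(channel.min()), float(channel.max())
    if lo == hi:  # constant channel: nothing to segment
        return float(np.inf)
    return float(threshold_otsu(np.asarray(channel)))


def segment_nuclei(
    stack: ImageStack,
    threshold: float | None = None,
    min_volume_um3: float = 50.0,
    min_separation_um: float = 5.0,
    clean: bool = True,
) -> LabelVolume:
    """Segment the nuclei channel into seed labels.

    Thresholds (Otsu unless ``threshold`` is given), optionally applies a
    light binary opening, splits merged blobs whose distance transform
    carries maxima farther apart than ``min_separation_um``, and removes
    objects below ``min_volume_um3``. Labels are relabeled contiguously.
    Deterministic for fixed input and parameters; an empty segmentation
    returns a zero-object volume with a logged warning.
    """
    nuclei = np.asarray(stack.channel("nuclei"))
    thr = _channel_threshold(nuclei, fixed=threshold)
    binary = nuclei > thr
    if clean and binary.any():
        # lateral-only opening: the coarse z step makes small nuclei only a
        # couple of slices thick, so a 3-D element would erode them away
        lateral = np.zeros((1, 3, 3), dtype=bool)
        lateral[0] = ndi.generate_binary_structure(2, 1)
        binary = ndi.binary_opening(binary, structure=lateral)
    if not binary.any():
        logger.warning("nuclei segmentation is empty")
        return LabelVolume(
            np.zeros(stack.spatial_shape, dtype=np.int32), stack.voxel_size
        )

    comp, n_comp = ndi.label(binary, structure=CONN26)
    dist = ndi.distance_transform_edt(binary, sampling=stack.voxel_size)

    # candidate peaks: strict-ish local maxima of the distance map
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (dist == ndi.maximum_filter(dist, footprint=footprint)) & binary
    coords = np.argwhere(local_max)
    values = dist[tuple(coords.T)]
    comp_of = comp[tuple(coords.T)]
    # deterministic order: value desc, then lexicographic position
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -values))
    vs = np.asarray(stack.voxel_size)

    markers = np.zeros_like(comp, dtype=np.int32)
    n_markers = 0
    accepted: dict[int, list[np.ndarray]] = {}
    for idx in order:
        c = coords[idx]
        lab = comp_of[idx]
        prev = accepted.setdefault(lab, [])
        c_um = c * vs
        if all(np.linalg.norm(c_um - q) >= min_separation_um for q in prev):
            prev.append(c_um)
            n_markers += 1
            markers[tuple(c)] = n_markers

    if n_markers > n_comp:
        labels = watershed(-dist, markers, mask=binary, connectivity=CONN26)
    else:
        labels = comp

    # minimum-volume filter + contiguous relabel
    voxvol = stack.voxel_volume
    min_vox = int(np.ceil(min_volume_um3 / voxvol))
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= max(min_vox, 1))
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    out = remap[labels]
    if keep.size == 0:
        logger.warning("nuclei segmentation is empty after volume filter")
    return LabelVolume(out, stack.voxel_size)


def assign_cell_territories(
    seeds: LabelVolume,
    stack: ImageStack,
    crop_pad_um: float = 10.0,
    actin_threshold: float | None = None,
    nascent_threshold: float | None = None,
) -> LabelVolume:
    """Assign every actin/nascent foreground voxel to exactly one seed.

    Seeded watershed on the inverted combined actin + nascent intensity
    landscape, restricted to the foreground (union of the two thresholded
    channels plus the seeds themselves). Each cell's assignment is limited
    to its seed bounding box padded by ``crop_pad_um``.
    """
    if seeds.n_objects < 1:
        raise ValueError("at least one seed required")
    actin = np.asarray(stack.channel("actin"), dtype=np.float64)
    nascent = np.asarray(stack.channel("nascent"), dtype=np.float64)
    if actin.shape != seeds.labels.shape:
        raise ShapeMismatchError("stack and seed grids differ")
    thr_a = _channel_threshold(actin, fixed=actin_threshold)
    thr_n = _channel_threshold(nascent, fixed=nascent_threshold)
    foreground = (actin > thr_a) | (nascent > thr_n) | (seeds.labels > 0)
    landscape = -(actin + nascent)
    labels = watershed(
        landscape, seeds.labels.astype(np.int32), mask=foreground,
        connectivity=CONN26,
    )
    # limit each territory to the padded seed crop
    pad_vox = [int(np.ceil(crop_pad_um / v)) for v in stack.voxel_size]
    objects = ndi.find_objects(seeds.labels)
    shape = labels.shape
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        padded = tuple(
            slice(max(0, s.start - p), min(shape[a], s.stop + p))
            for a, (s, p) in enumerate(zip(sl, pad_vox))
        )
        inside = np.zeros(shape, dtype=bool)
        inside[padded] = True
        labels[(labels == k) & ~inside] = 0
    return LabelVolume(labels.astype(np.int32), stack.voxel_size)


def extracellular_mask(nascent_mask: np.ndarray, actin_mask: np.ndarray) -> np.ndarray:
    """Subtract the cell-body (actin) mask from the nascent-protein mask.

    The result covers newly deposited extracellular matrix only: it is a
    subset of ``nascent_mask`` and disjoint from ``actin_mask``. An empty
    result means the cell's nascent protein is intracellularly restricted.
    """
    nascent_mask = np.asarray(nascent_mask, dtype=bool)
    actin_mask = np.asarray(actin_mask, dtype=bool)
    if nascent_mask.shape != actin_mask.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {nascent_mask.shape} vs {actin_mask.shape}"
        )
    return nascent_mask & ~actin_mask


def classify_cell(
    total_nascent_voxels: int, ecm_voxels: int, detection_min: int = 5
) -> str:
    """Three-way nascent-deposition phenotype.

    *negative* below the detection floor; *restricted* when all detectable
    nascent signal lies inside the cell body (empty subtraction);
    *secreting* when extracellular voxels remain.
    """
    if total_nascent_voxels < 0 or ecm_voxels < 0:
        raise ValueError("voxel counts must be >= 0")
    if ecm_voxels > total_nascent_voxels:
        raise InvariantViolationError(
            f"ECM voxels ({ecm_voxels}) exceed total nascent voxels "
            f"({total_nascent_voxels})"
        )
    if ecm_voxels > 0:
        return "secreting"
    if total_nascent_voxels >= detection_min:
        return "restricted"
    return "negative"


def quantify_stack(
    stack: ImageStack, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full single-cell quantification of one stack.

    Composes nuclei segmentation → territory assignment → per-cell crop →
    actin-mask subtraction → classification. Returns one row per retained
    cell (volumes in μm³, class label, border flag, collagen positivity
    when channels are present, mean intensities) plus a summary with class
    fractions (over all retained cells) and volume statistics (over cells
    not touching the lateral border, whose volumes would be truncated).
    """
    config = config or AnalysisConfig()
    fixed = config.fixed_thresholds if config.threshold_method == "fixed" else {}
    seeds = segment_nuclei(
        stack,
        threshold=fixed.get("nuclei"),
        min_volume_um3=config.min_nucleus_volume_um3,
        min_separation_um=config.nucleus_min_separation_um,
    )
    if seeds.n_objects == 0:
        return pd.DataFrame(), {"n_cells": 0, "class_fractions": {}}
    territories = assign_cell_territories(
        seeds,
        stack,
        crop_pad_um=config.crop_pad_um,
        actin_threshold=fixed.get("actin"),
        nascent_threshold=fixed.get("nascent"),
    )
    actin = np.asarray(stack.channel("actin"))
    nascent = np.asarray(stack.channel("nascent"))
    thr_a = _channel_threshold(actin, fixed=fixed.get("actin"))
    thr_n = _channel_threshold(nascent, fixed=fixed.get("nascent"))
    collagen = {}
    for role in ("collagen1", "collagen2"):
        if stack.has_role(role):
            ch = np.asarray(stack.channel(role))
            collagen[role] = (ch, _channel_threshold(ch, fixed=fixed.get(role)))

    voxvol = stack.voxel_volume
    centroids = seeds.centroids_um()
    objects = ndi.find_objects(territories.labels)
    ny, nx = stack.spatial_shape[1], stack.spatial_shape[2]
    rows = []
    for k in range(1, seeds.n_objects + 1):
        sl = objects[k - 1] if k - 1 < len(objects) else None
        if sl is None:  # seed with empty territory: nucleus only
            sl = ndi.find_objects(seeds.labels == k)[0]
        crop_terr = territories.labels[sl] == k
        nascent_mask = (nascent[sl] > thr_n) & crop_terr
        actin_mask = (actin[sl] > thr_a) & crop_terr
        ecm = extracellular_mask(nascent_mask, actin_mask)
        total_vox = int(nascent_mask.sum())
        ecm_vox = int(ecm.sum())
        label = classify_cell(total_vox, ecm_vox, config.detection_min_voxels)
        border = (
            sl[1].start == 0 or sl[1].stop == ny or sl[2].start == 0 or sl[2].stop == nx
        )
        row = {
            "cell_id": k,
            "centroid_z_um": centroids[k - 1][0],
            "centroid_y_um": centroids[k - 1][1],
            "centroid_x_um": centroids[k - 1][2],
            "bbox_z0": sl[0].start, "bbox_z1": sl[0].stop,
            "bbox_y0": sl[1].start, "bbox_y1": sl[1].stop,
            "bbox_x0": sl[2].start, "bbox_x1": sl[2].stop,
            "total_nascent_voxels": total_vox,
            "extracellular_nascent_voxels": ecm_vox,
            "total_nascent_volume_um3": total_vox * voxvol,
            "extracellular_nascent_volume_um3": ecm_vox * voxvol,
            "actin_volume_um3": float(actin_mask.sum()) * voxvol,
            "mean_nascent_intensity": float(nascent[sl][nascent_mask].mean())
            if total_vox else 0.0,
            "class_label": label,
            "border_touching": bool(border),
        }
        for role, (ch, thr_c) in collagen.items():
            n_pos = int(((ch[sl] > thr_c) & crop_terr).sum())
            row[f"{role}_positive"] = n_pos >= config.collagen_min_overlap_voxels
        rows.append(row)

    records = pd.DataFrame(rows)
    fractions = (
        records["class_label"].value_counts(normalize=True).to_dict()
    )
    interior = records[~records["border_touching"]]
    summary = {
        "n_cells": int(len(records)),
        "n_border_flagged": int(records["border_touching"].sum()),
        "class_fractions": {c: float(fractions.get(c, 0.0)) for c in
                            ("negative", "restricted", "secreting")},
        "total_nascent_volume_um3_mean": float(
            interior["total_nascent_volume_um3"].mean()
        ) if len(interior) else float("nan"),
        "extracellular_volume_um3_mean": float(
            interior["extracellular_nascent_volume_um3"].mean()
        ) if len(interior) else float("nan"),
    }
    for role in collagen:
        summary[f"{role}_positive_percent"] = float(
            100.0 * records[f"{role}_positive"].mean()
        )
    return records, summary


def collagen_positive_fraction(
    stack: ImageStack,
    nuclei: LabelVolume,
    role: str = "collagen1",
    threshold: float | None = None,
    min_overlap_voxels: int = 10,
) -> float:
    """Percent of segmented nuclei whose cell territory is collagen-positive.

    A cell is positive when its nearest-nucleus territory holds at least
    ``min_overlap_voxels`` voxels above the channel threshold. Returns
    100 × positives / nucleus count.
    """
    if not stack.has_role(role):
        raise MissingChannelError(role)
    n = nuclei.n_objects
    if n == 0:
        raise UndefinedFractionError("no nuclei segmented")
    ch = np.asarray(stack.channel(role))
    thr = _channel_threshold(ch, fixed=threshold)
    positive_vox = ch > thr
    # nearest-nucleus (Voronoi) territory assignment
    _, (iz, iy, ix) = ndi.distance_transform_edt(
        nuclei.labels == 0, sampling=nuclei.voxel_size, return_indices=True
    )
    territory = nuclei.labels[iz, iy, ix]
    counts = np.bincount(territory[positive_vox], minlength=n + 1)[1:]
    positives = int((counts >= min_overlap_voxels).sum())
    return 100.0 * positives / n


def quantify_viability(
    stack: ImageStack, config: AnalysisConfig | None = None
) -> tuple[float, dict]:
    """Percent viable cells from a calcein/ethidium two-channel image.

    Objects are counted per channel by threshold + 26-connected components
    with a minimum-volume filter. Objects positive in both channels (a
    compromised membrane admits ethidium) are counted once, as dead.
    Viability = 100 × live / (live + dead).
    """
    config = config or AnalysisConfig()
    fixed = config.fixed_thresholds if config.threshold_method == "fixed" else {}
    masks = {}
    for role in ("live", "dead"):
        ch = np.asarray(stack.channel(role))
        thr = _channel_threshold(ch, fixed=fixed.get(role))
        masks[role] = ch > thr
    min_vox = max(1, int(np.ceil(config.min_object_volume_um3 / stack.voxel_volume)))
    live_labels, n_live_raw = ndi.label(masks["live"], structure=CONN26)
    dead_labels, n_dead_raw = ndi.label(masks["dead"], structure=CONN26)
    live_counts = np.bincount(live_labels.ravel(), minlength=n_live_raw + 1)[1:]
    dead_counts = np.bincount(dead_labels.ravel(), minlength=n_dead_raw + 1)[1:]
    live_keep = np.flatnonzero(live_counts >= min_vox) + 1
    dead_keep = np.flatnonzero(dead_counts >= min_vox) + 1
    # live objects overlapping the dead mask are double-positive -> dead
    overlap = np.bincount(
        live_labels[masks["dead"]].ravel(), minlength=n_live_raw + 1
    )[1:]
    double_pos = np.flatnonzero(overlap > 0) + 1
    n_live = int(len(np.setdiff1d(live_keep, double_pos)))
    n_dead = int(len(dead_keep))
    total = n_live + n_dead
    if total == 0:
        raise UndefinedFractionError("no stained cells counted")
    percent = 100.0 * n_live / total
    return percent, {
        "live": n_live,
        "dead": n_dead,
        "double_positive": int(len(np.intersect1d(live_keep, double_pos))),
        "total": total,
    }
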