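"""Ground-truthed synthetic inputs for every pipeline stage.

Four input families are emulated, mirroring the statistical structure the
analyses assume:

* **3-D cell stacks** — chondrocyte-like cells as geometric idealizations:
  an ellipsoidal nucleus, a filled actin cell body around it, and nascent-
  protein signal that is absent (*negative*), intracellular only
  (*restricted*) or intracellular plus a pericellular shell (*secreting*).
  Ground truth (class, centroid, volumes) is computed from the noiseless
  masks, never from the noisy rendering.
* **Hertzian indentation curves** — forward evaluation of the sphere-on-
  half-space contact law with a pre-contact baseline, contact offset and
  additive Gaussian load noise.
* **Cytokine tables** — a full-factorial design (sex × condition ×
  compartment × day × replicates) with log-normal analyte values,
  multiplicative condition/compartment effects, spiked inflammatory
  analytes, and missing-completely-at-random gaps.
* **Diffusion series** — 1-D two-source erfc fronts across a chamber strip
  flanked by constant-concentration perfusion channels.

Every generator is a pure function of its parameters and seed: same seed +
params gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import DiffusionSeries, two_source_profile
from .errors import GeometryInfeasibleError, InvalidDesignError
from .io import DEFAULT_VOXEL_SIZE, ImageStack
from .mechanics import IndentationCurve, hertz_force
from .secretome import DEFAULT_PANEL, CytokineTable

CLASS_NAMES = ("negative", "restricted", "secreting")


# ---------------------------------------------------------------------------
# 3-D cell stacks
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeParams:
    """Geometry, intensities and noise of the simulated cell stack.

    Fractions order matches :data:`CLASS_NAMES`:
    (negative, restricted, secreting). Radii/thicknesses in μm; intensities
    in arbitrary units on a dark (zero) background. Gaussian read noise is
    applied last; ``noise_poisson_scale > 0`` additionally replaces each
    voxel by a scaled Poisson draw (shot noise).
    """

    n_cells: int = 100
    fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    nucleus_radius_um: tuple[float, float] = (4.0, 0.4)   # mean, sd
    actin_thickness_um: float = 2.0
    peri_thickness_um: float = 2.0
    nucleus_intensity: float = 200.0
    actin_intensity: float = 180.0
    nascent_intensity: float = 150.0
    peri_intensity: float = 150.0
    collagen1_positive_fraction: float = 0.0
    collagen2_positive_fraction: float = 0.0
    collagen_intensity: float = 150.0
    noise_gaussian_sd: float = 3.0
    noise_poisson_scale: float = 0.0
    shape: tuple[int, int, int] = (40, 512, 512)          # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    placement_margin_um: float = 2.0
    max_placement_attempts: int = 20000

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.min() < 0 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.nucleus_radius_um[0] <= 0:
            raise ValueError("nucleus radius must be > 0")
        if self.actin_thickness_um <= 0 or self.peri_thickness_um <= 0:
            raise ValueError("shell thicknesses must be > 0")


def _ellipsoid_mask(shape, voxel_size, center_um, semiaxes_um):
    """Boolean mask of an axis-aligned ellipsoid, on a local bounding box.

    Returns ``(slices, mask)`` where ``slices`` index the full volume.
    Voxel centers sit at ``index * voxel_size``.
    """
    lo_idx, hi_idx, coords = [], [], []
    for ax in range(3):
        vs = voxel_size[ax]
        lo = max(0, int(np.floor((center_um[ax] - semiaxes_um[ax]) / vs)) - 1)
        hi = min(shape[ax], int(np.ceil((center_um[ax] + semiaxes_um[ax]) / vs)) + 2)
        lo_idx.append(lo)
        hi_idx.append(hi)
        coords.append((np.arange(lo, hi) * vs - center_um[ax]) / semiaxes_um[ax])
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    mask = zz**2 + yy**2 + xx**2 <= 1.0
    slices = tuple(slice(lo, hi) for lo, hi in zip(lo_idx, hi_idx))
    return slices, mask


def generate_cell_stack(
    params: PhenotypeParams, seed: int
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a ground-truthed multi-channel stack.

    Channels: nuclei, actin, nascent (+ collagen1/collagen2 when their
    positive fractions are > 0). Cells are placed by rejection sampling so
    that rendered extents never overlap and never touch the stack border;
    placement failure after the attempt budget raises
    :class:`GeometryInfeasibleError`.

    Returns the stack and a ground-truth table with one row per cell:
    ``cell_id, centroid_z/y/x_um, class_label, total_nascent_volume_um3,
    extracellular_nascent_volume_um3, total_nascent_voxels,
    extracellular_nascent_voxels, actin_voxels, nucleus_voxels,
    collagen1_positive, collagen2_positive``.
    """
    p = params
    rng = np.random.default_rng(seed)
    dz, dy, dx = p.voxel_size
    size_um = (p.shape[0] * dz, p.shape[1] * dy, p.shape[2] * dx)
    voxvol = dz * dy * dx

    # per-cell phenotype draws (one multinomial-equivalent draw per cell)
    classes = rng.choice(3, size=p.n_cells, p=np.asarray(p.fractions))
    radii = np.clip(
        rng.normal(p.nucleus_radius_um[0], p.nucleus_radius_um[1], p.n_cells),
        0.5 * p.nucleus_radius_um[0],
        1.5 * p.nucleus_radius_um[0] + 3 * p.nucleus_radius_um[1],
    )
    coll1 = rng.random(p.n_cells) < p.collagen1_positive_fraction
    coll2 = rng.random(p.n_cells) < p.collagen2_positive_fraction

    # slight fixed anisotropy so nuclei are ellipsoids, not spheres
    axis_ratio = np.array([0.85, 1.0, 1.1])
    outer = p.actin_thickness_um + p.peri_thickness_um

    centers: list[np.ndarray] = []
    extents: list[np.ndarray] = []
    attempts = 0
    for i in range(p.n_cells):
        ext = radii[i] * axis_ratio + outer  # outermost rendered semi-axes
        placed = False
        while attempts < p.max_placement_attempts:
            attempts += 1
            c = np.array(
                [
                    rng.uniform(ext[a] + p.placement_margin_um,
                                size_um[a] - ext[a] - p.placement_margin_um)
                    for a in range(3)
                ]
            )
            ok = True
            for cj, ej in zip(centers, extents):
                d = (c - cj) / (ext + ej)
                if float(d @ d) < 1.15**2:  # 15% safety gap
                    ok = False
                    break
            if ok:
                centers.append(c)
                extents.append(ext)
                placed = True
                break
        if not placed:
            raise GeometryInfeasibleError(
                f"placed {i} of {p.n_cells} cells in {attempts} attempts"
            )

    roles = {"nuclei": 0, "actin": 1, "nascent": 2}
    if p.collagen1_positive_fraction > 0:
        roles["collagen1"] = len(roles)
    if p.collagen2_positive_fraction > 0:
        roles["collagen2"] = len(roles)
    vol = np.zeros((len(roles),) + p.shape, dtype=np.float32)

    records = []
    for i, (c, r) in enumerate(zip(centers, radii)):
        nuc_ax = r * axis_ratio
        body_ax = nuc_ax + p.actin_thickness_um
        peri_ax = body_ax + p.peri_thickness_um

        sl_n, m_nuc = _ellipsoid_mask(p.shape, p.voxel_size, c, nuc_ax)
        sl_b, m_body = _ellipsoid_mask(p.shape, p.voxel_size, c, body_ax)
        sl_p, m_peri_outer = _ellipsoid_mask(p.shape, p.voxel_size, c, peri_ax)

        vol[roles["nuclei"]][sl_n][m_nuc] = p.nucleus_intensity
        vol[roles["actin"]][sl_b][m_body] = p.actin_intensity

        # cytoplasmic (intracellular, non-nuclear) region on the body grid
        m_cyto = m_body.copy()
        # embed nucleus mask into body bounding box
        off = [sl_n[a].start - sl_b[a].start for a in range(3)]
        m_cyto[
            off[0]: off[0] + m_nuc.shape[0],
            off[1]: off[1] + m_nuc.shape[1],
            off[2]: off[2] + m_nuc.shape[2],
        ] &= ~m_nuc

        label = CLASS_NAMES[classes[i]]
        n_intra = n_peri = 0
        if label in ("restricted", "secreting"):
            vol[roles["nascent"]][sl_b][m_cyto] = p.nascent_intensity
            n_intra = int(m_cyto.sum())
        if label == "secreting":
            m_shell = m_peri_outer.copy()
            offb = [sl_b[a].start - sl_p[a].start for a in range(3)]
            m_shell[
                offb[0]: offb[0] + m_body.shape[0],
                offb[1]: offb[1] + m_body.shape[1],
                offb[2]: offb[2] + m_body.shape[2],
            ] &= ~m_body
            vol[roles["nascent"]][sl_p][m_shell] = p.peri_intensity
            n_peri = int(m_shell.sum())
        if coll1[i] and "collagen1" in roles:
            vol[roles["collagen1"]][sl_b][m_body] = p.collagen_intensity
        if coll2[i] and "collagen2" in roles:
            vol[roles["collagen2"]][sl_b][m_body] = p.collagen_intensity

        # centroid of the noiseless nucleus mask, in μm
        idz, idy, idx_ = np.nonzero(m_nuc)
        centroid = (
            (idz.mean() + sl_n[0].start) * dz,
            (idy.mean() + sl_n[1].start) * dy,
            (idx_.mean() + sl_n[2].start) * dx,
        )
        records.append(
            {
                "cell_id": i,
                "centroid_z_um": centroid[0],
                "centroid_y_um": centroid[1],
                "centroid_x_um": centroid[2],
                "class_label": label,
                "total_nascent_voxels": n_intra + n_peri,
                "extracellular_nascent_voxels": n_peri,
                "total_nascent_volume_um3": (n_intra + n_peri) * voxvol,
                "extracellular_nascent_volume_um3": n_peri * voxvol,
                "actin_voxels": int(m_body.sum()),
                "nucleus_voxels": int(m_nuc.sum()),
                "collagen1_positive": bool(coll1[i]),
                "collagen2_positive": bool(coll2[i]),
            }
        )

    if p.noise_poisson_scale > 0:
        vol = rng.poisson(vol * p.noise_poisson_scale).astype(np.float32)
        vol /= p.noise_poisson_scale
    if p.noise_gaussian_sd > 0:
        vol = vol + p.noise_gaussian_sd * rng.standard_normal(
            vol.shape, dtype=np.float32
        )
    vol = np.clip(vol, 0.0, None)

    stack = ImageStack(voxels=vol, voxel_size=p.voxel_size, channel_roles=roles)
    return stack, pd.DataFrame(records)


def generate_viability_stack(
    n_cells: int = 300,
    live_fraction: float = 0.9,
    cell_radius_um: float = 3.0,
    shape: tuple[int, int, int] = (6, 600, 600),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    intensity: float = 200.0,
    noise_gaussian_sd: float = 3.0,
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a two-channel live/dead stack with known viability.

    Calcein-positive (live) and ethidium-positive (dead) cells are rendered
    as small non-overlapping ellipsoids in their respective channels.
    Returns the stack and a per-cell ground-truth table with a ``live``
    column.
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel_size
    size_um = (shape[0] * dz, shape[1] * dy, shape[2] * dx)
    live = rng.random(n_cells) < live_fraction
    axes = cell_radius_um * np.array([0.8, 1.0, 1.0])
    centers: list[np.ndarray] = []
    attempts, budget = 0, 100 * n_cells
    for i in range(n_cells):
        placed = False
        while attempts < budget:
            attempts += 1
            c = np.array(
                [
                    rng.uniform(axes[a] + 1.0, size_um[a] - axes[a] - 1.0)
                    if size_um[a] - 2 * (axes[a] + 1.0) > 0
                    else size_um[a] / 2.0
                    for a in range(3)
                ]
            )
            if all(
                float(((c - cj) / (2 * axes)) @ ((c - cj) / (2 * axes))) >= 1.3
                for cj in centers
            ):
                centers.append(c)
                placed = True
                break
        if not placed:
            raise GeometryInfeasibleError(f"placed {i} of {n_cells} cells")
    vol = np.zeros((2,) + shape, dtype=np.float32)
    rows = []
    for i, c in enumerate(centers):
        sl, m = _ellipsoid_mask(shape, voxel_size, c, axes)
        vol[0 if live[i] else 1][sl][m] = intensity
        rows.append(
            {"cell_id": i, "live": bool(live[i]),
             "centroid_z_um": c[0], "centroid_y_um": c[1], "centroid_x_um": c[2]}
        )
    if noise_gaussian_sd > 0:
        vol = np.clip(
            vol + rng.normal(0.0, noise_gaussian_sd, vol.shape).astype(np.float32),
            0.0,
            None,
        )
    stack = ImageStack(
        voxels=vol, voxel_size=voxel_size, channel_roles={"live": 0, "dead": 1}
    )
    return stack, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Indentation curves
# ---------------------------------------------------------------------------

@dataclass
class CurveParams:
    """Forward-model parameters for one synthetic indentation curve.

    Defaults follow a soft-hydrogel nanoindentation setup: spherical tip of
    radius 25 μm on a ~0.5 N/m cantilever, incompressible gel (ν = 0.5).
    Cantilever compliance is ignored: the abscissa is taken as indentation
    directly, with compliance handled upstream by the instrument.
    """

    youngs_modulus_pa: float = 15e3
    poisson_ratio: float = 0.5
    tip_radius_um: float = 25.0
    cantilever_stiffness_n_per_m: float = 0.5
    contact_offset_um: float = 2.0
    max_indentation_um: float = 5.0
    step_um: float = 0.01
    noise_sd_n: float = 0.0
    position: tuple[float, float] | None = None

    def __post_init__(self):
        if self.youngs_modulus_pa <= 0:
            raise ValueError("E must be > 0")
        if not (0 <= self.poisson_ratio < 0.5 + 1e-12):
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.tip_radius_um <= 0:
            raise ValueError("tip radius must be > 0")
        if self.max_indentation_um <= 0 or self.step_um <= 0:
            raise ValueError("max indentation and step must be > 0")
        if self.contact_offset_um < 0:
            raise ValueError("contact offset must be >= 0")


def generate_indentation_curve(params: CurveParams, seed: int = 0) -> IndentationCurve:
    """Sample a load–indentation curve from the Hertz forward model.

    The abscissa runs from a pre-contact baseline through
    ``contact_offset + max_indentation``; the load is zero before contact,
    Hertzian after, with additive Gaussian noise of sd ``noise_sd_n``.
    The true parameters are carried in ``curve.truth`` for test use only.
    """
    p = params
    rng = np.random.default_rng(seed)
    baseline_um = max(1.0, p.contact_offset_um)
    start = p.contact_offset_um - baseline_um
    stop = p.contact_offset_um + p.max_indentation_um
    pos = np.arange(start, stop + p.step_um / 2, p.step_um)
    load = hertz_force(
        pos - p.contact_offset_um, p.youngs_modulus_pa, p.poisson_ratio, p.tip_radius_um
    )
    if p.noise_sd_n > 0:
        load = load + rng.normal(0.0, p.noise_sd_n, load.shape)
    return IndentationCurve(
        indentation=pos,
        load=load,
        tip_radius_um=p.tip_radius_um,
        cantilever_stiffness_n_per_m=p.cantilever_stiffness_n_per_m,
        position=p.position,
        truth={
            "youngs_modulus_pa": p.youngs_modulus_pa,
            "poisson_ratio": p.poisson_ratio,
            "contact_offset_um": p.contact_offset_um,
        },
    )


def generate_curve_grid(
    moduli_pa: np.ndarray,
    grid_shape: tuple[int, int],
    spacing_um: float = 50.0,
    noise_fraction: float = 0.01,
    seed: int = 0,
    **curve_kwargs,
) -> list[IndentationCurve]:
    """A matrix scan: one curve per grid site with per-site true modulus.

    ``moduli_pa`` must have ``grid_shape`` entries (row-major). Noise sd is
    ``noise_fraction`` × the site's maximum Hertzian load.
    """
    moduli = np.asarray(moduli_pa, dtype=float).reshape(grid_shape)
    rng = np.random.default_rng(seed)
    curves = []
    for iy in range(grid_shape[0]):
        for ix in range(grid_shape[1]):
            p = CurveParams(
                youngs_modulus_pa=float(moduli[iy, ix]),
                position=(ix * spacing_um, iy * spacing_um),
                **curve_kwargs,
            )
            fmax = hertz_force(
                p.max_indentation_um, p.youngs_modulus_pa, p.poisson_ratio,
                p.tip_radius_um,
            )
            p.noise_sd_n = noise_fraction * fmax
            curves.append(
                generate_indentation_curve(p, seed=int(rng.integers(2**31)))
            )
    return curves


# ---------------------------------------------------------------------------
# Cytokine tables
# ---------------------------------------------------------------------------

@dataclass
class CytokineDesign:
    """Full-factorial sampling design of the conditioned-medium collection."""

    sexes: tuple[str, ...] = ("female", "male")
    conditions: tuple[str, ...] = ("baseline", "inflamed")
    compartments: tuple[str, ...] = ("osteoblast", "chondrocyte")
    days: tuple[int, ...] = (3, 7)
    replicates: int = 3

    def __post_init__(self):
        if self.replicates < 1:
            raise InvalidDesignError("replicates must be >= 1")
        for name in ("sexes", "conditions", "compartments", "days"):
            if len(getattr(self, name)) == 0:
                raise InvalidDesignError(f"{name} must have at least one level")

    @property
    def n_samples(self) -> int:
        return (
            len(self.sexes) * len(self.conditions) * len(self.compartments)
            * len(self.days) * self.replicates
        )


#: default multiplicative effects emulating an inflammatory stimulation:
#: strongly induced IL-6/IL-8, the chemokines MCP-1/MIP-1α/MIP-1β forming a
#: correlated inflammation block, compartment-skewed IL-6/IL-8 secretion,
#: and the two spiked analytes elevated wherever the stimulus was added.
DEFAULT_EFFECTS: dict = {
    "IL-6": {"condition": {"inflamed": 12.0}, "compartment": {"osteoblast": 1.8}},
    "IL-8": {"condition": {"inflamed": 9.0}, "compartment": {"osteoblast": 1.6}},
    "MCP-1": {"condition": {"inflamed": 5.0}},
    "MIP-1 alpha": {"condition": {"inflamed": 4.0}},
    "MIP-1 beta": {"condition": {"inflamed": 4.0}},
    "GM-CSF": {"condition": {"inflamed": 3.0}},
    "IFN gamma": {"condition": {"inflamed": 2.5}},
    "IP-10": {"condition": {"inflamed": 3.5}},
    "ICAM-1": {"condition": {"inflamed": 2.0}},
    "IL-10": {"condition": {"inflamed": 2.0}},
    "IL-1 beta": {"condition": {"inflamed": 30.0}},
    "TNF alpha": {"condition": {"inflamed": 30.0}},
}


def generate_cytokine_table(
    design: CytokineDesign | None = None,
    effects: dict | None = None,
    analytes: tuple[str, ...] = DEFAULT_PANEL,
    baseline_level: float = 50.0,
    lognormal_sigma: float = 0.4,
    missing_fraction: float = 0.02,
    mode: str = "concentration",
    seed: int = 0,
) -> CytokineTable:
    """Generate a structured samples × analytes table.

    One row per (sex × condition × compartment × day × replicate) cell.
    Analyte values are log-normal around per-analyte baselines (geometric
    spread around ``baseline_level``), multiplied by the declared
    ``effects`` — a map ``analyte -> {factor -> {level -> multiplier}}``
    over the factors ``condition``, ``compartment``, ``sex``, ``day``.
    A ``missing_fraction`` of entries is blanked completely at random.
    """
    design = design or CytokineDesign()
    effects = DEFAULT_EFFECTS if effects is None else effects
    for analyte in effects:
        if analyte not in analytes:
            raise InvalidDesignError(f"effect references unknown analyte {analyte!r}")
    rng = np.random.default_rng(seed)
    # deterministic per-analyte baselines spanning ~1.5 decades
    baselines = baseline_level * 10 ** np.linspace(-0.75, 0.75, len(analytes))

    meta_rows = []
    for sex in design.sexes:
        for condition in design.conditions:
            for compartment in design.compartments:
                for day in design.days:
                    for rep in range(1, design.replicates + 1):
                        meta_rows.append(
                            {
                                "sample_id": f"{sex[0]}_{condition}_{compartment}"
                                             f"_d{day}_r{rep}",
                                "sex": sex,
                                "condition": condition,
                                "compartment": compartment,
                                "day": day,
                                "replicate": rep,
                            }
                        )
    meta = pd.DataFrame(meta_rows)
    n = len(meta)

    values = np.empty((n, len(analytes)))
    for j, analyte in enumerate(analytes):
        mult = np.ones(n)
        for factor, levels in effects.get(analyte, {}).items():
            col = meta[factor].astype(str)
            for level, m in levels.items():
                mult *= np.where(col == str(level), float(m), 1.0)
        values[:, j] = baselines[j] * mult * rng.lognormal(0.0, lognormal_sigma, n)
    if missing_fraction > 0:
        gaps = rng.random(values.shape) < missing_fraction
        values[gaps] = np.nan
    if mode == "MFI":
        values = values * 80.0  # arbitrary fluorescence scale
    return CytokineTable(
        values=pd.DataFrame(values, columns=list(analytes)),
        sample_meta=meta,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Diffusion series
# ---------------------------------------------------------------------------

@dataclass
class ChamberGeometry:
    """Transverse strip through the chip: channel | chamber | channel."""

    chamber_width_um: float = 1200.0
    channel_width_um: float = 250.0
    pixel_size_um: float = 5.0
    strip_height_px: int = 32


def generate_diffusion_series(
    diffusivity_um2_s: float = 100.0,
    geometry: ChamberGeometry | None = None,
    times_min: np.ndarray | None = None,
    source_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DiffusionSeries:
    """Simulate time-lapse frames of fluorophore diffusion into the chamber.

    Both flanking channels are constant-concentration sources; the chamber
    concentration follows the two-source erfc superposition, clipped to
    [0, source level]. Default sampling is every 15 min for 150 min.
    Optional Gaussian intensity noise is added per pixel (clipped at 0).
    """
    if diffusivity_um2_s <= 0:
        raise ValueError("diffusivity must be > 0")
    geometry = geometry or ChamberGeometry()
    if times_min is None:
        times_min = np.arange(0.0, 151.0, 15.0)
    times_min = np.asarray(times_min, dtype=float)
    if np.any(np.diff(times_min) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    g = geometry
    n_chan = int(round(g.channel_width_um / g.pixel_size_um))
    n_chamber = int(round(g.chamber_width_um / g.pixel_size_um)) + 1
    x_chamber = np.arange(n_chamber) * g.pixel_size_um
    frames = []
    for t in times_min:
        profile = two_source_profile(
            x_chamber, t * 60.0, diffusivity_um2_s, g.chamber_width_um, source_level
        )
        row = np.concatenate(
            [np.full(n_chan, source_level), profile, np.full(n_chan, source_level)]
        )
        frame = np.tile(row, (g.strip_height_px, 1))
        if noise_sd > 0:
            frame = np.clip(frame + rng.normal(0.0, noise_sd, frame.shape), 0.0, None)
        frames.append(frame.astype(np.float64))
    mid_row = g.strip_height_px / 2.0
    line = ((mid_row, float(n_chan)), (mid_row, float(n_chan + n_chamber - 1)))
    return DiffusionSeries(
        frames=frames,
        times_min=times_min,
        pixel_size_um=g.pixel_size_um,
        profile_line=line,
        profile_width_px=1,
        source_level=source_level,
        truth={
            "diffusivity_um2_s": diffusivity_um2_s,
            "chamber_width_um": g.chamber_width_um,
        },
    )
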