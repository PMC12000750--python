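"""Nanoindentation analysis via the Hertz contact model.

A spherical probe of radius :math:`R` indenting an elastic half-space obeys

.. math:: F(\\delta) = \\frac{4}{3}\\,\\frac{E}{1-\\nu^2}\\,\\sqrt{R}\\,\\delta^{3/2}

with Young's modulus :math:`E`, Poisson ratio :math:`\\nu` and indentation
depth :math:`\\delta \\ge 0`. Because the model is linear in :math:`E`, the
fit over a fixed indentation window (default 1–4 μm, matching soft-hydrogel
practice where the shallowest microns are surface-artifact prone and deeper
indentation violates the half-space assumption) reduces to closed-form
linear least squares of load against :math:`\\delta^{3/2}` — deterministic,
with no initialization choices.

Contact-point detection re-zeroes the indentation axis before fitting:
the pre-contact baseline (first 20% of samples by default) sets a robust
band, and contact is the first sustained load excursion above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ContactNotFoundError,
    FitFailureError,
    InsufficientRangeError,
    UndefinedSummaryError,
)


def hertz_force(
    delta_um: np.ndarray | float,
    youngs_modulus_pa: float,
    poisson_ratio: float,
    tip_radius_um: float,
) -> np.ndarray | float:
    """Forward Hertz law. Indentation in μm, force in N; F = 0 before contact."""
    delta_m = np.maximum(np.asarray(delta_um, dtype=float), 0.0) * 1e-6
    r_m = tip_radius_um * 1e-6
    pref = (4.0 / 3.0) * youngs_modulus_pa / (1.0 - poisson_ratio**2) * np.sqrt(r_m)
    out = pref * delta_m**1.5
    return float(out) if np.isscalar(delta_um) else out


@dataclass
class IndentationCurve:
    """One load–indentation record with probe metadata.

    ``indentation`` is the raw probe displacement axis in μm (contact point
    not necessarily at zero); ``load`` is in newtons. ``truth`` carries the
    generating parameters for synthetic curves and is used by tests only.
    """

    indentation: np.ndarray
    load: np.ndarray
    tip_radius_um: float = 25.0
    cantilever_stiffness_n_per_m: float = 0.5
    position: tuple[float, float] | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if self.indentation.shape != self.load.shape:
            raise ValueError("indentation and load must have equal length")
        if self.indentation.size < 10:
            raise ValueError("curve must hold at least 10 samples")
        if self.tip_radius_um <= 0:
            raise ValueError("tip_radius_um must be > 0")

    def rezeroed(self, offset_um: float) -> "IndentationCurve":
        """Return a copy with the contact point shifted to indentation 0."""
        return IndentationCurve(
            indentation=self.indentation - offset_um,
            load=self.load,
            tip_radius_um=self.tip_radius_um,
            cantilever_stiffness_n_per_m=self.cantilever_stiffness_n_per_m,
            position=self.position,
            truth=dict(self.truth),
        )


def detect_contact_point(
    curve: IndentationCurve,
    baseline_fraction: float = 0.2,
    k_sd: float = 5.0,
) -> float:
    """Locate the contact point from the pre-contact baseline.

    The first ``baseline_fraction`` of samples estimates the baseline load
    (median) and its spread (median absolute deviation scaled to an sd, with
    a floor of 1e-4 × the load range so that noiseless curves do not produce
    a zero-width band). Contact is the first sample whose load exceeds
    baseline + ``k_sd``·sd and stays above it for the following two samples.

    The coarse crossing is then refined to sub-step precision by exploiting
    the Hertz exponent: beyond contact, (F − baseline)^{2/3} is linear in
    position, so a straight-line fit over the early contact region (loads
    between 5% and 50% of the maximum excursion) extrapolates back to the
    true contact abscissa. The refinement falls back to the coarse crossing
    whenever the regression is degenerate.

    Returns the indentation-axis offset in μm such that subtracting it puts
    contact at zero.
    """
    load = curve.load
    pos = curve.indentation
    n_base = max(3, int(round(baseline_fraction * load.size)))
    base = load[:n_base]
    center = float(np.median(base))
    sd = 1.4826 * float(np.median(np.abs(base - center)))
    load_range = float(np.max(load) - np.min(load))
    sd = max(sd, 1e-4 * load_range, 1e-15)
    threshold = center + k_sd * sd
    above = load > threshold
    # sustained crossing: sample and its next two neighbours all above
    sustained = above.copy()
    sustained[:-1] &= above[1:]
    sustained[:-2] &= above[2:]
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        raise ContactNotFoundError("no sustained load excursion above baseline")
    coarse = float(pos[idx[0]])

    # sub-step refinement via the linearized Hertz law
    excursion = load - center
    fmax = float(excursion.max())
    sel = (excursion >= 0.05 * fmax) & (excursion <= 0.5 * fmax)
    sel &= np.arange(load.size) >= idx[0]
    if np.count_nonzero(sel) >= 5:
        x = pos[sel]
        y = excursion[sel] ** (2.0 / 3.0)
        slope, intercept = np.polyfit(x, y, 1)
        if slope > 0:
            x0 = float(-intercept / slope)
            if pos[0] <= x0 <= coarse + (pos[1] - pos[0]):
                return x0
    return coarse


def hertz_fit(
    curve: IndentationCurve,
    poisson_ratio: float = 0.5,
    window_um: tuple[float, float] = (1.0, 4.0),
) -> tuple[float, float]:
    """Fit Young's modulus over the stated indentation window.

    The curve must already be re-zeroed (contact at indentation 0). Load is
    regressed against δ^{3/2} (through the origin, closed form) over samples
    with δ inside ``window_um``; E follows from the Hertz prefactor.

    Returns ``(E_pa, residual)`` with residual the RMS load misfit in N.

    Raises
    ------
    InsufficientRangeError
        if the re-zeroed curve does not span the window.
    FitFailureError
        if the fitted modulus is not a positive finite number.
    """
    lo, hi = window_um
    if not 0 <= lo < hi:
        raise ValueError("window must satisfy 0 <= lo < hi")
    if not 0 <= poisson_ratio <= 0.5 + 1e-12:
        raise ValueError("poisson_ratio must lie in [0, 0.5]")
    delta = curve.indentation
    if delta.max() < hi or delta.min() > lo:
        raise InsufficientRangeError(
            f"curve spans [{delta.min():.3g}, {delta.max():.3g}] μm; "
            f"window [{lo}, {hi}] μm not covered"
        )
    sel = (delta >= lo) & (delta <= hi)
    if np.count_nonzero(sel) < 3:
        raise InsufficientRangeError("fewer than 3 samples inside the fit window")
    x = (delta[sel] * 1e-6) ** 1.5
    y = curve.load[sel]
    slope = float(np.dot(x, y) / np.dot(x, x))
    r_m = curve.tip_radius_um * 1e-6
    e_pa = slope * (1.0 - poisson_ratio**2) * 3.0 / (4.0 * np.sqrt(r_m))
    if not np.isfinite(e_pa) or e_pa <= 0:
        raise FitFailureError(f"fitted modulus {e_pa!r} is not positive")
    residual = float(np.sqrt(np.mean((slope * x - y) ** 2)))
    return e_pa, residual


@dataclass
class ElasticityMap:
    """Spatial grid of fitted Young's moduli.

    ``entries`` is a DataFrame with columns ``position_x``, ``position_y``
    (μm), ``youngs_modulus_pa``, ``residual``, ``accepted`` and ``note``.
    Failed curves are flagged not-accepted, never dropped.
    """

    entries: pd.DataFrame
    compartment: str | None = None

    def accepted(self) -> pd.DataFrame:
        return self.entries[self.entries["accepted"]]


def fit_array(
    curves: list[IndentationCurve],
    poisson_ratio: float = 0.5,
    window_um: tuple[float, float] = (1.0, 4.0),
    baseline_fraction: float = 0.2,
    k_sd: float = 5.0,
    compartment: str | None = None,
) -> ElasticityMap:
    """Contact-detect and Hertz-fit every curve of a matrix scan.

    Per-curve failures (no contact, insufficient range, bad fit) mark the
    entry ``accepted=False`` with the error recorded in ``note``; the map
    always has one entry per input curve, in input order.
    """
    if len(curves) == 0:
        raise ValueError("fit_array requires at least one curve")
    rows = []
    for i, curve in enumerate(curves):
        x, y = curve.position if curve.position is not None else (float(i), 0.0)
        row = {
            "position_x": x,
            "position_y": y,
            "youngs_modulus_pa": np.nan,
            "residual": np.nan,
            "accepted": False,
            "note": "",
        }
        try:
            offset = detect_contact_point(curve, baseline_fraction, k_sd)
            e_pa, resid = hertz_fit(curve.rezeroed(offset), poisson_ratio, window_um)
        except (ContactNotFoundError, InsufficientRangeError, FitFailureError) as exc:
            row["note"] = f"{type(exc).__name__}: {exc}"
        else:
            row.update(youngs_modulus_pa=e_pa, residual=resid, accepted=True)
        rows.append(row)
    return ElasticityMap(entries=pd.DataFrame(rows), compartment=compartment)


def summarize_map(
    emap: ElasticityMap, groups: list[str] | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-group mean/median/sd/n of accepted moduli.

    ``groups`` assigns one label per map entry (e.g. compartment); omitted,
    all entries form one group. Not-accepted entries never contribute.
    """
    entries = emap.entries
    if groups is None:
        groups = ["all"] * len(entries)
    groups = np.asarray(groups, dtype=object)
    if groups.size != len(entries):
        raise ValueError("one group label per entry required")
    out = []
    for label in pd.unique(groups):
        sub = entries[(groups == label) & entries["accepted"]]
        if sub.empty:
            raise UndefinedSummaryError(f"group {label!r} has no accepted entries")
        e = sub["youngs_modulus_pa"]
        out.append(
            {
                "group": label,
                "mean_pa": float(e.mean()),
                "median_pa": float(e.median()),
                "sd_pa": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
                "n": int(len(e)),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Curve table I/O (long format: curve_id, position_x, position_y,
# indentation_um, load with a declared unit column)
# ---------------------------------------------------------------------------

def curves_to_table(curves: list[IndentationCurve]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(curves):
        x, y = c.position if c.position is not None else (float(i), 0.0)
        for d, f in zip(c.indentation, c.load):
            rows.append(
                {
                    "curve_id": i,
                    "position_x": x,
                    "position_y": y,
                    "indentation_um": d,
                    "load": f,
                    "load_unit": "N",
                    "tip_radius_um": c.tip_radius_um,
                    "cantilever_stiffness_n_per_m": c.cantilever_stiffness_n_per_m,
                }
            )
    return pd.DataFrame(rows)


def curves_from_table(table: pd.DataFrame) -> list[IndentationCurve]:
    """Load curves from the long CSV format; loads accepted in N or nN."""
    curves = []
    for _, sub in table.groupby("curve_id", sort=True):
        unit = str(sub["load_unit"].iloc[0]) if "load_unit" in sub else "N"
        scale = {"N": 1.0, "nN": 1e-9}.get(unit)
        if scale is None:
            raise ValueError(f"unknown load unit {unit!r}")
        curves.append(
            IndentationCurve(
                indentation=sub["indentation_um"].to_numpy(),
                load=sub["load"].to_numpy() * scale,
                tip_radius_um=float(sub["tip_radius_um"].iloc[0])
                if "tip_radius_um" in sub
                else 25.0,
                cantilever_stiffness_n_per_m=float(
                    sub["cantilever_stiffness_n_per_m"].iloc[0]
                )
                if "cantilever_stiffness_n_per_m" in sub
                else 0.5,
                position=(
                    float(sub["position_x"].iloc[0]),
                    float(sub["position_y"].iloc[0]),
                ),
            )
        )
    return curves
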