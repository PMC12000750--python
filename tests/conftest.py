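"""Shared fixtures: small ground-truthed synthetic datasets.

Expensive stacks are session-scoped so several test modules can share
them; everything is generated programmatically with fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from osteochip import PhenotypeParams, generate_cell_stack


@pytest.fixture(scope="session")
def noiseless_stack():
    """20-cell noiseless stack: masks are crisp, volumes exactly checkable."""
    params = PhenotypeParams(
        n_cells=20, noise_gaussian_sd=0.0, shape=(32, 256, 256)
    )
    stack, truth = generate_cell_stack(params, seed=2)
    return stack, truth, params


@pytest.fixture(scope="session")
def lownoise_stack():
    """30-cell stack with realistic Gaussian read noise."""
    params = PhenotypeParams(
        n_cells=30, noise_gaussian_sd=3.0, shape=(32, 320, 320)
    )
    stack, truth = generate_cell_stack(params, seed=11)
    return stack, truth, params


def match_to_truth(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Align quantified cell records with ground-truth rows by centroid.

    Returns the truth rows reordered to match ``records`` row order.
    Raises if any match is farther than 3 μm (a mis-segmentation).
    """
    cols = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]
    tree = cKDTree(truth[cols].to_numpy())
    dist, idx = tree.query(records[cols].to_numpy())
    assert np.max(dist) < 3.0, f"centroid mismatch up to {np.max(dist):.2f} μm"
    assert len(np.unique(idx)) == len(idx), "two records matched one truth cell"
    return truth.iloc[idx].reset_index(drop=True)


def diffusion_fd_oracle(
    diffusivity_um2_s: float,
    chamber_width_um: float,
    t_seconds: float,
    n_grid: int = 481,
    source_level: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference solution of 1-D diffusion with fixed-source edges.

    Explicit scheme on a uniform grid, C(0)=C(W)=S held constant, C=0
    inside at t=0. Independent of the analytic erfc superposition used by
    the package. Returns ``(x_um, concentration)``.
    """
    x = np.linspace(0.0, chamber_width_um, n_grid)
    dx = x[1] - x[0]
    dt = 0.4 * dx * dx / diffusivity_um2_s
    n_steps = int(np.ceil(t_seconds / dt))
    dt = t_seconds / n_steps
    r = diffusivity_um2_s * dt / (dx * dx)
    c = np.zeros(n_grid)
    c[0] = c[-1] = source_level
    for _ in range(n_steps):
        c[1:-1] += r * (c[2:] - 2 * c[1:-1] + c[:-2])
    return x, c
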