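"""Cytokine/chemokine multiplex pipeline.

Bead-based multiplex immunoassays (Luminex) yield a samples × analytes
matrix, either as raw median fluorescence intensity (MFI) or as standard-
curve-converted concentrations. The pipeline here mirrors common practice
for small inflammation panels:

1. missing-value imputation — each missing entry replaced by 10% of the
   analyte's minimum non-missing value (a below-detection surrogate);
2. variance filtering — analytes with sample variance below a threshold
   (default 0.9) removed as uninformative;
3. z-score standardisation per analyte (zero mean, unit variance);
4. sample-space PCA (with exogenously spiked analytes excluded, since they
   were added to drive the stimulation and would bias sample clustering);
5. analyte clustering with correlation distance (1 − Pearson r) and
   complete linkage.

The pipeline order is fixed; :func:`run_secretome_pipeline` is the single
composed entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.decomposition import PCA

from .errors import (
    EmptyTableError,
    UndersizedInputError,
    UnimputableAnalyteError,
    ZeroVarianceError,
)

#: the 20-plex human inflammation panel
DEFAULT_PANEL = (
    "GM-CSF", "IFN alpha", "IFN gamma", "IL-1 alpha", "IL-1 beta",
    "IL-4", "IL-6", "IL-8", "IL-10", "IL-12p70", "IL-13", "IL-17A",
    "TNF alpha", "IP-10", "MCP-1", "MIP-1 alpha", "MIP-1 beta",
    "ICAM-1", "sCD62E", "sCD62P",
)

#: analytes spiked into the medium to induce inflammation; excluded from
#: sample-space PCA because their levels are experimenter-controlled
DEFAULT_SPIKED = ("IL-1 beta", "TNF alpha")


@dataclass
class CytokineTable:
    """Samples × analytes matrix with per-sample metadata.

    ``values`` rows align 1:1 with ``sample_meta`` rows (sex, condition,
    compartment, day, replicate). ``mode`` records whether values are raw
    MFI or converted concentrations.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    mode: str = "concentration"

    def __post_init__(self):
        if self.mode not in ("MFI", "concentration"):
            raise ValueError(f"mode must be 'MFI' or 'concentration'; got {self.mode!r}")
        if len(self.values) != len(self.sample_meta):
            raise ValueError("sample_meta rows must align 1:1 with value rows")
        if self.values.columns.duplicated().any():
            raise ValueError("analyte names must be unique")

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "CytokineTable":
        return CytokineTable(
            self.values.copy(), self.sample_meta.copy(), self.mode
        )

    def drop_samples(self, index) -> "CytokineTable":
        """Return a table with the given sample rows removed (by position)."""
        keep = np.ones(len(self.values), dtype=bool)
        keep[np.atleast_1d(index)] = False
        return CytokineTable(
            self.values.iloc[keep].reset_index(drop=True),
            self.sample_meta.iloc[keep].reset_index(drop=True),
            self.mode,
        )


@dataclass
class PcaResult:
    """Principal-component decomposition of the sample × analyte matrix."""

    scores: pd.DataFrame          # samples × components
    loadings: pd.DataFrame        # analytes × components
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(np.diff(evr) > 1e-12) or np.any(evr < -1e-12):
            raise ValueError("explained fractions must be non-increasing and >= 0")
        if evr.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must sum to <= 1")
        self.explained_variance_ratio = evr


@dataclass
class ClusterResult:
    """Analyte dendrogram plus the pairwise Pearson correlation matrix."""

    correlation: pd.DataFrame     # analytes × analytes, symmetric, unit diag
    linkage: np.ndarray           # scipy linkage matrix (complete)
    leaf_order: list[str] = field(default_factory=list)

    def cut(self, k: int) -> dict[str, int]:
        """Assign analytes to ``k`` flat clusters by cutting the tree."""
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.correlation.index, (int(v) for v in labels)))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (heights as branch lengths)."""
        tree = sch.to_tree(self.linkage)
        names = list(self.correlation.index)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def impute_missing(table: CytokineTable) -> CytokineTable:
    """Replace each missing entry by 10% of its analyte's minimum value.

    Non-missing entries are untouched. An analyte with no non-missing value
    cannot be imputed and raises :class:`UnimputableAnalyteError`.
    """
    out = table.copy()
    vals = out.values
    for col in vals.columns:
        column = vals[col]
        if column.isna().all():
            raise UnimputableAnalyteError(str(col))
        if column.isna().any():
            vals[col] = column.fillna(0.1 * column.min(skipna=True))
    return out


def filter_low_variance(
    table: CytokineTable, threshold: float = 0.9
) -> tuple[CytokineTable, list[str]]:
    """Drop analytes whose sample variance falls below ``threshold``.

    "Below" is strict: variance exactly at the threshold is retained. The
    variance is the unbiased (n−1) estimator on the imputed, pre-z-score
    values. Returns the filtered table and the removed-analyte list.
    """
    variances = table.values.var(axis=0, ddof=1)
    removed = [str(c) for c in table.values.columns[variances < threshold]]
    kept = table.values.drop(columns=removed)
    if kept.shape[1] == 0:
        raise EmptyTableError("variance filter removed every analyte")
    return CytokineTable(kept, table.sample_meta.copy(), table.mode), removed


def zscore(table: CytokineTable) -> CytokineTable:
    """Standardise each analyte to zero mean and unit variance.

    Uses the population (1/n) variance, matching StandardScaler; idempotent
    within floating tolerance.
    """
    vals = table.values
    std = vals.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = list(vals.columns[std == 0])
        raise ZeroVarianceError(f"zero-variance analytes cannot be z-scored: {bad}")
    z = (vals - vals.mean(axis=0)) / std
    return CytokineTable(z, table.sample_meta.copy(), table.mode)


def pca_samples(
    table: CytokineTable, exclude_analytes: tuple[str, ...] = ()
) -> PcaResult:
    """Sample-space PCA of a standardized table.

    ``exclude_analytes`` are dropped before the decomposition (names absent
    from the table are ignored). Component signs are fixed so that each
    loading vector's largest-magnitude element is positive, removing the
    eigenvector sign indeterminacy.
    """
    drop = [a for a in exclude_analytes if a in table.values.columns]
    vals = table.values.drop(columns=drop)
    if vals.shape[1] < 2:
        raise UndersizedInputError(
            f"only {vals.shape[1]} analytes remain after exclusion"
        )
    n_comp = min(vals.shape[0], vals.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(vals.to_numpy())
    loadings = pca.components_.T  # analytes × components
    # sign convention
    for c in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=vals.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def top_contributors(
    result: PcaResult, components: tuple[int, ...] = (1, 2), n: int | None = None
) -> pd.DataFrame:
    """Rank analytes by their contribution to the requested components.

    The contribution of analyte *j* is its squared loading on each requested
    component weighted by that component's explained-variance fraction,
    summed, then normalized so contributions sum to 1. Ties break
    alphabetically. ``n`` beyond the analyte count returns all analytes.
    """
    for c in components:
        if not (1 <= c <= result.loadings.shape[1]):
            raise ValueError(f"component {c} does not exist")
    weights = np.zeros(len(result.loadings))
    for c in components:
        lo = result.loadings.iloc[:, c - 1].to_numpy()
        weights += result.explained_variance_ratio[c - 1] * lo**2
    contrib = weights / weights.sum()
    df = pd.DataFrame(
        {"analyte": result.loadings.index, "contribution": contrib}
    ).sort_values(
        ["contribution", "analyte"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if n is not None:
        df = df.head(min(n, len(df)))
    return df


def cluster_analytes(table: CytokineTable) -> ClusterResult:
    """Hierarchical clustering of analytes by correlation distance.

    Pairwise distance d(j,k) = 1 − Pearson r of the analyte columns;
    agglomeration by complete linkage (merge heights therefore
    non-decreasing). Input should be standardized.
    """
    vals = table.values
    if vals.shape[1] < 2:
        raise UndersizedInputError("clustering requires at least 2 analytes")
    if (vals.std(axis=0, ddof=0) == 0).any():
        raise ZeroVarianceError("zero-variance analyte has undefined correlation")
    corr = np.corrcoef(vals.to_numpy(), rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="complete")
    leaves = sch.leaves_list(linkage)
    names = list(vals.columns)
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    return ClusterResult(
        correlation=corr_df,
        linkage=linkage,
        leaf_order=[names[i] for i in leaves],
    )


def run_secretome_pipeline(
    mfi_table: CytokineTable,
    conc_table: CytokineTable,
    exclude_analytes: tuple[str, ...] = DEFAULT_SPIKED,
    variance_threshold: float = 0.9,
    drop_samples: tuple[int, ...] = (),
) -> tuple[PcaResult, ClusterResult, dict]:
    """Composed two-dataset pipeline.

    The MFI table drives sample clustering: impute → z-score → PCA with the
    spiked analytes excluded (no variance filter on this path; MFI scales
    make the concentration-scale threshold inapplicable, and the asymmetry
    is recorded in the report). The concentration table drives analyte
    clustering: impute → variance filter → z-score → correlation-distance
    complete-linkage clustering.

    ``drop_samples`` removes samples (by row position, applied to both
    tables) before any processing, e.g. a technically failed well.

    Returns ``(PcaResult, ClusterResult, report)`` where the report records
    every parameter, drop and removal. Fully deterministic.
    """
    if set(mfi_table.analytes) != set(conc_table.analytes):
        raise ValueError("MFI and concentration tables must share the analyte panel")
    if drop_samples:
        mfi_table = mfi_table.drop_samples(list(drop_samples))
        conc_table = conc_table.drop_samples(list(drop_samples))

    mfi_z = zscore(impute_missing(mfi_table))
    pca_result = pca_samples(mfi_z, exclude_analytes=exclude_analytes)

    conc_imputed = impute_missing(conc_table)
    conc_filtered, removed = filter_low_variance(conc_imputed, variance_threshold)
    conc_z = zscore(conc_filtered)
    cluster_result = cluster_analytes(conc_z)

    report = {
        "n_samples_pca": int(len(mfi_table.values)),
        "n_samples_cluster": int(len(conc_table.values)),
        "dropped_samples": list(drop_samples),
        "excluded_analytes_pca": [
            a for a in exclude_analytes if a in mfi_table.analytes
        ],
        "variance_threshold": float(variance_threshold),
        "removed_low_variance": removed,
        "mfi_variance_filter_applied": False,
        "pc1_pc2_explained": float(pca_result.explained_variance_ratio[:2].sum()),
    }
    return pca_result, cluster_result, report


# ---------------------------------------------------------------------------
# Table I/O helpers
# ---------------------------------------------------------------------------

META_COLUMNS = ("sample_id", "sex", "condition", "compartment", "day", "replicate")


def table_to_frame(table: CytokineTable) -> pd.DataFrame:
    """Flatten to one CSV-ready frame: metadata block then analyte columns."""
    return pd.concat(
        [table.sample_meta.reset_index(drop=True), table.values.reset_index(drop=True)],
        axis=1,
    )


def table_from_frame(frame: pd.DataFrame, mode: str = "concentration") -> CytokineTable:
    meta_cols = [c for c in META_COLUMNS if c in frame.columns]
    return CytokineTable(
        values=frame.drop(columns=meta_cols),
        sample_meta=frame[meta_cols].copy(),
        mode=mode,
    )
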