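"""FPKM processing, low-expression filtering, average-linkage clustering,
and relative qPCR quantification (2^-dCT / 2^-ddCT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_FPKM_THRESHOLD = 2.0


@dataclass
class ExpressionMatrix:
    """Genes × conditions FPKM with its normalized and log2 views.

    ``equalized`` divides every cell by the single grand mean of the matrix
    (so the equalized grand mean is 1); ``logged`` is
    ``log2(equalized + pseudocount)``.
    """

    fpkm: pd.DataFrame
    equalized: pd.DataFrame
    logged: pd.DataFrame
    pseudocount: float


def normalize_matrix(matrix: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     per_gene: bool = False) -> ExpressionMatrix:
    """Equalize FPKM by the grand mean and log2-transform.

    With ``per_gene`` each row is divided by its own mean instead (rows with
    zero mean are left unscaled); the default is the single grand-mean scalar.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if (matrix.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if per_gene:
        means = matrix.mean(axis=1).replace(0.0, 1.0)
        equalized = matrix.div(means, axis=0)
    else:
        grand = float(matrix.values.mean())
        if grand == 0.0:
            raise ValueError("all-zero expression matrix")
        equalized = matrix / grand
    logged = np.log2(equalized + pseudocount)
    return ExpressionMatrix(matrix, equalized, logged, pseudocount)


def filter_expressed(
    matrix: pd.DataFrame, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split genes into expressed and barely-expressed sets.

    A gene is excluded iff its FPKM is strictly below *threshold* in every
    condition; a gene reaching the threshold anywhere is kept.
    """
    below_everywhere = (matrix < threshold).all(axis=1)
    excluded = list(matrix.index[below_everywhere])
    kept = list(matrix.index[~below_everywhere])
    return kept, excluded


@dataclass
class ClusterTree:
    """Average-linkage hierarchy over matrix rows (scipy linkage encoding)."""

    labels: list[str]
    linkage: np.ndarray

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def cluster_rows(
    logged: pd.DataFrame, metric: str = "euclidean"
) -> ClusterTree:
    """UPGMA-style average-linkage agglomeration of matrix rows.

    Rows must be finite and row labels unique; metric is ``euclidean`` or
    ``correlation``.
    """
    if logged.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if logged.index.duplicated().any():
        raise ValueError("duplicated row labels")
    values = logged.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in matrix")
    dist = pdist(values, metric=metric)
    linkage = hierarchy.linkage(dist, method="average")
    return ClusterTree(list(logged.index), linkage)


def cluster_heatmap(
    logged: pd.DataFrame,
    metric: str = "euclidean",
    cluster_columns: bool = False,
    image_path=None,
) -> ClusterTree:
    """Cluster rows (and optionally columns); optionally render a heatmap."""
    rows = cluster_rows(logged, metric)
    col_tree = cluster_rows(logged.T, metric) if cluster_columns else None
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        row_order = rows.leaf_order()
        col_order = col_tree.leaf_order() if col_tree else list(logged.columns)
        data = logged.loc[row_order, col_order]
        fig, ax = plt.subplots(
            figsize=(max(4, 0.3 * len(col_order)), max(4, 0.12 * len(row_order)))
        )
        im = ax.imshow(data.values, aspect="auto", cmap="RdYlBu_r")
        ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=6)
        ax.set_yticks(range(len(row_order)), row_order, fontsize=5)
        fig.colorbar(im, ax=ax, label="log2 equalized FPKM")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return rows


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    fold: float          # mean over biological replicates
    fold_sd: float       # sd over biological replicates (ddof=1; 0 if 1 rep)
    delta_ct: float      # mean ΔCT
    mode: str            # "dct" or "ddct"
    folds: list[float] = field(default_factory=list)  # per biological replicate


REQUIRED_CQ_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "cq")


def relative_expression(
    cq_table: pd.DataFrame,
    reference_gene: str,
    mode: str = "dct",
    control_condition: str | None = None,
) -> list[RelativeExpression]:
    """Relative expression by the 2^-dCT or 2^-ddCT method.

    Technical replicates are averaged to one Cq per biological replicate
    first.  Per biological replicate, dCT = Cq(target) - Cq(reference); in
    ``ddct`` mode ddCT = dCT - mean(control dCT) so the control condition's
    mean fold is 1 by construction.  Mean and sd of the per-replicate folds
    are reported.
    """
    if mode not in ("dct", "ddct"):
        raise ValueError("mode must be 'dct' or 'ddct'")
    if mode == "ddct" and control_condition is None:
        raise ValueError("ddct mode requires a control condition")
    missing = set(REQUIRED_CQ_COLUMNS) - set(cq_table.columns)
    if missing:
        raise ValueError(f"Cq table lacks columns {sorted(missing)}")

    # collapse technical replicates
    cq = (
        cq_table.groupby(["gene", "condition", "bio_rep"], sort=True)["cq"]
        .mean()
        .reset_index()
    )
    ref = cq[cq["gene"] == reference_gene].set_index(["condition", "bio_rep"])["cq"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")

    results = []
    for gene, sub in cq[cq["gene"] != reference_gene].groupby("gene", sort=True):
        dct = {}
        for cond, bysub in sub.groupby("condition", sort=True):
            vals = []
            for _, row in bysub.iterrows():
                key = (cond, row["bio_rep"])
                if key not in ref.index:
                    raise ValueError(
                        f"missing reference Cq for condition {cond!r}, "
                        f"biological replicate {row['bio_rep']!r}"
                    )
                vals.append(row["cq"] - ref.loc[key])
            if not vals:
                raise ValueError(f"gene {gene!r}, condition {cond!r}: no replicates")
            dct[cond] = np.array(vals, dtype=float)
        if mode == "ddct":
            if control_condition not in dct:
                raise ValueError(
                    f"gene {gene!r}: control condition {control_condition!r} absent"
                )
            calibrator = dct[control_condition].mean()
        for cond, vals in dct.items():
            exponent = vals - calibrator if mode == "ddct" else vals
            folds = 2.0 ** (-exponent)
            results.append(
                RelativeExpression(
                    gene=gene,
                    condition=cond,
                    fold=float(folds.mean()),
                    fold_sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                    delta_ct=float(vals.mean()),
                    mode=mode,
                    folds=[float(f) for f in folds],
                )
            )
    return results
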