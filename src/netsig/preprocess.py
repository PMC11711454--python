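"""Expression quality control, normalization, and covariate adjustment.

Stages mirror a standard bulk RNA-seq pre-analysis: remove degenerate
samples (exact duplicates, >50%-zero tumors), filter genes with low
variation (SD of normalized counts < 0.5) or too many zeros (>30%),
upper-quartile normalize, log2-transform with pseudocount 1, select the
enriched cell types, and residualize expression on them.  Quantiles use
the linear-interpolation convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


class PipelineOrderError(RuntimeError):
    """A stage was applied out of order (tracked by provenance flags)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with provenance flags.

    Flags are monotone: a matrix cannot be cell-adjusted before it has been
    log-transformed, nor log-transformed before normalization.
    """

    values: pd.DataFrame
    normalized: bool = False
    logged: bool = False
    adjusted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression entries must be finite")
        if self.adjusted and not self.logged:
            raise PipelineOrderError("cannot be cell-adjusted before log transform")
        if self.logged and not self.normalized:
            raise PipelineOrderError("cannot be log-transformed before normalization")


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("count matrix is empty")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene/sample ids must be unique")


def remove_degenerate_samples(counts: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop exact-duplicate sample columns (keeping the first) and samples
    with strictly more than 50% zero genes."""
    _check_counts(counts)
    dup_mask = counts.T.duplicated(keep="first")
    dropped_dup = list(counts.columns[dup_mask])
    kept = counts.loc[:, ~dup_mask.to_numpy()]
    zero_frac = (kept == 0).mean(axis=0)
    dropped_sparse = list(kept.columns[zero_frac > 0.5])
    kept = kept.loc[:, zero_frac <= 0.5]
    return kept, {"duplicate_samples": dropped_dup, "sparse_samples": dropped_sparse}


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its 75th percentile of nonzero counts equals the
    cohort reference (the mean of per-sample upper quartiles)."""
    _check_counts(counts)
    arr = counts.to_numpy(dtype=float)
    uqs = np.empty(arr.shape[1])
    for j, sample in enumerate(counts.columns):
        nz = arr[:, j][arr[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
        uqs[j] = np.quantile(nz, 0.75)  # linear interpolation
    ref = uqs.mean()
    return counts * (ref / uqs)


def filter_genes(
    counts: pd.DataFrame, sd_min: float = 0.5, zero_frac_max: float = 0.30
) -> tuple[pd.DataFrame, dict]:
    """Retain genes whose normalized-count SD is >= ``sd_min`` and whose
    zero fraction is <= ``zero_frac_max``; gene order preserved.

    The SD rule is evaluated on upper-quartile-normalized counts (before the
    log transform); the zero rule on the raw counts.
    """
    _check_counts(counts)
    norm = upper_quartile_normalize(counts)
    sds = norm.std(axis=1, ddof=1)
    zero_frac = (counts == 0).mean(axis=1)
    # a gene constant in raw counts is uninformative no matter how the
    # per-sample scaling spreads it out
    keep_sd = (sds >= sd_min) & (counts.std(axis=1, ddof=1) > 0)
    keep_zero = zero_frac <= zero_frac_max
    keep = keep_sd & keep_zero
    report = {
        "removed_low_sd": sorted(counts.index[~keep_sd]),
        "removed_zero_frac": sorted(counts.index[~keep_zero]),
        "n_retained": int(keep.sum()),
    }
    if keep.sum() == 0:
        import warnings

        warnings.warn("gene filter removed every gene", stacklevel=2)
    return counts.loc[keep], report


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount), marking provenance normalized+logged."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    vals = np.log2(matrix + pseudocount)
    return ExpressionMatrix(values=vals, normalized=True, logged=True)


def select_enriched_cell_types(
    fractions: pd.DataFrame, zero_frac_max: float = 0.30, sd_min: float = 0.1
) -> list[str]:
    """Cell types with at most ``zero_frac_max`` zero scores across samples
    and standard deviation strictly greater than ``sd_min``."""
    zero_frac = (fractions == 0).mean(axis=0)
    sds = fractions.std(axis=0, ddof=1)
    keep = (zero_frac <= zero_frac_max) & (sds > sd_min)
    return list(fractions.columns[keep])


def adjust_expression(
    expression: ExpressionMatrix, covariates: pd.DataFrame
) -> ExpressionMatrix:
    """Replace each gene by its least-squares residual on [1 | covariates].

    Residuals are exactly orthogonal to every covariate column (and to the
    intercept, i.e. centered).
    """
    if not expression.logged:
        raise PipelineOrderError("adjust_expression requires log-transformed input")
    X = covariates.loc[expression.values.columns].to_numpy(dtype=float)
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.ones((X.shape[0], 1))
        for j, name in enumerate(covariates.columns):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"rank-deficient covariates: collinear columns {bad}")
    Y = expression.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    out = pd.DataFrame(resid.T, index=expression.values.index, columns=expression.values.columns)
    return ExpressionMatrix(values=out, normalized=True, logged=True, adjusted=True)


def infer_sex_chrY(
    expression: pd.DataFrame,
    chry_genes: list[str],
    recorded_sex: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """k=2 k-means on chrY gene expression; the cluster with the higher mean
    chrY expression is labeled male-like; samples whose recorded sex
    (1=male, 0=female) disagrees with the cluster label are flagged."""
    present = [g for g in chry_genes if g in expression.index]
    if len(present) < 2:
        raise ValueError("need at least two chromosome-Y genes")
    if expression.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = expression.loc[present].to_numpy(dtype=float).T  # samples x chrY genes
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    labels = km.labels_
    means = [X[labels == k].mean() for k in (0, 1)]
    male_cluster = int(np.argmax(means))
    inferred_male = (labels == male_cluster).astype(int)
    rec = recorded_sex.loc[expression.columns].to_numpy()
    return pd.DataFrame(
        {
            "cluster": labels,
            "inferred_male": inferred_male,
            "recorded_male": rec,
            "discrepant": inferred_male != rec,
        },
        index=expression.columns,
    )


def principal_components(matrix: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Scores of the top principal components of the column-standardized
    matrix (rows = observations).  Zero-variance columns are dropped with a
    warning; each component's sign is fixed so its largest-magnitude loading
    is positive."""
    if n_components > min(matrix.shape):
        raise ValueError("n_components exceeds matrix dimensions")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        import warnings

        warnings.warn(
            f"dropping {int((sd == 0).sum())} zero-variance columns", stacklevel=2
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    Xs = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1
    return pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{k+1}" for k in range(scores.shape[1])]
    )
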