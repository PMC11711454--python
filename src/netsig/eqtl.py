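"""cis-eQTL mapping with gene-level adaptive permutation and enrichment.

Each gene is tested against every variant within +/- 1 Mb of its TSS
(closed window, same chromosome) with covariates in the linear model.
Gene-level significance comes from an adaptive permutation scheme: the
statistic is the minimum nominal p across the gene's cis variants, sample
labels of expression are permuted, and the adjusted p is the empirical
(r+1)/(n+1) with early stopping once enough permuted statistics beat the
observed one.  eGenes are genes with adjusted p < 0.05; their top variants
serve as candidate instruments downstream.

Enrichment of cis-eQTLs in genomic annotations is assessed against null
variant sets matched on user-chosen covariates (MAF, TSS distance, ...)
via equal-frequency bins, summarized as a z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CisPair:
    gene: str
    variant: str
    distance: int  # signed bp, variant pos - TSS
    beta: float
    se: float
    p: float


@dataclass
class EGeneRecord:
    gene: str
    top_variant: str
    nominal_p: float
    adjusted_p: float
    n_permutations: int


def enumerate_cis_pairs(
    gene_tss: dict[str, tuple[str, int]],
    variant_pos: dict[str, tuple[str, int]],
    window_bp: int = 1_000_000,
) -> list[tuple[str, str, int]]:
    """All (gene, variant, signed distance) with |pos - TSS| <= window on the
    same chromosome; the window is closed on both ends."""
    out = []
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for vid, (chrom, pos) in variant_pos.items():
        by_chrom.setdefault(chrom, []).append((vid, pos))
    for gene, loc in gene_tss.items():
        if loc is None:
            warnings.warn(f"gene {gene} has no TSS; skipped", stacklevel=2)
            continue
        chrom, tss = loc
        for vid, pos in by_chrom.get(chrom, []):
            d = pos - tss
            if abs(d) <= window_bp:
                out.append((gene, vid, d))
    return out


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def fit_cis_regression(
    expression: np.ndarray,
    dosage: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    gene: str = "",
    variant: str = "",
    distance: int = 0,
) -> Optional[CisPair]:
    """OLS of expression on dosage with covariates in the model; two-sided
    t-test on the dosage slope.  Monomorphic variants are skipped."""
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    if dosage.std() == 0:
        warnings.warn(f"monomorphic variant {variant}; skipped", stacklevel=2)
        return None
    n = y.size
    if covariates is None:
        design = np.column_stack([np.ones(n), dosage])
    else:
        design = np.column_stack([np.ones(n), covariates, dosage])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - design.shape[1]
    if df <= 0:
        return None
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.pinv(design.T @ design)
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    b = float(beta[-1])
    if se == 0:
        p = 0.0 if b != 0 else 1.0
    else:
        t = b / se
        p = float(2 * stats.t.sf(abs(t), df))
    return CisPair(gene=gene, variant=variant, distance=distance, beta=b, se=se, p=max(p, 5e-324))


def _min_p_from_corr(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for Pearson correlations with ``df`` residual degrees of
    freedom (covariates already projected out)."""
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt(df / np.maximum(1e-300, 1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df)


def gene_level_permutation(
    expression: np.ndarray,
    dosages: np.ndarray,
    covariates: Optional[np.ndarray],
    gene: str,
    variant_ids: Sequence[str],
    max_perm: int = 10_000,
    target_exceedances: int = 100,
    seed: int = 0,
    batch: int = 500,
) -> EGeneRecord:
    """Adaptive permutation gene-level p.

    The observed statistic is the minimum nominal p over the gene's cis
    variants.  Expression sample labels are permuted; permutation stops
    early once ``target_exceedances`` permuted minima fall at or below the
    observed one, or at ``max_perm``.  Adjusted p = (r+1)/(n+1).

    Covariates are residualized out of both expression and dosages once, so
    each permutation reduces to a correlation scan (the covariate-adjusted
    t-test is equivalent to the residual-residual correlation test with the
    degrees of freedom reduced by the number of covariates).
    """
    if max_perm < 1:
        raise ValueError("max_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(expression, dtype=float)
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    n = y.size
    k = 0
    if covariates is not None and covariates.size:
        design = np.column_stack([np.ones(n), covariates])
        y = _residualize(y, design)
        D = D - design @ np.linalg.lstsq(design, D, rcond=None)[0]
        k = design.shape[1] - 1
    else:
        y = y - y.mean()
        D = D - D.mean(axis=0)
    keep = D.std(axis=0) > 0
    D = D[:, keep]
    kept_ids = [v for v, m in zip(variant_ids, keep) if m]
    if D.shape[1] == 0:
        raise ValueError(f"gene {gene}: no polymorphic cis variants")
    df = n - 2 - k
    Dn = D / np.linalg.norm(D, axis=0)
    yn = y / np.linalg.norm(y)
    r_obs = yn @ Dn
    p_obs = _min_p_from_corr(r_obs, df)
    i_top = int(np.argmin(p_obs))
    obs_min_p = float(p_obs[i_top])

    exceed = 0
    done = 0
    while done < max_perm and exceed < target_exceedances:
        m = min(batch, max_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(m)])
        Yp = yn[perms]  # m x n
        R = Yp @ Dn  # m x variants
        pmin = _min_p_from_corr(R, df).min(axis=1)
        exceed += int((pmin <= obs_min_p).sum())
        done += m
    adj = (exceed + 1) / (done + 1)
    return EGeneRecord(
        gene=gene,
        top_variant=kept_ids[i_top],
        nominal_p=obs_min_p,
        adjusted_p=float(adj),
        n_permutations=done,
    )


def select_egenes(records: Sequence[EGeneRecord], alpha: float = 0.05) -> list[EGeneRecord]:
    """Genes with gene-level adjusted p strictly below ``alpha``."""
    return [r for r in records if r.adjusted_p < alpha]


def sample_matched_null_sets(
    query: pd.DataFrame,
    universe: pd.DataFrame,
    matching_covariates: Sequence[str],
    n_sets: int = 1000,
    n_bins: int = 10,
    seed: int = 0,
) -> list[list[str]]:
    """Null variant sets of the query's size, matched on covariates.

    Both frames are indexed by variant id.  Each covariate is cut into
    equal-frequency bins over the universe; a null counterpart of a query
    variant is drawn uniformly (without replacement within a set) from the
    universe variants sharing its full bin combination.
    """
    rng = np.random.default_rng(seed)
    if not matching_covariates:
        ids = np.asarray(universe.index)
        return [list(rng.choice(ids, size=len(query), replace=False)) for _ in range(n_sets)]
    edges = {}
    uni_bins = pd.DataFrame(index=universe.index)
    q_bins = pd.DataFrame(index=query.index)
    for cov in matching_covariates:
        qs = np.quantile(universe[cov].to_numpy(), np.linspace(0, 1, n_bins + 1))
        qs = np.unique(qs)
        edges[cov] = qs
        uni_bins[cov] = np.clip(np.searchsorted(qs, universe[cov], side="right") - 1, 0, len(qs) - 2)
        q_bins[cov] = np.clip(np.searchsorted(qs, query[cov], side="right") - 1, 0, len(qs) - 2)
    uni_key = uni_bins.apply(tuple, axis=1)
    strata: dict[tuple, np.ndarray] = {
        key: np.asarray(grp.index) for key, grp in universe.groupby(uni_key)
    }
    q_keys = q_bins.apply(tuple, axis=1)
    for vid, key in q_keys.items():
        if key not in strata:
            raise ValueError(f"unmatched stratum {dict(zip(matching_covariates, key))} for {vid}")
    sets = []
    for _ in range(n_sets):
        chosen: list[str] = []
        used: set[str] = set()
        for vid, key in q_keys.items():
            pool = strata[key]
            pick = pool[rng.integers(len(pool))]
            tries = 0
            while pick in used and tries < 50:
                pick = pool[rng.integers(len(pool))]
                tries += 1
            if pick in used:
                avail = [v for v in pool if v not in used]
                if not avail:
                    raise ValueError(
                        f"stratum {dict(zip(matching_covariates, key))} exhausted for {vid}"
                    )
                pick = avail[rng.integers(len(avail))]
            used.add(pick)
            chosen.append(str(pick))
        sets.append(chosen)
    return sets


def _count_overlap(
    positions: dict[str, tuple[str, int]], variants: Sequence[str], intervals: Sequence[tuple[str, int, int]]
) -> int:
    """Variants falling inside any 1-based closed interval."""
    count = 0
    for v in variants:
        chrom, pos = positions[v]
        for ic, lo, hi in intervals:
            if ic == chrom and lo <= pos <= hi:
                count += 1
                break
    return count


def annotation_enrichment_z(
    query: Sequence[str],
    null_sets: Sequence[Sequence[str]],
    positions: dict[str, tuple[str, int]],
    annotations: dict[str, Sequence[tuple[str, int, int]]],
) -> pd.DataFrame:
    """z = (observed - mean null) / sd(null) overlap count per annotation.

    Annotations are 1-based closed intervals.  A zero null SD yields a
    missing z with a warning.
    """
    if len(null_sets) < 2:
        raise ValueError("need at least two null sets")
    rows = []
    for name, intervals in annotations.items():
        obs = _count_overlap(positions, query, intervals)
        nulls = np.array([_count_overlap(positions, s, intervals) for s in null_sets], dtype=float)
        sd = nulls.std(ddof=1)
        if sd == 0:
            warnings.warn(f"annotation {name}: zero null variance, z undefined", stacklevel=2)
            z = np.nan
        else:
            z = (obs - nulls.mean()) / sd
        rows.append({"annotation": name, "observed": obs, "null_mean": nulls.mean(), "null_sd": sd, "z": z})
    return pd.DataFrame(rows).set_index("annotation")
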