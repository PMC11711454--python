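"""Learning the transcriptomic-causal network.

The network is learned per gene cluster (k-means, k=4 by default) with two
independent stability routes whose edges are intersected:

* an FDR route — full-order partial correlations over the dense
  within-cluster graph, Benjamini-Hochberg at q = 0.05;
* a Hamming-distance route — PC-stable skeletons along the significance
  grid alpha_i in {10^-i : i = 3..22}; consecutive skeletons are compared
  by Hamming distance and a piecewise (broken-stick) regression of HD on
  alpha locates the breakpoint marking the network's intrinsic sparsity
  level; the skeleton at the selected alpha is the HD-stable network.

Edges are then oriented by unshielded-collider (v-structure) detection and
by Mendelian randomization using each eGene's top cis variant as an
instrument; known regulatory relationships can be imposed as priors.
Finally, edges are validated on held-out samples by neighbor-based linear
prediction (a gene is validated when the train-fit prediction correlates
with its held-out expression above r = 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .graph import GeneGraph

DEFAULT_ALPHA_GRID = tuple(10.0 ** (-i) for i in range(3, 23))


# ---------------------------------------------------------------------------
# clustering and conditional-independence testing
# ---------------------------------------------------------------------------


def cluster_genes(expression: pd.DataFrame, k: int = 4, seed: int = 0) -> dict[str, int]:
    """k-means over standardized per-gene expression profiles (genes are the
    observations).  Deterministic given the seed; best of 10 restarts."""
    genes = list(expression.index)
    if k > len(genes):
        raise ValueError("more clusters than genes")
    if k == 1:
        return {g: 0 for g in genes}
    # canonical gene order: k-means init depends on row order, sorting makes
    # the partition invariant to how the caller listed the genes
    expression = expression.loc[sorted(genes)]
    genes = list(expression.index)
    X = expression.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xs)
    return {g: int(c) for g, c in zip(genes, km.labels_)}


def partial_correlation(
    i: int, j: int, S: Sequence[int], corr: np.ndarray
) -> float:
    """Partial correlation of variables i and j given the set S, from the
    correlation matrix (inversion of the {i,j}uS submatrix)."""
    if not len(S):
        return float(corr[i, j])
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular conditioning submatrix for pair ({i},{j}) given {list(S)}"
        ) from err
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def fisher_z_test(
    i: int, j: int, S: Sequence[int], corr: np.ndarray, n: int
) -> float:
    """Two-sided p for zero partial correlation via the Fisher z transform:
    z = sqrt(n - |S| - 3) * atanh(r)."""
    if n <= len(S) + 3:
        raise ValueError("need n > |S| + 3 samples")
    r = partial_correlation(i, j, S, corr)
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.sqrt(n - len(S) - 3) * np.arctanh(r)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# PC-stable skeleton
# ---------------------------------------------------------------------------

SepsetMap = dict[frozenset, tuple[str, ...]]


def learn_skeleton_pcstable(
    expression: pd.DataFrame,
    alpha: float,
    max_depth: Optional[int] = None,
    corr: Optional[np.ndarray] = None,
) -> tuple[set[frozenset], SepsetMap]:
    """Order-independent (stable) PC skeleton.

    At each depth the adjacency sets are frozen before any removal, so the
    output does not depend on the order in which genes are listed.  An edge
    i-j is removed as soon as some conditioning set S of the current depth,
    drawn from the frozen adjacencies of i or of j, gives a Fisher-z p
    strictly greater than ``alpha``; S is recorded as the pair's sepset.
    """
    genes = list(expression.index)
    X = expression.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression must be finite")
    n = expression.shape[1]
    if corr is None:
        corr = np.corrcoef(X)
    p = len(genes)
    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    sepsets: SepsetMap = {}
    depth = 0
    while True:
        if max_depth is not None and depth > max_depth:
            break
        if n <= depth + 3:
            break
        frozen = {i: frozenset(adj[i]) for i in range(p)}
        if all(len(frozen[i]) - 1 < depth for i in range(p)):
            break
        for i in range(p):
            for j in sorted(frozen[i]):
                if j < i or j not in adj[i]:
                    continue
                removed = False
                for base in (frozen[i] - {j}, frozen[j] - {i}):
                    if len(base) < depth:
                        continue
                    for S in combinations(sorted(base), depth):
                        pval = fisher_z_test(i, j, S, corr, n)
                        if pval > alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepsets[frozenset((genes[i], genes[j]))] = tuple(
                                genes[s] for s in S
                            )
                            removed = True
                            break
                    if removed:
                        break
        depth += 1
    skeleton = {
        frozenset((genes[i], genes[j]))
        for i in range(p)
        for j in adj[i]
        if i < j
    }
    return skeleton, sepsets


def orient_v_structures(
    nodes: Sequence[str], skeleton: set[frozenset], sepsets: SepsetMap
) -> GeneGraph:
    """Orient every unshielded triple a-c-b with c not in sepset(a, b) as the
    collider a->c<-b; conflicting orientations leave edges undirected."""
    g = GeneGraph(nodes)
    for key in skeleton:
        a, b = sorted(key)
        g.add_edge(a, b)
    votes: dict[tuple[str, str], int] = {}
    for c in g.nodes:
        nb = sorted(g.neighbors(c))
        for a, b in combinations(nb, 2):
            if g.has_edge(a, b):
                continue  # shielded
            sep = sepsets.get(frozenset((a, b)))
            if sep is None:
                continue
            if c not in sep:
                votes[(a, c)] = votes.get((a, c), 0) + 1
                votes[(b, c)] = votes.get((b, c), 0) + 1
    # an edge oriented both ways by different triples is a conflict
    for (src, dst), _ in sorted(votes.items()):
        if (dst, src) in votes:
            warnings.warn(
                f"conflicting v-structure orientations for {src}-{dst}; left undirected",
                stacklevel=2,
            )
            continue
        ok = g.orient(src, dst, provenance="v_structure")
        if not ok:
            warnings.warn(
                f"v-structure orientation {src}->{dst} refused (cycle)", stacklevel=2
            )
    return g


# ---------------------------------------------------------------------------
# FDR route
# ---------------------------------------------------------------------------


def dense_fdr_edges(
    expression: pd.DataFrame, q: float = 0.05, shrinkage: Optional[float] = None
) -> tuple[set[frozenset], pd.DataFrame]:
    """Full-order partial-correlation p-values for every within-cluster pair
    (conditioning on all remaining cluster genes), Benjamini-Hochberg at q.

    Returns the surviving edge set and the full pair table.  When genes
    outnumber samples the correlation matrix is singular; pass ``shrinkage``
    in (0, 1] to blend toward the identity.
    """
    genes = list(expression.index)
    p = len(genes)
    if p < 2:
        raise ValueError("need at least two genes")
    n = expression.shape[1]
    corr = np.corrcoef(expression.to_numpy(dtype=float))
    if shrinkage:
        corr = (1 - shrinkage) * corr + shrinkage * np.eye(p)
    elif p >= n or np.linalg.cond(corr) > 1e12:
        raise np.linalg.LinAlgError(
            "singular covariance (genes >= samples?); pass shrinkage=... to regularize"
        )
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    k = p - 2  # conditioning-set size for full-order partial correlation
    df = n - k - 3
    if df <= 0:
        if not shrinkage:
            raise ValueError("too few samples for full-order partial correlations")
        df = 1  # shrinkage-regularized p-values: conservative df floor
    rows = []
    for i, j in combinations(range(p), 2):
        r = float(np.clip(pcorr[i, j], -1 + 1e-15, 1 - 1e-15))
        z = np.sqrt(df) * np.arctanh(r)
        pval = 2 * stats.norm.sf(abs(z))
        rows.append({"a": genes[i], "b": genes[j], "pcorr": r, "p": pval})
    table = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(table["p"], alpha=q, method="fdr_bh")
    table["p_bh"] = p_adj
    table["significant"] = reject
    edges = {
        frozenset((r.a, r.b)) for r in table.itertuples() if r.significant
    }
    return edges, table


# ---------------------------------------------------------------------------
# Hamming-distance route
# ---------------------------------------------------------------------------


@dataclass
class AlphaPath:
    grid: tuple[float, ...]  # strictly decreasing
    skeletons: list[set[frozenset]]
    hds: list[int]  # hds[k] = HD(skeleton[k], skeleton[k+1])

    def __post_init__(self) -> None:
        if any(a <= b for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("alpha grid must be strictly decreasing")
        if len(self.hds) != len(self.grid) - 1:
            raise ValueError("need one HD per consecutive grid pair")


@dataclass
class PiecewiseFit:
    breakpoint: float
    beta0: float
    beta1: float
    beta3: float
    p_slope_change: float
    rss: float
    selected: bool = False


def hamming_distance(edges_a: set[frozenset], edges_b: set[frozenset]) -> int:
    """Edges present in exactly one of the two skeletons."""
    return len(edges_a ^ edges_b)


def alpha_path(
    expression: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    max_depth: Optional[int] = None,
) -> AlphaPath:
    """PC-stable skeleton at every alpha of the (decreasing) grid, plus the
    Hamming distance between each consecutive pair."""
    grid = tuple(grid)
    corr = np.corrcoef(expression.to_numpy(dtype=float))
    skeletons = [
        learn_skeleton_pcstable(expression, a, max_depth=max_depth, corr=corr)[0]
        for a in grid
    ]
    hds = [hamming_distance(s1, s2) for s1, s2 in zip(skeletons, skeletons[1:])]
    return AlphaPath(grid=grid, skeletons=skeletons, hds=hds)


def _piecewise_design(x: np.ndarray, bp: float) -> np.ndarray:
    extra = np.where(x > bp, x - bp, 0.0)
    return np.column_stack([np.ones_like(x), x, extra])


def select_alpha_breakpoint(
    path: AlphaPath,
    sig_level: float = 0.05,
    min_points_per_segment: int = 2,
    log_scale: bool = False,
) -> tuple[float, list[PiecewiseFit]]:
    """Locate the sparsification breakpoint of the HD-vs-alpha curve.

    Each consecutive-pair Hamming distance HD_{i,i-1} is regressed on the
    smaller alpha of its pair.  For every candidate breakpoint alpha_k in
    the grid interior (at least ``min_points_per_segment`` points strictly
    on each side) the broken-stick model

        HD = b0 + b1 * alpha + b3 * (alpha - alpha_k) * 1{alpha > alpha_k}

    is fit by least squares and the slope-change term b3 is t-tested.
    Among candidates with p < ``sig_level`` the minimum-RSS breakpoint is
    selected (ties resolved toward the larger alpha); if none is
    significant the global minimum-RSS candidate is chosen with a warning.
    With ``log_scale`` the regressor is log10(alpha).

    Note a "largest significant alpha" rule is not usable here: on a convex
    single-kink HD curve nearly every candidate shows a significant slope
    change, so the maximal one systematically overshoots the kink; the RSS
    criterion pins the candidate where the two-segment model actually fits.
    """
    x = np.asarray(path.grid[1:], dtype=float)
    y = np.asarray(path.hds, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least five HD points")
    xr = np.log10(x) if log_scale else x
    fits: list[PiecewiseFit] = []
    for k, bp_alpha in enumerate(path.grid[1:]):
        bp = np.log10(bp_alpha) if log_scale else bp_alpha
        n_above = int((xr > bp).sum())
        n_below = int((xr < bp).sum())
        if n_above < min_points_per_segment or n_below < min_points_per_segment:
            continue
        X = _piecewise_design(xr, bp)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        dof = len(y) - X.shape[1]
        if dof <= 0 or rank < X.shape[1]:
            continue
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se3 = float(np.sqrt(max(cov[2, 2], 0.0)))
        if se3 == 0:
            pval = 0.0 if abs(beta[2]) > 0 else 1.0
        else:
            pval = float(2 * stats.t.sf(abs(beta[2] / se3), dof))
        fits.append(
            PiecewiseFit(
                breakpoint=float(bp_alpha),
                beta0=float(beta[0]),
                beta1=float(beta[1]),
                beta3=float(beta[2]),
                p_slope_change=pval,
                rss=rss,
            )
        )
    if not fits:
        raise ValueError("fewer candidate breakpoints than required")
    significant = [f for f in fits if f.p_slope_change < sig_level]
    if significant:
        chosen = min(significant, key=lambda f: (f.rss, -f.breakpoint))
    else:
        warnings.warn(
            "no significant slope change; falling back to minimum-RSS breakpoint",
            stacklevel=2,
        )
        chosen = min(fits, key=lambda f: f.rss)
    chosen.selected = True
    return chosen.breakpoint, fits


def intersect_stable_edges(
    fdr_edges: set[frozenset],
    hd_skeleton: set[frozenset],
    nodes: Sequence[str],
    p_values: Optional[dict[frozenset, float]] = None,
) -> GeneGraph:
    """Edges identified by both stability routes, with provenance flags."""
    g = GeneGraph(nodes)
    for key in fdr_edges & hd_skeleton:
        a, b = sorted(key)
        g.add_edge(a, b, p=(p_values or {}).get(key), provenance={"fdr_stable", "hd_stable"})
    return g


# ---------------------------------------------------------------------------
# orientation by instruments and priors
# ---------------------------------------------------------------------------


def _slope_p(y: np.ndarray, x: np.ndarray, covar: Optional[np.ndarray] = None) -> float:
    n = y.size
    cols = [np.ones(n), x] if covar is None else [np.ones(n), covar, x]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.pinv(X.T @ X)[-1, -1])
    if se == 0:
        return 0.0 if abs(beta[-1]) > 0 else 1.0
    return float(2 * stats.t.sf(abs(beta[-1] / se), dof))


def orient_with_instruments(
    graph: GeneGraph,
    instruments: dict[str, str],  # eGene -> top cis variant id
    dosages: pd.DataFrame,  # samples x variants
    expression: pd.DataFrame,  # genes x samples
    alpha_mr: float = 0.05,
) -> GeneGraph:
    """Mendelian-randomization orientation of undirected edges.

    For an undirected edge g1-g2 where g1 carries instrument V: if V is
    associated with g2 marginally (p < alpha_mr) but NOT after conditioning
    on g1, the causal flow is inferred as g1 -> g2.  The symmetric check is
    run with g2's instrument; contradictory verdicts leave the edge
    undirected, and an orientation that would close a directed cycle is
    refused and logged.
    """
    out = graph.copy()
    samples = list(expression.columns)
    for e in sorted(out.edges, key=lambda e: (e.a, e.b)):
        if e.directed:
            continue
        verdicts = []
        for g_from, g_to in ((e.a, e.b), (e.b, e.a)):
            vid = instruments.get(g_from)
            if vid is None or vid not in dosages.columns:
                continue
            v = dosages.loc[samples, vid].to_numpy(dtype=float)
            if v.std() == 0:
                warnings.warn(f"instrument {vid} monomorphic; skipped", stacklevel=2)
                continue
            y = expression.loc[g_to].to_numpy(dtype=float)
            x1 = expression.loc[g_from].to_numpy(dtype=float)
            p_marg = _slope_p(y, v)
            p_cond = _slope_p(y, v, covar=x1)
            if p_marg < alpha_mr and p_cond >= alpha_mr:
                verdicts.append((g_from, g_to))
        if len(verdicts) == 1:
            src, dst = verdicts[0]
            if not out.orient(src, dst, provenance="mr_oriented"):
                warnings.warn(
                    f"MR orientation {src}->{dst} refused (would create cycle)",
                    stacklevel=2,
                )
        elif len(verdicts) == 2:
            warnings.warn(
                f"conflicting MR evidence for edge {e.a}-{e.b}; left undirected",
                stacklevel=2,
            )
    return out


def apply_prior_edges(
    graph: GeneGraph, priors: Sequence[tuple[str, str]]
) -> GeneGraph:
    """Orient existing edges per prior knowledge (src, dst); priors never add
    edges and take precedence over earlier orientations."""
    out = graph.copy()
    for src, dst in priors:
        if not out.has_edge(src, dst):
            warnings.warn(f"prior edge {src}->{dst} absent from graph; ignored", stacklevel=2)
            continue
        e = out.edge(src, dst)
        if e.directed and e.src != src:
            warnings.warn(
                f"prior {src}->{dst} overrides previous orientation {e.src}->{e.dst}",
                stacklevel=2,
            )
        if not out.orient(src, dst, provenance="prior", force=True):
            warnings.warn(f"prior orientation {src}->{dst} refused (cycle)", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# hold-out edge validation
# ---------------------------------------------------------------------------


def validate_edges_holdout(
    graph: GeneGraph,
    train: pd.DataFrame,  # genes x train samples
    test: pd.DataFrame,  # genes x test samples
    r_min: float = 0.5,
    ridge: float = 1e-8,
) -> tuple[GeneGraph, pd.DataFrame]:
    """Neighbor-based predictive validation on held-out samples.

    For each gene g with neighbors N(g) (direct upstream and downstream
    genes, direction ignored), coefficients (G'G)^-1 G' g are estimated on
    the training samples and applied to the test samples; the gene is
    validated when Pearson r(observed, predicted) > ``r_min``.  An edge is
    flagged validated when at least one endpoint's gene-level prediction is
    validated.  A singular G'G falls back to a ridge solve with a warning.
    """
    shared = set(train.columns) & set(test.columns)
    if shared:
        raise ValueError("train and test samples must be disjoint")
    rows = []
    gene_valid: dict[str, bool] = {}
    for g in graph.nodes:
        nb = sorted(graph.neighbors(g))
        if not nb:
            continue
        G = train.loc[nb].to_numpy(dtype=float).T
        y = train.loc[g].to_numpy(dtype=float)
        gram = G.T @ G
        try:
            coef = np.linalg.solve(gram, G.T @ y)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular G'G for gene {g}; ridge fallback", stacklevel=2)
            coef = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), G.T @ y)
        Gt = test.loc[nb].to_numpy(dtype=float).T
        pred = Gt @ coef
        obs = test.loc[g].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(obs) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(obs, pred)[0, 1])
        ok = bool(r > r_min) if np.isfinite(r) else False
        gene_valid[g] = ok
        rows.append({"gene": g, "n_neighbors": len(nb), "r": r, "validated": ok})
    out = graph.copy()
    for e in out.edges:
        if gene_valid.get(e.a, False) or gene_valid.get(e.b, False):
            e.provenance.add("validated")
    return out, pd.DataFrame(rows)
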