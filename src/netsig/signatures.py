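"""eGene-anchored subnetworks, network-adjusted Cox models, gene
signatures, and Kaplan-Meier patient stratification.

For each eGene, the subnetwork is its distance-<=2 neighborhood in the
mixed network (direction ignored for membership).  Within a subnetwork the
hazard for arm-specific overall survival is modeled as

    h(t) = h0(t) exp( gamma . Gtilde + beta . G + theta . Z + delta . T )

where Gtilde stacks each member gene residualized on its direct upstream
genes (hat-matrix projection, with intercept), G stacks the raw upstream
genes, Z the clinical covariates and T the enriched cell-type scores.
Residualization orthogonalizes each focal gene against its confounders, so
gamma_i estimates the direct effect of gene i on survival.  The partial
likelihood is maximized with Efron tie handling (lifelines).

A signature is the set of member genes with Wald p < 0.1 in an arm.  Each
signature gene is dichotomized at its cohort-wide third quartile
(linear-interpolation convention, strict >); a patient is "high" when all
signature genes are high, "medium-to-low" when all are below, otherwise
mixed (reported but excluded from the two-group Kaplan-Meier comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .graph import GeneGraph


@dataclass
class SubNetwork:
    anchor: str
    members: list[str]
    edges: list[tuple[str, str, bool]]  # (a, b, directed) induced
    upstream: dict[str, list[str]]  # gene -> direct parents within the subnetwork


@dataclass
class CoxResult:
    gene: str
    arm: str
    coef: float
    hr: float
    se: float
    p: float
    n_genes: int
    n_covariates: int
    n_cell_types: int


@dataclass
class GeneSignature:
    subnetwork: str
    arm: str
    genes: list[str]
    q3_cutoffs: dict[str, float] = field(default_factory=dict)


@dataclass
class KMCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]


# ---------------------------------------------------------------------------
# subnetworks
# ---------------------------------------------------------------------------


def extract_subnetworks(graph: GeneGraph, egenes: Sequence[str]) -> list[SubNetwork]:
    """One subnetwork per eGene: all genes within undirected-path distance
    two of the anchor, plus the induced edges and per-gene upstream sets."""
    for g in egenes:
        if g not in graph.nodes:
            raise KeyError(f"eGene {g} not in graph")
    ug = graph.undirected_view()
    out = []
    for anchor in egenes:
        dist1 = set(ug.neighbors(anchor))
        dist2 = set()
        for v in dist1:
            dist2 |= set(ug.neighbors(v))
        members = sorted({anchor} | dist1 | dist2)
        if len(members) == 1:
            warnings.warn(f"eGene {anchor} is isolated; singleton subnetwork", stacklevel=2)
        member_set = set(members)
        edges = [
            (e.a, e.b, e.directed)
            for e in graph.edges
            if e.a in member_set and e.b in member_set
        ]
        upstream = {
            g: sorted(p for p in graph.parents(g) if p in member_set) for g in members
        }
        out.append(SubNetwork(anchor=anchor, members=members, edges=edges, upstream=upstream))
    return out


def upstream_set(graph: GeneGraph, gene: str) -> set[str]:
    """Direct parents via directed edges; undirected neighbors excluded."""
    if gene not in graph.nodes:
        raise KeyError(f"gene {gene} not in graph")
    return graph.parents(gene)


def residualize_on_upstream(
    expression: pd.DataFrame, gene: str, upstream: Sequence[str]
) -> np.ndarray:
    """g_tilde = g minus its least-squares projection onto [1 | upstream].

    With an empty upstream set this is the centered gene.  The result is
    exactly orthogonal to the intercept and to every upstream gene.
    """
    y = expression.loc[gene].to_numpy(dtype=float)
    n = y.size
    if not upstream:
        return y - y.mean()
    U = expression.loc[list(upstream)].to_numpy(dtype=float).T
    X = np.column_stack([np.ones(n), U])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # the projection onto the column span is still well-defined; only
        # the individual coefficients are not, and we never report them
        warnings.warn(
            f"collinear upstream design for {gene}: {list(upstream)}", stacklevel=2
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _prune_collinear(design: pd.DataFrame, protected: Sequence[str], tol: float = 1e-8) -> pd.DataFrame:
    """Drop non-protected columns that are linearly dependent on the columns
    already kept (incremental rank check); protected columns always stay."""
    kept_cols: list[str] = []
    M = np.ones((design.shape[0], 1))
    for col in list(protected) + [c for c in design.columns if c not in protected]:
        v = design[col].to_numpy(dtype=float)[:, None]
        cand = np.column_stack([M, v])
        s = np.linalg.svd(cand, compute_uv=False)
        if s[-1] > tol * s[0]:
            M = cand
            kept_cols.append(col)
        elif col in protected:
            kept_cols.append(col)  # keep; lifelines will surface the issue
        else:
            warnings.warn(f"dropping collinear covariate column {col}", stacklevel=2)
    return design[[c for c in design.columns if c in kept_cols]]


def fit_network_adjusted_cox(
    subnetwork: SubNetwork,
    expression: pd.DataFrame,  # genes x samples (adjusted log2 scale)
    survival: pd.DataFrame,  # index sample, cols os_months / event / arm
    Z: Optional[pd.DataFrame] = None,  # samples x clinical covariates
    T: Optional[pd.DataFrame] = None,  # samples x enriched cell types
    arm: Optional[str] = None,
) -> list[CoxResult]:
    """Network-adjusted Cox model for one subnetwork and one treatment arm.

    Every member gene enters residualized on its in-subnetwork upstream
    genes; upstream genes additionally enter raw.  Raw columns that are
    exactly linear in the retained design (e.g. a root gene whose raw and
    residualized copies coincide up to centering) are pruned so the partial
    likelihood stays identifiable; residualized columns are always kept so
    each member gene receives a hazard ratio.
    """
    samples = list(expression.columns)
    surv = survival.loc[samples]
    if arm is not None:
        mask = (surv["arm"] == arm).to_numpy()
        if not mask.any():
            raise ValueError(f"no samples in arm {arm!r}")
        samples = [s for s, m in zip(samples, mask) if m]
        surv = surv.loc[samples]
    if int(surv["event"].sum()) < 1:
        raise ValueError("need at least one event")

    res_cols = {}
    for g in subnetwork.members:
        res_cols[f"res__{g}"] = residualize_on_upstream(
            expression[samples], g, subnetwork.upstream.get(g, [])
        )
    raw_genes = sorted({u for ups in subnetwork.upstream.values() for u in ups})
    design = pd.DataFrame(res_cols, index=samples)
    for g in raw_genes:
        design[f"raw__{g}"] = expression.loc[g, samples].to_numpy(dtype=float)
    n_z = n_t = 0
    if Z is not None and Z.shape[1]:
        for c in Z.columns:
            design[f"z__{c}"] = Z.loc[samples, c].to_numpy(dtype=float)
        n_z = Z.shape[1]
    if T is not None and T.shape[1]:
        for c in T.columns:
            design[f"t__{c}"] = T.loc[samples, c].to_numpy(dtype=float)
        n_t = T.shape[1]
    design = _prune_collinear(design, protected=list(res_cols))
    # degenerate (constant) residual columns cannot be estimated
    for col in list(design.columns):
        if design[col].std() == 0:
            warnings.warn(f"dropping constant column {col}", stacklevel=2)
            design = design.drop(columns=[col])

    df = design.copy()
    df["os_months"] = surv["os_months"].to_numpy(dtype=float)
    df["event"] = surv["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()  # Efron tie handling is the lifelines default
    cph.fit(df, duration_col="os_months", event_col="event", fit_options={"precision": 1e-9})
    summary = cph.summary
    results = []
    for g in subnetwork.members:
        key = f"res__{g}"
        if key not in summary.index:
            continue
        row = summary.loc[key]
        results.append(
            CoxResult(
                gene=g,
                arm=arm or "all",
                coef=float(row["coef"]),
                hr=float(np.exp(row["coef"])),
                se=float(row["se(coef)"]),
                p=float(row["p"]),
                n_genes=len(subnetwork.members),
                n_covariates=n_z,
                n_cell_types=n_t,
            )
        )
    return results


# ---------------------------------------------------------------------------
# signatures and stratification
# ---------------------------------------------------------------------------


def define_signature(
    results: Sequence[CoxResult], p_threshold: float = 0.1, subnetwork_id: str = ""
) -> GeneSignature:
    """Genes with Wald p strictly below the threshold; may be empty."""
    genes = [r.gene for r in results if r.p < p_threshold]
    arm = results[0].arm if results else ""
    return GeneSignature(subnetwork=subnetwork_id, arm=arm, genes=genes)


def dichotomize_q3(values: pd.Series) -> tuple[pd.Series, float]:
    """Label each patient 'high' when the gene value strictly exceeds the
    cohort-wide third quartile (linear interpolation), else 'medium-to-low'."""
    if len(values) < 4:
        raise ValueError("need at least four patients")
    cutoff = float(np.quantile(values.to_numpy(dtype=float), 0.75))
    if values.nunique() == 1:
        warnings.warn("constant gene; all patients medium-to-low", stacklevel=2)
    labels = pd.Series(
        np.where(values > cutoff, "high", "medium-to-low"), index=values.index
    )
    return labels, cutoff


def label_signature_groups(
    gene_labels: pd.DataFrame,  # patients x signature genes, values high/medium-to-low
) -> pd.Series:
    """'high' if every signature gene is high, 'medium-to-low' if every gene
    is below, otherwise 'mixed'."""
    arr = gene_labels.to_numpy()
    all_high = (arr == "high").all(axis=1)
    all_low = (arr == "medium-to-low").all(axis=1)
    out = np.where(all_high, "high", np.where(all_low, "medium-to-low", "mixed"))
    return pd.Series(out, index=gene_labels.index)


def stratify_patients(
    expression: pd.DataFrame, signature: GeneSignature
) -> tuple[pd.Series, dict[str, float]]:
    """Q3-dichotomize each signature gene across the whole cohort (all arms)
    and combine the per-gene labels into the signature group label."""
    if not signature.genes:
        raise ValueError("empty signature")
    labels = {}
    cutoffs = {}
    for g in signature.genes:
        lab, cut = dichotomize_q3(expression.loc[g])
        labels[g] = lab
        cutoffs[g] = cut
    signature.q3_cutoffs = cutoffs
    groups = label_signature_groups(pd.DataFrame(labels))
    return groups, cutoffs


# ---------------------------------------------------------------------------
# survival estimation
# ---------------------------------------------------------------------------


def km_estimate(
    times: Sequence[float], events: Sequence[int], label: str = ""
) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood 95% CI on the
    median; median = first time the survival curve drops to <= 0.5."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size < 1:
        raise ValueError("need at least one sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "KM")
    sf = kmf.survival_function_.iloc[:, 0]
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(
        label=label,
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=at_risk,
        median=median,
        median_ci=(
            None if not np.isfinite(lo) else lo,
            None if not np.isfinite(hi) else hi,
        ),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group one-degree-of-freedom log-rank test -> (chi2, p)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
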