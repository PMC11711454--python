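"""End-to-end orchestration: synthetic cohort -> preprocessing -> cis-eQTL
-> network learning -> subnetwork survival -> immune scoring -> report.

Every stage writes its artifacts plus a manifest (inputs, config hash,
stage seed, package version) so any artifact can be regenerated from the
manifest alone.  One global seed fans out to per-stage seeds by stable
hashing of the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import netlearn, preprocess, signatures, synthcohort
from .eqtl import gene_level_permutation, select_egenes
from .graph import GeneGraph
from .immune import ImmuneSignatureDef, gene_signature_correlations, score_immune_signatures

log = logging.getLogger("netsig")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their standard defaults."""

    seed: int
    outdir: str = "netsig_run"
    # synthetic cohort
    synthetic: bool = True
    cohort: dict = field(default_factory=dict)
    # preprocessing
    sd_min: float = 0.5
    zero_frac_max: float = 0.30
    cell_zero_frac_max: float = 0.30
    cell_sd_min: float = 0.1
    pseudocount: float = 1.0
    # eQTL
    window_bp: int = 1_000_000
    max_perm: int = 10_000
    egene_alpha: float = 0.05
    # network
    n_clusters: int = 4
    alpha_grid_exponents: tuple[int, int] = (3, 22)
    fdr_q: float = 0.05
    validation_r_min: float = 0.5
    alpha_mr: float = 0.05
    max_depth: Optional[int] = 3
    holdout_fraction: float = 0.2
    # survival
    signature_p: float = 0.1
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "preprocess": True,
            "eqtl": True,
            "network": True,
            "survival": True,
            "immune": True,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        if "alpha_grid_exponents" in raw:
            raw["alpha_grid_exponents"] = tuple(raw["alpha_grid_exponents"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_grid_exponents"] = list(d["alpha_grid_exponents"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @property
    def alpha_grid(self) -> tuple[float, ...]:
        lo, hi = self.alpha_grid_exponents
        return tuple(10.0 ** (-i) for i in range(lo, hi + 1))


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seed": stage_seed(config.seed, stage),
        "version": __version__,
        **extra,
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def compositional_drop(fractions: pd.DataFrame) -> pd.DataFrame:
    """Drop the last column as reference category when the columns span the
    whole simplex (row sums ~1), which would be collinear with an intercept."""
    if fractions.shape[1] > 1 and np.allclose(fractions.sum(axis=1), 1.0, atol=1e-6):
        return fractions.iloc[:, :-1]
    return fractions


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in order; returns a dict of key artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    t0 = time.time()

    # ---- simulate -------------------------------------------------------
    if not config.synthetic:
        raise NotImplementedError("only synthetic mode is wired end-to-end; use the library API for real inputs")
    cohort_kwargs = dict(config.cohort)
    cohort_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    sim_cfg = synthcohort.SimulationConfig(**cohort_kwargs)
    cohort = synthcohort.make_cohort(sim_cfg)
    artifacts["cohort"] = cohort
    nio.write_counts_tsv(cohort.counts, outdir / "counts.tsv")
    nio.write_dosage_tsv(cohort.variants, outdir / "dosages.tsv")
    nio.write_vcf(cohort.variants, outdir / "genotypes.vcf")
    nio.write_variant_positions_tsv(cohort.variants, outdir / "variants.tsv")
    nio.write_clinical_tsv(cohort.clinical.table, outdir / "clinical.tsv")
    cohort.fractions.to_csv(outdir / "cell_fractions.tsv", sep="\t", index_label="sample_id")
    nio.write_tss_tsv(cohort.gene_tss, outdir / "gene_tss.tsv")
    (outdir / "truth.json").write_text(
        json.dumps(synthcohort.truth_to_dict(cohort.truth), indent=2)
    )
    _write_manifest(outdir, "simulate", config, {"n_samples": sim_cfg.n_samples})
    log.info("simulate done in %.1fs", time.time() - t0)

    # ---- preprocess -----------------------------------------------------
    counts, sample_report = preprocess.remove_degenerate_samples(cohort.counts)
    counts, gene_report = preprocess.filter_genes(
        counts, sd_min=config.sd_min, zero_frac_max=config.zero_frac_max
    )
    norm = preprocess.upper_quartile_normalize(counts)
    expr = preprocess.log2_transform(norm, config.pseudocount)
    enriched = preprocess.select_enriched_cell_types(
        cohort.fractions.loc[expr.values.columns],
        zero_frac_max=config.cell_zero_frac_max,
        sd_min=config.cell_sd_min,
    )
    covar = compositional_drop(cohort.fractions.loc[expr.values.columns, enriched])
    adj = preprocess.adjust_expression(expr, covar) if enriched else expr
    artifacts["expression"] = adj
    artifacts["enriched_cell_types"] = enriched
    nio.write_counts_tsv(adj.values, outdir / "expression_adjusted.tsv")
    qc = {
        "samples_removed": sample_report,
        "genes": gene_report,
        "enriched_cell_types": enriched,
    }
    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=2, default=str))
    _write_manifest(outdir, "preprocess", config, {"n_genes": adj.values.shape[0]})

    expr_df = adj.values
    samples = list(expr_df.columns)
    clinical = cohort.clinical.table.loc[samples]

    # ---- eQTL -----------------------------------------------------------
    egene_records = []
    instruments: dict[str, str] = {}
    if config.stages.get("eqtl", True):
        from .eqtl import enumerate_cis_pairs

        positions = {
            vid: (c, int(p))
            for vid, c, p in zip(cohort.variants.variant_ids, cohort.variants.chrom, cohort.variants.pos)
        }
        tss = {g: cohort.gene_tss[g] for g in expr_df.index}
        pairs = enumerate_cis_pairs(tss, positions, window_bp=config.window_bp)
        by_gene: dict[str, list[str]] = {}
        for g, vid, _ in pairs:
            by_gene.setdefault(g, []).append(vid)
        Zcov = np.column_stack(
            [
                clinical["age"].to_numpy(float),
                clinical["gender"].to_numpy(float),
                clinical["ras"].to_numpy(float),
                clinical["braf"].to_numpy(float),
            ]
        )
        dose = cohort.variants.dosages.loc[samples]
        eq_seed = stage_seed(config.seed, "eqtl")
        for g, vids in sorted(by_gene.items()):
            D = dose[vids].to_numpy(dtype=float)
            if D.std(axis=0).max() == 0:
                continue
            rec = gene_level_permutation(
                expr_df.loc[g].to_numpy(dtype=float),
                D,
                Zcov,
                gene=g,
                variant_ids=vids,
                max_perm=config.max_perm,
                seed=(eq_seed + stage_seed(eq_seed, g)) % (2**31),
            )
            egene_records.append(rec)
        egenes = select_egenes(egene_records, alpha=config.egene_alpha)
        instruments = {r.gene: r.top_variant for r in egenes}
        pd.DataFrame(
            [dataclasses.asdict(r) for r in egene_records]
        ).to_csv(outdir / "egene_records.tsv", sep="\t", index=False)
        _write_manifest(outdir, "eqtl", config, {"n_egenes": len(egenes)})
    artifacts["egene_records"] = egene_records
    artifacts["instruments"] = instruments

    # ---- network --------------------------------------------------------
    net_seed = stage_seed(config.seed, "network")
    clusters = netlearn.cluster_genes(expr_df, k=config.n_clusters, seed=net_seed)
    rng = np.random.default_rng(net_seed)
    n_hold = max(2, int(round(config.holdout_fraction * len(samples))))
    holdout = list(rng.choice(samples, size=n_hold, replace=False))
    train_samples = [s for s in samples if s not in set(holdout)]
    merged = GeneGraph(list(expr_df.index))
    alpha_diag_rows = []
    for c in sorted(set(clusters.values())):
        genes_c = [g for g in expr_df.index if clusters[g] == c]
        if len(genes_c) < 2:
            continue
        sub = expr_df.loc[genes_c, train_samples]
        fdr_edges, _ = netlearn.dense_fdr_edges(sub, q=config.fdr_q)
        path = netlearn.alpha_path(sub, grid=config.alpha_grid, max_depth=config.max_depth)
        sel_alpha, fits = netlearn.select_alpha_breakpoint(path)
        sel_skeleton = path.skeletons[path.grid.index(sel_alpha)]
        _, sepsets = netlearn.learn_skeleton_pcstable(
            sub, sel_alpha, max_depth=config.max_depth
        )
        stable = netlearn.intersect_stable_edges(fdr_edges, sel_skeleton, genes_c)
        pdag = netlearn.orient_v_structures(genes_c, stable.undirected_edge_set(), sepsets)
        for e in pdag.edges:
            ne = merged.add_edge(e.a, e.b, p=e.p, provenance=e.provenance | {"fdr_stable", "hd_stable"})
            if e.directed:
                ne.directed, ne.src = True, e.src
        for a, hd in zip(path.grid[1:], path.hds):
            alpha_diag_rows.append({"cluster": c, "alpha": a, "hd": hd, "selected": a == sel_alpha})
    if instruments:
        merged = netlearn.orient_with_instruments(
            merged,
            instruments,
            cohort.variants.dosages.loc[train_samples],
            expr_df[train_samples],
            alpha_mr=config.alpha_mr,
        )
    elif not config.stages.get("eqtl", True):
        log.warning("eqtl stage disabled: MR orientation skipped")
    merged, validation = netlearn.validate_edges_holdout(
        merged, expr_df[train_samples], expr_df[holdout], r_min=config.validation_r_min
    )
    artifacts["graph"] = merged
    artifacts["clusters"] = clusters
    artifacts["validation"] = validation
    nio.write_edge_list(merged, outdir / "network_edges.tsv")
    nio.write_sif(merged, outdir / "network.sif")
    nio.write_graphml(merged, outdir / "network.graphml")
    pd.DataFrame(alpha_diag_rows).to_csv(outdir / "alpha_path.tsv", sep="\t", index=False)
    validation.to_csv(outdir / "edge_validation.tsv", sep="\t", index=False)
    _write_manifest(outdir, "network", config, {"n_edges": len(merged)})

    # ---- survival -------------------------------------------------------
    sig_results = []
    strat_rows = []
    if config.stages.get("survival", True):
        anchor_genes = [g for g in instruments if g in merged.nodes] or list(expr_df.index[:1])
        subnets = signatures.extract_subnetworks(merged, anchor_genes)
        Z = clinical[["age", "gender", "ras", "braf"]]
        T = cohort.fractions.loc[samples, enriched] if enriched else None
        cox_rows = []
        for sn in subnets:
            if len(sn.members) < 2:
                continue
            for arm in sorted(clinical["arm"].unique()):
                try:
                    res = signatures.fit_network_adjusted_cox(
                        sn, expr_df, clinical, Z=Z, T=T, arm=arm
                    )
                except ValueError as err:
                    log.warning("Cox fit skipped for %s/%s: %s", sn.anchor, arm, err)
                    continue
                cox_rows.extend(res)
                sig = signatures.define_signature(
                    res, p_threshold=config.signature_p, subnetwork_id=sn.anchor
                )
                if sig.genes:
                    sig_results.append(sig)
                    groups, cutoffs = signatures.stratify_patients(expr_df, sig)
                    arm_samples = clinical.index[clinical["arm"] == arm]
                    g_arm = groups.loc[arm_samples]
                    hi = arm_samples[g_arm == "high"]
                    lo = arm_samples[g_arm == "medium-to-low"]
                    if len(hi) and len(lo):
                        km_hi = signatures.km_estimate(
                            clinical.loc[hi, "os_months"], clinical.loc[hi, "event"], "high"
                        )
                        km_lo = signatures.km_estimate(
                            clinical.loc[lo, "os_months"], clinical.loc[lo, "event"], "medium-to-low"
                        )
                        try:
                            chi2, p = signatures.logrank_test(
                                clinical.loc[hi, "os_months"], clinical.loc[hi, "event"],
                                clinical.loc[lo, "os_months"], clinical.loc[lo, "event"],
                            )
                        except ValueError:
                            chi2, p = np.nan, np.nan
                        strat_rows.append(
                            {
                                "subnetwork": sn.anchor,
                                "arm": arm,
                                "genes": ",".join(sig.genes),
                                "n_high": len(hi),
                                "n_low": len(lo),
                                "median_high": km_hi.median,
                                "median_low": km_lo.median,
                                "logrank_chi2": chi2,
                                "logrank_p": p,
                            }
                        )
        cox_df = pd.DataFrame([dataclasses.asdict(r) for r in cox_rows])
        cox_df.to_csv(outdir / "cox_results.tsv", sep="\t", index=False)
        (outdir / "signatures.json").write_text(
            json.dumps(
                [
                    {
                        "subnetwork": s.subnetwork,
                        "arm": s.arm,
                        "genes": s.genes,
                        "q3_cutoffs": s.q3_cutoffs,
                    }
                    for s in sig_results
                ],
                indent=2,
            )
        )
        km_cols = [
            "subnetwork", "arm", "genes", "n_high", "n_low",
            "median_high", "median_low", "logrank_chi2", "logrank_p",
        ]
        pd.DataFrame(strat_rows, columns=km_cols).to_csv(
            outdir / "km_summary.tsv", sep="\t", index=False
        )
        _write_manifest(outdir, "survival", config, {"n_signatures": len(sig_results)})
    artifacts["signatures"] = sig_results
    artifacts["km_summary"] = pd.DataFrame(strat_rows)

    # ---- immune ---------------------------------------------------------
    if config.stages.get("immune", True) and len(expr_df.index) >= 4:
        genes = list(expr_df.index)
        defs = [
            ImmuneSignatureDef("immune_a", tuple(genes[:3]), "median"),
            ImmuneSignatureDef("immune_b", tuple(genes[3:6] or genes[:2]), "geometric_mean"),
        ]
        scores = score_immune_signatures(expr_df, defs)
        focus = sorted({g for s in sig_results for g in s.genes}) or genes[:3]
        corr = gene_signature_correlations(focus, expr_df, scores)
        scores.to_csv(outdir / "immune_scores.tsv", sep="\t", index_label="sample_id")
        corr.to_csv(outdir / "immune_correlations.tsv", sep="\t", index=False)
        artifacts["immune_scores"] = scores
        artifacts["immune_correlations"] = corr
        _write_manifest(outdir, "immune", config, {"n_signatures": len(defs)})

    log.info("pipeline finished in %.1fs", time.time() - t0)
    return artifacts


def report(outdir) -> dict:
    """Regenerate summary tables and KM plots from written artifacts alone."""
    outdir = Path(outdir)
    summary: dict = {}
    cox_path = outdir / "cox_results.tsv"
    if cox_path.exists():
        try:
            summary["cox"] = pd.read_csv(cox_path, sep="\t")
        except pd.errors.EmptyDataError:
            summary["cox"] = pd.DataFrame()
    km_path = outdir / "km_summary.tsv"
    if km_path.exists():
        km = pd.read_csv(km_path, sep="\t")
        summary["km"] = km
        if km.empty:
            summary["note"] = "no signature called"
        else:
            _plot_km_summary(km, outdir / "km_medians.png")
    sig_path = outdir / "signatures.json"
    if sig_path.exists():
        sigs = json.loads(sig_path.read_text())
        summary["signatures"] = sigs
        if not sigs:
            summary["note"] = "no signature called"
    ap = outdir / "alpha_path.tsv"
    if ap.exists():
        summary["alpha_path"] = pd.read_csv(ap, sep="\t")
    return summary


def _plot_km_summary(km: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(km))
    ax.bar(x - 0.2, km["median_high"], width=0.4, label="high")
    ax.bar(x + 0.2, km["median_low"], width=0.4, label="medium-to-low")
    ax.set_xticks(x)
    ax.set_xticklabels(km["subnetwork"] + "/" + km["arm"], rotation=45, ha="right")
    ax.set_ylabel("median OS (months)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
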