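"""File formats of the pipeline's external interface.

Conventions: counts TSV is genes x samples with a header row of sample
ids; dosage TSV is samples x variants; genomic coordinates are 1-based
closed internally, BED input (0-based half-open) is converted at the
boundary; VCF is minimal v4.2 with a DS FORMAT field (dosages derived
from GT when DS is absent).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .graph import GeneGraph
from .synthcohort import VariantTable


class FormatError(ValueError):
    pass


# -- matrices ---------------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty count matrix")
    return df


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MatrixMarket triple: <prefix>.mtx / .genes.txt / .samples.txt."""
    from scipy import io as sio
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(counts.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(counts.columns) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    from scipy import io as sio

    prefix = Path(prefix)
    mat = sio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=genes, columns=samples)


def write_table_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"os_months", "event", "arm", "age", "gender", "ras", "braf"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing clinical columns {sorted(missing)}")
    return df


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


# -- genotypes --------------------------------------------------------------


def write_dosage_tsv(variants: VariantTable, path) -> None:
    variants.dosages.to_csv(path, sep="\t", index_label="sample_id")


def read_dosage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_variant_positions_tsv(variants: VariantTable, path) -> None:
    pd.DataFrame(
        {
            "variant_id": variants.variant_ids,
            "chrom": variants.chrom,
            "pos": variants.pos,
            "maf": variants.maf,
        }
    ).to_csv(path, sep="\t", index=False)


def read_variant_positions_tsv(path) -> dict[str, tuple[str, int]]:
    df = pd.read_csv(path, sep="\t")
    return {r.variant_id: (r.chrom, int(r.pos)) for r in df.itertuples()}


def write_vcf(variants: VariantTable, path) -> None:
    """Minimal VCF v4.2 with per-sample DS (dosage) and rounded GT."""
    samples = list(variants.dosages.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
    ]
    chroms = sorted(set(variants.chrom))
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    order = np.lexsort((variants.pos, np.asarray(variants.chrom, dtype=object)))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for k in order:
        vid = variants.variant_ids[k]
        doses = variants.dosages[vid].to_numpy(dtype=float)
        cells = [f"{gt_map[int(round(d))]}:{d:g}" for d in doses]
        lines.append(
            f"{variants.chrom[k]}\t{int(variants.pos[k])}\t{vid}\tA\tG\t.\tPASS\t.\tGT:DS\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_dosages(path) -> tuple[pd.DataFrame, dict[str, tuple[str, int]]]:
    """Dosage matrix (samples x variants) and positions from a VCF; DS field
    preferred, GT allele counts otherwise."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    positions: dict[str, tuple[str, int]] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = rec.genotypes  # [a0, a1, phased]
            dose = np.array([float(g[0] + g[1]) for g in gts])
        cols[vid] = dose
        positions[vid] = (rec.CHROM, int(rec.POS))
    vcf.close()
    return pd.DataFrame(cols, index=samples), positions


# -- annotations ------------------------------------------------------------


def write_tss_tsv(gene_tss: dict[str, tuple[str, int]], path) -> None:
    pd.DataFrame(
        [{"gene_id": g, "chrom": c, "tss": p} for g, (c, p) in gene_tss.items()]
    ).to_csv(path, sep="\t", index=False)


def read_tss_tsv(path) -> dict[str, tuple[str, int]]:
    """TSS table with 1-based `tss` column."""
    df = pd.read_csv(path, sep="\t")
    return {r.gene_id: (r.chrom, int(r.tss)) for r in df.itertuples()}


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """BED (0-based, half-open) -> 1-based closed intervals."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: BED row needs >= 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        out.append((chrom, start + 1, end))
    return out


def read_bed_tss(path) -> dict[str, tuple[str, int]]:
    """BED of single-base TSS features (name column = gene id)."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: TSS BED needs a name column")
        out[parts[3]] = (parts[0], int(parts[1]) + 1)
    return out


# -- networks ---------------------------------------------------------------


def write_edge_list(graph: GeneGraph, path) -> None:
    rows = []
    for e in sorted(graph.edges, key=lambda e: (e.a, e.b)):
        src = e.src if e.directed else e.a
        dst = e.dst if e.directed else e.b
        row = {
            "src": src,
            "dst": dst,
            "directed": int(e.directed),
            "p": "" if e.p is None else e.p,
        }
        for flag in ("fdr_stable", "hd_stable", "v_structure", "mr_oriented", "prior", "validated"):
            row[flag] = int(flag in e.provenance)
        rows.append(row)
    pd.DataFrame(
        rows,
        columns=[
            "src", "dst", "directed", "p",
            "fdr_stable", "hd_stable", "v_structure", "mr_oriented", "prior", "validated",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path, nodes=None) -> GeneGraph:
    df = pd.read_csv(path, sep="\t")
    if nodes is None:
        nodes = sorted(set(df["src"]) | set(df["dst"]))
    g = GeneGraph(nodes)
    flags = ("fdr_stable", "hd_stable", "v_structure", "mr_oriented", "prior", "validated")
    for r in df.itertuples():
        prov = {f for f in flags if getattr(r, f, 0)}
        p = None if pd.isna(r.p) or r.p == "" else float(r.p)
        e = g.add_edge(r.src, r.dst, p=p, provenance=prov)
        if r.directed:
            e.directed = True
            e.src = r.src
    return g


def write_sif(graph: GeneGraph, path) -> None:
    lines = []
    for e in sorted(graph.edges, key=lambda e: (e.a, e.b)):
        if e.directed:
            lines.append(f"{e.src}\tregulates\t{e.dst}")
        else:
            lines.append(f"{e.a}\tassociates\t{e.b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(graph: GeneGraph, path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for e in graph.edges:
        a, b = (e.src, e.dst) if e.directed else (e.a, e.b)
        g.add_edge(
            a,
            b,
            directed=int(e.directed),
            p=float("nan") if e.p is None else e.p,
            provenance=",".join(sorted(e.provenance)),
        )
    nx.write_graphml(g, str(path))
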