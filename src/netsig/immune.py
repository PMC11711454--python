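"""Literature immune-signature scoring and subnetwork-gene correlations.

Each immune signature (macrophages, lymphocytes, TGF-beta, IFN-gamma,
wound healing, CD8+ T cells, cytotoxicity, Tfh, B/T-cell cooperation, ...)
is a named gene list with an aggregation rule: the per-patient median of
the member genes' expression, except signatures (cytotoxicity) scored by
the geometric mean on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

AGGREGATIONS = ("median", "geometric_mean")


@dataclass(frozen=True)
class ImmuneSignatureDef:
    name: str
    genes: tuple[str, ...]
    aggregation: str = "median"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name}: empty gene list")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"signature {self.name}: unknown aggregation {self.aggregation}")


def score_immune_signatures(
    expression: pd.DataFrame,  # genes x samples, log2 scale
    defs: Sequence[ImmuneSignatureDef],
) -> pd.DataFrame:
    """Per-patient signature scores (patients x signatures).

    Median scores stay on the log2 scale of the input.  Geometric-mean
    scores are computed on the linear scale (2**log2 values, always
    positive): gm = 2**mean(log2 values).  Member genes missing from the
    expression matrix are dropped with a warning; a signature with no
    overlap is an error.
    """
    scores = {}
    for d in defs:
        present = [g for g in d.genes if g in expression.index]
        missing = [g for g in d.genes if g not in expression.index]
        if not present:
            raise KeyError(f"signature {d.name}: no genes present in expression")
        if missing:
            warnings.warn(f"signature {d.name}: dropping missing genes {missing}", stacklevel=2)
        block = expression.loc[present].to_numpy(dtype=float)
        if d.aggregation == "median":
            scores[d.name] = np.median(block, axis=0)
        else:  # geometric mean on linear scale
            scores[d.name] = np.power(2.0, block.mean(axis=0))
    return pd.DataFrame(scores, index=expression.columns)


def gene_signature_correlations(
    genes: Sequence[str],
    expression: pd.DataFrame,  # genes x samples
    scores: pd.DataFrame,  # patients x signatures
    display_threshold: float = 0.4,
) -> pd.DataFrame:
    """Pearson correlation of each subnetwork gene with each immune
    signature score, with a display mask flagging |r| > threshold.

    Returns a long table (gene, signature, r, display); constant score
    columns yield missing r.
    """
    if scores.shape[0] < 3:
        raise ValueError("need at least three patients")
    rows = []
    for g in genes:
        x = expression.loc[g, scores.index].to_numpy(dtype=float)
        for sig in scores.columns:
            y = scores[sig].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"constant column for ({g}, {sig}); r missing", stacklevel=2)
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "gene": g,
                    "signature": sig,
                    "r": r,
                    "display": bool(np.isfinite(r) and abs(r) > display_threshold),
                }
            )
    return pd.DataFrame(rows)


def read_signature_defs(path) -> list[ImmuneSignatureDef]:
    """Signature definitions from a TSV with columns name, gene, aggregation."""
    df = pd.read_csv(path, sep="\t")
    defs = []
    for name, grp in df.groupby("name", sort=True):
        aggs = grp["aggregation"].unique()
        if len(aggs) != 1:
            raise ValueError(f"signature {name}: inconsistent aggregation {list(aggs)}")
        defs.append(ImmuneSignatureDef(name=name, genes=tuple(grp["gene"]), aggregation=aggs[0]))
    return defs


def write_signature_defs(defs: Sequence[ImmuneSignatureDef], path) -> None:
    rows = [
        {"name": d.name, "gene": g, "aggregation": d.aggregation} for d in defs for g in d.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
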