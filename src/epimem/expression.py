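"""Relative expression by the ddCq method.

dCq = Cq[target] − Cq[reference gene] (technical replicates averaged on
the Cq scale first); ddCq = dCq[sample] − dCq[control]; fold change =
2^(−ddCq) with amplification efficiency fixed at 2. Biological replicates
are summarized by the geometric mean of fold changes with SEM on the log2
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionResult",
    "dcq",
    "ddcq_fold",
    "analyze_cq_table",
    "summarize_by_condition",
    "read_cq_table",
]

CQ_COLUMNS = ["sample", "condition", "gene", "tech_rep", "cq"]


@dataclass(frozen=True)
class ExpressionResult:
    """One sample × gene relative-expression record."""

    sample: str
    gene: str
    dcq: float
    ddcq: float
    fold_change: float       # 2 ** (-ddcq)
    repression_fold: float   # 1 / fold_change


def dcq(cq_target, cq_reference) -> float:
    """Cq difference to the reference gene; replicate Cqs averaged first."""
    t = float(np.mean(np.asarray(cq_target, dtype=float)))
    r = float(np.mean(np.asarray(cq_reference, dtype=float)))
    if not (math.isfinite(t) and math.isfinite(r)):
        raise ValueError("Cq values must be finite")
    return t - r


def ddcq_fold(dcq_sample: float, dcq_control: float,
              sample: str = "", gene: str = "") -> ExpressionResult:
    """Fold change relative to the control sample's dCq."""
    if not (math.isfinite(dcq_sample) and math.isfinite(dcq_control)):
        raise ValueError("dCq values must be finite")
    dd = dcq_sample - dcq_control
    fold = 2.0 ** (-dd)
    return ExpressionResult(sample, gene, dcq_sample, dd, fold, 1.0 / fold)


def analyze_cq_table(cq: pd.DataFrame, reference_gene: str = "GAPDH",
                     control_condition: str = "dCas9") -> pd.DataFrame:
    """Per-sample fold changes for every non-reference gene in a Cq table.

    The control dCq for each gene is the mean dCq over all samples of
    ``control_condition``; those samples' fold changes therefore average
    to 1 on the log2 scale.
    """
    if missing := set(CQ_COLUMNS) - set(cq.columns):
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    if not np.isfinite(cq["cq"]).all():
        raise ValueError("Cq values must be finite")
    if reference_gene not in set(cq["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if control_condition not in set(cq["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")

    mean_cq = (cq.groupby(["sample", "condition", "gene"])["cq"]
                 .mean().reset_index())
    ref = mean_cq[mean_cq["gene"] == reference_gene]
    missing_ref = set(mean_cq["sample"]) - set(ref["sample"])
    if missing_ref:
        raise ValueError(f"samples without reference gene: {sorted(missing_ref)}")
    ref_by_sample = ref.set_index("sample")["cq"]

    targets = mean_cq[mean_cq["gene"] != reference_gene].copy()
    targets["dcq"] = targets["cq"].to_numpy() - ref_by_sample.loc[targets["sample"]].to_numpy()
    control_dcq = (targets[targets["condition"] == control_condition]
                   .groupby("gene")["dcq"].mean())
    absent = set(targets["gene"]) - set(control_dcq.index)
    if absent:
        raise ValueError(f"genes without control-condition measurements: {sorted(absent)}")
    targets["ddcq"] = targets["dcq"] - control_dcq.loc[targets["gene"]].to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["ddcq"])
    targets["repression_fold"] = 1.0 / targets["fold_change"]
    out = targets[["sample", "condition", "gene", "dcq", "ddcq",
                   "fold_change", "repression_fold"]]
    return out.sort_values(["gene", "condition", "sample"]).reset_index(drop=True)


def summarize_by_condition(results: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean fold change per (condition, gene) with log2-scale SEM."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        logs = np.log2(g["fold_change"].to_numpy())
        sem = logs.std(ddof=1) / math.sqrt(len(logs)) if len(logs) > 1 else 0.0
        return pd.Series({"fold_change_geomean": float(2.0 ** logs.mean()),
                          "log2_sem": float(sem), "n": len(logs)})

    out = (results.groupby(["condition", "gene"])
                  .apply(_agg, include_groups=False).reset_index())
    out["n"] = out["n"].astype(int)
    return out


def read_cq_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str,
                                            "gene": str})
    if missing := set(CQ_COLUMNS) - set(df.columns):
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return df
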