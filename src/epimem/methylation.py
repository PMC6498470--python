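"""Beta-value differential methylation and promoter-level summaries.

Workflow: per-probe condition means over replicates → fixed Δβ threshold
(default 0.2) classifies each probe hyper/hypo/unchanged → promoter
probes (TSS1500/TSS200/5UTR) counted per gene → genes with more than
``min_probes`` (default 3, i.e. >= 4) hypermethylated promoter probes are
differentially methylated promoters (DMPs). Also: persistence overlap and
concordance between timepoints, DMP Venn partition, and intersection of
flank-expanded hypermethylated CpGs with predicted off-target sites.

This is a fixed-threshold filter, not a statistical test; no variance
filter or multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .offtarget import GenomicInterval, OffTargetSite, expand_interval, intersect

__all__ = [
    "PROMOTER_GROUPS",
    "compute_beta",
    "DifferentialResult",
    "call_differential_probes",
    "summarize_promoters",
    "OverlapResult",
    "persistence_overlap",
    "VennResult",
    "venn_dmps",
    "hyper_cpgs_near_offtargets",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_manifest",
]

PROMOTER_GROUPS = ("TSS1500", "TSS200", "5UTR")

MANIFEST_COLUMNS = ["probe", "contig", "pos_1based", "gene", "region_group"]


def compute_beta(M, U):
    """Beta value M/(M+U); positions with M+U == 0 become NaN (missing)."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be non-negative")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / total, np.nan)
    return beta if beta.ndim else float(beta)


@dataclass
class DifferentialResult:
    """Per-probe calls plus the QC tally of probes excluded for missingness."""

    calls: pd.DataFrame  # probe, mean_beta_treated, mean_beta_control, delta_beta, direction
    threshold: float
    n_excluded: int
    excluded_probes: tuple[str, ...]

    @property
    def hyper_probes(self) -> set[str]:
        c = self.calls
        return set(c.loc[c["direction"] == "hyper", "probe"])

    @property
    def hypo_probes(self) -> set[str]:
        c = self.calls
        return set(c.loc[c["direction"] == "hypo", "probe"])


def _condition_columns(samples: pd.DataFrame, condition: str) -> list[str]:
    cols = samples.loc[samples["condition"] == condition, "sample"].tolist()
    if not cols:
        raise ValueError(f"unknown or empty condition: {condition!r}")
    return cols


def call_differential_probes(betas: pd.DataFrame, samples: pd.DataFrame,
                             treated: str, control: str,
                             threshold: float = 0.2) -> DifferentialResult:
    """Classify probes by the difference of condition-mean beta values.

    hyper ⇔ Δβ >= threshold, hypo ⇔ Δβ <= −threshold, else unchanged;
    Δβ = mean(treated) − mean(control). Probes missing (NaN) in any
    required sample are excluded and tallied.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    t_cols = _condition_columns(samples, treated)
    c_cols = _condition_columns(samples, control)
    missing_cols = set(t_cols + c_cols) - set(betas.columns)
    if missing_cols:
        raise ValueError(f"samples absent from beta matrix: {sorted(missing_cols)}")
    sub = betas[t_cols + c_cols]
    bad = ((sub < 0) | (sub > 1)).any().any()
    if bad:
        raise ValueError("beta values must lie in [0, 1]")

    complete = sub.notna().all(axis=1)
    excluded = tuple(betas.index[~complete])
    kept = betas.loc[complete]
    mean_t = kept[t_cols].mean(axis=1)
    mean_c = kept[c_cols].mean(axis=1)
    delta = mean_t - mean_c
    direction = np.where(delta >= threshold, "hyper",
                         np.where(delta <= -threshold, "hypo", "unchanged"))
    calls = pd.DataFrame({
        "probe": kept.index.to_numpy(),
        "mean_beta_treated": mean_t.to_numpy(),
        "mean_beta_control": mean_c.to_numpy(),
        "delta_beta": delta.to_numpy(),
        "direction": direction,
    }).reset_index(drop=True)
    return DifferentialResult(calls, threshold, len(excluded), excluded)


def _explode_genes(manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per (probe, gene); semicolon-separated genes count toward
    every listed gene (manifest RefGene semantics)."""
    m = manifest.copy()
    m["gene"] = m["gene"].str.split(";")
    return m.explode("gene", ignore_index=True)


def summarize_promoters(calls: pd.DataFrame | DifferentialResult,
                        manifest: pd.DataFrame,
                        min_probes: int = 3,
                        include_all: bool = False) -> pd.DataFrame:
    """Per-gene promoter hypermethylation summary.

    ``is_dmp`` is true iff the gene has strictly more than ``min_probes``
    hypermethylated promoter probes. Genes with zero hyper probes are
    omitted unless ``include_all``.
    """
    if isinstance(calls, DifferentialResult):
        calls = calls.calls
    if min_probes < 0:
        raise ValueError("min_probes must be >= 0")
    mani = _explode_genes(manifest)
    mani = mani[mani["region_group"].isin(PROMOTER_GROUPS)]
    unknown = set(calls["probe"]) - set(manifest["probe"])
    if unknown:
        raise ValueError(f"calls refer to probes absent from manifest: "
                         f"{sorted(unknown)[:5]}...")
    merged = mani.merge(calls, on="probe", how="inner")
    if merged.empty:
        cols = ["gene", "n_hyper_probes", "n_promoter_probes",
                "mean_beta_treated", "mean_beta_control", "is_dmp"]
        return pd.DataFrame(columns=cols)
    per_gene_total = mani.groupby("gene")["probe"].nunique()
    grp = merged.groupby("gene")
    summary = pd.DataFrame({
        "n_hyper_probes": grp.apply(
            lambda g: int((g["direction"] == "hyper").sum()), include_groups=False),
        "mean_beta_treated": grp["mean_beta_treated"].mean(),
        "mean_beta_control": grp["mean_beta_control"].mean(),
    })
    summary["n_promoter_probes"] = per_gene_total.reindex(summary.index).astype(int)
    summary["is_dmp"] = summary["n_hyper_probes"] > min_probes
    summary = summary.reset_index()[["gene", "n_hyper_probes", "n_promoter_probes",
                                     "mean_beta_treated", "mean_beta_control", "is_dmp"]]
    if not include_all:
        summary = summary[summary["n_hyper_probes"] > 0]
    return (summary.sort_values(["n_hyper_probes", "gene"],
                                ascending=[False, True])
                   .reset_index(drop=True))


@dataclass(frozen=True)
class OverlapResult:
    overlap: frozenset[str]
    size_a: int
    size_b: int
    concordance_pct: float | None  # None (flagged) when a set is empty

    @property
    def undefined(self) -> bool:
        return self.concordance_pct is None


def persistence_overlap(calls_a: Iterable[str], calls_b: Iterable[str],
                        denominator: str = "min") -> OverlapResult:
    """Overlap of two hyper-probe sets and its concordance percentage.

    concordance = 100 · |A ∩ B| / denom, where denom is min(|A|, |B|)
    by default (also: "a", "b", "union").
    """
    a, b = set(calls_a), set(calls_b)
    overlap = frozenset(a & b)
    if not a or not b:
        return OverlapResult(overlap, len(a), len(b), None)
    denoms = {"min": min(len(a), len(b)), "a": len(a), "b": len(b),
              "union": len(a | b)}
    if denominator not in denoms:
        raise ValueError(f"denominator must be one of {sorted(denoms)}")
    return OverlapResult(overlap, len(a), len(b),
                         100.0 * len(overlap) / denoms[denominator])


@dataclass(frozen=True)
class VennResult:
    a_only: frozenset[str]
    shared: frozenset[str]
    b_only: frozenset[str]


def venn_dmps(summaries_a: pd.DataFrame, summaries_b: pd.DataFrame) -> VennResult:
    """Partition DMP genes of two timepoints into A-only / shared / B-only."""
    a = set(summaries_a.loc[summaries_a["is_dmp"], "gene"])
    b = set(summaries_b.loc[summaries_b["is_dmp"], "gene"])
    return VennResult(frozenset(a - b), frozenset(a & b), frozenset(b - a))


def hyper_cpgs_near_offtargets(calls: pd.DataFrame | DifferentialResult,
                               manifest: pd.DataFrame,
                               sites: Sequence[OffTargetSite],
                               flank: int = 146
                               ) -> list[tuple[str, OffTargetSite]]:
    """Pairs of (hyper probe, predicted site) within ``flank`` bp.

    Each hypermethylated CpG (a 1-bp point at the manifest position) is
    expanded by ±``flank`` bp and intersected with the site footprints;
    an empty list is the expected negative result.
    """
    if isinstance(calls, DifferentialResult):
        calls = calls.calls
    hyper = set(calls.loc[calls["direction"] == "hyper", "probe"])
    rows = manifest[manifest["probe"].isin(hyper)].drop_duplicates("probe")
    cpg_ivs = [expand_interval(
        GenomicInterval(r.contig, r.pos_1based - 1, r.pos_1based, payload=r.probe),
        flank=flank) for r in rows.itertuples()]
    site_ivs = [GenomicInterval(s.contig, s.start, s.end, payload=s) for s in sites]
    pairs = intersect(cpg_ivs, site_ivs)
    return sorted(((c.payload, s.payload) for c, s in pairs),
                  key=lambda t: (t[0], t[1].contig, t[1].start, t[1].strand))


# --- I/O -------------------------------------------------------------------

def read_beta_matrix(path) -> pd.DataFrame:
    """TSV, probes as rows (index), samples as columns, 'NA' for missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = "probe"
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    required = {"sample", "condition"}
    if missing := required - set(df.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "contig": str,
                                            "gene": str, "region_group": str})
    if missing := set(MANIFEST_COLUMNS) - set(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
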