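"""Integration of the three evidence layers into a per-gene report.

A candidate off-target must show *both* persistent promoter
hypermethylation (DMP at both timepoints) and reduced promoter H3K27ac;
proximity to a sequence-predicted off-target site is reported as evidence
but does not gate the classification (configurable). The declared target
gene is always labeled ``on_target``.

Classification is a partition with precedence:
on_target → candidate_off_target → methylation_only → peak_only → background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import methylation, offtarget, peaks
from .offtarget import GuideRNA, OffTargetSite

__all__ = [
    "RunConfig",
    "PipelineInputs",
    "CLASSIFICATIONS",
    "integrate",
    "run_pipeline",
    "load_inputs",
    "load_run_config",
]

CLASSIFICATIONS = ("on_target", "candidate_off_target", "methylation_only",
                   "peak_only", "background")

TRIAGE_COLUMNS = ["gene", "n_hyper_probes", "n_hyper_probes_a", "n_hyper_probes_b",
                  "is_persistent_dmp", "has_reduced_h3k27ac", "h3k27ac_fold_change",
                  "near_predicted_offtarget", "min_offtarget_distance",
                  "classification"]


@dataclass
class RunConfig:
    """Thresholds for a full run; defaults are the study's values."""

    target_gene: str
    treated_condition: str = "treated"
    control_condition: str = "dCas9"
    delta_beta: float = 0.2
    min_probes: int = 3
    tss_window: int = 1000
    top_n: int = 15_000
    fc_threshold: float = 2.0
    flank: int = 146
    max_mismatch: int = 3
    pam: str = "NGG"
    min_overlap_fraction: float = 0.5
    concordance_denominator: str = "min"
    require_offtarget_proximity: bool = False

    def __post_init__(self) -> None:
        for name in ("delta_beta", "tss_window", "top_n", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("min_probes", "flank", "max_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PipelineInputs:
    """In-memory inputs for :func:`run_pipeline`."""

    betas: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame
    annotation: pd.DataFrame
    control_peaks: Sequence[pd.DataFrame]
    treated_peaks: Sequence[pd.DataFrame]
    genome: Mapping[str, str] | object
    guides: Sequence[GuideRNA] = field(default_factory=list)


def _classify(gene: str, target: str, persistent: bool, reduced: bool,
              meth_evidence: bool, near_offtarget: bool,
              require_proximity: bool) -> str:
    if gene == target:
        return "on_target"
    if persistent and reduced and (near_offtarget or not require_proximity):
        return "candidate_off_target"
    if meth_evidence and not reduced:
        return "methylation_only"
    if reduced and not meth_evidence:
        return "peak_only"
    return "background"


def integrate(summary_a: pd.DataFrame, summary_b: pd.DataFrame,
              reduced_report: pd.DataFrame,
              offtarget_distances: Mapping[str, int],
              target_gene: str,
              annotation_genes: Sequence[str] | None = None,
              require_offtarget_proximity: bool = False) -> pd.DataFrame:
    """One row per gene in any evidence layer (the target is always present).

    ``summary_a``/``summary_b`` are promoter summaries of the two
    timepoints; ``reduced_report`` is the output of
    :func:`epimem.peaks.reduced_promoter_report`; ``offtarget_distances``
    maps gene → minimal distance (bp) from one of its hypermethylated CpGs
    to a predicted site within the flank.
    """
    if annotation_genes is not None and target_gene not in set(annotation_genes):
        raise ValueError(f"target gene {target_gene!r} absent from annotation")

    a = summary_a.set_index("gene")
    b = summary_b.set_index("gene")
    reduced_only = reduced_report[reduced_report["reduced"]] \
        if "reduced" in reduced_report.columns else reduced_report
    fc_by_gene = reduced_only.groupby("gene")["fold_change"].max() \
        if len(reduced_only) else pd.Series(dtype=float)

    universe = (set(a.index) | set(b.index) | set(fc_by_gene.index)
                | set(offtarget_distances) | {target_gene})
    rows = []
    for gene in sorted(universe):
        n_a = int(a["n_hyper_probes"].get(gene, 0))
        n_b = int(b["n_hyper_probes"].get(gene, 0))
        dmp_a = bool(a["is_dmp"].get(gene, False))
        dmp_b = bool(b["is_dmp"].get(gene, False))
        persistent = dmp_a and dmp_b
        reduced = gene in fc_by_gene.index
        fc = float(fc_by_gene.get(gene, np.nan))
        near = gene in offtarget_distances
        dist = offtarget_distances.get(gene)
        cls = _classify(gene, target_gene, persistent, reduced,
                        meth_evidence=dmp_a or dmp_b, near_offtarget=near,
                        require_proximity=require_offtarget_proximity)
        rows.append((gene, max(n_a, n_b), n_a, n_b, persistent, reduced, fc,
                     near, dist, cls))
    report = pd.DataFrame(rows, columns=TRIAGE_COLUMNS)
    report["_order"] = report["classification"].map(
        {c: i for i, c in enumerate(CLASSIFICATIONS)})
    report = (report.sort_values(["_order", "n_hyper_probes", "gene"],
                                 ascending=[True, False, True])
                    .drop(columns="_order").reset_index(drop=True))
    return report


def _gene_offtarget_distances(pairs: Sequence[tuple[str, OffTargetSite]],
                              manifest: pd.DataFrame) -> dict[str, int]:
    """Min distance (bp) between a gene's hyper CpGs and predicted sites."""
    pos_by_probe = manifest.drop_duplicates("probe").set_index("probe")["pos_1based"]
    genes_by_probe = (manifest.assign(gene=manifest["gene"].str.split(";"))
                      .explode("gene").groupby("probe")["gene"].apply(list))
    out: dict[str, int] = {}
    for probe, site in pairs:
        c = int(pos_by_probe[probe]) - 1  # 0-based CpG cytosine
        if c < site.start:
            d = site.start - c
        elif c >= site.end:
            d = c - (site.end - 1)
        else:
            d = 0
        for gene in genes_by_probe[probe]:
            if gene not in out or d < out[gene]:
                out[gene] = d
    return out


def run_pipeline(cfg: RunConfig, inputs: PipelineInputs,
                 outdir: str | Path | None = None) -> dict:
    """Full composition: methylation (per timepoint) → Venn/persistence →
    reduced-promoter report → off-target search and flank intersection →
    triage. Returns a bundle dict; writes TSVs plus a threshold log when
    ``outdir`` is given. Deterministic for fixed inputs.
    """
    samples = inputs.samples
    if "timepoint_days" in samples.columns:
        treated_tps = sorted(samples.loc[
            samples["condition"] == cfg.treated_condition, "timepoint_days"].unique())
    else:
        treated_tps = [None]
    if not treated_tps:
        raise ValueError(f"no samples for condition {cfg.treated_condition!r}")

    per_tp: dict = {}
    for tp in treated_tps:
        if tp is None:
            sheet = samples
        else:
            at_tp = samples[samples["timepoint_days"] == tp]
            ctrl = at_tp[at_tp["condition"] == cfg.control_condition]
            sheet = at_tp if len(ctrl) else pd.concat(
                [at_tp, samples[samples["condition"] == cfg.control_condition]])
        diff = methylation.call_differential_probes(
            inputs.betas, sheet, cfg.treated_condition, cfg.control_condition,
            threshold=cfg.delta_beta)
        summary = methylation.summarize_promoters(
            diff, inputs.manifest, min_probes=cfg.min_probes)
        per_tp[tp] = {"diff": diff, "summary": summary}

    tps = list(per_tp)
    tp_a, tp_b = tps[0], tps[-1]
    summary_a = per_tp[tp_a]["summary"]
    summary_b = per_tp[tp_b]["summary"]
    venn = methylation.venn_dmps(summary_a, summary_b)
    overlap = methylation.persistence_overlap(
        per_tp[tp_a]["diff"].hyper_probes, per_tp[tp_b]["diff"].hyper_probes,
        denominator=cfg.concordance_denominator)

    persistent_hypers = sorted(overlap.overlap)
    sites: list[OffTargetSite] = []
    for guide in inputs.guides:
        g = GuideRNA(guide.name, guide.protospacer, cfg.pam)
        sites.extend(offtarget.find_sites(inputs.genome, g, cfg.max_mismatch))
    pseudo_calls = pd.DataFrame({"probe": persistent_hypers,
                                 "direction": "hyper"})
    pairs = methylation.hyper_cpgs_near_offtargets(
        pseudo_calls, inputs.manifest, sites, flank=cfg.flank)
    offtarget_distances = _gene_offtarget_distances(pairs, inputs.manifest)

    reduced = peaks.reduced_promoter_report(
        inputs.control_peaks, inputs.treated_peaks, inputs.annotation,
        n=cfg.top_n, window=cfg.tss_window, fc_threshold=cfg.fc_threshold,
        min_overlap_fraction=cfg.min_overlap_fraction, include_all=True)

    triage_report = integrate(
        summary_a, summary_b, reduced, offtarget_distances, cfg.target_gene,
        annotation_genes=inputs.annotation["gene"].tolist(),
        require_offtarget_proximity=cfg.require_offtarget_proximity)

    bundle = {
        "config": cfg,
        "timepoints": tps,
        "per_timepoint": per_tp,
        "venn": venn,
        "persistence": overlap,
        "sites": sites,
        "offtarget_pairs": pairs,
        "offtarget_distances": offtarget_distances,
        "reduced_report": reduced,
        "triage": triage_report,
    }
    if outdir is not None:
        _write_bundle(bundle, inputs, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, inputs: PipelineInputs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    for tp, d in bundle["per_timepoint"].items():
        tag = f"d{tp}" if tp is not None else "all"
        d["diff"].calls.to_csv(outdir / f"probe_calls_{tag}.tsv", **fmt)
        d["summary"].to_csv(outdir / f"promoter_summary_{tag}.tsv", **fmt)

    venn = bundle["venn"]
    with open(outdir / "venn.tsv", "w") as fh:
        fh.write("gene\tmembership\n")
        for label, genes in (("a_only", venn.a_only), ("shared", venn.shared),
                             ("b_only", venn.b_only)):
            for g in sorted(genes):
                fh.write(f"{g}\t{label}\n")

    ov = bundle["persistence"]
    with open(outdir / "persistence.tsv", "w") as fh:
        fh.write("size_a\tsize_b\toverlap\tconcordance_pct\n")
        pct = "NA" if ov.concordance_pct is None else f"{ov.concordance_pct:.4f}"
        fh.write(f"{ov.size_a}\t{ov.size_b}\t{len(ov.overlap)}\t{pct}\n")

    offtarget.write_sites_bed(bundle["sites"], outdir / "offtarget_sites.bed")
    with open(outdir / "offtarget_pairs.tsv", "w") as fh:
        fh.write("probe\tcontig\tsite_start\tsite_end\tstrand\tmismatches\n")
        for probe, s in bundle["offtarget_pairs"]:
            fh.write(f"{probe}\t{s.contig}\t{s.start}\t{s.end}\t{s.strand}\t{s.mismatches}\n")

    bundle["reduced_report"].to_csv(outdir / "reduced_promoters.tsv", **fmt)
    bundle["triage"].to_csv(outdir / "triage.tsv", **fmt)

    cfg = bundle["config"]
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("# thresholds and settings used for this run\n")
        for k, v in sorted(dataclasses.asdict(cfg).items()):
            fh.write(f"{k}={v}\n")
        fh.write(f"timepoints={bundle['timepoints']}\n")
        fh.write("note=peak signal normalization is counts-per-million of the "
                 "narrowPeak signalValue column; no occupancy model is refit\n")


# --- file-based entry points -----------------------------------------------

def load_run_config(path: str | Path) -> tuple[RunConfig, dict]:
    """Read a YAML run config; returns (RunConfig, paths section)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    paths = raw.pop("paths", {})
    return RunConfig(**raw), paths


def load_inputs(paths: Mapping[str, object]) -> PipelineInputs:
    """Load pipeline inputs from a path mapping (see README for keys)."""
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(paths["genome"]), "fasta")}
    guides = []
    gpath = paths.get("guides")
    if gpath:
        gdf = pd.read_csv(gpath, sep="\t")
        for r in gdf.itertuples():
            guides.append(GuideRNA(r.name, r.protospacer,
                                   getattr(r, "pam", "NGG")))
    return PipelineInputs(
        betas=methylation.read_beta_matrix(paths["betas"]),
        samples=methylation.read_sample_sheet(paths["samples"]),
        manifest=methylation.read_manifest(paths["manifest"]),
        annotation=pd.read_csv(paths["annotation"], sep="\t"),
        control_peaks=[peaks.read_narrowpeak(p) for p in paths["control_peaks"]],
        treated_peaks=[peaks.read_narrowpeak(p) for p in paths["treated_peaks"]],
        genome=genome,
        guides=guides,
    )
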