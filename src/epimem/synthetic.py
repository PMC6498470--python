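"""Synthetic data with planted ground truth.

Generates toy genomes, gene annotations with promoter CpG probes, beta
matrices with planted hypermethylated promoters (defaults: treated mean
0.48 vs background 0.07), replicate H3K27ac-style peak sets with planted
promoter-peak losses, bisulfite-converted amplicon clone reads, and qPCR
Cq tables — each paired with a :class:`GroundTruth` record so downstream
modules can be validated for exact recovery.

Determinism: a single config seed is split hierarchically per generator
(seed, crc32(tag)), so each artifact can be regenerated independently and
fixed seeds yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite import AmpliconReference
from .peaks import NARROWPEAK_COLUMNS, write_narrowpeak

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Genome",
    "make_genome",
    "make_annotation",
    "simulate_beta_matrix",
    "simulate_peaks",
    "simulate_bisulfite_clones",
    "simulate_cq",
    "generate_scenario",
    "Scenario",
    "write_fasta",
]

PROMOTER_GROUPS = ("TSS1500", "TSS200", "5UTR")

# Gene layout constants (bp). Each gene occupies a slot: 1600 bp upstream
# clearance + promoter windows + 500 bp of 5'UTR; background peaks live in
# the inter-gene gap, > 1 kb + half a peak width away from every TSS.
_TSS_OFFSET = 1800
_MIN_SLOT = 4500
_PROMOTER_PEAK_HALFWIDTH = 200
_BACKGROUND_PEAK_HALFWIDTH = 150


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Child generator for one artifact, derived from the global seed."""
    return np.random.default_rng([seed, zlib.crc32(tag.encode())])


@dataclass
class SimConfig:
    """Knobs for every generator; defaults mirror the study's scale."""

    seed: int = 0
    n_contigs: int = 1
    contig_length: int = 60_000
    gc_fraction: float = 0.5
    n_genes: int = 12
    probes_per_promoter: int = 14
    n_replicates_per_condition: int = 2
    background_beta_mean: float = 0.07
    planted_beta_mean: float = 0.48
    beta_precision: float = 50.0
    planted_dmr_genes: tuple[str, ...] = ()
    transient_dmr_genes: tuple[str, ...] = ()
    planted_lost_peak_genes: tuple[str, ...] = ()
    lost_peak_ratio: float = 4.0
    conversion_rate: float = 0.99
    clone_count: int = 20
    n_background_peaks: int = 60
    promoter_peak_signal: float = 40.0
    background_peak_signal: float = 20.0
    peak_jitter_sd: float = 0.1
    cq_noise_sd: float = 0.15
    timepoints: tuple[int, ...] = (17, 24)
    control_condition: str = "dCas9"
    treated_condition: str = "treated"

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "background_beta_mean", "planted_beta_mean",
                     "conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_contigs", "contig_length", "n_genes",
                     "probes_per_promoter", "n_replicates_per_condition",
                     "clone_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        if self.lost_peak_ratio <= 0:
            raise ValueError("lost_peak_ratio must be > 0")
        self.planted_dmr_genes = tuple(self.planted_dmr_genes)
        self.transient_dmr_genes = tuple(self.transient_dmr_genes)
        self.planted_lost_peak_genes = tuple(self.planted_lost_peak_genes)


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    dmr_genes: set[str] = field(default_factory=set)
    transient_dmr_genes: set[str] = field(default_factory=set)
    lost_peak_genes: set[str] = field(default_factory=set)
    per_probe_planted_delta: dict[str, float] = field(default_factory=dict)
    clone_methylation_probs: dict[int, float] = field(default_factory=dict)
    lost_peak_ratio: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dmr_genes": sorted(self.dmr_genes),
            "transient_dmr_genes": sorted(self.transient_dmr_genes),
            "lost_peak_genes": sorted(self.lost_peak_genes),
            "per_probe_planted_delta": dict(sorted(self.per_probe_planted_delta.items())),
            "clone_methylation_probs": {str(k): v for k, v in sorted(self.clone_methylation_probs.items())},
            "lost_peak_ratio": self.lost_peak_ratio,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


@dataclass
class Genome:
    """Named contigs; sequences are plain upper-case strings."""

    contigs: dict[str, str]

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        write_fasta(self.contigs.items(), path, width=width)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def make_genome(cfg: SimConfig) -> Genome:
    """I.i.d. random contigs at the requested GC fraction."""
    if cfg.contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    rng = _rng(cfg.seed, "genome")
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs = {}
    for c in range(cfg.n_contigs):
        draw = rng.choice(bases, size=cfg.contig_length, p=probs)
        contigs[f"contig{c + 1}"] = draw.tobytes().decode()
    return Genome(contigs)


def _split_groups(n_probes: int) -> list[str]:
    """Cycle TSS1500 → TSS200 → 5UTR; 14 probes gives the 5/5/4 split."""
    return [PROMOTER_GROUPS[i % 3] for i in range(n_probes)]


def _group_window(group: str, tss: int, strand: str) -> tuple[int, int]:
    """1-based inclusive window of a promoter group, strand-aware.

    TSS1500: 1500–201 bp upstream; TSS200: 200–1 bp upstream;
    5UTR: 1–500 bp downstream of the TSS.
    """
    if strand == "+":
        windows = {"TSS1500": (tss - 1500, tss - 201),
                   "TSS200": (tss - 200, tss - 1),
                   "5UTR": (tss + 1, tss + 500)}
    else:
        windows = {"TSS1500": (tss + 201, tss + 1500),
                   "TSS200": (tss + 1, tss + 200),
                   "5UTR": (tss - 500, tss - 1)}
    return windows[group]


def make_annotation(genome: Genome, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes and promoter CpG probes; plants CG dinucleotides in-place.

    Returns (annotation, manifest): annotation has columns
    (gene, contig, tss, strand); manifest has
    (probe, contig, pos_1based, gene, region_group). Positions are the
    1-based coordinate of the CpG cytosine on the forward strand.
    """
    per_contig = math.ceil(cfg.n_genes / cfg.n_contigs)
    names = list(genome.contigs)
    slot = (min(len(genome.contigs[n]) for n in names) - 1000) // per_contig
    if slot < _MIN_SLOT:
        raise ValueError(
            f"genome too small for {cfg.n_genes} genes: slot {slot} < {_MIN_SLOT} bp")

    ann_rows, probe_rows = [], []
    buffers = {n: bytearray(genome.contigs[n].encode()) for n in names}
    gene_idx = 0
    for contig in names:
        for k in range(per_contig):
            if gene_idx >= cfg.n_genes:
                break
            gene = f"GENE{gene_idx + 1:04d}"
            strand = "+" if gene_idx % 2 == 0 else "-"
            tss = k * slot + _TSS_OFFSET  # 1-based; >=1600 bp clearance both sides
            ann_rows.append((gene, contig, tss, strand))

            groups = _split_groups(cfg.probes_per_promoter)
            buf = buffers[contig]
            seen: set[int] = set()
            per_group: dict[str, int] = {}
            for g in groups:
                per_group[g] = per_group.get(g, 0) + 1
            probe_no = 0
            for g in PROMOTER_GROUPS:
                cnt = per_group.get(g, 0)
                if cnt == 0:
                    continue
                lo, hi = _group_window(g, tss, strand)
                positions = np.linspace(lo, hi - 1, cnt).round().astype(int)
                for pos in positions:
                    pos = int(pos)
                    while pos in seen or pos - 1 in seen or pos + 1 in seen:
                        pos += 3  # keep planted CGs from clobbering each other
                    seen.add(pos)
                    i = pos - 1  # 0-based index of the C
                    buf[i:i + 2] = b"CG"
                    probe_no += 1
                    probe_rows.append((f"cg_{gene}_{probe_no:02d}", contig,
                                       pos, gene, g))
            gene_idx += 1

    for n in names:
        genome.contigs[n] = buffers[n].decode()

    annotation = pd.DataFrame(ann_rows, columns=["gene", "contig", "tss", "strand"])
    manifest = pd.DataFrame(probe_rows,
                            columns=["probe", "contig", "pos_1based", "gene", "region_group"])
    return annotation, manifest


def _check_planted(cfg: SimConfig, genes: Sequence[str]) -> None:
    known = set(genes)
    for attr in ("planted_dmr_genes", "transient_dmr_genes", "planted_lost_peak_genes"):
        extra = set(getattr(cfg, attr)) - known
        if extra:
            raise ValueError(f"{attr} not in annotation: {sorted(extra)}")


def _draw_beta(rng: np.random.Generator, mean: float, precision: float,
               size: int) -> np.ndarray:
    if not np.isfinite(precision):  # zero-variance limit
        return np.full(size, mean)
    a = mean * precision
    b = (1.0 - mean) * precision
    if a == 0.0:
        return np.zeros(size)
    if b == 0.0:
        return np.ones(size)
    return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)


def simulate_beta_matrix(manifest: pd.DataFrame, cfg: SimConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Beta matrix (probes × samples) plus sample sheet and ground truth.

    Control samples draw every probe from the background Beta distribution;
    treated samples draw probes of planted genes from the planted
    distribution. Genes in ``transient_dmr_genes`` are planted only at the
    earliest timepoint. Samples cover condition × timepoint × replicate.
    """
    _check_planted(cfg, manifest["gene"].unique())
    rng = _rng(cfg.seed, "betas")
    persistent = set(cfg.planted_dmr_genes)
    transient = set(cfg.transient_dmr_genes)
    first_tp = min(cfg.timepoints)

    probes = manifest["probe"].to_numpy()
    genes = manifest["gene"].to_numpy()
    n = len(probes)

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for tp in cfg.timepoints:
        for cond in (cfg.control_condition, cfg.treated_condition):
            for rep in range(1, cfg.n_replicates_per_condition + 1):
                sample = f"{cond}_d{tp}_r{rep}"
                sheet_rows.append((sample, cond, tp, rep))
                vals = _draw_beta(rng, cfg.background_beta_mean,
                                  cfg.beta_precision, n)
                if cond == cfg.treated_condition:
                    planted = persistent | (transient if tp == first_tp else set())
                    mask = np.isin(genes, sorted(planted))
                    if mask.any():
                        vals[mask] = _draw_beta(rng, cfg.planted_beta_mean,
                                                cfg.beta_precision, int(mask.sum()))
                columns[sample] = vals

    betas = pd.DataFrame(columns, index=pd.Index(probes, name="probe"))
    samples = pd.DataFrame(sheet_rows,
                           columns=["sample", "condition", "timepoint_days", "replicate"])
    delta = cfg.planted_beta_mean - cfg.background_beta_mean
    truth = GroundTruth(
        dmr_genes=set(persistent),
        transient_dmr_genes=set(transient),
        per_probe_planted_delta={p: delta for p, g in zip(probes, genes)
                                 if g in persistent},
    )
    return betas, samples, truth


def _background_peak_centers(annotation: pd.DataFrame, cfg: SimConfig,
                             slot: int) -> list[tuple[str, int]]:
    """Deterministic background-peak centers in inter-gene gaps, each
    > 1 kb + half a peak width away from every TSS."""
    centers: list[tuple[str, int]] = []
    per_gap = math.ceil(cfg.n_background_peaks / len(annotation))
    lo_off = _TSS_OFFSET + 1000 + _BACKGROUND_PEAK_HALFWIDTH + 50
    hi_off = slot - 200
    for _, row in annotation.iterrows():
        base = row.tss - _TSS_OFFSET  # slot start
        offs = np.linspace(lo_off, hi_off, per_gap).round().astype(int)
        for o in offs:
            centers.append((row.contig, int(base + o)))
    centers = centers[: cfg.n_background_peaks]
    return centers


def simulate_peaks(annotation: pd.DataFrame, cfg: SimConfig
                   ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Replicate narrowPeak-style peak sets with planted promoter losses.

    Every sample has a promoter peak per gene (summit at the TSS) plus
    shared background peaks. In treated replicates, peaks of
    ``planted_lost_peak_genes`` are attenuated by ``lost_peak_ratio``.
    Signal tiers (promoter 40, background 20, default 4-fold loss → 10)
    guarantee that attenuated peaks rank below every background peak, so a
    top-N cut excluding them behaves like the upstream peak caller.
    """
    _check_planted(cfg, annotation["gene"].unique())
    rng = _rng(cfg.seed, "peaks")
    lost = set(cfg.planted_lost_peak_genes)
    tss_sorted = annotation.sort_values(["contig", "tss"])
    slots = tss_sorted.groupby("contig")["tss"].diff().dropna()
    slot = int(slots.min()) if len(slots) else _MIN_SLOT
    bg_centers = _background_peak_centers(annotation, cfg, slot)

    def jitter(size: int) -> np.ndarray:
        return np.exp(rng.normal(0.0, cfg.peak_jitter_sd, size=size))

    peaksets: dict[str, pd.DataFrame] = {}
    for cond in ("control", "treated"):
        for rep in range(1, cfg.n_replicates_per_condition + 1):
            rows = []
            jp = jitter(len(annotation))
            for i, row in enumerate(annotation.itertuples()):
                signal = cfg.promoter_peak_signal * jp[i]
                if cond == "treated" and row.gene in lost:
                    signal /= cfg.lost_peak_ratio
                tss0 = row.tss - 1
                start = max(0, tss0 - _PROMOTER_PEAK_HALFWIDTH)
                end = tss0 + _PROMOTER_PEAK_HALFWIDTH
                rows.append((row.contig, start, end,
                             f"{cond}_r{rep}_prom_{row.gene}",
                             int(min(1000, signal * 10)), ".",
                             round(float(signal), 4), -1.0, -1.0, tss0 - start))
            jb = jitter(len(bg_centers))
            for i, (contig, center) in enumerate(bg_centers):
                signal = cfg.background_peak_signal * jb[i]
                start = center - _BACKGROUND_PEAK_HALFWIDTH
                end = center + _BACKGROUND_PEAK_HALFWIDTH
                rows.append((contig, start, end,
                             f"{cond}_r{rep}_bg_{i + 1:03d}",
                             int(min(1000, signal * 10)), ".",
                             round(float(signal), 4), -1.0, -1.0,
                             _BACKGROUND_PEAK_HALFWIDTH))
            df = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
            peaksets[f"{cond}_rep{rep}"] = df.sort_values(
                ["chrom", "start", "end"]).reset_index(drop=True)

    truth = GroundTruth(lost_peak_genes=set(lost), lost_peak_ratio=cfg.lost_peak_ratio)
    return peaksets, truth


def simulate_bisulfite_clones(amplicon: AmpliconReference, cfg: SimConfig,
                              methylation_probs: float | Sequence[float] | Mapping[int, float] = 0.54,
                              ) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Bisulfite-converted clone reads from an amplicon reference.

    Each clone: non-CpG Cs convert to T with probability
    ``conversion_rate``; the C of each CpG stays C (methylated) with its
    per-CpG probability, else reads T.
    """
    seq = amplicon.sequence
    cpgs = amplicon.cpg_positions
    if not seq:
        raise ValueError("empty amplicon")
    if not cpgs:
        raise ValueError("amplicon contains no CpG")
    if isinstance(methylation_probs, Mapping):
        probs = [float(methylation_probs[i]) for i in range(len(cpgs))]
    elif isinstance(methylation_probs, (int, float)):
        probs = [float(methylation_probs)] * len(cpgs)
    else:
        probs = [float(p) for p in methylation_probs]
        if len(probs) != len(cpgs):
            raise ValueError("one methylation probability per CpG required")
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError("methylation probabilities must be in [0, 1]")

    rng = _rng(cfg.seed, "clones")
    cpg_set = set(cpgs)
    non_cpg_c = [i for i, b in enumerate(seq) if b == "C" and i not in cpg_set]
    reads = []
    for k in range(cfg.clone_count):
        out = list(seq)
        conv = rng.random(len(non_cpg_c)) < cfg.conversion_rate
        for i, c in zip(non_cpg_c, conv):
            if c:
                out[i] = "T"
        meth = rng.random(len(cpgs)) < np.asarray(probs)
        for i, m in zip(cpgs, meth):
            if not m:
                out[i] = "T"
        reads.append((f"clone{k + 1:03d}", "".join(out)))
    truth = GroundTruth(clone_methylation_probs={i: p for i, p in enumerate(probs)})
    return reads, truth


def simulate_cq(design: pd.DataFrame, cfg: SimConfig,
                reference_gene: str = "GAPDH",
                target_baseline: float = 25.0,
                reference_baseline: float = 20.0,
                n_technical: int = 3) -> pd.DataFrame:
    """Cq table from a (sample, condition, gene, true_fold_change) design.

    Cq[target] = baseline − log2(fold change) + Gaussian noise; the
    reference gene is constant up to noise; triplicate wells by default.
    """
    required = {"sample", "condition", "gene", "true_fold_change"}
    if missing := required - set(design.columns):
        raise ValueError(f"design missing columns: {sorted(missing)}")
    if (design["true_fold_change"] <= 0).any():
        raise ValueError("fold changes must be > 0")
    rng = _rng(cfg.seed, "cq")
    rows = []
    for _, r in design.iterrows():
        true_cq = target_baseline - math.log2(r.true_fold_change)
        for t in range(1, n_technical + 1):
            rows.append((r["sample"], r.condition, r.gene, t,
                         true_cq + rng.normal(0.0, cfg.cq_noise_sd)))
    for sample, cond in design[["sample", "condition"]].drop_duplicates().itertuples(index=False):
        for t in range(1, n_technical + 1):
            rows.append((sample, cond, reference_gene, t,
                         reference_baseline + rng.normal(0.0, cfg.cq_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "tech_rep", "cq"])


# ---------------------------------------------------------------------------
# end-to-end scenario


@dataclass
class Scenario:
    """All inputs for a full pipeline run, with planted truth attached."""

    cfg: SimConfig
    genome: Genome
    annotation: pd.DataFrame
    manifest: pd.DataFrame
    betas: pd.DataFrame
    samples: pd.DataFrame
    peaksets: dict[str, pd.DataFrame]
    guides: list  # list[offtarget.GuideRNA]
    truth: GroundTruth
    #: top-N that keeps all control peaks but drops attenuated treated peaks
    suggested_top_n: int


def generate_scenario(cfg: SimConfig, outdir: str | Path | None = None) -> Scenario:
    """Genome + annotation + betas + peaks + one guide, optionally on disk.

    The guide's protospacer is lifted from an intergenic stretch of the
    genome and an AGG PAM is planted after it, so the search always has
    one exact on-target hit far from every promoter probe.
    """
    from .offtarget import GuideRNA  # local import to avoid cycle at import time

    genome = make_genome(cfg)
    annotation, manifest = make_annotation(genome, cfg)

    # plant a guide target 600 bp before the contig end (intergenic)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    pos = len(seq) - 600
    proto = seq[pos:pos + 19]
    genome.contigs[contig] = seq[:pos + 19] + "AGG" + seq[pos + 22:]
    guides = [GuideRNA("g1", proto)]

    betas, samples, truth_b = simulate_beta_matrix(manifest, cfg)
    peaksets, truth_p = simulate_peaks(annotation, cfg)
    truth = GroundTruth(
        dmr_genes=truth_b.dmr_genes,
        transient_dmr_genes=truth_b.transient_dmr_genes,
        lost_peak_genes=truth_p.lost_peak_genes,
        per_probe_planted_delta=truth_b.per_probe_planted_delta,
        lost_peak_ratio=truth_p.lost_peak_ratio,
    )
    # the margin must cover the attenuated treated peaks (lowest signals)
    margin = max(5, len(cfg.planted_lost_peak_genes))
    top_n = cfg.n_genes + cfg.n_background_peaks - margin

    scenario = Scenario(cfg, genome, annotation, manifest, betas, samples,
                        peaksets, guides, truth, suggested_top_n=top_n)
    if outdir is not None:
        write_scenario(scenario, outdir)
    return scenario


def write_scenario(s: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    s.genome.write_fasta(paths["genome"])

    paths["annotation_bed"] = out / "annotation.bed"
    with open(paths["annotation_bed"], "w") as fh:
        for r in s.annotation.itertuples():
            fh.write(f"{r.contig}\t{r.tss - 1}\t{r.tss}\t{r.gene}\t0\t{r.strand}\n")
    paths["annotation"] = out / "annotation.tsv"
    s.annotation.to_csv(paths["annotation"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.tsv"
    s.manifest.to_csv(paths["manifest"], sep="\t", index=False)

    paths["betas"] = out / "betas.tsv"
    s.betas.to_csv(paths["betas"], sep="\t", na_rep="NA", float_format="%.6f")
    paths["samples"] = out / "samples.tsv"
    s.samples.to_csv(paths["samples"], sep="\t", index=False)

    for name, df in s.peaksets.items():
        p = out / f"peaks_{name}.narrowPeak"
        write_narrowpeak(df, p)
        paths[f"peaks_{name}"] = p

    paths["guides"] = out / "guides.tsv"
    with open(paths["guides"], "w") as fh:
        fh.write("name\tprotospacer\tpam\n")
        for g in s.guides:
            fh.write(f"{g.name}\t{g.protospacer}\t{g.pam_pattern}\n")

    paths["ground_truth"] = out / "ground_truth.json"
    s.truth.to_json(paths["ground_truth"])

    paths["config"] = out / "sim_config.json"
    Path(paths["config"]).write_text(
        json.dumps(dataclasses.asdict(s.cfg), indent=1, default=list) + "\n")
    return paths
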