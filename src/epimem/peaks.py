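"""Peak-set logic downstream of peak calling.

Top-N robust-peak selection, naive-overlap replicate reproducibility,
control-specific peaks, TSS-proximal assignment, library-size-normalized
fold change, and the composed reduced-promoter report with its >2-fold
classifier. All interval logic is 0-based half-open; adjacency is never
overlap.

Note: signals are compared after counts-per-million scaling of the
narrowPeak signalValue column; no occupancy model is refit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NARROWPEAK_COLUMNS",
    "read_narrowpeak",
    "write_narrowpeak",
    "top_n_peaks",
    "reproducible_peaks",
    "control_specific_peaks",
    "tss_proximal",
    "normalized_fold_change",
    "PromoterPeakChange",
    "reduced_promoter_report",
    "peak_centers",
]

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signalValue", "pValue", "qValue", "summit"]


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                     dtype={"chrom": str, "name": str, "strand": str})
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: empty/inverted peak interval")
    if (df["signalValue"] < 0).any():
        raise ValueError(f"{path}: negative signalValue")
    return df


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    df[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def top_n_peaks(peaks: pd.DataFrame, n: int = 15_000) -> pd.DataFrame:
    """The ``n`` highest-signal peaks (ties: score, then coordinate)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = peaks.sort_values(
        ["signalValue", "score", "chrom", "start", "end"],
        ascending=[False, False, True, True, True], kind="mergesort")
    kept = ordered.head(n)
    return kept.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _overlap_lengths(start: int, end: int, others: pd.DataFrame) -> np.ndarray:
    ov = np.minimum(end, others["end"].to_numpy()) - np.maximum(start, others["start"].to_numpy())
    return np.maximum(ov, 0)


def _max_overlap(peak, others: pd.DataFrame) -> int:
    same = others[others["chrom"] == peak.chrom]
    if same.empty:
        return 0
    return int(_overlap_lengths(peak.start, peak.end, same).max())


def reproducible_peaks(replicates: Sequence[pd.DataFrame],
                       min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Peaks of replicate 1 supported by every other replicate.

    A peak is supported when some peak in each other replicate overlaps it
    by at least ``min_overlap_fraction`` of the peak's own length (and by
    at least 1 bp).
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates")
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    first = replicates[0]
    keep = []
    for peak in first.itertuples():
        need = max(1.0, min_overlap_fraction * (peak.end - peak.start))
        if all(_max_overlap(peak, other) >= need for other in replicates[1:]):
            keep.append(peak.Index)
    return first.loc[keep].reset_index(drop=True)


def control_specific_peaks(control: pd.DataFrame, treated: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition control peaks into (specific, shared) by >= 1 bp overlap
    against the treated set."""
    specific_idx, shared_idx = [], []
    for peak in control.itertuples():
        (shared_idx if _max_overlap(peak, treated) > 0 else specific_idx).append(peak.Index)
    return (control.loc[specific_idx].reset_index(drop=True),
            control.loc[shared_idx].reset_index(drop=True))


def peak_centers(peaks: pd.DataFrame) -> np.ndarray:
    """Summit position when recorded (summit >= 0), else the midpoint
    (rounded down)."""
    mid = peaks["start"] + (peaks["end"] - peaks["start"]) // 2
    summit = peaks["start"] + peaks["summit"]
    return np.where(peaks["summit"].to_numpy() >= 0, summit, mid).astype(np.int64)


def tss_proximal(peaks: pd.DataFrame, annotation: pd.DataFrame,
                 window: int = 1000) -> pd.DataFrame:
    """Peaks whose center lies within ±``window`` bp of a TSS.

    ``annotation`` columns: gene, contig, tss (1-based), strand. Distances
    are transcription-oriented (upstream negative). Genes with multiple
    TSS rows are deduplicated per (gene, peak), keeping the smallest
    |distance|.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    centers = peak_centers(peaks)
    rows = []
    for g in annotation.itertuples():
        tss0 = g.tss - 1
        same = peaks["chrom"] == g.contig
        d_genomic = centers - tss0
        d = d_genomic if g.strand == "+" else -d_genomic
        hit = same.to_numpy() & (np.abs(d) <= window)
        for i in np.nonzero(hit)[0]:
            rows.append((g.gene, int(d[i]), peaks.index[i]))
    if not rows:
        return peaks.iloc[0:0].assign(gene=pd.Series(dtype=str),
                                      tss_distance=pd.Series(dtype=int))
    hits = pd.DataFrame(rows, columns=["gene", "tss_distance", "_peak_idx"])
    hits["_abs"] = hits["tss_distance"].abs()
    hits = (hits.sort_values(["gene", "_peak_idx", "_abs", "tss_distance"])
                .drop_duplicates(["gene", "_peak_idx"]))
    out = peaks.loc[hits["_peak_idx"]].reset_index(drop=True)
    out["gene"] = hits["gene"].to_numpy()
    out["tss_distance"] = hits["tss_distance"].to_numpy()
    return out.sort_values(["chrom", "start", "gene"]).reset_index(drop=True)


@dataclass(frozen=True)
class PromoterPeakChange:
    """Normalized control/treated signal at one promoter peak."""

    control_signal_norm: float
    treated_signal_norm: float
    fold_change: float  # control / treated; inf when treated is 0

    @property
    def reduced(self) -> bool:
        return self.fold_change > 2.0


def normalized_fold_change(control_signal, treated_signal,
                           control_library: float, treated_library: float
                           ) -> PromoterPeakChange:
    """Counts-per-million scaling, replicates averaged before the ratio.

    ``control_signal``/``treated_signal`` may be scalars or per-replicate
    sequences (paired with scalar or per-replicate library sizes).
    """
    def norm(signal, library) -> float:
        s = np.atleast_1d(np.asarray(signal, dtype=float))
        lib = np.broadcast_to(np.asarray(library, dtype=float), s.shape)
        if (lib <= 0).any():
            raise ValueError("library sizes must be > 0")
        return float(np.mean(s / lib * 1e6))

    c = norm(control_signal, control_library)
    t = norm(treated_signal, treated_library)
    fc = math.inf if t == 0 else c / t
    return PromoterPeakChange(c, t, fc)


def _signal_at(peak, replicates: Sequence[pd.DataFrame]) -> list[float]:
    """Per-replicate signal of the best-overlapping peak (0 when absent)."""
    out = []
    for rep in replicates:
        same = rep[rep["chrom"] == peak.chrom]
        if same.empty:
            out.append(0.0)
            continue
        ov = _overlap_lengths(peak.start, peak.end, same)
        out.append(float(same["signalValue"].to_numpy()[np.argmax(ov)]) if ov.max() > 0 else 0.0)
    return out


def reduced_promoter_report(control_reps: Sequence[pd.DataFrame],
                            treated_reps: Sequence[pd.DataFrame],
                            annotation: pd.DataFrame,
                            n: int = 15_000,
                            window: int = 1000,
                            fc_threshold: float = 2.0,
                            min_overlap_fraction: float = 0.5,
                            control_libraries: Sequence[float] | None = None,
                            treated_libraries: Sequence[float] | None = None,
                            include_all: bool = False) -> pd.DataFrame:
    """Promoter peaks lost in treatment with > ``fc_threshold`` signal loss.

    Pipeline: reproducible peaks per condition (when replicated) → top-N →
    control-specific → TSS-proximal → normalized fold change → filter.
    Treated signal at a control-specific peak is looked up in the *full*
    treated replicate sets, so attenuated-below-top-N peaks still yield a
    finite ratio. Library sizes default to each replicate's total
    signalValue. Ranked by fold change, then control signal.
    """
    control_reps = list(control_reps)
    treated_reps = list(treated_reps)
    if not control_reps or not treated_reps:
        raise ValueError("need >= 1 control and >= 1 treated peak set")
    if control_libraries is None:
        control_libraries = [float(df["signalValue"].sum()) for df in control_reps]
    if treated_libraries is None:
        treated_libraries = [float(df["signalValue"].sum()) for df in treated_reps]

    def merged(reps: Sequence[pd.DataFrame]) -> pd.DataFrame:
        return (reproducible_peaks(reps, min_overlap_fraction)
                if len(reps) > 1 else reps[0])

    ctrl_top = top_n_peaks(merged(control_reps), n)
    trt_top = top_n_peaks(merged(treated_reps), n)
    specific, _shared = control_specific_peaks(ctrl_top, trt_top)
    prox = tss_proximal(specific, annotation, window)

    records = []
    for peak in prox.itertuples():
        change = normalized_fold_change(
            _signal_at(peak, control_reps), _signal_at(peak, treated_reps),
            np.asarray(control_libraries), np.asarray(treated_libraries))
        records.append((peak.gene, peak.chrom, peak.start, peak.end,
                        peak.tss_distance,
                        change.control_signal_norm, change.treated_signal_norm,
                        change.fold_change, change.fold_change > fc_threshold))
    report = pd.DataFrame(records, columns=[
        "gene", "chrom", "start", "end", "tss_distance",
        "control_signal_norm", "treated_signal_norm", "fold_change", "reduced"])
    report = report.sort_values(["fold_change", "control_signal_norm"],
                                ascending=[False, False]).reset_index(drop=True)
    if include_all:
        return report
    return report[report["reduced"]].reset_index(drop=True)
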