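"""Per-CpG methylation calling from bisulfite-converted amplicon clones.

Clone reads are assumed pre-aligned to the unconverted reference and
top-strand oriented. At each CpG cytosine, C reads as methylated, T as
unmethylated, anything else as ambiguous. Conversion efficiency — the
fraction of non-CpG reference cytosines read as T — is computed per clone
as QC; a clone with efficiency 0 is an unconverted artifact and is
flagged as such even when no efficiency floor is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmpliconReference",
    "CloneCall",
    "CloneMethylationMatrix",
    "AggregateResult",
    "locate_cpgs",
    "call_clone",
    "call_clones",
    "aggregate",
    "render_lollipop",
    "plot_lollipop",
    "read_fasta",
]

METHYLATED, UNMETHYLATED, AMBIGUOUS = "M", "U", "?"
_GLYPHS = {METHYLATED: "●", UNMETHYLATED: "○", AMBIGUOUS: "?"}


def locate_cpgs(reference: str) -> list[int]:
    """0-based indices i with reference[i:i+2] == 'CG', ascending."""
    seq = reference.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("reference must contain only A/C/G/T")
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


@dataclass(frozen=True)
class AmpliconReference:
    """Unconverted amplicon sequence with its CpG cytosine positions."""

    name: str
    sequence: str
    cpg_positions: tuple[int, ...] = ()
    coordinates: tuple[str, int] | None = None  # (contig, 1-based start)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty amplicon sequence")
        if not self.cpg_positions:
            object.__setattr__(self, "cpg_positions", tuple(locate_cpgs(seq)))
        else:
            object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
            for i in self.cpg_positions:
                if seq[i:i + 2] != "CG":
                    raise ValueError(f"position {i} is not a CpG cytosine")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass(frozen=True)
class CloneCall:
    """Per-CpG states of one clone plus its conversion-efficiency QC."""

    name: str
    states: tuple[str, ...]
    conversion_efficiency: float | None  # None when no non-CpG C exists
    passes_qc: bool
    fully_unconverted: bool


def call_clone(read: str, reference: AmpliconReference,
               min_conversion: float = 0.0, name: str = "clone") -> CloneCall:
    """Call one pre-aligned clone read against the reference."""
    read = read.upper()
    if len(read) != len(reference.sequence):
        raise ValueError(
            f"read length {len(read)} != reference length {len(reference.sequence)}")
    states = []
    for i in reference.cpg_positions:
        if read[i] == "C":
            states.append(METHYLATED)
        elif read[i] == "T":
            states.append(UNMETHYLATED)
        else:
            states.append(AMBIGUOUS)

    cpg = set(reference.cpg_positions)
    non_cpg_c = [i for i, b in enumerate(reference.sequence)
                 if b == "C" and i not in cpg]
    if non_cpg_c:
        eff = sum(read[i] == "T" for i in non_cpg_c) / len(non_cpg_c)
    else:
        eff = None
    fully_unconverted = eff == 0.0
    passes = eff is None or eff >= min_conversion
    return CloneCall(name, tuple(states), eff, passes, fully_unconverted)


@dataclass
class CloneMethylationMatrix:
    """Clones × CpG sites state matrix."""

    reference: AmpliconReference
    clones: list[CloneCall] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [c.states for c in self.clones],
            index=pd.Index([c.name for c in self.clones], name="clone"),
            columns=[f"CpG{i + 1}" for i in range(self.reference.n_cpgs)])

    def __len__(self) -> int:
        return len(self.clones)


def call_clones(reads: Iterable[tuple[str, str]], reference: AmpliconReference,
                min_conversion: float = 0.0) -> CloneMethylationMatrix:
    matrix = CloneMethylationMatrix(reference)
    for name, seq in reads:
        matrix.clones.append(call_clone(seq, reference, min_conversion, name=name))
    return matrix


@dataclass(frozen=True)
class AggregateResult:
    """Per-site percentages and the two overall summaries."""

    per_site_pct: tuple[float, ...]       # NaN where no informative call
    mean_of_site_pcts: float              # primary overall average
    pooled_pct: float                     # pooled over all informative calls
    n_clones_used: int
    n_clones_excluded: int
    uninformative_sites: tuple[int, ...]  # 0-based CpG indices


def aggregate(matrix: CloneMethylationMatrix) -> AggregateResult:
    """Per-CpG % methylation (ambiguous excluded) and overall averages.

    The primary overall average is the mean over per-site percentages;
    the pooled fraction over all informative calls is also reported.
    """
    used = [c for c in matrix.clones if c.passes_qc]
    excluded = len(matrix.clones) - len(used)
    if not used:
        raise ValueError("no clones pass QC")
    states = np.array([c.states for c in used])
    meth = (states == METHYLATED).sum(axis=0)
    unmeth = (states == UNMETHYLATED).sum(axis=0)
    informative = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(informative > 0, 100.0 * meth / informative, np.nan)
    uninformative = tuple(int(i) for i in np.nonzero(informative == 0)[0])
    mean_sites = float(np.nanmean(per_site)) if (informative > 0).any() else float("nan")
    pooled = (100.0 * meth.sum() / informative.sum()
              if informative.sum() > 0 else float("nan"))
    return AggregateResult(tuple(float(x) for x in per_site), mean_sites,
                           float(pooled), len(used), excluded, uninformative)


def render_lollipop(matrix: CloneMethylationMatrix) -> str:
    """Text grid: one row per clone, ● methylated / ○ unmethylated / ? ambiguous."""
    if not matrix.clones:
        raise ValueError("empty matrix")
    return "\n".join("".join(_GLYPHS[s] for s in c.states) for c in matrix.clones)


def plot_lollipop(matrix: CloneMethylationMatrix, path: str | Path) -> None:
    """Lollipop-style figure: filled/open circles per clone and CpG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_clones, n_sites = len(matrix.clones), matrix.reference.n_cpgs
    fig, ax = plt.subplots(figsize=(max(2, 0.3 * n_sites), max(2, 0.25 * n_clones)))
    for y, clone in enumerate(matrix.clones):
        for x, s in enumerate(clone.states):
            face = {"M": "black", "U": "white", "?": "lightgray"}[s]
            ax.scatter(x, n_clones - 1 - y, s=60, facecolors=face,
                       edgecolors="black", zorder=3)
    ax.set_xticks(range(n_sites))
    ax.set_xticklabels([f"CpG{i + 1}" for i in range(n_sites)], rotation=90)
    ax.set_yticks([])
    ax.set_xlim(-0.5, n_sites - 0.5)
    ax.set_ylim(-0.5, n_clones - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) records via Biopython."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
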