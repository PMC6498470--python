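"""Mismatch-tolerant protospacer search with an IUPAC PAM constraint.

Enumerates, on both strands of a genome, every window whose Hamming
distance to a guide's protospacer is at most ``max_mismatch`` and whose
immediately-3' window (on the protospacer-matching strand) matches the
PAM pattern. Also provides the flank-expansion and interval-intersection
primitives used by the methylation/off-target overlap analyses.

Conventions
-----------
* Coordinates are 0-based half-open and always reported on the forward
  strand; the protospacer footprint excludes the PAM.
* Mismatches are counted in the protospacer only, never in the PAM.
* ``N`` in the genome counts as a mismatch at every protospacer position
  and fails every PAM position whose pattern code is not ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GuideRNA",
    "OffTargetSite",
    "GenomicInterval",
    "revcomp",
    "find_sites",
    "expand_interval",
    "intersect",
    "sites_to_intervals",
    "write_sites_bed",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC code -> set of genome bases it accepts. ``N`` accepts anything,
#: including an ambiguous genome base; every other code rejects genome N.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideRNA:
    """A guide defined by its protospacer and a PAM pattern (default NGG)."""

    name: str
    protospacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if not proto or set(proto) - set("ACGT"):
            raise ValueError(f"protospacer must be non-empty A/C/G/T only: {self.protospacer!r}")
        if not 17 <= len(proto) <= 23:
            raise ValueError(f"protospacer length {len(proto)} outside 17–23 nt")
        if not self.pam_pattern or set(self.pam_pattern) - set(IUPAC_SETS):
            raise ValueError(f"PAM pattern must be IUPAC codes: {self.pam_pattern!r}")


@dataclass(frozen=True)
class OffTargetSite:
    """Genomic protospacer match (footprint excludes the PAM)."""

    contig: str
    start: int  # 0-based, forward strand
    end: int    # half-open
    strand: str
    mismatches: int
    matched_sequence: str  # protospacer-strand orientation
    pam_sequence: str      # protospacer-strand orientation
    guide: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if self.end - self.start != len(self.matched_sequence):
            raise ValueError("footprint length does not match sequence")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with an opaque payload (not compared)."""

    contig: str
    start: int
    end: int
    payload: Any = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


def _contig_items(genome: Any) -> Iterable[tuple[str, str]]:
    """Accept a mapping name->sequence or an object with a ``contigs`` mapping."""
    contigs = getattr(genome, "contigs", genome)
    if not isinstance(contigs, Mapping):
        raise TypeError("genome must be a mapping of contig name to sequence")
    return contigs.items()


def _pam_ok(arr: np.ndarray, offsets: np.ndarray, pattern: str) -> np.ndarray:
    """Vectorized IUPAC PAM check at ``offsets`` (start of the PAM window)."""
    ok = np.ones(len(offsets), dtype=bool)
    for j, code in enumerate(pattern):
        allowed = np.frombuffer("".join(sorted(IUPAC_SETS[code])).encode(), dtype=np.uint8)
        ok &= np.isin(arr[offsets + j], allowed)
    return ok


def _hamming_all(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Hamming distance of every length-``len(pattern)`` window to ``pattern``."""
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    n = len(arr) - len(pat) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, len(pat))
    return (windows != pat).sum(axis=1)


def find_sites(genome: Any, guide: GuideRNA, max_mismatch: int) -> list[OffTargetSite]:
    """Enumerate all PAM-adjacent protospacer matches with ≤ ``max_mismatch``.

    Returns sites sorted by (contig, start, strand); '+' sorts before '-'.
    Contigs shorter than protospacer + PAM contribute no sites.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    proto = guide.protospacer
    pam = guide.pam_pattern
    L, P = len(proto), len(pam)
    sites: list[OffTargetSite] = []
    for name, seq in _contig_items(genome):
        seq = seq.upper()
        if len(seq) < L + P:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)

        # plus strand: protospacer at i, PAM at [i+L, i+L+P)
        mm = _hamming_all(arr, proto)[: len(arr) - L - P + 1]
        cand = np.nonzero(mm <= max_mismatch)[0]
        if cand.size:
            keep = _pam_ok(arr, cand + L, pam)
            for i in cand[keep]:
                i = int(i)
                sites.append(OffTargetSite(name, i, i + L, "+", int(mm[i]),
                                           seq[i:i + L], seq[i + L:i + L + P],
                                           guide.name))

        # minus strand: revcomp(protospacer) at i, revcomp(PAM) at [i-P, i)
        mm_rc = _hamming_all(arr, revcomp(proto))
        cand = np.nonzero(mm_rc <= max_mismatch)[0]
        cand = cand[cand >= P]
        if cand.size:
            keep = _pam_ok(arr, cand - P, revcomp(pam))
            for i in cand[keep]:
                i = int(i)
                sites.append(OffTargetSite(name, i, i + L, "-", int(mm_rc[i]),
                                           revcomp(seq[i:i + L]),
                                           revcomp(seq[i - P:i]),
                                           guide.name))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def expand_interval(interval: GenomicInterval, flank: int = 146,
                    contig_length: int | None = None) -> GenomicInterval:
    """Widen an interval by ``flank`` bp on each side, clipped at 0 (and
    at ``contig_length`` when known)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(0, interval.start - flank)
    end = interval.end + flank
    if contig_length is not None:
        end = min(end, contig_length)
    return GenomicInterval(interval.contig, start, end, interval.payload)


def intersect(a: Sequence[GenomicInterval],
              b: Sequence[GenomicInterval]) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (x in a, y in b) on the same contig with >= 1 bp overlap
    under half-open semantics, in (index-in-a, index-in-b) order."""
    by_contig: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        by_contig.setdefault(iv.contig, []).append((j, iv))
    for lst in by_contig.values():
        lst.sort(key=lambda t: t[1].start)

    pairs: list[tuple[int, int, GenomicInterval, GenomicInterval]] = []
    for i, x in enumerate(a):
        for j, y in by_contig.get(x.contig, ()):
            if y.start >= x.end:
                break
            if y.end > x.start:
                pairs.append((i, j, x, y))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return [(x, y) for _, _, x, y in pairs]


def sites_to_intervals(sites: Iterable[OffTargetSite]) -> list[GenomicInterval]:
    return [GenomicInterval(s.contig, s.start, s.end, payload=s) for s in sites]


def write_sites_bed(sites: Iterable[OffTargetSite], path: str) -> None:
    """BED6+2: contig, start, end, guide name, mismatches, strand, seq, PAM."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.guide or 'guide'}\t"
                     f"{s.mismatches}\t{s.strand}\t{s.matched_sequence}\t{s.pam_sequence}\n")
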