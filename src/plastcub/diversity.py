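"""Sliding-window nucleotide diversity and hypervariable-region calling.

Nucleotide diversity pi in a window is the mean, over all sequence pairs,
of the proportion of differing sites among compared sites. Sites carrying
a gap or ambiguous base in ANY row are excluded window-wise (complete
deletion), so every pair shares the same site set and the denominator is
the number of usable sites, not the nominal window length.

Hypervariable regions (HVRs) are runs of windows whose pi exceeds the
track mean plus two sample standard deviations; overlapping or abutting
above-threshold windows merge into a single region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "Window",
    "WindowDiversityTrack",
    "HvrRegion",
    "load_alignment",
    "window_pi",
    "hvr_threshold",
    "call_hvrs",
]


@dataclass
class Alignment:
    """Gapped equal-length rows over an ordered taxon list."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must be parallel")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])


def load_alignment(path: str | Path) -> Alignment:
    """Load an aligned FASTA file."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    return Alignment(taxa=[r.id for r in aln], rows=[str(r.seq) for r in aln])


@dataclass
class Window:
    start: int
    end: int
    n_sites_used: int
    pi: float

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class WindowDiversityTrack:
    window_length: int
    step: int
    windows: list[Window]
    mean_pi: float = math.nan
    sd_pi: float = math.nan
    threshold: float = math.nan


@dataclass
class HvrRegion:
    start: int
    end: int
    peak_pi: float
    n_windows: int
    member_windows: list[Window] = field(default_factory=list)


_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode(alignment: Alignment) -> np.ndarray:
    """Rows as uint8 codes; anything outside A/C/G/T (gap, N) becomes 255."""
    arr = np.frombuffer(
        "".join(alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(alignment.rows), alignment.length).copy()
    out = np.full_like(arr, 255)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _column_pi_terms(block: np.ndarray) -> tuple[int, float]:
    """(usable sites, summed pairwise differences) for one window block."""
    n = block.shape[0]
    valid = (block != 255).all(axis=0)
    used = block[:, valid]
    n_sites = used.shape[1]
    if n_sites == 0:
        return 0, 0.0
    # pairwise differences per column from base multiplicities
    diffs = 0.0
    pairs_total = n * (n - 1) / 2
    same = np.zeros(n_sites)
    for code in range(4):
        cnt = (used == code).sum(axis=0)
        same += cnt * (cnt - 1) / 2
    diffs = float((pairs_total - same).sum())
    return n_sites, diffs


def window_pi(
    alignment: Alignment, window_length: int = 600, step: int = 200
) -> WindowDiversityTrack:
    """Sliding-window pi with complete deletion of gapped/ambiguous columns.

    Windows start at column 0 and advance by ``step``; a trailing short
    window is kept if at least half the window length, else dropped.
    Windows with zero usable sites get missing pi. Track mean/SD (sample
    SD, ddof=1) and the mean + 2 SD threshold summarize defined windows.
    """
    if window_length < 1 or step < 1:
        raise ValueError("window_length and step must be positive")
    coded = _encode(alignment)
    n = alignment.length
    n_rows = coded.shape[0]
    pairs = n_rows * (n_rows - 1) / 2

    windows: list[Window] = []
    for start in range(0, n, step):
        end = min(start + window_length, n)
        if end - start < window_length:
            if end - start >= window_length / 2:
                logger.info("keeping trailing window [%d, %d) (%d bp)", start, end, end - start)
            else:
                logger.info("dropping trailing window [%d, %d) (%d bp)", start, end, end - start)
                break
        n_sites, diffs = _column_pi_terms(coded[:, start:end])
        pi = diffs / (pairs * n_sites) if n_sites else math.nan
        windows.append(Window(start=start, end=end, n_sites_used=n_sites, pi=pi))

    track = WindowDiversityTrack(window_length=window_length, step=step, windows=windows)
    defined = [w.pi for w in windows if not math.isnan(w.pi)]
    if len(defined) >= 2:
        track.mean_pi = float(np.mean(defined))
        track.sd_pi = float(np.std(defined, ddof=1))
        track.threshold = track.mean_pi + 2.0 * track.sd_pi
    elif len(defined) == 1:
        track.mean_pi = defined[0]
    return track


def hvr_threshold(track: WindowDiversityTrack) -> float:
    """Mean + 2 sample standard deviations of the defined window pi values."""
    defined = [w.pi for w in track.windows if not math.isnan(w.pi)]
    if len(defined) < 2:
        raise ValueError("threshold needs >= 2 defined windows")
    return float(np.mean(defined) + 2.0 * np.std(defined, ddof=1))


def call_hvrs(track: WindowDiversityTrack, threshold: float | None = None) -> list[HvrRegion]:
    """Merge above-threshold windows (strict pi > threshold) into regions.

    Overlapping or abutting window spans form one region whose peak pi is
    the maximum member window pi.
    """
    thr = hvr_threshold(track) if threshold is None else threshold
    hot = [w for w in track.windows if not math.isnan(w.pi) and w.pi > thr]
    hot.sort(key=lambda w: w.start)
    regions: list[HvrRegion] = []
    for w in hot:
        if regions and w.start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.peak_pi = max(r.peak_pi, w.pi)
            r.n_windows += 1
            r.member_windows.append(w)
        else:
            regions.append(
                HvrRegion(start=w.start, end=w.end, peak_pi=w.pi, n_windows=1,
                          member_windows=[w])
            )
    return regions


def lift_to_taxon(alignment: Alignment, taxon: str, column: int) -> int:
    """Alignment column -> ungapped coordinate in the named taxon's sequence."""
    row = alignment.rows[alignment.taxa.index(taxon)]
    return sum(1 for c in row[:column] if c != "-")


def track_rows(track: WindowDiversityTrack) -> list[dict]:
    return [
        {"start": w.start, "end": w.end, "midpoint": w.midpoint,
         "n_sites": w.n_sites_used, "pi": w.pi}
        for w in track.windows
    ]


def hvrs_to_bed(regions: Sequence[HvrRegion], path: str | Path) -> None:
    """HVRs as BED (0-based half-open), score = round(peak_pi * 1000)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            fh.write(f"aln\t{r.start}\t{r.end}\tHVR_{i}\t{round(r.peak_pi * 1000)}\n")
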