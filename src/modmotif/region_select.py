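"""Control comparison and top-K window extraction.

The test track is compared position-wise with an unmodified negative
control so that systematic caller errors cancel; fixed-width windows are
then ranked by their summed differential fraction (both strands pooled)
and the K highest-scoring, pairwise-disjoint windows are extracted with
their plus-strand sequences for motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tracks_io import FractionTrack, Genome

log = logging.getLogger(__name__)


@dataclass
class Window:
    """A scored fixed-width genomic interval (0-based, half-open)."""

    start: int
    end: int
    score: float
    seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if len(self.seq) != self.end - self.start:
            raise ValueError("window sequence length must equal end - start")


def differential_track(test: FractionTrack, control: FractionTrack) -> FractionTrack:
    """Pointwise ``max(0, test - control)``; missing control counts as 0.

    Positions missing in the test track stay missing, so the output never
    claims signal where the caller produced none.
    """
    if test.genome_name != control.genome_name:
        raise ValueError(
            f"genome mismatch: {test.genome_name!r} vs {control.genome_name!r}"
        )
    if test.length != control.length:
        raise ValueError("test and control tracks have different lengths")
    out = FractionTrack(test.genome_name, test.length)
    for t_arr, c_arr, o_arr in (
        (test.plus, control.plus, out.plus),
        (test.minus, control.minus, out.minus),
    ):
        diff = t_arr - np.nan_to_num(c_arr, nan=0.0)
        np.clip(diff, 0.0, None, out=diff)  # NaN (missing test) propagates
        o_arr[:] = diff
    return out


def top_windows(
    track: FractionTrack, genome: Genome, width: int = 10, k: int = 100
) -> list[Window]:
    """Greedy top-``k`` non-overlapping windows by summed fraction.

    A window's score is the sum of all non-missing fractions on both
    strands inside ``[start, start + width)``.  Candidates at every start
    are ranked by descending score (ties: smaller start) and selected
    greedily subject to disjointness; only positive-score windows are
    returned, with a warning if fewer than ``k`` exist.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    L = len(genome)
    if L < width:
        raise ValueError("genome shorter than window width")
    if track.length != L:
        raise ValueError("track length does not match genome")

    pooled = np.nan_to_num(track.plus, nan=0.0) + np.nan_to_num(track.minus, nan=0.0)
    kernel = np.ones(width)
    scores = np.convolve(pooled, kernel, mode="valid")  # score per start

    starts = np.arange(scores.size)
    order = np.lexsort((starts, -scores))  # descending score, then smaller start

    occupied = np.zeros(L, dtype=bool)
    selected: list[Window] = []
    for idx in order:
        s = int(starts[idx])
        if scores[idx] <= 0:
            break
        if occupied[s : s + width].any():
            continue
        occupied[s : s + width] = True
        selected.append(Window(s, s + width, float(scores[idx]), genome.fetch(s, s + width)))
        if len(selected) == k:
            break
    if len(selected) < k:
        log.warning(
            "only %d positive-score non-overlapping windows available (k=%d)",
            len(selected), k,
        )
    return selected


def window_sequences(windows: list[Window], genome: Genome) -> list[str]:
    """Plus-strand sequences in window order.

    Strand resolution is deliberately deferred to the two-strand motif
    search.  Windows spanning the origin are only legal on circular
    genomes.
    """
    seqs = []
    for w in windows:
        if w.start < 0 or (w.end > len(genome) and not genome.circular):
            raise ValueError(f"window [{w.start}, {w.end}) outside genome")
        seqs.append(genome.fetch(w.start, w.end))
    return seqs


def write_bed(windows: list[Window], genome_name: str, path) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            fh.write(
                f"{genome_name}\t{w.start}\t{w.end}\twindow_{i + 1}\t{w.score!r}\t.\n"
            )


def write_window_fasta(windows: list[Window], path) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            fh.write(f">window_{i + 1}|{w.start}-{w.end}|score={w.score:.4f}\n{w.seq}\n")
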