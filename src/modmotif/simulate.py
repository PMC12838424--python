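"""Synthetic genomes, planted-motif fraction tracks, and read qualities.

The generator emulates the data a nanopore modification caller produces
after mapping: for every adenine on either strand a fraction of modified
reads in [0, 1].  Adenines at a fixed offset inside a planted motif
(default the A of ATC, on both strands) draw from a high Beta
distribution; all other adenines — and the entire negative control —
draw from a low background Beta.  Because nanopore signal localises a
modified base only to within roughly five bases, each planted fraction
is geometrically blurred onto covered neighbours within ±2 positions of
the same strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

from .tracks_io import FractionTrack, Genome, reverse_complement, write_fasta, write_track

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Mean / sd of the average per-read quality score by library preparation,
#: truncated to [1, 30].  Native DNA reads are low quality (median ~7.5,
#: i.e. ~20% error); PCR-amplified reads are cleaner (median ~11.5).
QSCORE_PARAMS = {"native": (7.5, 1.5), "pcr": (11.5, 2.0)}


@dataclass
class SimulationConfig:
    """Study conditions for the planted-motif benchmark.

    Defaults define the standard synthetic dataset: a 200 kb uniform
    genome with every ATC adenine modified at Beta(8, 2) (mean 0.8),
    background and control adenines at Beta(1, 19) (mean 0.05), blurred
    over ±2 bases with geometric decay 0.5.
    """

    genome_length: int = 200_000
    gc: float = 0.5
    motif: str = "ATC"
    mod_offset: int = 0
    p_hi_alpha: float = 8.0
    p_hi_beta: float = 2.0
    p_bg_alpha: float = 1.0
    p_bg_beta: float = 19.0
    blur_halfwidth: int = 2
    blur_decay: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if not set(self.motif) <= set("ACGT"):
            raise ValueError("motif must be over A/C/G/T")
        if not 0 <= self.mod_offset < len(self.motif):
            raise ValueError("mod_offset must lie within the motif")
        if self.motif[self.mod_offset] != "A":
            raise ValueError(
                "the modified base (motif[mod_offset]) must be an adenine"
            )
        for shape in (self.p_hi_alpha, self.p_hi_beta, self.p_bg_alpha, self.p_bg_beta):
            if shape <= 0:
                raise ValueError("Beta shape parameters must be > 0")
        if self.blur_halfwidth < 0:
            raise ValueError("blur_halfwidth must be >= 0")
        if not 0.0 <= self.blur_decay <= 1.0:
            raise ValueError("blur_decay must be in [0, 1]")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.genome_length < 0:
            raise ValueError("genome_length must be >= 0")


def simulate_genome(length: int, gc: float, seed: int) -> Genome:
    """I.i.d. genome with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p)) if length else ""
    return Genome("sim", seq)


def _occurrences(seq: str, motif: str) -> list[int]:
    """Start positions of all (overlapping) exact occurrences."""
    return [m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq)]


def planted_positions(genome: Genome, config: SimulationConfig) -> dict[str, list[int]]:
    """Ground-truth modified-adenine positions per strand.

    Plus-strand motif occurrences modify the adenine at ``mod_offset``;
    minus-strand occurrences (reverse-complement footprints on the plus
    strand) modify the paired adenine of the minus strand, recorded at its
    plus-strand coordinate.
    """
    w = len(config.motif)
    plus = [s + config.mod_offset for s in _occurrences(genome.seq, config.motif)]
    minus = [
        s + w - 1 - config.mod_offset
        for s in _occurrences(genome.seq, reverse_complement(config.motif))
    ]
    return {"+": plus, "-": minus}


def simulate_tracks(
    genome: Genome, config: SimulationConfig
) -> tuple[FractionTrack, FractionTrack]:
    """Planted-motif test track and background-only control track.

    Only adenine-bearing positions are covered: plus-strand adenines on
    ``+`` and plus-strand thymines (minus-strand adenines) on ``-``.
    """
    if len(genome) == 0:
        raise ValueError("genome must be non-empty")
    seq = np.frombuffer(genome.seq.encode(), dtype="S1")
    a_plus = np.flatnonzero(seq == b"A")
    a_minus = np.flatnonzero(seq == b"T")

    rng_bg, rng_hi, rng_ctl = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    ]

    test = FractionTrack.for_genome(genome)
    control = FractionTrack.for_genome(genome)

    test.plus[a_plus] = rng_bg.beta(config.p_bg_alpha, config.p_bg_beta, a_plus.size)
    test.minus[a_minus] = rng_bg.beta(config.p_bg_alpha, config.p_bg_beta, a_minus.size)

    sites = planted_positions(genome, config)
    if not sites["+"] and not sites["-"]:
        log.warning("motif %r does not occur in genome %r", config.motif, genome.name)

    planted_draws: dict[str, np.ndarray] = {}
    for strand, arr in (("+", test.plus), ("-", test.minus)):
        pos = np.asarray(sites[strand], dtype=int)
        draws = rng_hi.beta(config.p_hi_alpha, config.p_hi_beta, pos.size)
        arr[pos] = draws
        planted_draws[strand] = draws

    # Positional blur: raise covered same-strand neighbours to
    # max(current, f * decay^d) without ever exceeding 1.
    L = len(genome)
    for strand, arr in (("+", test.plus), ("-", test.minus)):
        for p, f in zip(sites[strand], planted_draws[strand]):
            for d in range(1, config.blur_halfwidth + 1):
                spread = f * config.blur_decay**d
                for q in (p - d, p + d):
                    if 0 <= q < L and np.isfinite(arr[q]) and arr[q] < spread:
                        arr[q] = spread

    control.plus[a_plus] = rng_ctl.beta(config.p_bg_alpha, config.p_bg_beta, a_plus.size)
    control.minus[a_minus] = rng_ctl.beta(
        config.p_bg_alpha, config.p_bg_beta, a_minus.size
    )
    return test, control


def simulate_read_qscores(n: int, library: str, seed: int) -> list[float]:
    """Average per-read quality scores for a native or PCR library."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if library not in QSCORE_PARAMS:
        raise ValueError(f"unknown library {library!r}; expected 'native' or 'pcr'")
    mu, sd = QSCORE_PARAMS[library]
    a, b = (1.0 - mu) / sd, (30.0 - mu) / sd
    rng = np.random.default_rng(seed)
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng).tolist()


def write_run(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Simulate and write FASTA + test/control bedGraphs + run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config.genome_length, config.gc, config.seed)
    test, control = simulate_tracks(genome, config)
    paths = {
        "genome": out / "genome.fasta",
        "test": out / "test.bedgraph",
        "control": out / "control.bedgraph",
        "metadata": out / "run_info.yaml",
    }
    write_fasta([genome], paths["genome"])
    write_track(test, paths["test"])
    write_track(control, paths["control"])
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump({"simulation": asdict(config)}, fh, sort_keys=True)
    return paths
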