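"""Genomes, per-base modification-fraction tracks, and sequence primitives.

All coordinates are 0-based and half-open, matching bedGraph, so values
round-trip through disk without shifting.  A :class:`FractionTrack` stores
one modified-base fraction in [0, 1] per covered ``(position, strand)``;
positions absent from the track are *missing*, which is deliberately
distinct from a stored 0.0 — downstream stages decide how missing values
are treated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: IUPAC nucleotide codes mapped to their degeneracy sets.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string.

    Accepts the full IUPAC alphabet and is an involution:
    ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in IUPAC:
            raise ValueError(f"non-IUPAC character {c!r} at offset {i}")
    return str(Seq(s).reverse_complement())


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff ``seq`` matches the IUPAC ``pattern`` position by position.

    A position matches when the degeneracy set of the sequence symbol is
    contained in that of the pattern symbol, so ``N`` in the pattern
    matches anything while an ``N`` in the sequence only matches a
    pattern ``N`` — ambiguous reference bases never satisfy a concrete
    motif position.
    """
    p, s = pattern.upper(), seq.upper()
    if len(p) != len(s):
        raise ValueError(f"pattern length {len(p)} != sequence length {len(s)}")
    for i, (pc, sc) in enumerate(zip(p, s)):
        if pc not in IUPAC:
            raise ValueError(f"non-IUPAC pattern character {pc!r} at offset {i}")
        if sc not in IUPAC:
            raise ValueError(f"non-IUPAC sequence character {sc!r} at offset {i}")
        if not IUPAC[sc] <= IUPAC[pc]:
            return False
    return True


@dataclass
class Genome:
    """A named nucleotide sequence.

    The sequence is uppercased on construction and restricted to
    A/C/G/T/N.  ``N`` is tolerated in real references but never emitted by
    the simulator and never matches as a modification site.
    """

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"genome {self.name!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; wraps the origin iff circular."""
        if start < 0 or end < start:
            raise ValueError(f"invalid interval [{start}, {end})")
        L = len(self.seq)
        if end <= L:
            return self.seq[start:end]
        if not self.circular:
            raise ValueError(
                f"interval [{start}, {end}) exceeds linear genome of length {L}"
            )
        if start >= L or end - start > L:
            raise ValueError(f"interval [{start}, {end}) wraps more than once")
        return self.seq[start:] + self.seq[: end - L]


class FractionTrack:
    """Sparse per-position, per-strand modified-base fractions in [0, 1].

    Backed by two dense float arrays (one per strand) with NaN marking
    missing positions; the arrays are exposed as ``plus`` / ``minus`` for
    vectorised pipeline stages, while ``get``/``set``/``items`` provide the
    mapping view.
    """

    __slots__ = ("genome_name", "length", "plus", "minus")

    def __init__(self, genome_name: str, length: int):
        if length < 0:
            raise ValueError("length must be >= 0")
        self.genome_name = genome_name
        self.length = length
        self.plus = np.full(length, np.nan)
        self.minus = np.full(length, np.nan)

    @classmethod
    def for_genome(cls, genome: Genome) -> "FractionTrack":
        return cls(genome.name, len(genome))

    def _arr(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"invalid strand {strand!r}")

    def set(self, pos: int, strand: str, value: float) -> None:
        if not 0 <= pos < self.length:
            raise ValueError(f"position {pos} outside genome of length {self.length}")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"fraction {value} outside [0, 1]")
        self._arr(strand)[pos] = value

    def get(self, pos: int, strand: str, default: Optional[float] = None):
        v = self._arr(strand)[pos]
        return default if np.isnan(v) else float(v)

    def __contains__(self, key) -> bool:
        pos, strand = key
        return bool(np.isfinite(self._arr(strand)[pos]))

    def __getitem__(self, key) -> float:
        pos, strand = key
        v = self._arr(strand)[pos]
        if np.isnan(v):
            raise KeyError(key)
        return float(v)

    def items(self) -> Iterator[tuple[tuple[int, str], float]]:
        for strand, arr in (("+", self.plus), ("-", self.minus)):
            for pos in np.flatnonzero(np.isfinite(arr)):
                yield (int(pos), strand), float(arr[pos])

    def n_covered(self) -> int:
        return int(np.isfinite(self.plus).sum() + np.isfinite(self.minus).sum())

    def validate(self) -> None:
        for arr in (self.plus, self.minus):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("track holds fractions outside [0, 1]")


def read_fasta(path) -> list[Genome]:
    """Read a (multi-record) FASTA file into :class:`Genome` objects.

    Sequences are uppercased; any character outside A/C/G/T/N raises with
    the offending record name and offset.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate record names in {path}")
    genomes = []
    for rec in records:
        s = str(rec.seq).upper()
        for i, c in enumerate(s):
            if c not in "ACGTN":
                raise ValueError(
                    f"invalid character {c!r} in record {rec.id!r} at offset {i}"
                )
        genomes.append(Genome(rec.id, s))
    return genomes


def write_fasta(genomes: list[Genome], path) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.name, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_track(path, genome: Genome, strand_default: str = "+") -> FractionTrack:
    """Read a 4/5-column bedGraph into a :class:`FractionTrack`.

    Columns: name, start, end, value[, strand].  Every base in the
    half-open interval receives the row value on the row strand (or
    ``strand_default``).  Overlapping rows overwrite (last wins) with a
    logged warning.
    """
    if strand_default not in STRANDS:
        raise ValueError(f"invalid strand_default {strand_default!r}")
    track = FractionTrack.for_genome(genome)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.strip()
            if not text or text.startswith(("track", "browser", "#")):
                continue
            fields = text.split()
            if len(fields) not in (4, 5):
                raise ValueError(f"{path}:{lineno}: expected 4 or 5 columns")
            name, start_s, end_s, value_s = fields[:4]
            strand = fields[4] if len(fields) == 5 else strand_default
            if name != genome.name:
                raise ValueError(
                    f"{path}:{lineno}: record name {name!r} does not match "
                    f"genome {genome.name!r}"
                )
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{path}:{lineno}: fraction {value} outside [0, 1]")
            if not (0 <= start < end <= len(genome)):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside genome "
                    f"of length {len(genome)}"
                )
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            arr = track.plus if strand == "+" else track.minus
            if np.isfinite(arr[start:end]).any():
                log.warning(
                    "%s:%d: overlapping row [%d, %d)%s overwrites earlier values",
                    path, lineno, start, end, strand,
                )
            arr[start:end] = value
    return track


def write_track(track: FractionTrack, path) -> None:
    """Write one 5-column bedGraph row per covered base.

    Fractions are serialised with :func:`repr` so that a read-back
    reproduces them bit-exactly.
    """
    with open(path, "w") as fh:
        for (pos, strand), value in track.items():
            fh.write(f"{track.genome_name}\t{pos}\t{pos + 1}\t{value!r}\t{strand}\n")
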