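"""Motif-anchored statistics on the genome and methylation-aware digestion.

Once a candidate motif is known, its genomic occurrences are scanned on
both strands, the mean modified fraction at the target adenine is
computed per motif, and the motif is extended one position at a time up-
and downstream to probe for flanking-base preferences.  An in-silico
methylation-sensitive restriction digest (DpnI-style: cuts only fully
methylated GATC, optionally hemimethylated CATC/GATG) provides an
orthogonal cross-check of the inferred methylation site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .tracks_io import IUPAC, FractionTrack, Genome, reverse_complement

log = logging.getLogger(__name__)


@dataclass
class MotifStat:
    """Occurrence count and mean modified fraction for one IUPAC pattern."""

    pattern: str
    mod_offset: int
    n_loci: int
    mean_fraction: Optional[float]  # None when n_loci == 0


@dataclass
class LadderRow:
    """One extension-ladder entry: the core, or core + one concrete base."""

    direction: str  # "core" | "up" | "down"
    distance: int
    base: Optional[str]
    stat: MotifStat


@dataclass
class EnzymeProfile:
    """A restriction enzyme with optional methylation dependence.

    ``cut_offset`` counts bases from the 5' end of the recognition site on
    the matched strand; ``methyl_offset`` locates the adenine whose
    methylation licenses cleavage.
    """

    name: str
    primary_sites: list[str]
    secondary_sites: list[str] = field(default_factory=list)
    cut_offset: int = 0
    requires_methylation: bool = False
    methyl_offset: int = 0

    def __post_init__(self) -> None:
        for site in self.primary_sites + self.secondary_sites:
            if not 0 <= self.cut_offset <= len(site):
                raise ValueError(f"cut_offset outside site {site!r}")
            if not 0 <= self.methyl_offset < len(site):
                raise ValueError(f"methyl_offset outside site {site!r}")


#: DpnI cleaves fully (both-strand) methylated GATC blunt between A and T
#: (GA^TC) and, to a lesser degree, hemimethylated CATC/GATG sites.
DPNI = EnzymeProfile(
    name="DpnI",
    primary_sites=["GATC"],
    secondary_sites=["CATC", "GATG"],
    cut_offset=2,
    requires_methylation=True,
    methyl_offset=1,
)


def _iupac_regex(pattern: str) -> str:
    parts = []
    for c in pattern.upper():
        if c not in IUPAC:
            raise ValueError(f"non-IUPAC pattern character {c!r}")
        parts.append("[" + "".join(sorted(IUPAC[c])) + "]")
    return "".join(parts)


def scan_sites(
    genome: Genome, pattern: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (overlapping) occurrences of an IUPAC pattern.

    Minus-strand matches are reported at the start of their plus-strand
    footprint with strand ``-``; a palindromic pattern therefore yields
    one record per strand per locus.  Circular genomes are scanned across
    the origin.
    """
    pat = pattern.upper()
    if len(pat) > len(genome):
        raise ValueError("pattern longer than genome")
    scanseq = genome.seq
    if genome.circular and len(pat) > 1:
        scanseq = genome.seq + genome.seq[: len(pat) - 1]

    hits: list[tuple[int, str]] = []
    for strand, p in (("+", pat), ("-", reverse_complement(pat))):
        if strand == "-" and not both_strands:
            continue
        rx = re.compile(f"(?={_iupac_regex(p)})")
        hits.extend((m.start(), strand) for m in rx.finditer(scanseq))
    hits.sort()
    return hits


def _modified_base_position(
    start: int, strand: str, pattern_len: int, mod_offset: int, L: int, circular: bool
) -> int:
    """Plus-strand coordinate of the modified base of a motif occurrence."""
    pos = start + (mod_offset if strand == "+" else pattern_len - 1 - mod_offset)
    return pos % L if circular else pos


def motif_mean_fraction(
    genome: Genome,
    track: FractionTrack,
    pattern: str,
    mod_offset: int,
) -> MotifStat:
    """Mean modified fraction at the target base over all occurrences.

    Both strands are scanned; missing track values count as 0, and a
    palindromic locus contributes one observation per strand (each
    strand's adenine is a distinct modifiable base).
    """
    pat = pattern.upper()
    if not 0 <= mod_offset < len(pat):
        raise ValueError("mod_offset must lie within the pattern")
    hits = scan_sites(genome, pat, both_strands=True)
    if not hits:
        log.warning("pattern %r has no occurrences in genome %r", pat, genome.name)
        return MotifStat(pat, mod_offset, 0, None)
    total = 0.0
    for start, strand in hits:
        pos = _modified_base_position(
            start, strand, len(pat), mod_offset, len(genome), genome.circular
        )
        total += track.get(pos, strand, default=0.0)
    return MotifStat(pat, mod_offset, len(hits), total / len(hits))


def extension_ladder(
    genome: Genome,
    track: FractionTrack,
    core: str,
    mod_offset: int,
    max_ext: int,
) -> list[LadderRow]:
    """Mean fractions for the core and every one-base up/down extension.

    For distance ``d`` in 1..``max_ext`` and each concrete base, the core
    is extended by that base placed ``d`` positions upstream (or
    downstream) with all intervening positions ``N``, and the mean
    modified fraction across all matching loci is recorded.  The ``d=0``
    row is the bare core.
    """
    if max_ext < 0:
        raise ValueError("max_ext must be >= 0")
    core = core.upper()
    rows = [LadderRow("core", 0, None, motif_mean_fraction(genome, track, core, mod_offset))]
    for d in range(1, max_ext + 1):
        for base in "ACGT":
            up = base + "N" * (d - 1) + core
            rows.append(
                LadderRow(
                    "up", d, base,
                    motif_mean_fraction(genome, track, up, mod_offset + d),
                )
            )
        for base in "ACGT":
            down = core + "N" * (d - 1) + base
            rows.append(
                LadderRow(
                    "down", d, base,
                    motif_mean_fraction(genome, track, down, mod_offset),
                )
            )
    return rows


def ladder_frame(rows: list[LadderRow]) -> pd.DataFrame:
    """Extension ladder as a tidy table (for the TSV output)."""
    return pd.DataFrame(
        {
            "pattern": [r.stat.pattern for r in rows],
            "direction": [r.direction for r in rows],
            "distance": [r.distance for r in rows],
            "base": [r.base if r.base is not None else "" for r in rows],
            "n_loci": [r.stat.n_loci for r in rows],
            "mean_fraction": [r.stat.mean_fraction for r in rows],
        }
    )


def digest(
    genome: Genome,
    enzyme: EnzymeProfile,
    methylated_sites: set[tuple[int, str]],
    include_secondary: bool = False,
) -> list[int]:
    """Fragment lengths of a methylation-aware in-silico digestion.

    A palindromic primary site is cut only when *fully* methylated — both
    ``(start, '+')`` and ``(start, '-')`` present in ``methylated_sites``
    (keys as returned by :func:`scan_sites` for the site pattern).
    Secondary sites cut on single-strand methylation and only when
    ``include_secondary`` is set.  Fragments are returned in genomic
    order; a linear genome with c cuts yields c+1 fragments (empty ones
    dropped), a circular genome with c >= 1 cuts yields c fragments.
    """
    L = len(genome)
    cuts: set[int] = set()

    def consider(pattern: str, secondary: bool) -> None:
        palindromic = pattern == reverse_complement(pattern)
        for start, strand in scan_sites(genome, pattern, both_strands=True):
            if enzyme.requires_methylation:
                if palindromic and not secondary:
                    ok = (start, "+") in methylated_sites and (start, "-") in methylated_sites
                else:
                    ok = (start, strand) in methylated_sites
            else:
                ok = True
            if not ok:
                continue
            offset = (
                enzyme.cut_offset if strand == "+" else len(pattern) - enzyme.cut_offset
            )
            cut = start + offset
            cut = cut % L if genome.circular else cut
            assert 0 <= cut <= L, "cut position outside genome"
            cuts.add(cut)

    for site in enzyme.primary_sites:
        consider(site, secondary=False)
    if include_secondary:
        for site in enzyme.secondary_sites:
            consider(site, secondary=True)

    ordered = sorted(cuts)
    if genome.circular:
        if not ordered:
            return [L]
        frags = [b - a for a, b in zip(ordered, ordered[1:])]
        frags.append(L - ordered[-1] + ordered[0])
        return [f for f in frags if f > 0] or [L]
    bounds = [0] + ordered + [L]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b - a > 0] or ([0] if L == 0 else [])
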