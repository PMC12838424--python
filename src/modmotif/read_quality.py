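"""Per-read Phred quality summaries and quality <-> error conversion.

The average per-read quality score is computed in error-probability
space, the convention of nanopore tooling: per-base Phred scores are
converted to error probabilities, averaged, and converted back.  A Phred
score Q corresponds to an error probability 10^(-Q/10); Q7 is therefore
roughly 20% wrongly called bases and Q13 roughly 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO


@dataclass
class QualitySummary:
    """Five-number-ish summary of per-read mean quality scores."""

    n: int
    median: float
    q1: float
    q3: float
    mean_error_percent: float


def qscore_to_error_percent(q: float) -> float:
    """Percent wrongly called bases: 100 * 10^(-q/10)."""
    if q < 0:
        raise ValueError("quality score must be >= 0")
    return 100.0 * 10.0 ** (-q / 10.0)


def error_percent_to_qscore(p: float) -> float:
    """Inverse of :func:`qscore_to_error_percent`."""
    if not 0 < p <= 100:
        raise ValueError("error percent must be in (0, 100]")
    return -10.0 * np.log10(p / 100.0)


def mean_read_qscore(per_base_q: list[float]) -> float:
    """Mean quality of a read, averaged in error-probability space."""
    if len(per_base_q) == 0:
        raise ValueError("empty quality list")
    q = np.asarray(per_base_q, dtype=float)
    if (q < 0).any():
        raise ValueError("quality scores must be >= 0")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def summarize(qscores: list[float]) -> QualitySummary:
    """Median/quartiles (linear interpolation) and the error-domain mean."""
    if len(qscores) == 0:
        raise ValueError("empty quality-score list")
    q = np.asarray(qscores, dtype=float)
    if (q < 0).any():
        raise ValueError("quality scores must be >= 0")
    q1, med, q3 = np.percentile(q, [25, 50, 75])
    mean_err = float(np.mean(100.0 * 10.0 ** (-q / 10.0)))
    return QualitySummary(len(qscores), float(med), float(q1), float(q3), mean_err)


def read_qscore_file(path) -> list[float]:
    """One mean quality score per line (blank lines and # comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            out.append(float(text))
    return out


def fastq_mean_qscores(path) -> list[float]:
    """Per-read mean quality scores from a FASTQ file (Phred+33)."""
    return [
        mean_read_qscore(rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]
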