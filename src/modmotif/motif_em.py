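"""De novo motif discovery by two-strand ZOOPS expectation-maximisation.

Each input sequence is assumed to contain zero or one motif site (the
ZOOPS model): with prior probability ``lam`` a site is present, uniformly
placed over all start positions — and, in reverse-complement mode, over
both strands.  Site columns follow a position weight matrix (PWM); all
other positions follow a 0-order background estimated once from the input
(strand-symmetrised in reverse-complement mode).  The E-step computes the
posterior over {no site} ∪ {(start, strand)} per sequence; the M-step
re-estimates the PWM with a pseudocount of 0.25 per base and the site
prior ``lam``.  Because of the pseudocount the iteration is MAP-EM: the
provably non-decreasing objective is the log-likelihood plus the
Dirichlet(1.25) log-prior of the PWM, which is what the recorded
trajectory tracks; the reported ``loglik`` is the plain data
log-likelihood of the final model.

A motif and its reverse complement are indistinguishable under a
two-strand search, so the returned model is canonicalised: of the two
equivalent orientations the one with the lexicographically smaller
consensus is reported (ties broken toward more plus-strand assignments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

log = logging.getLogger(__name__)

BASES = "ACGT"
_IDX = {c: i for i, c in enumerate(BASES)}

PSEUDOCOUNT = 0.25
MAX_ITER = 500
#: Convergence threshold on the per-iteration objective gain.  Tight
#: enough that independently converged runs of the same optimum (e.g. the
#: forward and reverse-complemented inputs) agree to ~1e-6 in likelihood.
TOL = 1e-9


@dataclass
class MotifModel:
    """PWM + background + ZOOPS occurrence prior."""

    pwm: np.ndarray  # (width, 4), columns in A,C,G,T order
    background: np.ndarray  # (4,)
    lam: float

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    def validate(self) -> None:
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be width x 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.pwm[::-1, ::-1].copy(), self.background.copy(), self.lam)


@dataclass
class MotifResult:
    """Best EM model plus per-sequence maximum-posterior assignments.

    ``assignments[i]`` is ``None`` when sequence ``i`` is assigned no
    site, else ``(site_start, strand)``.  ``n_rc`` counts minus-strand
    assignments.  ``trajectory`` is the monotone MAP-EM objective of the
    winning start, one value per iteration.
    """

    model: MotifModel
    assignments: list[Optional[tuple[int, str]]]
    loglik: float
    n_rc: int
    trajectory: list[float] = field(default_factory=list, repr=False)


def _encode(seqs: list[str]) -> list[np.ndarray]:
    encoded = []
    for i, s in enumerate(seqs):
        try:
            encoded.append(np.array([_IDX[c] for c in s.upper()], dtype=np.int64))
        except KeyError as exc:
            raise ValueError(
                f"sequence {i} contains non-A/C/G/T character {exc.args[0]!r}"
            ) from None
    return encoded


def estimate_background(seqs: list[str], symmetrize: bool) -> np.ndarray:
    """0-order base frequencies (1-count smoothing); optionally strand-averaged."""
    counts = np.ones(4)
    for s in seqs:
        for c in s.upper():
            counts[_IDX[c]] += 1
    if symmetrize:
        counts = (counts + counts[::-1]) / 2.0  # A<->T, C<->G
    return counts / counts.sum()


class _Group:
    """Equal-length sequences, windowed once up front."""

    def __init__(self, indices: list[int], mat: np.ndarray, width: int, revcomp: bool):
        self.indices = indices
        self.mat = mat
        self.win = np.ascontiguousarray(sliding_window_view(mat, width, axis=1))
        self.m = self.win.shape[1]
        self.win_rc = np.ascontiguousarray(3 - self.win[:, :, ::-1]) if revcomp else None


def _posteriors(group: _Group, pwm: np.ndarray, bg: np.ndarray, lam: float, revcomp: bool):
    """Per-sequence log-likelihoods and component posteriors for one group."""
    w = pwm.shape[0]
    with np.errstate(divide="ignore"):
        lp = np.log(pwm)
        l_lam = np.log(lam)
        l_nolam = np.log1p(-lam) if lam < 1.0 else -np.inf
    lbg = np.log(bg)
    ar = np.arange(w)

    bg_ll = lbg[group.mat].sum(axis=1)  # (n,)
    site_bg = lbg[group.win].sum(axis=2)  # (n, m)
    score_p = lp[ar, group.win].sum(axis=2)  # (n, m)
    n_opts = group.m * (2 if revcomp else 1)
    site_prior = l_lam - np.log(n_opts)

    cols = [l_nolam + bg_ll[:, None]]
    cols.append(site_prior + bg_ll[:, None] - site_bg + score_p)
    if revcomp:
        score_m = lp[ar, group.win_rc].sum(axis=2)
        cols.append(site_prior + bg_ll[:, None] - site_bg + score_m)
    mat = np.concatenate(cols, axis=1)  # (n, 1 + n_opts)
    ll = logsumexp(mat, axis=1)
    post = np.exp(mat - ll[:, None])
    return ll, post


def _em_one_start(groups, pwm, bg, revcomp, lam=0.5):
    """Run MAP-EM from one initialisation; returns model + objective path."""
    w = pwm.shape[0]
    n_seqs = sum(len(g.indices) for g in groups)
    trajectory: list[float] = []
    prior_weight = PSEUDOCOUNT

    for _ in range(MAX_ITER):
        loglik = 0.0
        counts = np.zeros((w, 4))
        lam_num = 0.0
        for g in groups:
            ll, post = _posteriors(g, pwm, bg, lam, revcomp)
            loglik += float(ll.sum())
            zp = post[:, 1 : 1 + g.m]
            for i in range(w):
                np.add.at(counts[i], g.win[:, :, i].ravel(), zp.ravel())
            if revcomp:
                zm = post[:, 1 + g.m :]
                for i in range(w):
                    np.add.at(counts[i], g.win_rc[:, :, i].ravel(), zm.ravel())
                lam_num += float(zp.sum() + zm.sum())
            else:
                lam_num += float(zp.sum())
        with np.errstate(divide="ignore"):
            objective = loglik + prior_weight * float(np.log(pwm).sum())
        if trajectory and objective < trajectory[-1] - 1e-9:
            raise AssertionError("EM objective decreased")  # theory violation
        done = bool(trajectory) and (objective - trajectory[-1] < TOL)
        trajectory.append(objective)
        if done:
            break
        pwm = counts + PSEUDOCOUNT
        pwm /= pwm.sum(axis=1, keepdims=True)
        lam = min(max(lam_num / n_seqs, 0.0), 1.0)
    return MotifModel(pwm, bg.copy(), lam), trajectory


def _assignments(groups, model, revcomp, n_seqs):
    """Maximum-posterior site per sequence, plus raw data log-likelihood."""
    out: list[Optional[tuple[int, str]]] = [None] * n_seqs
    loglik = 0.0
    for g in groups:
        ll, post = _posteriors(g, model.pwm, model.background, model.lam, revcomp)
        loglik += float(ll.sum())
        best = post.argmax(axis=1)  # lowest index wins ties
        for row, seq_idx in enumerate(g.indices):
            b = int(best[row])
            if b == 0:
                out[seq_idx] = None
            elif b <= g.m:
                out[seq_idx] = (b - 1, "+")
            else:
                out[seq_idx] = (b - 1 - g.m, "-")
    return out, loglik


def discover_motif(
    seqs: list[str],
    width: int,
    revcomp: bool = True,
    n_starts: int = 10,
    seed: int = 0,
) -> MotifResult:
    """ZOOPS EM motif discovery over ``n_starts`` seeded initialisations.

    Each start initialises the PWM from a randomly chosen width-``width``
    subsequence (0.7 on the observed base, 0.1 elsewhere) and ``lam`` at
    0.5; the best final objective wins (ties: earlier start).
    """
    if not seqs:
        raise ValueError("no input sequences")
    if width < 2:
        raise ValueError("width must be >= 2")
    encoded = _encode(seqs)
    if min(len(e) for e in encoded) < width:
        raise ValueError("width exceeds the shortest sequence")

    bg = estimate_background(seqs, symmetrize=revcomp)

    by_len: dict[int, list[int]] = {}
    for i, e in enumerate(encoded):
        by_len.setdefault(len(e), []).append(i)
    groups = [
        _Group(idx, np.stack([encoded[i] for i in idx]), width, revcomp)
        for _, idx in sorted(by_len.items())
    ]

    # Starts are compared on the raw data log-likelihood of their final
    # model (the within-start iteration maximises the MAP objective).
    best: Optional[tuple[float, MotifModel, list[float]]] = None
    for child in np.random.SeedSequence(seed).spawn(max(1, n_starts)):
        rng = np.random.default_rng(child)
        i = int(rng.integers(len(encoded)))
        j = int(rng.integers(len(encoded[i]) - width + 1))
        pwm0 = np.full((width, 4), 0.1)
        pwm0[np.arange(width), encoded[i][j : j + width]] = 0.7
        model, traj = _em_one_start(groups, pwm0, bg, revcomp)
        _, raw_ll = _assignments(groups, model, revcomp, len(seqs))
        if best is None or raw_ll > best[0]:
            best = (raw_ll, model, traj)

    _, model, trajectory = best
    assignments, loglik = _assignments(groups, model, revcomp, len(seqs))

    if revcomp:
        flipped = model.reverse_complement()
        cons, cons_rc = consensus(model), consensus(flipped)
        n_minus = sum(1 for a in assignments if a is not None and a[1] == "-")
        n_plus = sum(1 for a in assignments if a is not None and a[1] == "+")
        if cons_rc < cons or (cons_rc == cons and n_minus > n_plus):
            model = flipped
            assignments = [
                None if a is None else (a[0], "-" if a[1] == "+" else "+")
                for a in assignments
            ]

    n_rc = sum(1 for a in assignments if a is not None and a[1] == "-")
    return MotifResult(model, assignments, loglik, n_rc, trajectory)


def consensus(model: MotifModel) -> str:
    """Per-position argmax base; ties resolved in A < C < G < T order."""
    return "".join(BASES[int(np.argmax(row))] for row in model.pwm)


def information_content(model: MotifModel) -> list[float]:
    """Bits per position relative to the background: Σ p·log2(p/q)."""
    ic = []
    for row in model.pwm:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = row * np.log2(row / model.background)
        ic.append(float(np.where(row > 0, terms, 0.0).sum()))
    return ic


def count_matching(seqs: list[str], consensus_str: str, revcomp: bool) -> int:
    """Sequences containing the consensus (or, if allowed, its revcomp)."""
    if not consensus_str:
        raise ValueError("consensus must be non-empty")
    from .tracks_io import reverse_complement

    pats = [consensus_str.upper()]
    if revcomp:
        pats.append(reverse_complement(consensus_str))
    return sum(1 for s in seqs if any(p in s.upper() for p in pats))


def scan_widths(
    seqs: list[str],
    widths=range(3, 9),
    revcomp: bool = True,
    n_starts: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Best model per width, ranked by BIC (3·width + 1 free parameters).

    Returns one record per width sorted ascending by BIC, so the first
    entry is the preferred model.
    """
    n = len(seqs)
    records = []
    for w in widths:
        result = discover_motif(seqs, w, revcomp=revcomp, n_starts=n_starts, seed=seed)
        bic = -2.0 * result.loglik + (3 * w + 1) * np.log(n)
        records.append({"width": w, "result": result, "bic": float(bic)})
    records.sort(key=lambda r: (r["bic"], r["width"]))
    return records


def trim_to_core(
    seqs: list[str],
    result: MotifResult,
    revcomp: bool = True,
    min_bits: float = 0.25,
) -> MotifResult:
    """Trim uninformative flanking columns and re-assign sites.

    Wide models fitted to co-selected windows often carry flanking columns
    with real but weak enrichment (here, context from neighbouring sites
    rather than motif specificity).  Columns at either end contributing
    fewer than ``min_bits`` bits are dropped; the conserved core between
    the outermost informative columns is re-scored on the sequences.
    Returns the input result unchanged when nothing can be trimmed.
    """
    ic = information_content(result.model)
    keep = [i for i, bits in enumerate(ic) if bits >= min_bits]
    if not keep:
        return result
    left, right = keep[0], len(ic) - 1 - keep[-1]
    if left == 0 and right == 0:
        return result
    core_pwm = result.model.pwm[keep[0] : keep[-1] + 1].copy()
    if core_pwm.shape[0] < 2:  # refuse to trim below a 2-column motif
        return result
    model = MotifModel(core_pwm, result.model.background.copy(), result.model.lam)

    encoded = _encode(seqs)
    by_len: dict[int, list[int]] = {}
    for i, e in enumerate(encoded):
        by_len.setdefault(len(e), []).append(i)
    groups = [
        _Group(idx, np.stack([encoded[i] for i in idx]), model.width, revcomp)
        for _, idx in sorted(by_len.items())
    ]
    assignments, loglik = _assignments(groups, model, revcomp, len(seqs))
    n_rc = sum(1 for a in assignments if a is not None and a[1] == "-")
    return MotifResult(model, assignments, loglik, n_rc, list(result.trajectory))


def serialize_result(result: MotifResult) -> dict:
    """JSON-ready representation of a :class:`MotifResult`."""
    return {
        "consensus": consensus(result.model),
        "width": result.model.width,
        "pwm": result.model.pwm.tolist(),
        "background": result.model.background.tolist(),
        "lam": result.model.lam,
        "loglik": result.loglik,
        "n_rc": result.n_rc,
        "information_content": information_content(result.model),
        "assignments": [
            None if a is None else {"start": a[0], "strand": a[1]}
            for a in result.assignments
        ],
    }
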