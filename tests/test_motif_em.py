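from itertools import product

import numpy as np
import pytest

from modmotif.motif_em import (
    MotifModel,
    consensus,
    count_matching,
    discover_motif,
    information_content,
    scan_widths,
    trim_to_core,
)
from modmotif.tracks_io import reverse_complement


def _best_trimer_by_substring_count(seqs, revcomp):
    """Oracle: exhaustively score all 64 trimer consensi by the number of
    sequences containing them (on either strand when revcomp)."""
    best, best_n = None, -1
    for mer in ("".join(p) for p in product("ACGT", repeat=3)):
        n = count_matching(seqs, mer, revcomp)
        if n > best_n:
            best, best_n = mer, n
    return best, best_n


class TestDiscoverMotif:
    def test_recovers_planted_trimer(self, planted_seqs):
        res = discover_motif(planted_seqs, 3, revcomp=False, n_starts=10, seed=0)
        oracle, n = _best_trimer_by_substring_count(planted_seqs, revcomp=False)
        assert n == len(planted_seqs)  # every sequence carries the plant
        assert consensus(res.model) == oracle == "ATC"

    def test_identical_sequences_drive_lambda_to_one(self):
        seqs = ["ATCATCATCA"] * 20
        res = discover_motif(seqs, 3, revcomp=True, n_starts=5, seed=1)
        # the repeat makes the phase ambiguous: ATC and TCA fit equally
        assert consensus(res.model) in {"ATC", "TCA", "CAT"}
        assert res.model.lam == pytest.approx(1.0, abs=1e-3)
        assert all(a is not None and a[1] == "+" for a in res.assignments)

    def test_strand_mix_recovered_in_revcomp_mode(self):
        """Half the sequences carry ATC, half carry GAT; the minus-strand
        assignment count must track the planted split within 10%."""
        rng = np.random.default_rng(4)
        seqs = []
        for i in range(60):
            motif = "ATC" if i < 30 else "GAT"
            other = "GAT" if i < 30 else "ATC"
            while True:
                s = "".join(rng.choice(list("ACGT"), 10))
                j = int(rng.integers(8))
                planted = s[:j] + motif + s[j + 3 :]
                # exactly one site, in the planted orientation only
                if planted.count(motif) == 1 and other not in planted:
                    seqs.append(planted)
                    break
        res = discover_motif(seqs, 3, revcomp=True, n_starts=10, seed=4)
        assert consensus(res.model) == "ATC"
        assert abs(res.n_rc - 30) <= 3

    def test_objective_monotone_on_fixtures(self, planted_seqs, default_run):
        for seqs, seed in ((planted_seqs, 0), (default_run["seqs"], 1)):
            res = discover_motif(seqs, 3, revcomp=True, n_starts=10, seed=seed)
            traj = res.trajectory
            assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_model_stays_on_simplex(self, planted_seqs):
        res = discover_motif(planted_seqs, 4, revcomp=True, n_starts=5, seed=2)
        res.model.validate()
        assert (res.model.pwm > 0).all()

    def test_strand_symmetry(self, planted_seqs):
        fwd = discover_motif(planted_seqs, 3, revcomp=True, n_starts=10, seed=0)
        rc_inputs = [reverse_complement(s) for s in planted_seqs]
        rev = discover_motif(rc_inputs, 3, revcomp=True, n_starts=10, seed=0)
        assert rev.loglik == pytest.approx(fwd.loglik, abs=1e-6)
        assert consensus(rev.model) == consensus(fwd.model)
        flipped = {"+": "-", "-": "+"}
        n_rc_expected = sum(
            1 for a in fwd.assignments if a is not None and flipped[a[1]] == "-"
        )
        assert rev.n_rc == n_rc_expected

    def test_matches_brute_force_assignment_optimum(self):
        """On a tiny high-signal fixture: the EM recovers the planted
        site, its marginal likelihood matches an independent plain-Python
        evaluation, and each returned assignment is the brute-force
        optimum over every (position, strand, none) option under the
        returned model."""
        # flanks balance the base composition so the planted site is the
        # unambiguous maximum-likelihood motif
        seqs = ["ATCGGCGT", "CATCGGTA", "TTATCGGA", "ACCATCGG", "TGGCATCA"]
        res = discover_motif(seqs, 3, revcomp=True, n_starts=15, seed=0)
        assert consensus(res.model) == "ATC"
        assert res.assignments == [(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")]

        enc = [[{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in s] for s in seqs]
        bg = res.model.background
        pwm = res.model.pwm
        lam = res.model.lam

        def component_logliks(e):
            """log P(seq, component) for none / every (start, strand)."""
            m = len(e) - 2
            bg_ll = sum(np.log(bg[b]) for b in e)
            comps = {None: (np.log1p(-lam) if lam < 1 else -np.inf) + bg_ll}
            for j in range(m):
                flank = bg_ll - sum(np.log(bg[e[j + i]]) for i in range(3))
                site_p = sum(np.log(pwm[i][e[j + i]]) for i in range(3))
                comps[(j, "+")] = np.log(lam / (2 * m)) + site_p + flank
                site_m = sum(np.log(pwm[i][3 - e[j + 2 - i]]) for i in range(3))
                comps[(j, "-")] = np.log(lam / (2 * m)) + site_m + flank
            return comps

        total = 0.0
        for e, returned in zip(enc, res.assignments):
            comps = component_logliks(e)
            best_key = max(comps, key=lambda k: comps[k])
            assert comps[returned] == pytest.approx(comps[best_key], abs=1e-9)
            total += np.logaddexp.reduce(list(comps.values()))
        assert res.loglik == pytest.approx(total, abs=1e-6)

    @pytest.mark.parametrize(
        "seqs,width,err",
        [([], 3, "no input"), (["AT"], 3, "shortest"), (["ATCG"], 1, "width")],
    )
    def test_preconditions(self, seqs, width, err):
        with pytest.raises(ValueError, match=err):
            discover_motif(seqs, width)

    def test_rejects_ambiguous_bases(self):
        with pytest.raises(ValueError, match="non-A/C/G/T"):
            discover_motif(["ATCN"], 3)


class TestConsensusAndInformation:
    def test_one_hot_consensus(self):
        pwm = np.zeros((3, 4))
        pwm[0, 0] = pwm[1, 3] = pwm[2, 1] = 1.0
        model = MotifModel(pwm, np.full(4, 0.25), 0.5)
        assert consensus(model) == "ATC"
        assert information_content(model) == pytest.approx([2.0, 2.0, 2.0])

    def test_uniform_column_ties_to_a_and_zero_bits(self):
        model = MotifModel(np.full((1, 4), 0.25), np.full(4, 0.25), 0.5)
        assert consensus(model) == "A"
        assert information_content(model) == pytest.approx([0.0])

    def test_half_half_column_is_one_bit(self):
        model = MotifModel(
            np.array([[0.5, 0.5, 0.0, 0.0]]), np.full(4, 0.25), 0.5
        )
        assert information_content(model) == pytest.approx([1.0])


class TestCountMatching:
    @pytest.mark.parametrize(
        "seqs,cons,rc,expected",
        [
            (["GGATCG", "CCGATC", "TTTTT"], "ATC", True, 2),
            ([], "ATC", True, 0),
            (["GATGAT"], "ATC", True, 1),
            (["GATGAT"], "ATC", False, 0),
        ],
    )
    def test_examples(self, seqs, cons, rc, expected):
        assert count_matching(seqs, cons, rc) == expected

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            count_matching(["ATC"], "", True)


class TestWidthScanAndTrim:
    def test_scan_orders_by_bic(self, planted_seqs):
        records = scan_widths(planted_seqs, widths=(3, 4), n_starts=5, seed=0)
        assert [r["bic"] for r in records] == sorted(r["bic"] for r in records)

    def test_wide_model_trims_to_planted_core(self, planted_seqs):
        wide = discover_motif(planted_seqs, 5, revcomp=True, n_starts=10, seed=0)
        trimmed = trim_to_core(planted_seqs, wide, revcomp=True)
        assert consensus(trimmed.model) == "ATC"
        assert trimmed.model.width < wide.model.width
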