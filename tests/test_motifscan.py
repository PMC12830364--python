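"""PWM scoring, exact null p-values, BH, scanning and consensus building."""

import itertools

import numpy as np
import pytest

from pacefinder.motifscan import (
    bh_qvalues,
    best_hit_per_species,
    consensus_pwm,
    exact_pvalue_table,
    scan,
    score_logodds,
    PresenceCall,
    ScanHit,
)
from pacefinder.promoters import PromoterRecord
from pacefinder.pwm import PWM

TOY = PWM(np.array([[0.7, 0.1], [0.1, 0.7], [0.1, 0.1], [0.1, 0.1]]))


def random_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


def _prom(seq, gene="g", sp="s", family="NIN"):
    return PromoterRecord(gene_id=gene, species_id=sp, family=family,
                          sequence=seq, requested_length=len(seq),
                          actual_length=len(seq), truncated=False)


class TestScoreLogodds:
    def test_background_pwm_scores_zero(self):
        pwm = PWM(np.full((4, 3), 0.25))
        assert score_logodds(pwm, "ACG") == pytest.approx(0.0)

    def test_match_and_mismatch(self):
        assert score_logodds(TOY, "AC") == pytest.approx(2 * np.log2(2.8))
        assert score_logodds(TOY, "GG") == pytest.approx(2 * np.log2(0.4))

    def test_non_acgt_raises(self):
        with pytest.raises(ValueError):
            score_logodds(TOY, "AN")


class TestExactPValueTable:
    def test_minimum_score_has_p_one(self):
        t = exact_pvalue_table(TOY)
        assert t.pvalue(t.min_score * t.granularity) == 1.0

    def test_only_ac_attains_top_score(self):
        t = exact_pvalue_table(TOY)
        assert t.pvalue(2.97) == pytest.approx(1 / 16)

    def test_background_pwm_is_degenerate(self):
        pwm = PWM(np.full((4, 4), 0.25))
        t = exact_pvalue_table(pwm)
        assert t.pvalue(0.0) == 1.0

    @pytest.mark.parametrize("w", [3, 4, 5, 6])
    @pytest.mark.parametrize("case", ["uniform_bg", "skewed_bg"])
    def test_agrees_with_full_enumeration(self, w, case):
        """DP table equals brute-force enumeration of all 4^w windows."""
        rng = np.random.default_rng(10 * w + (case == "skewed_bg"))
        probs = rng.dirichlet(np.full(4, 0.8), size=w).T
        bg = np.full(4, 0.25) if case == "uniform_bg" else np.array([0.4, 0.2, 0.1, 0.3])
        pwm = PWM(probs, background=bg)
        t = exact_pvalue_table(pwm)
        wins = np.array(list(itertools.product(range(4), repeat=w)), dtype=np.int8)
        iscores = t.int_scores(wins)
        weights = np.prod(bg[wins], axis=1)
        for s in np.unique(iscores):
            expect = weights[iscores >= s].sum()
            assert t.pvalue_int(int(s)) == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_invalid_granularity(self):
        with pytest.raises(ValueError):
            exact_pvalue_table(TOY, granularity=0.0)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.2]) == pytest.approx([0.2])

    def test_step_up_by_hand(self):
        assert bh_qvalues([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    def test_equal_ps_unchanged(self):
        assert bh_qvalues([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.1, 1.2])

    def test_q_at_least_p(self, rng):
        p = rng.random(200)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()


class TestScan:
    def test_short_promoter_called_absent(self):
        _, calls = scan(TOY, [_prom("A")])
        assert calls[0].status == "absent" and calls[0].best_hit is None

    def test_lowest_q_hit_retained(self, rng):
        # one promoter containing a perfect and a weaker occurrence
        pwm = PWM.from_sites(["ACGTACGTAC"] * 5, pseudocount=0.25)
        seq = random_seq(rng, 120)
        seq = seq[:20] + "ACGTACGTAC" + seq[30:60] + "ACGTACGTTT" + seq[70:]
        hits, calls = scan(pwm, [_prom(seq)])
        assert len(hits) == 1
        assert hits[0].offset == 20  # the exact match has the smaller p/q

    def test_presence_boundary_is_inclusive(self):
        pwm = PWM(np.array([[0.4], [0.2], [0.2], [0.2]]))
        _, calls = scan(pwm, [_prom("A")], fdr=0.25)
        assert calls[0].best_hit.q == pytest.approx(0.25)
        assert calls[0].present

    def test_deterministic(self, default_bundle, protocol_report):
        prom = default_bundle.promoters[:10]
        a = scan(protocol_report.final_pwm, prom)
        b = scan(protocol_report.final_pwm, prom)
        assert a == b

    def test_q_never_below_p(self, default_bundle, final_scan):
        hits, _ = final_scan
        assert all(h.q >= h.p - 1e-12 for h in hits)

    def test_single_strand_contract(self, rng):
        """A motif planted only as its reverse complement must not be
        called when scanning the given strand with the forward model."""
        from pacefinder._sequence import revcomp

        # strongly non-palindromic: the reverse complement shares no
        # composition with the forward model
        motif = "CCCAACCCAAACACC"
        pwm = PWM.from_sites([motif] * 8, pseudocount=0.25)
        proms = []
        for i in range(15):
            s = random_seq(rng, 300)
            s = s[:100] + revcomp(motif) + s[100 + len(motif):]
            proms.append(_prom(s, gene=f"g{i}", sp=f"s{i}"))
        _, calls = scan(pwm, proms, fdr=0.1)
        assert not any(c.present for c in calls)


class TestBestHitPerSpecies:
    def _call(self, sp, gene, p, q=None, offset=0, present=True):
        hit = ScanHit(promoter_id=gene, species_id=sp, offset=offset,
                      matched="ACGT", score=5.0, p=p, q=q if q is not None else p)
        return PresenceCall(sp, gene, "NIN", "present" if present else "absent", hit)

    def test_lowest_p_wins(self):
        calls = [self._call("s1", "a", 1e-3), self._call("s1", "b", 1e-8)]
        assert best_hit_per_species(calls) == {"s1": "b"}

    def test_singleton(self):
        assert best_hit_per_species([self._call("s1", "a", 0.01)]) == {"s1": "a"}

    def test_tie_breaks_by_gene_id(self):
        calls = [self._call("s1", "b", 1e-4), self._call("s1", "a", 1e-4)]
        assert best_hit_per_species(calls) == {"s1": "a"}

    def test_species_without_present_call_omitted(self, caplog):
        calls = [self._call("s1", "a", 0.5, present=False)]
        with caplog.at_level("WARNING"):
            out = best_hit_per_species(calls)
        assert out == {}
        assert "s1" in caplog.text


class TestConsensusPWM:
    def test_identical_inputs_are_point_mass(self):
        pwm = consensus_pwm(["ACG", "ACG"], pseudocount=0.0)
        assert pwm.consensus == "ACG"
        assert pwm.information_content == pytest.approx([2.0, 2.0, 2.0])

    def test_half_split_column(self):
        pwm = consensus_pwm(["AC", "AT"], pseudocount=0.0)
        assert pwm.probs[:, 0] == pytest.approx([1.0, 0.0, 0.0, 0.0])
        assert pwm.probs[1, 1] == pytest.approx(0.5)
        assert pwm.probs[3, 1] == pytest.approx(0.5)
        assert pwm.information_content == pytest.approx([2.0, 1.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            consensus_pwm(["ACGT", "ACG"])

    def test_protocol_consensus_has_core_width(self, default_bundle, final_scan):
        """One matched w-mer per trait-positive species -> 29-column PWM."""
        _, calls = final_scan
        status = {s.species_id: s for s in default_bundle.statuses}
        picks = {}
        for c in calls:
            st = status[c.species_id]
            if c.family == "NIN" and st.clade and st.trait and c.present:
                picks[c.species_id] = c.best_hit.matched
        pwm = consensus_pwm(list(picks.values()))
        assert pwm.width == 29
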