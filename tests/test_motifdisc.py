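"""Seeding, ZOOPS EM, width refinement, discovery and the four-pass protocol."""

import numpy as np
import pytest

from pacefinder._sequence import revcomp
from pacefinder.motifdisc import (
    DiscoveryConfig,
    MissingControlError,
    discover,
    em_zoops,
    refine_window,
    seed_candidates,
)
from pacefinder.promoters import DiscoverySets, PromoterRecord
from pacefinder.pwm import PWM
from pacefinder.simdata import DEFAULT_TRUTH_MOTIF


def random_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


def _prom(seq, gene, sp="s", family="NIN"):
    return PromoterRecord(gene_id=gene, species_id=sp, family=family,
                          sequence=seq, requested_length=len(seq),
                          actual_length=len(seq), truncated=False)


def _planted_set(rng, n_seq=10, length=80, motif="ACGTACGT"):
    seqs, offsets = [], []
    for _ in range(n_seq):
        s = random_seq(rng, length)
        o = int(rng.integers(0, length - len(motif) + 1))
        seqs.append(s[:o] + motif + s[o + len(motif):])
        offsets.append(o)
    return seqs, offsets


class TestSeedCandidates:
    def test_distinct_kmers(self):
        seeds = seed_candidates(["AAAA", "AAAT"], w=4, max_seeds=100)
        assert sorted(s.consensus for s in seeds) == ["AAAA", "AAAT"]
        # seed model: 0.7 on the consensus base, 0.1 elsewhere
        assert seeds[0].probs.max(axis=0) == pytest.approx([0.7] * 4)

    def test_width_larger_than_all_sequences(self):
        with pytest.raises(ValueError):
            seed_candidates(["ACGT"], w=5, max_seeds=10)

    def test_subsampling_is_deterministic(self):
        a = seed_candidates(["ACGTACGTAC"], w=4, max_seeds=2, seed=3)
        b = seed_candidates(["ACGTACGTAC"], w=4, max_seeds=2, seed=3)
        assert [s.consensus for s in a] == [s.consensus for s in b]
        assert len(a) == 2


class TestEMZoops:
    def test_gamma_zero_returns_init_unchanged(self):
        init = PWM.from_consensus("ACGT")
        model = em_zoops(init, ["ACGTACGT", "TTTTACGT"], gamma0=0.0)
        assert model.pwm is init
        assert model.gamma == 0.0
        assert model.objective == 0.0

    def test_planted_motif_recovered(self, rng):
        """10 sequences with an identical planted 8-mer: EM from a seed on
        the truth puts >= 0.9 on the planted base everywhere and all best
        sites land on the planted offsets."""
        seqs, offsets = _planted_set(rng)
        model = em_zoops(PWM.from_consensus("ACGTACGT"), seqs, gamma0=0.5)
        assert model.pwm.probs.max(axis=0).min() >= 0.9
        assert model.pwm.consensus == "ACGTACGT"
        assert [o.offset for o in model.occurrences] == offsets

    def test_objective_trace_never_decreases(self, rng):
        seqs, _ = _planted_set(rng, n_seq=6, length=50)
        for seed_kmer in ("ACGTACGT", "TTTTTTTT", "ACGGACGG"):
            model = em_zoops(PWM.from_consensus(seed_kmer), seqs, gamma0=0.3)
            trace = np.asarray(model.trace)
            assert (np.diff(trace) >= -1e-9).all()

    def test_empty_positive_set(self):
        with pytest.raises(ValueError):
            em_zoops(PWM.from_consensus("ACGT"), [])

    def test_sequence_shorter_than_width(self):
        with pytest.raises(ValueError):
            em_zoops(PWM.from_consensus("ACGTAC"), ["ACGT"])


class TestRefineWindow:
    def test_conserved_core_positions_10_to_38(self, rng):
        """45-column alignment conserved exactly at 1-based columns 10-38
        refines to offset 9 for a 29-column target."""
        n = 8
        rows = []
        for i in range(n):
            row = [("ACGT" * 12)[(i + j) % 4] for j in range(45)]  # balanced
            for j in range(9, 38):
                row[j] = "ACGTACGATTGACCGTGAATCGATCGGCA"[j - 9]
            rows.append("".join(row))
        assert refine_window(rows, 29) == 9

    def test_full_width_is_identity(self):
        assert refine_window(["ACGT", "ACGT"], 4) == 0

    def test_three_window_enumeration(self):
        # IC profile ~ [0, 2, 2, 0]: middle window wins
        rows = ["AACA", "CACC", "GACG", "TACT"]
        assert refine_window(rows, 2, pseudocount=0.0) == 1

    def test_target_wider_than_alignment(self):
        with pytest.raises(ValueError):
            refine_window(["ACGT"], 5)


def _toy_sets(rng, motif="GTACCGGATAAC", n_pos=10, n_ctrl=12, length=200):
    pos = []
    for i in range(n_pos):
        s = random_seq(rng, length)
        o = int(rng.integers(0, length - len(motif) + 1))
        pos.append(_prom(s[:o] + motif + s[o + len(motif):], f"p{i}", f"sp{i}"))
    ctrl = [_prom(random_seq(rng, length), f"c{i}", f"csp{i}") for i in range(n_ctrl)]
    return DiscoverySets(positives=pos, controls=ctrl, design="discriminative")


class TestDiscover:
    def test_fixed_width_is_honoured(self, rng):
        sets = _toy_sets(rng)
        models = discover(sets, 12, "discriminative", 1, DiscoveryConfig(max_seeds=300))
        assert models[0].width == 12
        assert models[0].consensus == "GTACCGGATAAC"

    def test_missing_controls_rejected(self, rng):
        sets = _toy_sets(rng)
        empty = DiscoverySets(positives=sets.positives, controls=[], design="d")
        with pytest.raises(MissingControlError):
            discover(empty, 8, "discriminative")

    def test_masking_prevents_overlapping_motifs(self, rng):
        """With n_motifs=2 the second motif's sites never overlap the
        first motif's masked intervals."""
        m1, m2 = "GTACCGGATAAC", "TTGCACGGTCAA"
        pos = []
        for i in range(10):
            s = random_seq(rng, 220)
            pos.append(_prom(s[:30] + m1 + s[42:130] + m2 + s[142:], f"p{i}", f"sp{i}"))
        sets = DiscoverySets(positives=pos, controls=[], design="normal")
        models = discover(sets, 12, "normal", n_motifs=2,
                          cfg=DiscoveryConfig(max_seeds=300, report_threshold=1e-3))
        assert len(models) == 2
        assert {models[0].consensus, models[1].consensus} == {m1, m2}
        first = {(o.seq_index, o.offset) for o in models[0].sites()}
        for occ in models[1].sites():
            for (si, off) in first:
                if si == occ.seq_index:
                    assert abs(occ.offset - off) >= 12  # disjoint windows

    def test_reverse_complement_plant_is_not_recovered(self, rng):
        """The search is single-strand: a motif planted only as its reverse
        complement is invisible to forward discovery."""
        motif = "GTACCGGATAAC"
        rc = revcomp(motif)
        pos = []
        for i in range(10):
            s = random_seq(rng, 200)
            pos.append(_prom(s[:50] + rc + s[62:], f"p{i}", f"sp{i}"))
        sets = DiscoverySets(
            positives=pos,
            controls=[_prom(random_seq(rng, 200), f"c{i}", f"csp{i}") for i in range(10)],
            design="discriminative",
        )
        models = discover(sets, 12, "discriminative", 1, DiscoveryConfig(max_seeds=300))
        # the forward motif itself must not surface; its RC may
        assert models[0].consensus != motif

    def test_best_significance_reproducible(self, rng):
        sets = _toy_sets(rng)
        cfg = DiscoveryConfig(max_seeds=200, seed=9)
        a = discover(sets, [10, 12], "discriminative", 1, cfg)[0]
        b = discover(sets, [10, 12], "discriminative", 1, cfg)[0]
        assert a.significance == b.significance
        assert a.consensus == b.consensus


class TestProtocol:
    def test_report_structure(self, protocol_report):
        assert [p.name for p in protocol_report.passes] == ["A", "B", "C", "D"]
        assert protocol_report.final_pwm.width == 29

    def test_final_consensus_close_to_truth(self, protocol_report):
        truth = DEFAULT_TRUTH_MOTIF
        ham = sum(a != b for a, b in zip(protocol_report.final_pwm.consensus, truth))
        assert ham <= 3

    def test_one_per_species_covers_nodulators(self, default_bundle, protocol_report):
        nodulators = {s.species_id for s in default_bundle.statuses
                      if s.clade and s.trait}
        assert set(protocol_report.one_per_species) == nodulators
        # and exactly one gene per species
        assert len(set(protocol_report.one_per_species.values())) == len(nodulators)

    def test_em_traces_monotone_in_every_pass(self, protocol_report):
        for p in protocol_report.passes:
            trace = np.asarray(p.model.trace)
            assert (np.diff(trace) >= -1e-9).all()
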