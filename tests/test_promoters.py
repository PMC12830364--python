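"""Upstream extraction and discovery-set assembly."""

import pytest
from hypothesis import given, settings, strategies as st

import pacefinder as pf
from pacefinder._sequence import revcomp
from pacefinder.promoters import (
    EmptyPositiveSetError,
    GeneRecord,
    PromoterRecord,
    build_sets,
    extract_upstream,
)


def _gene(**kw):
    base = dict(gene_id="g", species_id="sp", family="NIN", contig="c",
                strand="+", translation_start=0)
    base.update(kw)
    return GeneRecord(**base)


class TestExtractUpstream:
    def test_plus_strand(self):
        rec = extract_upstream({"c": "ACGTACGTAC"}, _gene(translation_start=6), L=3)
        assert rec.sequence == "TAC" and not rec.truncated

    def test_minus_strand(self):
        rec = extract_upstream(
            {"c": "ACGTACGTAC"}, _gene(strand="-", translation_start=3), L=3
        )
        assert rec.sequence == "CGT" and not rec.truncated

    def test_truncation_keeps_longest_stretch(self):
        contig = "A" * 1200
        rec = extract_upstream({"c": contig}, _gene(translation_start=1200), L=3000)
        assert rec.actual_length == 1200
        assert rec.truncated
        assert rec.requested_length == 3000

    def test_length_override(self):
        rec = extract_upstream(
            {"c": "ACGTACGTAC"}, _gene(translation_start=8, length_override=4), L=3000
        )
        assert rec.sequence == "ACGT"
        assert rec.requested_length == 4

    def test_unknown_contig(self):
        with pytest.raises(KeyError):
            extract_upstream({"c": "ACGT"}, _gene(contig="missing"), L=2)

    def test_out_of_bounds_start(self):
        with pytest.raises(IndexError):
            extract_upstream({"c": "ACGT"}, _gene(translation_start=9), L=2)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60), st.data())
    @settings(max_examples=50, deadline=None)
    def test_strand_involution(self, contig, data):
        """+ extraction at t equals - extraction on the reverse-complemented
        contig at the mirrored coordinate."""
        t = data.draw(st.integers(min_value=1, max_value=len(contig) - 1))
        L = data.draw(st.integers(min_value=1, max_value=len(contig)))
        fwd = extract_upstream({"c": contig}, _gene(translation_start=t), L=L)
        mirrored = extract_upstream(
            {"c": revcomp(contig)},
            _gene(strand="-", translation_start=len(contig) - 1 - t),
            L=L,
        )
        assert fwd.sequence == mirrored.sequence
        assert fwd.truncated == mirrored.truncated


def _prom(gene_id, species_id, family):
    return PromoterRecord(gene_id=gene_id, species_id=species_id, family=family,
                          sequence="ACGTACGT", requested_length=8,
                          actual_length=8, truncated=False)


@pytest.fixture()
def toy():
    promoters = [
        _prom("nin1", "cladeA", "NIN"),
        _prom("nin2", "cladeB", "NIN"),
        _prom("nin3", "outX", "NIN"),
        _prom("nlp1", "cladeA", "NLP"),
        _prom("nlp2", "cladeB", "NLP"),
        _prom("nlp3", "outX", "NLP"),
    ]
    species = [
        pf.SpeciesStatus("cladeA", clade=True, trait=True),
        pf.SpeciesStatus("cladeB", clade=True, trait=True),
        pf.SpeciesStatus("outX", clade=False, trait=False),
    ]
    return promoters, species


class TestBuildSets:
    def test_discriminative_partition(self, toy):
        promoters, species = toy
        sets = build_sets(promoters, species, "discriminative")
        assert sorted(p.gene_id for p in sets.positives) == ["nin1", "nin2"]
        assert sorted(p.gene_id for p in sets.controls) == ["nin3", "nlp1", "nlp2", "nlp3"]

    def test_normal_has_no_controls(self, toy):
        promoters, species = toy
        sets = build_sets(promoters, species, "normal")
        assert sorted(p.gene_id for p in sets.positives) == ["nin1", "nin2"]
        assert sets.controls == []

    def test_all_non_nodulating_is_an_error(self, toy):
        promoters, _ = toy
        species = [
            pf.SpeciesStatus("cladeA", clade=True, trait=False),
            pf.SpeciesStatus("cladeB", clade=True, trait=False),
            pf.SpeciesStatus("outX", clade=False, trait=False),
        ]
        with pytest.raises(EmptyPositiveSetError):
            build_sets(promoters, species, "discriminative")

    def test_every_promoter_lands_in_exactly_one_bin(self, default_bundle):
        b = default_bundle
        sets = build_sets(b.promoters, b.statuses, "discriminative")
        pos = {p.gene_id for p in sets.positives}
        ctrl = {p.gene_id for p in sets.controls}
        assert not pos & ctrl
        everything = {p.gene_id for p in b.promoters}
        excluded = everything - pos - ctrl
        # excluded = focal promoters of trait-negative clade species
        losers = {s.species_id for s in b.statuses if s.clade and not s.trait}
        assert excluded == {f"{sp}_NIN" for sp in losers}

    def test_one_per_species_uses_mapping(self, toy):
        promoters, species = toy
        sets = build_sets(promoters, species, "one_per_species",
                          best_per_species={"cladeA": "nin1"})
        assert [p.gene_id for p in sets.positives] == ["nin1"]

    def test_missing_species_status(self, toy):
        promoters, species = toy
        with pytest.raises(KeyError):
            build_sets(promoters, species[:-1], "normal")
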