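"""Gap surprisal, exon totals, isoform ranking, and branch-point scanning."""

import math

import numpy as np
import pytest

from spliceinfo.exondef import (
    GapSurprisalModel,
    default_edges,
    default_exon_length_model,
    default_regulatory_distance_model,
    exon_total,
    find_branchpoints,
    gap_surprisal,
    rank_isoforms,
)
from spliceinfo.scoring import ScoredSite, score_site, site_span
from spliceinfo.synthetic import design_site_sequence, random_background
from spliceinfo.variants import VariantRecord


def _site(kind, zero, r_i):
    return ScoredSite(model_name=kind, site_kind=kind, zero_coord=zero,
                      strand="+", r_i=r_i, contributions=np.array([r_i]),
                      window_seq="A")


@pytest.fixture
def simple_gs():
    # four bins with probabilities 1/2, 1/4, 1/8, 1/8
    return GapSurprisalModel(
        kind="exon_length",
        edges=np.array([50, 100, 200, 400]),
        probabilities=np.array([0.5, 0.25, 0.125, 0.125]),
    )


class TestGapSurprisal:
    def test_probability_one_bin_is_zero_bits(self):
        model = GapSurprisalModel("exon_length", np.array([100]), np.array([1.0]))
        assert gap_surprisal(model, 40) == pytest.approx(0.0)

    def test_eighth_probability_bin_is_three_bits(self, simple_gs):
        assert gap_surprisal(simple_gs, 150) == pytest.approx(3.0)

    def test_rarer_bins_cost_more_than_modal_bins(self, simple_gs):
        """Uncommon lengths always carry a larger surprisal penalty."""
        probs = {L: simple_gs.probability(L) for L in (25, 75, 150, 300)}
        for a in probs:
            for b in probs:
                if probs[a] < probs[b]:
                    assert simple_gs.surprisal(a) > simple_gs.surprisal(b)

    def test_tail_floor_policy(self, simple_gs):
        assert simple_gs.surprisal(10_000) == pytest.approx(20.0)

    def test_tail_last_bin_policy(self):
        model = GapSurprisalModel("exon_length", np.array([50, 100]),
                                  np.array([0.75, 0.25]), tail_policy="last_bin")
        assert model.surprisal(999) == pytest.approx(2.0)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            GapSurprisalModel("exon_length", np.array([10, 20]),
                              np.array([0.5, 0.4]))

    def test_from_lengths_normalizes(self):
        model = GapSurprisalModel.from_lengths([100, 100, 120, 5000])
        assert model.probabilities.sum() == pytest.approx(1.0)

    def test_default_model_is_modal_near_120nt(self):
        model = default_exon_length_model()
        assert model.surprisal(120) < model.surprisal(3400)
        assert model.surprisal(120) < model.surprisal(12)

    def test_regulatory_distances_penalize_remoteness(self):
        model = default_regulatory_distance_model()
        assert model.surprisal(5) < model.surprisal(50) < model.surprisal(300)


class TestExonTotal:
    def test_direct_sum(self, simple_gs):
        cand = exon_total(_site("acceptor", 100, 10.0), _site("donor", 251, 8.0),
                          simple_gs)
        # length 150 falls in the 1/8 bin: 10 + 8 - 3
        assert cand.length == 150
        assert cand.r_i_total == pytest.approx(15.0)

    def test_zero_surprisal_total_is_site_sum(self):
        gs = GapSurprisalModel("exon_length", np.array([1000]), np.array([1.0]))
        cand = exon_total(_site("acceptor", 0, 9.0), _site("donor", 120, 7.0), gs)
        assert cand.r_i_total == pytest.approx(16.0)

    def test_regulatory_term_adds_ri_minus_surprisal(self, simple_gs):
        dist = default_regulatory_distance_model()
        reg_site = _site("regulatory", 108, 5.0)
        plain = exon_total(_site("acceptor", 100, 10.0), _site("donor", 251, 8.0),
                           simple_gs)
        with_reg = exon_total(_site("acceptor", 100, 10.0), _site("donor", 251, 8.0),
                              simple_gs, regulatory=("SF2", [reg_site], dist))
        s = dist.surprisal(8)
        assert with_reg.r_i_total == pytest.approx(plain.r_i_total + 5.0 - s)
        # splice-site strengths are untouched by the regulatory term
        assert with_reg.acceptor.r_i == plain.acceptor.r_i
        assert with_reg.donor.r_i == plain.donor.r_i

    def test_strongest_regulatory_site_chosen(self, simple_gs):
        dist = default_regulatory_distance_model()
        sites = [_site("regulatory", 108, 2.0), _site("regulatory", 108, 6.5)]
        cand = exon_total(_site("acceptor", 100, 10.0), _site("donor", 251, 8.0),
                          simple_gs, regulatory=("SF2", sites, dist))
        assert cand.regulatory.r_i == 6.5

    def test_donor_upstream_of_acceptor_rejected(self, simple_gs):
        with pytest.raises(ValueError, match="downstream"):
            exon_total(_site("acceptor", 100, 10.0), _site("donor", 50, 8.0),
                       simple_gs)

    def test_total_decreases_when_length_moves_to_rarer_bin(self, simple_gs):
        common = exon_total(_site("acceptor", 0, 10.0), _site("donor", 41, 8.0),
                            simple_gs)   # length 40, p = 1/2
        rare = exon_total(_site("acceptor", 0, 10.0), _site("donor", 301, 8.0),
                          simple_gs)     # length 300, p = 1/8
        assert rare.r_i_total < common.r_i_total


class TestRankIsoforms:
    def _kwargs(self, gene, models):
        acc = next(p for p in gene.naturals
                   if p.site_kind == "acceptor" and p.zero_coord > 1000)
        don = next(p for p in gene.naturals
                   if p.site_kind == "donor" and p.zero_coord > acc.zero_coord)
        return dict(
            acceptor_model=models["acceptor"],
            donor_model=models["donor"],
            natural_acceptor=acc.zero_coord,
            natural_donor=don.zero_coord,
            gs_model=default_exon_length_model(),
        )

    def test_noop_variant_keeps_rankings_identical(self, gene, models):
        kw = self._kwargs(gene, models)
        pos = kw["natural_donor"] + 1
        v = VariantRecord(gene.seq_id, pos, gene.sequence[pos - 1], gene.sequence[pos - 1])
        out = rank_isoforms(gene.sequence, v, **kw)
        pre = [(i.candidate.acceptor.zero_coord, i.candidate.donor.zero_coord, i.rank)
               for i in out["pre"] if i.candidate]
        post = [(i.candidate.acceptor.zero_coord, i.candidate.donor.zero_coord, i.rank)
                for i in out["post"] if i.candidate]
        assert pre == post
        assert out["pre"][0].candidate.is_wild_type

    def test_abolishing_donor_ranks_skipping_first(self, gene, models):
        kw = self._kwargs(gene, models)
        don = kw["natural_donor"]
        v = VariantRecord(gene.seq_id, don + 1, gene.sequence[don], "T")  # kill the G
        out = rank_isoforms(gene.sequence, v, **kw)
        assert out["post"][0].isoform_type == "skipping"
        assert out["post"][0].rank == 1

    def test_stronger_cryptic_exon_outranks_weakened_natural(self, gene, models):
        """A ~3.5-bit hit to the natural donor (below the skip threshold)
        hands the top rank to the planted cryptic donor 20 nt downstream."""
        kw = self._kwargs(gene, models)
        don = kw["natural_donor"]
        model = models["donor"]
        ref = gene.sequence[don - 1]  # offset -1
        alt = min("ACGT".replace(ref, ""),
                  key=lambda b: abs(model.weight(b, -1) - model.weight(ref, -1) + 3.5))
        v = VariantRecord(gene.seq_id, don, ref, alt)
        out = rank_isoforms(gene.sequence, v, **kw)
        top = out["post"][0]
        assert top.isoform_type == "exon"
        assert top.candidate.donor.zero_coord == don + 20
        assert not top.candidate.is_wild_type


class TestBranchPoints:
    def _scaffold(self, models, offset_from_acceptor):
        bps = models["branchpoint"]
        rng = np.random.default_rng(31)
        seq = list(random_background(700, rng))
        acceptor_zero = 600
        z = acceptor_zero - offset_from_acceptor
        seq[z - 5 : z + 2] = list(bps.consensus())
        return "".join(seq), acceptor_zero, z

    def test_planted_consensus_30nt_upstream_found(self, models):
        seq, acc, z = self._scaffold(models, 30)
        hits = find_branchpoints(models["branchpoint"], seq, acc)
        best = hits[0]
        assert best.site.zero_coord == z
        assert best.distance_to_acceptor == 30
        assert best.context_ok

    def test_hit_inside_donor_window_flagged(self, models):
        seq, acc, z = self._scaffold(models, 30)
        donor_span = site_span(models["donor"], z + 2, "+")
        hits = find_branchpoints(models["branchpoint"], seq, acc,
                                 donor_windows=[donor_span])
        best = next(h for h in hits if h.site.zero_coord == z)
        assert not best.context_ok

    def test_motif_beyond_hard_max_absent(self, models):
        seq, acc, z = self._scaffold(models, 500)
        hits = find_branchpoints(models["branchpoint"], seq, acc,
                                 search_nt=600, hard_max_nt=400)
        assert z not in [h.site.zero_coord for h in hits]

    def test_distances_bounded_and_nonnegative(self, models):
        seq, acc, _ = self._scaffold(models, 30)
        hits = find_branchpoints(models["branchpoint"], seq, acc, search_nt=400,
                                 hard_max_nt=400)
        assert all(0 <= h.distance_to_acceptor <= 400 for h in hits)
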