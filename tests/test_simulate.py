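"""The synthetic-data generator: planted truth must be exactly recoverable."""
import numpy as np
import pytest
from scipy import stats

from fivec.reads import ReferenceIndex, filter_reads, map_reads
from fivec.regions import ECORI_SITE, GenomicInterval, RestrictionFragment, digest
from fivec.simulate import (
    ContactModelParams,
    ContaminationRates,
    SpecificContact,
    build_scenario,
    expected_matrix,
    fragment_map,
    mini_hoxa_params,
    plant_site_positions,
    simulate_counts,
    simulate_reads,
    simulate_region,
    write_scenario,
)


class TestParamsValidation:
    def test_defaults_are_valid(self):
        mini_hoxa_params()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(region_length=10_000),
            dict(decay_exponent=0.0),
            dict(cross_tad_multiplier=1.5),
            dict(cross_tad_multiplier=0.8, cross_subtad_multiplier=0.5),
            dict(tad_boundaries=(500_000, 100_000)),
            dict(n_reads=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mini_hoxa_params(**kwargs)

    def test_contamination_must_sum_below_one(self):
        with pytest.raises(ValueError):
            ContaminationRates(0.5, 0.4, 0.2)


class TestSimulateRegion:
    def test_zero_site_density_gives_single_fragment(self):
        params = mini_hoxa_params(site_density=0.0, region_length=60_000,
                                  gene_promoter_positions=(30_000,),
                                  enhancer_positions=(10_000,),
                                  tad_boundaries=(), subtad_boundaries=())
        region = simulate_region(params, seed=0)
        assert len(region.fragments) == 1
        # a 60 kb single fragment is ineligible only if > 20 kb — it is,
        # but annotation hosting falls back to any fragment
        assert region.fragments[0].length == 60_000

    def test_seeded_runs_are_identical(self):
        a = simulate_region(mini_hoxa_params(), seed=9)
        b = simulate_region(mini_hoxa_params(), seed=9)
        assert a.sequence == b.sequence
        assert a.site_positions == b.site_positions
        assert [f.interval for f in a.fragments] == [f.interval for f in b.fragments]

    def test_digest_reproduces_planted_fragment_map(self):
        region = simulate_region(mini_hoxa_params(), seed=5)
        redigested = digest(region.sequence, seq_name=region.params.seq_name)
        assert [f.interval for f in redigested] == [f.interval for f in region.fragments]
        assert len(redigested) == len(region.site_positions) + 1
        for frag in redigested[1:]:
            assert region.sequence[frag.start: frag.start + 6] == ECORI_SITE

    def test_fragment_map_matches_materialized_region(self):
        params = mini_hoxa_params()
        frags = fragment_map(params, np.random.SeedSequence(5).spawn(2)[0])
        region = simulate_region(params, seed=5)
        assert [f.interval for f in frags] == [f.interval for f in region.fragments]

    def test_annotations_sit_on_eligible_fragments(self):
        region = simulate_region(mini_hoxa_params(), seed=2)
        elig = [f.interval for f in region.fragments if f.eligible]
        for iv in region.promoters + region.enhancers:
            assert any(iv.overlaps(e) for e in elig)


class TestExpectedMatrix:
    def frags(self, mids, seq="chrS"):
        out = []
        for i, m in enumerate(mids):
            out.append(RestrictionFragment(GenomicInterval(seq, m - 500, m + 500), i))
        return out

    def test_hand_computed_four_fragment_example(self):
        # fragments at 10, 30, 50, 70 kb; one sub-TAD boundary at 40 kb;
        # one specific "limb" contact between fragments 0 and 3
        frags = self.frags([10_000, 30_000, 50_000, 70_000])
        params = mini_hoxa_params(
            tad_boundaries=(), subtad_boundaries=(40_000,),
            cross_subtad_multiplier=0.5, decay_exponent=1.0, decay_offset=10_000,
            specific_contacts=(SpecificContact(
                GenomicInterval("chrS", 9_500, 10_500),
                GenomicInterval("chrS", 69_500, 70_500), 4.0, "limb"),),
        )
        m = expected_matrix(params, frags, "limb")
        d = np.abs(np.subtract.outer([10_000, 30_000, 50_000, 70_000],
                                     [10_000, 30_000, 50_000, 70_000]))
        w = (d + 10_000.0) ** -1.0
        crossed = np.array([[(a < 40_000) != (b < 40_000)
                             for b in (10_000, 30_000, 50_000, 70_000)]
                            for a in (10_000, 30_000, 50_000, 70_000)])
        w = np.where(crossed, w * 0.5, w)
        w[0, 3] *= 4.0
        w[3, 0] *= 4.0
        np.fill_diagonal(w, 0.0)
        w /= w.sum()
        np.testing.assert_allclose(m.values, w, rtol=1e-12)

    def test_head_tissue_lacks_limb_contacts(self):
        frags = self.frags([10_000, 30_000, 50_000, 70_000])
        params = mini_hoxa_params(
            tad_boundaries=(), subtad_boundaries=(),
            specific_contacts=(SpecificContact(
                GenomicInterval("chrS", 9_500, 10_500),
                GenomicInterval("chrS", 69_500, 70_500), 4.0, "limb"),),
        )
        limb = expected_matrix(params, frags, "limb")
        head = expected_matrix(params, frags, "head")
        assert limb.values[0, 3] > head.values[0, 3]
        # away from the planted cell the two tissues share the same structure
        # up to renormalization
        ratio = limb.values[1, 2] / head.values[1, 2]
        ratio2 = limb.values[0, 1] / head.values[0, 1]
        assert ratio == pytest.approx(ratio2, rel=1e-9)

    def test_sums_to_one_and_symmetric(self):
        region = simulate_region(mini_hoxa_params(), seed=7)
        m = expected_matrix(region.params, region.fragments, "limb")
        assert m.values.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(m.values, m.values.T, rtol=1e-12)
        assert np.all(np.diag(m.values) == 0)

    def test_monotone_decay_without_blocks(self):
        frags = self.frags(list(range(10_000, 90_000, 5_000)))
        params = mini_hoxa_params(tad_boundaries=(), subtad_boundaries=())
        m = expected_matrix(params, frags, "limb")
        row = m.values[0, 1:]
        assert np.all(np.diff(row) < 0)


class TestSimulateReads:
    def test_clean_run_keeps_every_read(self, anchored_scenario):
        sc = anchored_scenario
        params = mini_hoxa_params(contamination=ContaminationRates(0, 0, 0))
        reads, planted = simulate_reads(sc.expected["limb"], sc.design,
                                        sc.references, params, seed=1,
                                        n_reads=2_000)
        map_reads(reads, ReferenceIndex(sc.references))
        kept, rejected = filter_reads(reads)
        assert len(kept) == 2_000
        assert sum(rejected.values()) == 0
        assert (planted.low_quality, planted.offset_shift, planted.site_ablated) == (0, 0, 0)

    def test_planted_contaminants_rejected_exactly(self, anchored_scenario):
        sc = anchored_scenario
        reads, planted = simulate_reads(sc.expected["limb"], sc.design,
                                        sc.references, sc.region.params, seed=2,
                                        n_reads=10_000)
        assert (planted.low_quality, planted.offset_shift, planted.site_ablated) == (120, 80, 50)
        map_reads(reads, ReferenceIndex(sc.references))
        kept, rejected = filter_reads(reads)
        assert rejected["low_quality"] == 120
        assert rejected["offset"] == 80
        assert rejected["no_site"] == 50
        assert rejected["unmapped"] == 0
        assert len(kept) == 10_000 - 250

    def test_deterministic_under_seed(self, anchored_scenario):
        sc = anchored_scenario
        args = (sc.expected["limb"], sc.design, sc.references, sc.region.params)
        a, _ = simulate_reads(*args, seed=3, n_reads=500)
        b, _ = simulate_reads(*args, seed=3, n_reads=500)
        assert [(r.sequence, r.quality) for r in a] == [(r.sequence, r.quality) for r in b]

    def test_pair_frequencies_converge_to_expected(self, anchored_scenario):
        """Multinomial goodness of fit of sampled counts to the model."""
        sc = anchored_scenario
        n = 1_000_000
        _, counts = simulate_counts(sc.expected["limb"], sc.design, n, seed=4)
        from fivec.simulate import _design_pair_probabilities

        pairs, probs = _design_pair_probabilities(sc.expected["limb"], sc.design)
        observed = np.array([counts[p] for p in pairs], dtype=float)
        expected = probs * n
        # pool cells with small expectation so the chi-square approximation holds
        order = np.argsort(expected)
        obs_p, exp_p = [], []
        acc_o = acc_e = 0.0
        for i in order:
            acc_o += observed[i]
            acc_e += expected[i]
            if acc_e >= 5:
                obs_p.append(acc_o)
                exp_p.append(acc_e)
                acc_o = acc_e = 0.0
        if acc_e > 0:
            obs_p[-1] += acc_o
            exp_p[-1] += acc_e
        stat, p = stats.chisquare(obs_p, exp_p)
        assert p > 0.01

    def test_deep_run_concentrates_on_expected(self, anchored_scenario):
        """Multinomial concentration: cells with a large expected count land
        within 20% of the model.  The count floor (500) is where a 20% band
        actually follows from Poisson scaling across thousands of cells
        (relative SD ~4.5%, so even the worst of ~10^3 cells stays inside)."""
        sc = anchored_scenario
        n = 1_000_000
        _, counts = simulate_counts(sc.expected["limb"], sc.design, n, seed=6)
        from fivec.simulate import _design_pair_probabilities

        pairs, probs = _design_pair_probabilities(sc.expected["limb"], sc.design)
        expected = probs * n
        big = expected >= 500
        assert big.sum() >= 50  # the band is exercised on many cells
        observed = np.array([counts[p] for p in pairs], dtype=float)
        rel_err = np.abs(observed[big] - expected[big]) / expected[big]
        assert rel_err.max() < 0.2


def test_write_scenario_materializes_all_inputs(tmp_path):
    scenario = build_scenario(mini_hoxa_params(), seed=1)
    paths = write_scenario(scenario, tmp_path / "demo")
    for key in ("fasta", "fragments", "promoters", "enhancers", "design", "truth"):
        assert key in paths
    from fivec.regions import read_fasta

    seqs = read_fasta(paths["fasta"])
    assert seqs[scenario.region.params.seq_name] == scenario.region.sequence
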