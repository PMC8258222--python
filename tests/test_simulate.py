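"""Census and trait simulators against planted truth."""

import numpy as np
import pytest

import treedemog as td
from treedemog.simulate import OGAWA_SAMPLE_SIZES, random_tree

from conftest import random_valid_rates


def one_class_config(scheme, rates, n, class_index=5, years=(2000, 2001), mode="mechanistic", seed=0):
    return td.SimConfig(
        scheme=scheme,
        true_rates=rates,
        initial_counts={(rates.species[0], class_index): n},
        schedules={i: years for i in range(1, scheme.n_classes + 1)},
        seed=seed,
        mode=mode,
    )


class TestSimulatePopulation:
    def test_pure_stasis_never_moves(self, scheme):
        K, C = 1, scheme.n_classes
        S = np.zeros((K, C))
        S[0, 1:] = 1.0  # class 1 cannot have stasis
        rates = td.AnnualRates(("sp1",), scheme, S, np.zeros((K, C)), np.zeros((K, C)))
        cfg = one_class_config(scheme, rates, 50, years=tuple(range(2000, 2006)))
        tallies = td.tally_transitions(td.simulate_population(cfg), scheme)
        assert all(t.n_st == t.n_all and t.n_pr == t.n_rt == 0 for t in tallies)

    def test_lethal_entry_class_kills_every_seedling(self, scheme):
        K, C = 1, scheme.n_classes
        rates = td.AnnualRates(
            ("sp1",), scheme, np.zeros((K, C)), np.zeros((K, C)), np.zeros((K, C))
        )
        cfg = one_class_config(scheme, rates, 200, class_index=1, years=(2000, 2001))
        histories = td.simulate_population(cfg)
        assert all(not h.observations[-1].alive for h in histories)

    def test_survival_frequency_within_binomial_error(self, scheme):
        rng = np.random.default_rng(0)
        rates = random_valid_rates(rng, scheme, species=("sp1",))
        p_sv = rates.S[0, 4] + rates.G[0, 4] + rates.R[0, 4]
        n = 10_000
        cfg = one_class_config(scheme, rates, n, seed=1)
        tallies = td.tally_transitions(td.simulate_population(cfg), scheme)
        survivors = sum(t.n_survivors for t in tallies)
        sd = np.sqrt(n * p_sv * (1 - p_sv))
        assert abs(survivors - n * p_sv) < 3 * sd

    def test_model_exact_two_year_frequencies_match_linked_probs(self, scheme):
        """In model-exact mode the 2-year outcome law is the linked law."""
        rng = np.random.default_rng(3)
        rates = random_valid_rates(rng, scheme, species=("sp1",))
        n = 8_000
        cfg = one_class_config(
            scheme, rates, n, class_index=4, years=(2000, 2002), mode="model-exact", seed=5
        )
        tallies = td.tally_transitions(td.simulate_population(cfg), scheme)
        (t,) = [x for x in tallies if x.class_index == 4]
        S2, G2, R2 = td.link_interval(rates, 2)
        for observed, p in ((t.n_st, S2[0, 3]), (t.n_pr, G2[0, 3]), (t.n_rt, R2[0, 3])):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) < 4 * sd + 1

    def test_modes_agree_where_simplification_term_vanishes(self, scheme):
        """With no retrogression the dropped linking term R*G(below) is zero,
        so mechanistic and model-exact laws coincide."""
        rng = np.random.default_rng(4)
        rates = random_valid_rates(rng, scheme, species=("sp1",))
        rates.R[:] = 0.0
        n = 8_000
        freqs = {}
        # class 11: the class above is the ladder top, so no 2-step path
        # leaves the one-class band and the two laws coincide exactly
        for mode in ("mechanistic", "model-exact"):
            cfg = one_class_config(
                scheme, rates, n, class_index=11, years=(2000, 2002), mode=mode, seed=6
            )
            tallies = td.tally_transitions(td.simulate_population(cfg), scheme)
            (t,) = [x for x in tallies if x.class_index == 11]
            freqs[mode] = np.array([t.n_st, t.n_pr]) / n
        assert np.all(np.abs(freqs["mechanistic"] - freqs["model-exact"]) < 0.03)

    def test_invalid_rates_rejected_before_simulation(self, scheme):
        K, C = 1, scheme.n_classes
        S = np.full((K, C), 0.9)
        G = np.full((K, C), 0.3)  # S + G > 1
        with pytest.raises(ValueError):
            td.AnnualRates(("sp1",), scheme, S, G, np.zeros((K, C)))

    def test_intervals_only_1_2_4(self, scheme):
        rng = np.random.default_rng(5)
        rates = random_valid_rates(rng, scheme, species=("sp1",))
        with pytest.raises(ValueError, match="gaps"):
            one_class_config(scheme, rates, 10, years=(2000, 2003))


class TestOgawaLikeConfig:
    def test_structure(self):
        cfg = td.make_ogawa_like_config(0)
        assert cfg.scheme.n_classes == 12
        assert len(cfg.true_rates.species) == 17

    def test_no_individuals_above_species_max(self):
        cfg = td.make_ogawa_like_config(0)
        m = cfg.scheme.max_class("Acer_rufinerve")  # D30
        above = [
            (sp, i) for (sp, i) in cfg.initial_counts
            if sp == "Acer_rufinerve" and i > m
        ]
        assert m == 7 and above == []

    def test_equal_seeds_equal_configs(self):
        a = td.make_ogawa_like_config(42)
        b = td.make_ogawa_like_config(42)
        assert a.initial_counts == b.initial_counts
        assert np.array_equal(a.true_rates.S, b.true_rates.S)
        c = td.make_ogawa_like_config(43)
        assert not np.array_equal(a.true_rates.S, c.true_rates.S)

    def test_counts_match_design_magnitudes(self):
        cfg = td.make_ogawa_like_config(1)
        # pooled starters over the study should be within a factor ~3 of the
        # design's tabulated totals for well-populated cells
        histories = td.simulate_population(
            td.make_ogawa_like_config(1, count_scale=1.0)
        )
        tallies = td.tally_transitions(histories, cfg.scheme)
        sap = sum(t.n_all for t in tallies
                  if t.species == "Fagus_crenata" and t.class_index == 3)
        assert 2213 / 3 < sap < 2213 * 3

    def test_seedling_schedule_is_yearly(self):
        cfg = td.make_ogawa_like_config(0)
        gaps = {b - a for a, b in zip(cfg.schedules[1], cfg.schedules[1][1:])}
        assert gaps == {1}
        gaps_plot = {b - a for a, b in zip(cfg.schedules[5], cfg.schedules[5][1:])}
        assert gaps_plot == {2, 4}


class TestTraitSimulation:
    def test_perfect_correlation_degenerate(self, tree17):
        x, y = td.simulate_traits(
            td.TraitSimConfig(tree=tree17, target_corr=1.0, seed=1)
        )
        assert td.correlate(x, y, tree17, "pic").r == pytest.approx(1.0, abs=1e-9)

    def test_zero_correlation_unbiased(self, tree17):
        rs = [
            td.correlate(*td.simulate_traits(
                td.TraitSimConfig(tree=tree17, target_corr=0.0, seed=rep)
            ), tree17, "pic").r
            for rep in range(200)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_lambda_zero_traits_recover_low_lambda(self, tree17):
        lams = [
            td.pagel_lambda(
                tree17,
                td.simulate_traits(
                    td.TraitSimConfig(tree=tree17, lam=0.0, seed=rep)
                )[0],
            ).lambda_hat
            for rep in range(20)
        ]
        assert np.median(lams) < 0.2

    def test_seed_determinism(self, tree17):
        a = td.simulate_traits(td.TraitSimConfig(tree=tree17, seed=7))
        b = td.simulate_traits(td.TraitSimConfig(tree=tree17, seed=7))
        assert a == b

    def test_random_tree_is_deterministic_and_binary(self):
        assert random_tree(10, seed=3) == random_tree(10, seed=3)
        tree = td.read_newick(random_tree(10, seed=3))
        from treedemog.phylo import has_polytomy, tip_labels

        assert not has_polytomy(tree)
        assert len(tip_labels(tree)) == 10
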