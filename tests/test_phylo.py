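"""Tree IO, contrasts, phylogenetic signal and correlation tests."""

import math

import numpy as np
import pytest
from scipy import stats

import treedemog as td
from treedemog.simulate import random_tree


class TestNewickIO:
    def test_canonical_parse(self):
        tree = td.read_newick("((A:1,B:1):1,C:2);")
        assert sorted(td.phylo.tip_labels(tree)) == ["A", "B", "C"]
        root_children = tree.seed_node.child_nodes()
        assert len(root_children) == 2

    def test_round_trip(self):
        text = "((A:1.5,B:0.5):0.25,(C:1.0,D:1.0):1.25);"
        tree = td.read_newick(text)
        again = td.read_newick(td.write_newick(tree))
        labels, C1 = td.tip_covariance(tree)
        labels2, C2 = td.tip_covariance(again, labels)
        assert np.allclose(C1, C2)

    def test_parse_error_is_reported(self):
        with pytest.raises(ValueError, match="parse"):
            td.read_newick("((A:1,B:1):1,C:2;")

    def test_polytomy_accepted_on_read_rejected_for_pic(self):
        tree = td.read_newick("(A:1,B:1,C:1,D:1);")
        traits = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        with pytest.raises(ValueError, match="polytom"):
            td.pic(tree, traits)
        cv = td.pic(tree, traits, resolve_polytomies=True)
        assert len(cv.contrasts) == 3


class TestLogit:
    def test_center(self):
        assert td.logit(0.5) == 0.0

    def test_closed_form(self):
        assert math.isclose(td.logit(0.9), math.log(9), rel_tol=1e-12)

    def test_symmetry(self):
        for p in (0.2, 0.43, 0.77):
            assert math.isclose(td.logit(1 - p), -td.logit(p), rel_tol=1e-12)

    def test_clamping_keeps_finite(self):
        assert np.isfinite(td.logit(0.0)) and np.isfinite(td.logit(1.0))


class TestPic:
    def test_two_sister_tips_closed_form(self):
        tree = td.read_newick("((A:1,B:1):1,C:2);")
        cv = td.pic(tree, {"A": 1.0, "B": 3.0, "C": 2.0})
        mags = sorted(np.abs(cv.contrasts))
        assert math.isclose(max(mags), 2 / math.sqrt(2), rel_tol=1e-12)

    def test_constant_trait_gives_zero_contrasts(self, tree17):
        labels = td.phylo.tip_labels(tree17)
        cv = td.pic(tree17, {l: 3.7 for l in labels})
        assert np.allclose(cv.contrasts, 0.0)

    def test_contrast_count(self, tree17):
        labels = td.phylo.tip_labels(tree17)
        rng = np.random.default_rng(0)
        cv = td.pic(tree17, dict(zip(labels, rng.standard_normal(17))))
        assert len(cv.contrasts) == 16 and cv.n_species == 17

    def test_matches_gls_whitening_oracle(self, tree5):
        """Contrast rows U satisfy U C U' = I under the BM tip covariance.

        PIC is a linear map; extracting it by applying pic() to unit
        vectors and checking the whitening identity against the explicit
        covariance matrix is an independent linear-algebra oracle.
        """
        labels, C = td.tip_covariance(tree5)
        n = len(labels)
        U = np.column_stack(
            [
                td.pic(tree5, {l: float(l == lab) for l in labels}).contrasts
                for lab in labels
            ]
        )
        assert np.max(np.abs(U @ C @ U.T - np.eye(n - 1))) < 1e-10
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        cv = td.pic(tree5, dict(zip(labels, x)))
        assert np.allclose(cv.contrasts, U @ x, atol=1e-12)

    def test_tip_order_invariance(self, tree5):
        labels, _ = td.tip_covariance(tree5)
        rng = np.random.default_rng(2)
        x = dict(zip(labels, rng.standard_normal(len(labels))))
        a = td.pic(tree5, x).contrasts
        shuffled = {k: x[k] for k in reversed(list(x))}
        b = td.pic(tree5, shuffled).contrasts
        assert np.allclose(sorted(np.abs(a)), sorted(np.abs(b)))

    def test_contrasts_iid_standard_under_bm(self, tree17):
        """Standardized contrasts are ~N(0, rate) i.i.d. under BM."""
        all_c = []
        for rep in range(60):
            x, _ = td.simulate_traits(
                td.TraitSimConfig(tree=tree17, lam=1.0, rate=2.0, seed=rep)
            )
            all_c.append(td.pic(tree17, x).contrasts)
        arr = np.array(all_c)
        assert abs(arr.var() - 2.0) < 0.25
        lag = np.mean([np.corrcoef(c[:-1], c[1:])[0, 1] for c in arr])
        assert abs(lag) < 0.1

    def test_missing_branch_lengths_rejected(self):
        tree = td.read_newick("((A:1,B:1),C:2);")
        with pytest.raises(ValueError, match="branch length"):
            td.pic(tree, {"A": 1.0, "B": 2.0, "C": 0.0})


class TestPagelLambda:
    def test_bm_traits_recover_high_lambda(self, tree17):
        lams = [
            td.pagel_lambda(
                tree17,
                td.simulate_traits(
                    td.TraitSimConfig(tree=tree17, lam=1.0, seed=rep)
                )[0],
            ).lambda_hat
            for rep in range(20)
        ]
        assert np.mean(lams) > 0.8

    def test_permuted_traits_lose_signal(self, tree17):
        labels = td.phylo.tip_labels(tree17)
        rng = np.random.default_rng(3)
        lams = []
        for rep in range(20):
            x, _ = td.simulate_traits(
                td.TraitSimConfig(tree=tree17, lam=1.0, seed=100 + rep)
            )
            vals = np.array([x[l] for l in labels])
            rng.shuffle(vals)
            lams.append(td.pagel_lambda(tree17, dict(zip(labels, vals))).lambda_hat)
        assert np.median(lams) < 0.3

    def test_mle_beats_dense_grid(self, tree17):
        """Golden-section optimum matches a dense grid search."""
        x, _ = td.simulate_traits(td.TraitSimConfig(tree=tree17, lam=0.7, seed=11))
        fit = td.pagel_lambda(tree17, x)
        labels, C = td.tip_covariance(tree17)
        vals = np.array([x[l] for l in labels])
        from treedemog.phylo import _bm_profile_loglik, _lambda_cov

        grid = np.linspace(0, 1, 501)
        lls = [_bm_profile_loglik(vals, _lambda_cov(C, g)) for g in grid]
        g_best = grid[int(np.argmax(lls))]
        assert fit.log_likelihood >= max(lls) - 1e-6
        assert abs(fit.lambda_hat - g_best) < 5e-3

    def test_likelihood_at_bounds_not_above_mle(self, tree17):
        x, _ = td.simulate_traits(td.TraitSimConfig(tree=tree17, lam=0.5, seed=21))
        fit = td.pagel_lambda(tree17, x)
        labels, C = td.tip_covariance(tree17)
        vals = np.array([x[l] for l in labels])
        from treedemog.phylo import _bm_profile_loglik, _lambda_cov

        for lam in (0.0, 1.0):
            assert fit.log_likelihood >= _bm_profile_loglik(vals, _lambda_cov(C, lam)) - 1e-9


class TestCorrelate:
    def test_identity_and_reversal(self):
        x = {"A": 1.0, "B": 2.0, "C": 3.0}
        assert td.correlate(x, x).r == pytest.approx(1.0)
        y = {"A": 3.0, "B": 2.0, "C": 1.0}
        assert td.correlate(x, y).r == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self, tree17):
        x, y = td.simulate_traits(
            td.TraitSimConfig(tree=tree17, target_corr=0.4, seed=0)
        )
        for method in ("raw", "pic"):
            a = td.correlate(x, y, tree17, method)
            b = td.correlate(y, x, tree17, method)
            assert a.r == pytest.approx(b.r) and a.p == pytest.approx(b.p)
            y2 = {k: 3.0 * v - 7.0 for k, v in y.items()}
            c = td.correlate(x, y2, tree17, method)
            assert c.r == pytest.approx(a.r) and c.p == pytest.approx(a.p)

    def test_raw_matches_scipy_pearsonr(self, tree17):
        x, y = td.simulate_traits(
            td.TraitSimConfig(tree=tree17, target_corr=-0.5, seed=4)
        )
        res = td.correlate(x, y, method="raw")
        keys = sorted(x)
        ref = stats.pearsonr([x[k] for k in keys], [y[k] for k in keys])
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize(
        "method,n,r,p_printed",
        [
            ("pic", 9, 0.929, 0.001),
            ("pic", 15, -0.741, 0.002),
            ("pic", 11, -0.663, 0.037),
            ("raw", 15, -0.814, 0.000),
        ],
    )
    def test_df_convention_reproduces_printed_p_values(self, method, n, r, p_printed):
        """Contrast-test p-values are consistent with df = (n-1) - 2.

        Back-computing the two-sided t-test from published (r, n) pairs of
        per-class survivorship-growth correlation tables reproduces the
        printed three-decimal p-values under this package's df convention:
        n - 2 for plain Pearson, (n-1) - 2 for Pearson on the n-1 contrasts.
        """
        df = n - 2 if method == "raw" else (n - 1) - 2
        t = abs(r) * math.sqrt(df / (1 - r * r))
        p = 2 * stats.t.sf(t, df)
        assert round(p, 3) == p_printed

    def test_insufficient_species_refused(self, tree17):
        x = {"t0": 1.0, "t1": 2.0}
        with pytest.raises(ValueError, match="at least 3"):
            td.correlate(x, x, method="raw")
        x3 = {"t0": 1.0, "t1": 2.0, "t2": 0.5}
        with pytest.raises(ValueError, match="at least 4"):
            td.correlate(x3, x3, tree17, method="pic")


class TestFiltersAndNormality:
    def _summary_and_tallies(self, scheme):
        rng = np.random.default_rng(0)
        from conftest import random_valid_rates

        species = tuple(sorted(td.OGAWA_MAX_CLASS))
        rates = random_valid_rates(rng, scheme, species=species)
        summary = td.derive_summary(rates)
        tallies = []
        for k, sp in enumerate(species):
            n = 4 if sp.startswith("Cerasus") else 5 + k
            tallies.append(td.TransitionTally(sp, 5, 2, n, max(n - 2, 0), 1, 0))
        return summary, tallies

    def test_min_n_boundary(self, scheme):
        summary, tallies = self._summary_and_tallies(scheme)
        kept = td.filter_species_for_class(summary, tallies, scheme, 5, min_n=5)
        assert "Cerasus_leveilleana" not in kept  # n = 4 excluded
        assert "Acer_amoenum" in kept  # n = 5 boundary included

    def test_growth_excluded_at_entry_and_max_class(self, scheme):
        summary, tallies = self._summary_and_tallies(scheme)
        assert td.filter_species_for_class(
            summary, tallies, scheme, 1, trait="growth") == []
        tallies7 = [
            td.TransitionTally(sp, 7, 2, 20, 15, 0, 0)
            for sp in ("Styrax_obassia", "Fagus_crenata")
        ]
        kept = td.filter_species_for_class(
            summary, tallies7, scheme, 7, trait="growth")
        assert "Styrax_obassia" not in kept  # D30 is its maximum class
        assert "Fagus_crenata" in kept

    def test_sparse_species_count_matches_hand_count(self, scheme):
        cfg = td.make_ogawa_like_config(4, count_scale=0.05)
        tallies = td.tally_transitions(td.simulate_population(cfg), scheme)
        summary = td.derive_summary(cfg.true_rates)
        by_hand = {
            sp for sp in cfg.true_rates.species
            if sum(t.n_all for t in tallies if t.species == sp and t.class_index == 6) >= 5
        }
        kept = td.filter_species_for_class(summary, tallies, scheme, 6, min_n=5)
        assert set(kept) == by_hand

    def test_normality_p_uniform_under_null(self):
        rng = np.random.default_rng(5)
        ps = [td.normality_check(rng.standard_normal(50))[1] for _ in range(200)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(6)
        rejected = 0
        for _ in range(50):
            x = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
            rejected += td.normality_check(x)[1] < 0.05
        assert rejected > 45

    def test_minimal_and_constant_inputs(self):
        stat, p = td.normality_check([0.1, 0.5, 0.9])
        assert np.isfinite(stat) and 0 <= p <= 1
        with pytest.raises(ValueError, match="constant"):
            td.normality_check([1.0, 1.0, 1.0])


class TestCorrelationTable:
    def test_planted_correlation_detected_end_to_end(self, scheme):
        """A strong planted survivorship-growth association at one class
        shows up in both the PIC and the raw column."""
        from conftest import random_valid_rates

        species = tuple(sorted(td.OGAWA_MAX_CLASS))
        # rename tips of a random tree to the species labels (reverse order
        # so that t1 does not clobber t10..t16)
        nw = random_tree(17, seed=9)
        for q in reversed(range(17)):
            nw = nw.replace(f"t{q}:", f"{species[q]}:")
        tree = td.read_newick(nw)
        rng = np.random.default_rng(10)
        rates = random_valid_rates(rng, scheme, species=species)
        # plant: survivorship and growth perfectly rank-associated at D10
        sv = np.linspace(0.55, 0.95, 17)
        gi = np.linspace(0.1, 0.6, 17)
        rates.S[:, 4] = sv * (1 - gi)
        rates.G[:, 4] = sv * gi
        summary = td.derive_summary(rates)
        tallies = [
            td.TransitionTally(sp, i, 2, 40, 30, 5, 0)
            for sp in species
            for i in (4, 5, 6)
            if i <= scheme.max_class(sp)
        ]
        table = td.correlation_table(summary, tallies, tree, scheme)
        row = table[table["class"] == "D10"].iloc[0]
        assert row["r_raw"] > 0.9 and row["p_raw"] < 1e-4
        assert row["r_pic"] > 0.5 and row["n"] == 17
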