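"""Model fits, nesting, parameter recovery, LRTs, and NEB posteriors."""

import numpy as np
import pytest

from mytilomito.codon_model import CodonModelError
from mytilomito.selection import (
    FitConfig,
    fit_branch_model,
    fit_branch_site,
    fit_one_ratio,
    lrt,
    neb_site_posteriors,
)
from mytilomito.synthetic import SimAlignmentSpec, simulate_codon_alignment

EIGHT_TAXON_TREE = (
    "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,"
    "((E:0.2,F:0.2):0.1,(G:0.2,H:0.2):0.1):0.1);"
)
SIX_TAXON_TREE = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,(E:0.2,F:0.2):0.15);"
CLASSES = {"A": "deep", "B": "deep", "C": "shallow", "D": "shallow",
           "E": "fresh", "F": "fresh"}
FAST = FitConfig(n_starts=1)


@pytest.fixture(scope="module")
def purifying_data():
    spec = SimAlignmentSpec(newick=SIX_TAXON_TREE, n_codons=300, omega=0.1, seed=5)
    return simulate_codon_alignment(spec)


@pytest.fixture(scope="module")
def one_ratio_fit(purifying_data):
    aln, truth = purifying_data
    return fit_one_ratio(aln, truth["tree"], FAST)


class TestNesting:
    def test_branch_model_lnl_at_least_one_ratio(self, purifying_data, one_ratio_fit):
        aln, truth = purifying_data
        alt = fit_branch_model(aln, truth["tree"], CLASSES, FAST, init=one_ratio_fit)
        assert alt.lnL >= one_ratio_fit.lnL - 1e-4
        assert alt.n_free_params == one_ratio_fit.n_free_params + 2

    def test_degenerate_partition_equals_one_ratio(self, purifying_data, one_ratio_fit):
        aln, truth = purifying_data
        same = fit_branch_model(
            aln, truth["tree"], {t: "x" for t in truth["tree"].taxa}, FAST
        )
        assert same.model_tag == "one_ratio"
        assert same.lnL == pytest.approx(one_ratio_fit.lnL, abs=1e-3)
        (w_same,) = same.params.omega_map.values()
        (w_one,) = one_ratio_fit.params.omega_map.values()
        assert w_same == pytest.approx(w_one, rel=1e-2)

    def test_branch_site_alt_at_least_null(self, purifying_data, one_ratio_fit):
        aln, truth = purifying_data
        null = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=True,
                               config=FAST, init=one_ratio_fit)
        alt = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=False,
                              config=FAST, init=one_ratio_fit)
        assert alt.lnL >= null.lnL - 1e-4
        assert alt.n_free_params == null.n_free_params + 1


class TestBranchSiteParameterization:
    def test_proportion_invariant(self, purifying_data, one_ratio_fit):
        aln, truth = purifying_data
        fit = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=False,
                              config=FAST, init=one_ratio_fit)
        assert fit.p0 + fit.p1 + fit.p2a + fit.p2b == pytest.approx(1.0)
        if fit.p1 > 1e-8 and fit.p2b > 1e-8:
            assert fit.p2a / fit.p2b == pytest.approx(fit.p0 / fit.p1, rel=1e-6)
        assert 0 < fit.omega0 < 1 and fit.omega2 >= 1

    def test_foreground_must_be_proper_subset(self, purifying_data):
        aln, truth = purifying_data
        with pytest.raises(CodonModelError, match="foreground"):
            fit_branch_site(aln, truth["tree"], set(), null=True, config=FAST)


class TestRecovery:
    def test_one_ratio_recovers_omega(self):
        """omega-hat close to the simulated 0.2 (2-seed spot check; the full
        20-seed bias bound runs in the acceptance suite)."""
        for seed in (11, 12):
            spec = SimAlignmentSpec(newick=EIGHT_TAXON_TREE, n_codons=1500,
                                    omega=0.2, seed=seed)
            aln, truth = simulate_codon_alignment(spec)
            fit = fit_one_ratio(aln, truth["tree"], FAST)
            (omega,) = fit.params.omega_map.values()
            assert fit.converged
            assert omega == pytest.approx(0.2, abs=0.05)

    def test_branch_class_ordering_recovered(self):
        """Simulated deep-sea relaxation (omega 0.10 vs 0.03): class
        estimates ordered correctly in >=18/20 seeded replicates."""
        ok = 0
        for seed in range(20):
            spec = SimAlignmentSpec(
                newick=SIX_TAXON_TREE, n_codons=300, omega=0.03,
                class_omegas={"deep": 0.10, "shallow": 0.03, "fresh": 0.03},
                class_by_taxon=CLASSES, seed=100 + seed,
            )
            aln, truth = simulate_codon_alignment(spec)
            one = fit_one_ratio(aln, truth["tree"], FAST)
            fit = fit_branch_model(aln, truth["tree"], CLASSES, FAST, init=one)
            w = fit.params.omega_map
            if w["deep"] > w["shallow"] and w["deep"] > w["fresh"]:
                ok += 1
        assert ok >= 18

    def test_branch_site_power(self):
        """Planted positive selection (omega2=5 on 10% of sites on the
        foreground): LRT p < 0.05 in >=80% of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            spec = SimAlignmentSpec(
                newick=SIX_TAXON_TREE, n_codons=300, omega=0.1,
                foreground=("E", "F"), pos_fraction=0.1, omega2=5.0,
                seed=200 + seed,
            )
            aln, truth = simulate_codon_alignment(spec)
            one = fit_one_ratio(aln, truth["tree"], FAST)
            null = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=True,
                                   config=FAST, init=one)
            alt = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=False,
                                  config=FAST, init=one)
            if lrt(null, alt, df=1).p_value < 0.05:
                hits += 1
        assert hits >= 16


class TestLrt:
    def test_equal_lnl_gives_p_one(self, one_ratio_fit):
        res = lrt(one_ratio_fit, one_ratio_fit, df=2)
        assert res.stat == 0 and res.p_value == 1

    def test_small_negative_clamped(self, one_ratio_fit):
        import dataclasses

        slightly_worse = dataclasses.replace(one_ratio_fit,
                                             lnL=one_ratio_fit.lnL - 0.01)
        assert lrt(one_ratio_fit, slightly_worse, df=1).stat == 0

    def test_large_deficit_raises(self, one_ratio_fit):
        import dataclasses

        worse = dataclasses.replace(one_ratio_fit, lnL=one_ratio_fit.lnL - 5)
        with pytest.raises(CodonModelError, match="optimizer"):
            lrt(one_ratio_fit, worse, df=1)

    def test_df_must_be_positive(self, one_ratio_fit):
        with pytest.raises(ValueError):
            lrt(one_ratio_fit, one_ratio_fit, df=0)


class TestNebPosteriors:
    def test_posteriors_normalized_and_enriched(self):
        """Each site's class posteriors sum to 1; flagged sites are enriched
        for the truly positively selected ones (pooled Fisher test)."""
        from scipy.stats import fisher_exact

        table = np.zeros((2, 2), dtype=int)
        for seed in (300, 301, 302):
            spec = SimAlignmentSpec(
                newick=SIX_TAXON_TREE, n_codons=300, omega=0.1,
                foreground=("E", "F"), pos_fraction=0.1, omega2=5.0, seed=seed,
            )
            aln, truth = simulate_codon_alignment(spec)
            one = fit_one_ratio(aln, truth["tree"], FAST)
            alt = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=False,
                                  config=FAST, init=one)
            post = neb_site_posteriors(alt, aln, truth["tree"])
            assert post.method == "NEB"
            assert np.allclose(post.posteriors.sum(axis=1), 1.0, atol=1e-9)
            flagged = set(post.flagged)
            positive = set(np.flatnonzero(truth["site_positive"]))
            for site in range(spec.n_codons):
                table[int(site in positive), int(site in flagged)] += 1
        _, p = fisher_exact(table)
        assert p < 0.05
        # flagged sites should mostly be true positives
        assert table[1, 1] > table[0, 1]

    def test_no_positive_class_no_flags(self, purifying_data, one_ratio_fit):
        aln, truth = purifying_data
        null = fit_branch_site(aln, truth["tree"], {"E", "F"}, null=True,
                               config=FAST, init=one_ratio_fit)
        import dataclasses

        degenerate = dataclasses.replace(null, p2a=0.0, p2b=0.0, p0=0.9, p1=0.1)
        post = neb_site_posteriors(degenerate, aln, truth["tree"])
        assert len(post.flagged) == 0
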