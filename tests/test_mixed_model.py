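import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srtmkit import (
    fit_mixed_cs,
    groupwise_comparison,
    holm_adjust,
    interaction_contrast,
    all_pairwise_interaction_contrasts,
    make_longitudinal_dataset,
    rebound_cell_means,
    run_design_power,
)
from srtmkit.exceptions import DesignError

DAYS = (30, 44, 65, 86, 142)
GROUPS = ("treated", "control")


def flat_means(level=1.0):
    return {(g, d): level for g in GROUPS for d in DAYS}


class TestFitMixedCs:
    def test_noiseless_cell_means_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        means = {(g, d): float(rng.uniform(0.5, 2.5)) for g in GROUPS for d in DAYS}
        table = make_longitudinal_dataset(means, sigma_animal=0, sigma_resid=0, seed=0)
        fit = fit_mixed_cs(table)
        for cell, mu in means.items():
            assert fit.cell_means[cell] == pytest.approx(mu, abs=1e-12)
        assert fit.sigma2_resid == 0.0
        assert fit.balanced

    def test_no_animal_variance_matches_ols_cell_means(self):
        means = rebound_cell_means()
        table = make_longitudinal_dataset(means, sigma_animal=0.0, sigma_resid=0.15, seed=3)
        fit = fit_mixed_cs(table)
        ols = table.groupby(["group", "day"])["value"].mean()
        for cell in fit.cell_means.index:
            assert fit.cell_means[cell] == pytest.approx(ols[cell], abs=1e-6)

    def test_variance_component_recovery(self):
        """REML recovers the generating components within Monte-Carlo error (rho = 0.5)."""
        s2a = s2e = 0.04
        rng = np.random.default_rng(7)
        est_a, est_e = [], []
        for _ in range(120):
            t = make_longitudinal_dataset(
                flat_means(), sigma_animal=np.sqrt(s2a), sigma_resid=np.sqrt(s2e),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fit = fit_mixed_cs(t)
            est_a.append(fit.sigma2_animal)
            est_e.append(fit.sigma2_resid)
        # sigma2_resid has 30 df per replicate -> tight; sigma2_animal only 6 animals' worth
        assert np.mean(est_e) == pytest.approx(s2e, rel=0.10)
        assert np.mean(est_a) == pytest.approx(s2a, rel=0.35)
        assert 0 <= np.mean([a / (a + e) for a, e in zip(est_a, est_e)]) <= 1

    def test_rho_bounded(self):
        t = make_longitudinal_dataset(flat_means(), sigma_animal=0.3, sigma_resid=0.1, seed=5)
        fit = fit_mixed_cs(t)
        assert 0.0 <= fit.rho <= 1.0
        assert fit.sigma2_animal >= 0 and fit.sigma2_resid >= 0

    def test_single_timepoint_group_rejected(self):
        t = make_longitudinal_dataset(flat_means(), sigma_animal=0, sigma_resid=0, seed=0)
        t = t[(t.group == "treated") | (t.day == 30)]
        with pytest.raises(DesignError):
            fit_mixed_cs(t.reset_index(drop=True))

    def test_single_animal_group_rejected(self):
        t = make_longitudinal_dataset(flat_means(), n_per_group=1, sigma_animal=0, sigma_resid=0)
        with pytest.raises(DesignError):
            fit_mixed_cs(t)


class TestContrasts:
    def test_interaction_contrast_arithmetic(self):
        means = flat_means()
        means[("treated", 65)] += 0.5  # treated rises by 0.5 between day 44 and 65
        means[("control", 65)] -= 0.2  # control falls by 0.2
        table = make_longitudinal_dataset(means, sigma_animal=0, sigma_resid=0)
        fit = fit_mixed_cs(table)
        c = interaction_contrast(fit, "treated", "control", 44, 65)
        assert c.estimate == pytest.approx(0.7, abs=1e-12)
        assert c.pvalue == 0.0  # exact effect with zero noise

    def test_self_contrast_is_zero(self):
        table = make_longitudinal_dataset(rebound_cell_means(), sigma_animal=0.1, sigma_resid=0.1, seed=9)
        fit = fit_mixed_cs(table)
        c = interaction_contrast(fit, "treated", "treated", 44, 65)
        assert c.estimate == pytest.approx(0.0, abs=1e-12)

    def test_groupwise_equal_means_zero(self):
        table = make_longitudinal_dataset(flat_means(), sigma_animal=0, sigma_resid=0)
        fit = fit_mixed_cs(table)
        assert groupwise_comparison(fit, 65).estimate == pytest.approx(0.0, abs=1e-12)

    def test_groupwise_offset_recovered(self):
        means = flat_means()
        means[("treated", 86)] += 0.3
        table = make_longitudinal_dataset(means, sigma_animal=0, sigma_resid=0)
        fit = fit_mixed_cs(table)
        c = groupwise_comparison(fit, 86, "treated", "control")
        assert c.estimate == pytest.approx(0.3, abs=1e-12)

    def test_unknown_cell_raises_key_error(self):
        table = make_longitudinal_dataset(flat_means(), sigma_animal=0, sigma_resid=0)
        fit = fit_mixed_cs(table)
        with pytest.raises(KeyError):
            interaction_contrast(fit, "treated", "control", 44, 999)

    def test_se_shrinks_with_sample_size(self):
        ses = []
        for n in (4, 16):
            t = make_longitudinal_dataset(flat_means(), n_per_group=n, sigma_animal=0.2, sigma_resid=0.2, seed=13)
            fit = fit_mixed_cs(t)
            ses.append(interaction_contrast(fit, "treated", "control", 44, 65).se)
        assert ses[1] < ses[0]

    def test_pairwise_table_covers_all_day_pairs(self):
        table = make_longitudinal_dataset(rebound_cell_means(), sigma_animal=0.1, sigma_resid=0.1, seed=2)
        fit = fit_mixed_cs(table)
        tab = all_pairwise_interaction_contrasts(fit, "treated", "control")
        assert len(tab) == 10  # C(5, 2)

    def test_holm_adjustment_monotone(self):
        p = [0.001, 0.02, 0.04, 0.5]
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p))
        assert np.all(np.diff(adj[np.argsort(p)]) >= 0)


class TestDesignPower:
    def test_seeded_determinism(self):
        kw = dict(cell_means=flat_means(), sigma_animal=0.2, sigma_resid=0.2,
                  n_per_group=4, n_replicates=20, seed=21,
                  contrast=("treated", "control", 44, 65))
        assert run_design_power(**kw).rejection_rate == run_design_power(**kw).rejection_rate

    def test_null_rate_near_alpha(self):
        pr = run_design_power(
            flat_means(), sigma_animal=0.2, sigma_resid=0.2, n_per_group=4,
            n_replicates=200, seed=22, contrast=("treated", "control", 44, 65),
        )
        lo, hi = sps.binom.interval(0.99, 200, 0.05)
        assert lo / 200 <= pr.rejection_rate <= hi / 200
        assert pr.ci_low <= 0.05 <= pr.ci_high

    def test_large_effect_gives_high_power(self):
        """A 5-residual-SD day-65 offset is detected essentially always."""
        means = flat_means()
        means[("treated", 65)] += 5 * 0.2
        pr = run_design_power(
            means, sigma_animal=0.2, sigma_resid=0.2, n_per_group=4,
            n_replicates=100, seed=23, contrast=("treated", "control", 44, 65),
        )
        assert pr.rejection_rate > 0.9

    def test_moderate_effect_matches_noncentral_t_oracle(self):
        """Empirical power at a 3-residual-SD offset agrees with the analytic
        noncentral-t computation (SE of the difference-in-differences is
        exactly sigma_resid for n=4/group, so the noncentrality is 3)."""
        means = flat_means()
        means[("treated", 65)] += 3 * 0.2
        pr = run_design_power(
            means, sigma_animal=0.2, sigma_resid=0.2, n_per_group=4,
            n_replicates=200, seed=24, contrast=("treated", "control", 44, 65),
        )
        df = 30  # 40 obs - 10 cells
        tc = sps.t.ppf(0.975, df)
        analytic = 1 - sps.nct.cdf(tc, df, 3.0) + sps.nct.cdf(-tc, df, 3.0)
        lo, hi = sps.binom.interval(0.999, 200, analytic)
        assert lo / 200 <= pr.rejection_rate <= hi / 200
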