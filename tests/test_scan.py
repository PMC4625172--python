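"""Fixed-effects admixture mapping: scan, delta-R^2, effective tests, peaks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from admixvar import (
    AdmixtureSimConfig,
    bonferroni_alpha,
    effective_tests,
    locus_variance_explained,
    scan,
    significant_peaks,
    simulate_panel,
    simulate_single_locus_phenotype,
)
from admixvar.errors import DegenerateLocusError
from admixvar.scan import _ar1_contribution, _lag1_autocorrelation


@pytest.fixture(scope="module")
def unlinked_panel():
    """1000 effectively unlinked loci (500 chromosomes x 2 distant loci):
    the right fixture for calibration checks that assume independence."""
    cfg = AdmixtureSimConfig(
        n_individuals=500,
        n_chromosomes=500,
        loci_per_chromosome=2,
        chromosome_length_morgans=1.5,
        seed=77,
    )
    return simulate_panel(cfg)


class TestScan:
    def test_null_pvalues_uniform(self, unlinked_panel):
        p = unlinked_panel
        rng = np.random.default_rng(5)
        y = rng.normal(size=p.n_individuals)
        res = scan(p, y, np.ones((p.n_individuals, 1)))
        pv = res.table.p_value.dropna().to_numpy()
        from scipy.stats import kstest

        assert kstest(pv, "uniform").pvalue > 0.001

    def test_type_one_error_at_nominal_level(self, unlinked_panel):
        p = unlinked_panel
        y = np.random.default_rng(6).normal(size=p.n_individuals)
        res = scan(p, y, np.ones((p.n_individuals, 1)))
        frac = (res.table.p_value.dropna() < 0.05).mean()
        # binomial 3-sigma band around 0.05 with ~1000 near-independent loci
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_injected_large_effect_is_overwhelming(self):
        cfg = AdmixtureSimConfig(n_individuals=2600, n_chromosomes=4, loci_per_chromosome=30, seed=9)
        panel = simulate_panel(cfg)
        causal = 45
        y = simulate_single_locus_phenotype(panel.dosages[causal].astype(float), 0.193, 10)
        res = scan(panel, y, np.ones((2600, 1)))
        assert res.table.p_value[causal] < 1e-50

    def test_degenerate_locus_flagged(self):
        from admixvar import LocalAncestryPanel, Locus

        panel = LocalAncestryPanel(
            individual_ids=[f"i{j}" for j in range(30)],
            loci=[Locus("1", 100, "poly"), Locus("1", 200, "fixed")],
            dosages=np.vstack([
                np.random.default_rng(0).integers(0, 3, 30),
                np.full(30, 2),
            ]),
        )
        y = np.random.default_rng(1).normal(size=30)
        res = scan(panel, y, np.ones((30, 1)))
        assert bool(res.table.degenerate[1])
        assert np.isnan(res.table.p_value[1])
        assert not res.table.degenerate[0]

    def test_matches_statsmodels_ols(self, small_panel):
        """Independent oracle: per-locus OLS via statsmodels."""
        p = small_panel
        rng = np.random.default_rng(11)
        y = simulate_single_locus_phenotype(p.dosages[17].astype(float), 0.1, rng)
        covar = rng.normal(size=p.n_individuals)
        X = np.column_stack([np.ones(p.n_individuals), covar])
        res = scan(p, y, X)
        for locus in (0, 17, 101):
            x = p.dosages[locus].astype(float)
            fit = sm.OLS(y, np.column_stack([X, x])).fit()
            assert np.isclose(res.table.beta[locus], fit.params[-1], atol=1e-10)
            assert np.isclose(res.table.p_value[locus], fit.pvalues[-1], rtol=1e-8)

    def test_invariant_to_covariate_rescaling(self, small_panel):
        p = small_panel
        rng = np.random.default_rng(12)
        covar = rng.normal(size=p.n_individuals)
        y = rng.normal(size=p.n_individuals) + 0.5 * covar
        X1 = np.column_stack([np.ones(p.n_individuals), covar])
        X2 = np.column_stack([np.ones(p.n_individuals), 13.0 * covar - 2.0])
        r1, r2 = scan(p, y, X1), scan(p, y, X2)
        assert np.allclose(r1.table.beta, r2.table.beta, atol=1e-10)
        assert np.allclose(r1.table.p_value, r2.table.p_value, rtol=1e-8)


class TestDeltaR2:
    def test_perfect_predictor(self):
        x = np.random.default_rng(0).integers(0, 3, 200).astype(float)
        assert np.isclose(locus_variance_explained(x, x, np.ones((200, 1))), 1.0)

    def test_independent_locus_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=2600)
        x = rng.binomial(2, 0.8, 2600).astype(float)
        assert locus_variance_explained(y, x, np.ones((2600, 1))) < 0.01

    def test_mean_recovery_at_five_percent(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.8, 2600).astype(float)
        X = np.ones((2600, 1))
        vals = [
            locus_variance_explained(simulate_single_locus_phenotype(x, 0.05, rng), x, X)
            for _ in range(100)
        ]
        assert abs(np.mean(vals) - 0.05) < 0.01

    def test_algebraic_cross_check(self, small_panel):
        """delta-R^2 equals the RSS-ratio formula computed independently."""
        p = small_panel
        rng = np.random.default_rng(3)
        y = rng.normal(size=p.n_individuals)
        x = p.dosages[7].astype(float)
        X = np.ones((p.n_individuals, 1))
        d1 = locus_variance_explained(y, x, X)
        rss_red = np.sum(sm.OLS(y, X).fit().resid ** 2)
        rss_full = np.sum(sm.OLS(y, np.column_stack([X, x])).fit().resid ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert np.isclose(d1, (rss_red - rss_full) / tss, atol=1e-12)

    def test_degenerate_locus_raises(self):
        y = np.random.default_rng(4).normal(size=50)
        with pytest.raises(DegenerateLocusError):
            locus_variance_explained(y, np.full(50, 1.0), np.ones((50, 1)))


class TestEffectiveTests:
    def test_unlinked_loci_near_full_count(self, unlinked_panel):
        """Widely spaced loci are nearly independent along the genome; the
        residual ~0.14 correlation through shared global ancestry keeps the
        effective count slightly below the locus count."""
        eff = effective_tests(unlinked_panel)
        assert eff.n_eff > 0.7 * unlinked_panel.n_loci

    def test_perfect_correlation_contributes_one(self):
        assert _ar1_contribution(300, 1.0) == 1.0

    def test_zero_correlation_contributes_all(self):
        assert _ar1_contribution(300, 0.0) == 300.0

    def test_ar1_contribution_against_known_rho(self):
        """AR(1) series with rho=0.5 across 300 loci: effective sample size
        300 * (1-rho)/(1+rho) = 100."""
        rng = np.random.default_rng(8)
        n_ind, n_loci, rho = 400, 300, 0.5
        series = np.empty((n_loci, n_ind))
        series[0] = rng.normal(size=n_ind)
        for i in range(1, n_loci):
            series[i] = rho * series[i - 1] + np.sqrt(1 - rho**2) * rng.normal(size=n_ind)
        rho_hat = _lag1_autocorrelation(series)
        contrib = _ar1_contribution(n_loci, rho_hat)
        assert abs(contrib - 100.0) < 10.0

    def test_autocorrelated_panel_reduces_tests(self, small_panel):
        eff = effective_tests(small_panel)
        assert len(small_panel.chromosomes) <= eff.n_eff < small_panel.n_loci

    def test_bonferroni_thresholds(self):
        assert f"{bonferroni_alpha(373.1):.3g}" == "0.000134"
        assert f"{bonferroni_alpha(226.2):.3g}" == "0.000221"
        assert bonferroni_alpha(1.0) == 0.05
        with pytest.raises(ValueError):
            bonferroni_alpha(0.5)


class TestPeaks:
    @staticmethod
    def result_from(pvals, chroms):
        table = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": range(1, len(pvals) + 1),
                "locus_id": [f"l{k}" for k in range(len(pvals))],
                "beta": 1.0,
                "se": 1.0,
                "p_value": pvals,
                "delta_r2": 0.01,
                "degenerate": False,
            }
        )
        from admixvar import AdmixtureScanResult

        return AdmixtureScanResult(table=table)

    def test_no_hits_no_peaks(self):
        res = self.result_from([0.5, 0.9, 0.2], ["1"] * 3)
        assert significant_peaks(res, 1e-4) == []

    def test_single_run_single_peak(self):
        res = self.result_from([0.5, 1e-6, 1e-8, 1e-5, 0.7], ["1"] * 5)
        peaks = significant_peaks(res, 1e-4)
        assert len(peaks) == 1
        assert peaks[0].best_locus == "l2"

    def test_runs_on_distinct_chromosomes_are_distinct_peaks(self):
        res = self.result_from([1e-6, 0.5, 1e-6], ["1", "1", "2"])
        assert len(significant_peaks(res, 1e-4)) == 2

    def test_single_gap_does_not_break_a_peak(self):
        res = self.result_from([1e-6, 0.5, 1e-6], ["1"] * 3)
        assert len(significant_peaks(res, 1e-4)) == 1

    def test_double_gap_breaks_a_peak(self):
        res = self.result_from([1e-6, 0.5, 0.5, 1e-6], ["1"] * 4)
        assert len(significant_peaks(res, 1e-4)) == 2
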