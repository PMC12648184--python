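import itertools

import numpy as np
import pytest
from scipy import stats

from connpred.prediction import AccuracyTable, PredictionConfig
from connpred.probindex import (
    BlockMaxVector,
    EVDParams,
    GaussianParams,
    ZTable,
    block_maxima,
    count_top_tail,
    fit_evd,
    fit_pooled_gaussian,
    probability_index,
    tail_probability,
    trimmed_mean,
)


def make_table(values):
    values = np.asarray(values, dtype=float)
    return AccuracyTable(
        values=values,
        parcel_ids=[f"parcel_{j + 1:02d}" for j in range(values.shape[0])],
        fold_assignments=np.zeros((values.shape[1], 1), dtype=int),
        selected_lambdas=np.zeros((values.shape[0], values.shape[1], 1)),
    )


def oracle_trimmed_mean(values, trim_fraction):
    """Brute-force sort-and-discard reference."""
    v = sorted(values)
    k = int(np.floor(len(v) * trim_fraction / 2.0))
    kept = v[k:len(v) - k] if len(v) - 2 * k > 0 else None
    if kept is None:
        return float(np.median(v))
    return float(np.mean(kept))


class TestPooledGaussian:
    def test_recovers_sampling_moments(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(0.2, 0.05, size=(22, 100)))
        params, ztable = fit_pooled_gaussian(table)
        assert params.mu == pytest.approx(0.2, abs=0.01)
        assert params.sigma == pytest.approx(0.05, abs=0.01)
        cell = table.values[3, 7]
        assert ztable.values[3, 7] == pytest.approx((cell - params.mu) / params.sigma)

    def test_value_at_mean_has_zero_z(self):
        vals = np.arange(40, dtype=float).reshape(4, 10)
        params, ztable = fit_pooled_gaussian(make_table(vals))
        z_of_mu = (params.mu - params.mu) / params.sigma
        assert z_of_mu == 0.0

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            fit_pooled_gaussian(make_table(np.ones((5, 10))))

    def test_missing_cells_excluded(self):
        vals = np.arange(40, dtype=float).reshape(4, 10)
        vals[0, 0] = np.nan
        params, ztable = fit_pooled_gaussian(make_table(vals))
        assert params.mu == pytest.approx(np.nanmean(vals))
        assert np.isnan(ztable.values[0, 0])


class TestTailProbability:
    def test_median(self):
        p = GaussianParams(mu=0.3, sigma=0.1)
        assert tail_probability(0.3, p) == pytest.approx(0.5)

    def test_critical_value(self):
        p = GaussianParams(mu=0.0, sigma=1.0)
        assert tail_probability(1.96, p) == pytest.approx(0.025, abs=1e-3)

    def test_monotone_decreasing(self):
        p = GaussianParams(mu=0.0, sigma=0.2)
        rs = np.linspace(-1, 1, 21)
        probs = tail_probability(rs, p)
        assert (np.diff(probs) < 0).all()


class TestCountTopTail:
    def test_forced_counts(self):
        z = np.zeros((3, 100))
        z[0] = 3.0
        counts = count_top_tail(ZTable(values=z, parcel_ids=list("abc")))
        np.testing.assert_array_equal(counts, [100, 0, 0])

    def test_all_below_cutoff(self):
        z = np.full((2, 10), -1.0)
        counts = count_top_tail(ZTable(values=z, parcel_ids=list("ab")))
        np.testing.assert_array_equal(counts, [0, 0])

    def test_boundary_is_strict(self):
        z = np.array([[1.96, 1.9600001]])
        counts = count_top_tail(ZTable(values=z, parcel_ids=["a"]), z_cut=1.96)
        assert counts[0] == 1


class TestTrimmedMean:
    def test_ninety_percent_trim_keeps_middle(self):
        v = [0, 0, 0, 0, 0, 0, 0, 0, 0, 100]
        assert trimmed_mean(v, 0.9) == 0.0

    def test_zero_trim_is_mean(self):
        v = [0, 0, 0, 0, 0, 0, 0, 0, 0, 100]
        assert trimmed_mean(v, 0.0) == 10.0

    def test_singleton_fallback(self):
        assert trimmed_mean([7.5], 0.9) == 7.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            trimmed_mean([], 0.5)

    def test_exhaustive_against_oracle(self):
        rng = np.random.default_rng(11)
        fractions = [0.0, 0.1, 0.25, 0.45, 0.5, 0.75, 0.9, 0.99]
        for n, f in itertools.product(range(1, 13), fractions):
            v = rng.normal(size=n)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                got = trimmed_mean(v, f)
            assert got == pytest.approx(oracle_trimmed_mean(v, f), abs=1e-12)


class TestBlockMaxima:
    def test_linear_row_example(self):
        row = np.arange(0.1, 10.05, 0.1)  # 0.1 .. 10.0, R = 100
        z = np.vstack([row, np.zeros(100) + 0.001])
        bm = block_maxima(ZTable(values=z, parcel_ids=["a", "b"]))
        # top 10 are 9.1..10.0; 90% trim keeps ranks 5-6 -> 9.55
        assert bm.values[0] == pytest.approx(9.55)

    def test_constant_row_invariance(self):
        z = np.full((1, 50), 2.2)
        bm = block_maxima(ZTable(values=z, parcel_ids=["a"]))
        assert bm.values[0] == pytest.approx(2.2)

    def test_small_r_uses_row_maximum(self):
        z = np.array([[0.5, 3.0, -1.0, 0.2, 0.1]])
        bm = block_maxima(ZTable(values=z, parcel_ids=["a"]))
        assert bm.values[0] == 3.0

    def test_missing_runs_excluded(self):
        z = np.full((1, 100), 1.0)
        z[0, :50] = np.nan
        bm = block_maxima(ZTable(values=z, parcel_ids=["a"]))
        assert bm.effective_runs[0] == 50
        assert bm.values[0] == pytest.approx(1.0)

    def test_all_missing_raises(self):
        z = np.full((1, 10), np.nan)
        with pytest.raises(ValueError, match="non-missing"):
            block_maxima(ZTable(values=z, parcel_ids=["a"]))


class TestEVDFit:
    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(5)
        x = stats.gumbel_r.rvs(loc=0.0, scale=1.0, size=10000, random_state=rng)
        params = fit_evd(BlockMaxVector(values=x, parcel_ids=[""] * len(x)))
        assert params.location == pytest.approx(0.0, abs=0.05)
        assert params.scale == pytest.approx(1.0, abs=0.05)

    def test_location_equivariance(self):
        rng = np.random.default_rng(6)
        x = stats.gumbel_r.rvs(loc=1.0, scale=0.5, size=500, random_state=rng)
        base = fit_evd(BlockMaxVector(values=x, parcel_ids=[""] * len(x)))
        shifted = fit_evd(BlockMaxVector(values=x + 2.5, parcel_ids=[""] * len(x)))
        assert shifted.location == pytest.approx(base.location + 2.5, abs=1e-6)
        assert shifted.scale == pytest.approx(base.scale, abs=1e-6)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="zero spread"):
            fit_evd(BlockMaxVector(values=np.ones(10), parcel_ids=[""] * 10))

    def test_gev_family(self):
        rng = np.random.default_rng(7)
        x = stats.gumbel_r.rvs(loc=0.0, scale=1.0, size=2000, random_state=rng)
        params = fit_evd(BlockMaxVector(values=x, parcel_ids=[""] * len(x)),
                         family="gev")
        assert params.family == "gev"
        assert params.shape == pytest.approx(0.0, abs=0.1)


class TestProbabilityIndex:
    def test_value_at_gumbel_location(self):
        evd = EVDParams(family="gumbel", location=1.5, scale=0.7)
        bm = BlockMaxVector(values=np.array([1.5]), parcel_ids=["a"])
        out = probability_index(bm, evd)
        assert out.values[0] == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_strictly_decreasing_in_z(self):
        evd = EVDParams(family="gumbel", location=0.0, scale=1.0)
        # left of about loc - 3*scale the survival function saturates at 1.0
        zs = np.linspace(-1, 6, 30)
        bm = BlockMaxVector(values=zs, parcel_ids=[str(i) for i in range(30)])
        out = probability_index(bm, evd).values
        assert (np.diff(out) < 0).all()
        assert ((out >= 0) & (out <= 1)).all()

    def test_tail_limit(self):
        evd = EVDParams(family="gumbel", location=0.0, scale=1.0)
        bm = BlockMaxVector(values=np.array([50.0]), parcel_ids=["a"])
        assert probability_index(bm, evd).values[0] == pytest.approx(0.0, abs=1e-12)


class TestSelfConsistency:
    def test_iid_gaussian_tables_flag_near_nominal_rate(self):
        # grand total of top-tail counts over 50 i.i.d. tables stays within
        # binomial 99% sampling bounds of P*R*(1 - Phi(1.96))
        p_tail = stats.norm.sf(1.96)
        total = 0
        n_tables, P, R = 50, 22, 100
        for seed in range(n_tables):
            rng = np.random.default_rng(1000 + seed)
            table = make_table(rng.normal(0.1, 0.08, size=(P, R)))
            _, ztable = fit_pooled_gaussian(table)
            total += int(count_top_tail(ztable).sum())
        n = n_tables * P * R
        lo = stats.binom.ppf(0.005, n, p_tail)
        hi = stats.binom.ppf(0.995, n, p_tail)
        assert lo <= total <= hi
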