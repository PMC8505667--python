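import numpy as np
import pytest
from scipy import stats as sstats

from nirsmusic import activation as act
from nirsmusic import synthetic as syn
from nirsmusic.core import Recording
from nirsmusic.features import Regressor
from nirsmusic.preprocess import bandpass

FS = 8.9286


def _reg(values, name="rms", valid=True):
    return Regressor(feature_name=name, values=values, sampling_rate=FS, valid=valid)


def _rec(data):
    return Recording(data=data, sampling_rate=FS)


class TestCorrelate:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        rec = _rec(np.column_stack([x, -x, rng.normal(size=200)]))
        r = act.correlate(rec, [_reg(x)])
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(-1.0)
        assert abs(r[0, 2]) < 0.3

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 4))
        regs = [_reg(rng.normal(size=50), name=n)
                for n in ("rms", "mode", "roughness")]
        r = act.correlate(_rec(data), regs)
        for i, reg in enumerate(regs):
            for c in range(4):
                x, y = reg.values, data[:, c]
                oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
                assert r[i, c] == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_cells_marked_invalid_not_raised(self):
        data = np.column_stack([np.ones(50), np.arange(50.0)])
        regs = [_reg(np.arange(50.0)), _reg(np.zeros(50), name="mode", valid=False)]
        r = act.correlate(_rec(data), regs)
        assert np.isnan(r[0, 0])        # constant channel
        assert np.isnan(r[1, 1])        # invalid regressor
        assert r[0, 1] == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            act.correlate(_rec(np.zeros((50, 2))), [_reg(np.zeros(40))])


class TestEffectiveDf:
    def test_white_noise_near_nominal(self):
        rng = np.random.default_rng(0)
        dfs = [act.effective_df(rng.normal(size=1000), rng.normal(size=1000))
               for _ in range(20)]
        assert 800 <= np.mean(dfs) <= 1000

    def test_slow_sinusoids_heavily_penalised(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 0.02 * t)
        assert act.effective_df(x, x) < 1000 / 5

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            act.effective_df(np.arange(8.0), np.arange(8.0))

    def test_nominal_method_returns_n(self):
        assert act.effective_df(np.random.default_rng(0).normal(size=100),
                                np.random.default_rng(1).normal(size=100),
                                method="nominal") == 100

    def test_map_agrees_with_scalar(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(300, 3))
        regs = [_reg(rng.normal(size=300)), _reg(rng.normal(size=300), name="mode")]
        df_map = act.effective_df_map(_rec(data), regs)
        for i, reg in enumerate(regs):
            for c in range(3):
                assert df_map[i, c] == pytest.approx(
                    act.effective_df(reg.values, data[:, c]), rel=1e-9)


class TestZTransform:
    def test_zero_r_gives_zero_z_unit_p(self):
        z, zn, p = act.z_transform(np.array([[0.0]]), np.array([[100.0]]))
        assert z[0, 0] == 0 and zn[0, 0] == 0 and p[0, 0] == 1

    def test_known_value(self):
        z, zn, p = act.z_transform(np.array([[0.5]]), np.array([[103.0]]))
        assert zn[0, 0] == pytest.approx(np.arctanh(0.5) * 10, rel=1e-12)
        assert zn[0, 0] == pytest.approx(5.493, abs=1e-3)
        assert p[0, 0] < 1e-7

    def test_low_df_invalidated(self):
        z, zn, p = act.z_transform(np.array([[0.5]]), np.array([[3.0]]))
        assert np.isnan(p[0, 0])

    def test_null_p_values_uniform(self):
        # simulated null cells: independent white series pairs
        rng = np.random.default_rng(3)
        n = 300
        ps = []
        for _ in range(1000):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = np.corrcoef(x, y)[0, 1]
            df = act.effective_df(x, y)
            _, _, p = act.z_transform(np.array([[r]]), np.array([[df]]))
            ps.append(p[0, 0])
        assert sstats.kstest(ps, "uniform").pvalue > 0.01


class TestFisherCombine:
    def test_all_ones_give_zero(self):
        assert act.fisher_combine(np.ones(7)) == 0.0

    def test_known_value(self):
        t = act.fisher_combine(np.full(10, 0.05))
        assert t == pytest.approx(-20 * np.log(0.05), rel=1e-12)
        assert t == pytest.approx(59.915, abs=1e-3)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=9)
        assert act.fisher_combine(p) == pytest.approx(
            act.fisher_combine(rng.permutation(p)), rel=1e-12)

    def test_null_distribution_matches_chi2_2k(self):
        rng = np.random.default_rng(1)
        k = 10
        t = act.fisher_combine(rng.uniform(size=(k, 10_000)), axis=0)
        assert abs(t.mean() - 2 * k) / (2 * k) < 0.05

    def test_zero_p_clamped_with_warning(self):
        before = act.fisher_combine.n_clamped
        with pytest.warns(UserWarning, match="clamped"):
            t = act.fisher_combine(np.array([0.0, 0.5]))
        assert np.isfinite(t)
        assert act.fisher_combine.n_clamped == before + 1


class TestThreshold:
    def test_chi2_critical_value_k10(self):
        g = act.threshold_activation(np.zeros((2, 2)), k=10, alpha=0.01)
        assert round(g.critical_value, 2) == 37.57
        assert g.df_chi2 == 20

    def test_median_threshold(self):
        g = act.threshold_activation(np.zeros((1, 1)), k=10, alpha=0.5)
        assert g.critical_value == pytest.approx(sstats.chi2.median(20), rel=1e-9)
        assert g.critical_value == pytest.approx(19.34, abs=0.01)

    def test_zero_map_nothing_active(self):
        g = act.threshold_activation(np.zeros((4, 6)), k=5, alpha=0.05)
        assert not g.active.any()

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            act.threshold_activation(np.zeros((1, 1)), k=5, alpha=0.0)


class TestGroupActivation:
    def _cohort(self, regressors, montage, planted_r, k=5, seed0=0,
                duration=90.0):
        reg = next(r for r in regressors if r.feature_name == "rms")
        n = int(round(duration * FS))
        spec = syn.StimulusSpec(target_channels=[13], feature_name="rms",
                                target_correlation=planted_r)
        short = [Regressor(r.feature_name, r.values[:n], FS, r.valid)
                 for r in regressors]
        reg_short = next(r for r in short if r.feature_name == "rms")
        recs = [bandpass(syn.gen_stimulus_recording(
            reg_short, spec, montage, duration, seed=seed0 + s))
            for s in range(k)]
        return act.GroupActivation(recs, short, alpha=0.01).fit()

    def test_monotone_in_planted_correlation(self, montage, regressors180):
        medians = []
        for planted in (0.2, 0.5, 0.8):
            ts = [self._cohort(regressors180, montage, planted,
                               seed0=100 * rep).t_map[18, 12]
                  for rep in range(5)]
            medians.append(np.median(ts))
        assert medians[0] <= medians[1] <= medians[2]

    def test_summary_and_frame(self, montage, regressors180):
        res = self._cohort(regressors180, montage, 0.6)
        text = res.summary()
        assert "subjects (k):       5" in text
        frame = res.to_frame()
        assert set(frame.columns) == {"feature", "channel", "T", "active"}
        assert len(frame) == 24 * 19

    def test_plot_returns_axis(self, montage, regressors180):
        res = self._cohort(regressors180, montage, 0.6)
        ax = res.plot_tmap()
        assert ax.get_xlabel() == "channel"
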