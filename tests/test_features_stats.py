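import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbvent import SubjectParams, compare_cohorts, count_peaks, emd, \
    features_for_subject, filter_mee, generate_cohort, ttest_two_sample
from pbvent.datasets import load_reference_deltas, reference_feature_vectors
from pbvent.errors import ParameterError
from pbvent.features_stats import FeatureVector


def oracle_count(x, frac):
    """Exhaustive peak count: scan every interior sample, apply the
    plateau-first rule, and compute topographic prominence by brute force."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return 0
    count = 0
    for i in range(1, n - 1):
        if not x[i] > x[i - 1]:
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 >= n or not x[j + 1] < x[i]:
            continue
        if not x[i] > 0:
            continue
        # prominence: lowest point on each side before a strictly higher one
        left_min = x[i]
        for m in range(i - 1, -1, -1):
            if x[m] > x[i]:
                break
            left_min = min(left_min, x[m])
        right_min = x[i]
        for m in range(j + 1, n):
            if x[m] > x[i]:
                break
            right_min = min(right_min, x[m])
        prominence = x[i] - max(left_min, right_min)
        if prominence >= frac * rms:
            count += 1
    return count


class TestCountPeaks:
    def test_sinusoid_cycle_count(self):
        i = np.arange(196)  # 14 full cycles of period 14
        assert count_peaks(np.sin(2 * np.pi * i / 14)) == 14

    def test_all_zero(self):
        assert count_peaks(np.zeros(50)) == 0

    def test_noisy_sinusoid_matches_oracle(self):
        rng = np.random.default_rng(5)
        i = np.arange(300)
        x = np.sin(2 * np.pi * i / 20) + rng.uniform(-0.1, 0.1, 300)
        got = count_peaks(x, prominence_frac=0.5)
        assert got == oracle_count(x, 0.5)
        assert got == 15  # one peak per cycle

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fixture_oracle_equality(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(150) + 0.5 * np.sin(2 * np.pi * np.arange(150) / 12)
        assert count_peaks(x, 0.5) == oracle_count(x, 0.5)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 100_000),
           frac=st.floats(0.1, 1.5),
           n=st.integers(10, 120))
    def test_oracle_equality_property(self, seed, frac, n):
        x = np.random.default_rng(seed).standard_normal(n)
        assert count_peaks(x, frac) == oracle_count(x, frac)

    def test_detrend_allows_raw_signal(self):
        from scipy.ndimage import median_filter
        i = np.arange(300)
        x = 50.0 + 0.1 * i + np.sin(2 * np.pi * i / 20)
        detrended = x - median_filter(x, size=21, mode="nearest")
        assert count_peaks(x, 0.5, detrend=21) == oracle_count(detrended, 0.5)

    def test_too_short(self):
        with pytest.raises(ParameterError):
            count_peaks(np.zeros(2))


class TestFeaturesForSubject:
    def test_two_tone_deltas(self):
        # 20 cycles of period 14 plus 5 cycles of period 56
        i = np.arange(280)
        x = np.sin(2 * np.pi * i / 14) + np.sin(2 * np.pi * i / 56)
        fv = features_for_subject(emd(x), subject_id="t", label="PB")
        assert fv.deltas[0] == 20
        assert fv.deltas[1] == 5

    def test_single_imf_vector(self):
        i = np.arange(200)
        fv = features_for_subject(emd(np.sin(2 * np.pi * i / 20)))
        assert len(fv.deltas) >= 1
        assert fv.deltas[0] == 10

    def test_scale_invariance(self):
        x = np.random.default_rng(2).standard_normal(200)
        a = features_for_subject(emd(x)).deltas
        b = features_for_subject(emd(1000.0 * x)).deltas
        assert a == b

    def test_invalid_label(self):
        with pytest.raises(ParameterError):
            FeatureVector(subject_id="x", deltas=(1, 2), label="maybe")


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_reference_delta3_significant(self):
        df = load_reference_deltas()
        a = df[df.label == "PB"]["delta_3"]
        b = df[df.label == "nPB"]["delta_3"]
        for variant in ("pooled", "welch"):
            _, p = ttest_two_sample(a, b, variant=variant)
            assert p < 0.02

    def test_pooled_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t_ref), na + nb - 2)
        t, p = ttest_two_sample(a, b, variant="pooled")
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.4, 1.0, 10)
        _, p = ttest_two_sample(a, b, variant="pooled")
        p_perm = permutation_p(a, b, n_perm=100_000, seed=seed)
        assert abs(p - p_perm) < 0.02

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t1, p1 = ttest_two_sample(a, b)
        t2, p2 = ttest_two_sample(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        assert ttest_two_sample([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)
        t, p = ttest_two_sample([5.0, 5.0], [7.0, 7.0])
        assert np.isinf(t) and p == 0.0

    def test_size_errors(self):
        with pytest.raises(ParameterError):
            ttest_two_sample([1.0], [2.0, 3.0])


def permutation_p(a, b, n_perm, seed):
    """Two-sided permutation p-value of the pooled-t statistic."""
    pooled = np.concatenate([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    ga, gb = perm[:, :na], perm[:, na:]
    va = ga.var(axis=1, ddof=1)
    vb = gb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (len(b) - 1) * vb) / (len(pooled) - 2)
    t = (ga.mean(axis=1) - gb.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / len(b)))
    t_obs = ttest_two_sample(a, b)[0]
    return float(np.mean(np.abs(t) >= abs(t_obs)))


class TestCompareCohorts:
    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_reference_cohort_bounds(self, variant):
        comp = compare_cohorts(reference_feature_vectors(), variant=variant)
        assert comp.p_value(1) > 0.1
        assert comp.p_value(2) > 0.1
        assert comp.p_value(3) < 0.02
        assert comp.p_value(4) < 0.02
        assert comp.n_pb == 10 and comp.n_npb == 10

    def test_missing_group_errors(self):
        fv = [FeatureVector("a", (1,), "PB"), FeatureVector("b", (2,), "PB")]
        with pytest.raises(ParameterError):
            compare_cohorts(fv)

    def test_null_calibration_identical_generation(self):
        # both groups drawn with no oscillation: p-values should be null-ish
        low = {3: 0, 4: 0}
        n_seeds = 50
        for seed in range(n_seeds):
            cohort = generate_cohort(10, 10, seed=seed,
                                     pb_amplitude_range=(0.0, 0.0),
                                     npb_amplitude_range=(0.0, 0.0))
            feats = []
            for s in cohort:
                kept = filter_mee(s, allow_short=True).kept
                feats.append(features_for_subject(emd(kept),
                                                  subject_id=s.subject_id,
                                                  label=s.label))
            comp = compare_cohorts(feats)
            present = {r["imf_index"] for r in comp.rows}
            for i in (3, 4):
                if i in present and comp.p_value(i) < 0.05:
                    low[i] += 1
        for i in (3, 4):
            assert low[i] / n_seeds <= 0.15
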