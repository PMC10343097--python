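import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msaforge.stats_compare import (
    CLASSES,
    HYPOTHESES,
    SampleSet,
    best_class_frequencies,
    build_comparison_table,
    shapiro_normality,
    wilcoxon_one_sided,
)

from . import oracles


class TestShapiro:
    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            shapiro_normality([0.5] * 10)

    def test_uniform_sample_rejects_normality(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(size=200)
        assert shapiro_normality(x) < 0.05

    def test_normal_samples_mostly_pass(self):
        passed = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=50)
            if shapiro_normality(x) > 0.05:
                passed += 1
        assert passed >= 90

    def test_matches_scipy(self):
        x = np.random.default_rng(3).normal(size=30)
        assert shapiro_normality(x) == pytest.approx(sps.shapiro(x).pvalue)


class TestWilcoxon:
    def test_all_positive_differences_minimal_p(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a - 1.0
        assert wilcoxon_one_sided(a, b) == pytest.approx(1 / 2**6)

    def test_equal_samples_p_one(self):
        a = np.array([0.2, 0.4, 0.6])
        assert wilcoxon_one_sided(a, a) == 1.0

    def test_exact_matches_sign_enumeration(self, rng):
        """Exact p equals brute-force enumeration for n <= 10, ties included."""
        for _ in range(100):
            n = int(rng.integers(3, 11))
            # quantised values produce tied and zero differences regularly
            a = np.round(rng.uniform(0, 1, size=n), 1)
            b = np.round(rng.uniform(0, 1, size=n), 1)
            assert wilcoxon_one_sided(a, b) == pytest.approx(
                oracles.wilcoxon_exact_enumeration(a, b), abs=1e-12
            )

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 15))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            d = a - b
            if len(np.unique(np.abs(d))) != n or (d == 0).any():
                continue
            expected = sps.wilcoxon(a, b, alternative="greater",
                                    method="exact").pvalue
            assert wilcoxon_one_sided(a, b) == pytest.approx(expected)

    def test_one_sided_pair_sums_exceed_one_in_exact_case(self, rng):
        """p(a>b) + p(b>a) = 1 + P(W = w_obs) under the exact distribution."""
        for _ in range(20):
            n = int(rng.integers(4, 10))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            p1 = wilcoxon_one_sided(a, b)
            p2 = wilcoxon_one_sided(b, a)
            assert p1 + p2 >= 1.0 - 1e-12

    def test_approx_close_to_exact_at_cutoff(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.3, size=30)
        p_approx = wilcoxon_one_sided(a, b, method="approx")
        p_scipy = sps.wilcoxon(a, b, alternative="greater",
                               method="approx", correction=True).pvalue
        assert p_approx == pytest.approx(p_scipy, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([1, 2], [1, 2, 3])


def _make_store(n_instances=12, benchmark="bench", band="band1", delta=None, seed=0):
    """Synthetic score store over all 20 variations x 4 classes."""
    from msaforge.pipeline import enumerate_variations

    rng = np.random.default_rng(seed)
    rows = []
    for var in enumerate_variations():
        base = rng.uniform(0.3, 0.6, size=n_instances)
        for cls in CLASSES:
            vals = base.copy()
            if delta is not None and cls in delta:
                vals = np.clip(vals + delta[cls], 0, 1)
            for k in range(n_instances):
                rows.append(
                    {
                        "benchmark": benchmark,
                        "band": band,
                        "instance": f"i{k:02d}",
                        "variation": var,
                        "cls": cls,
                        "strategy": f"{var}+{cls}",
                        "ds": vals[k],
                    }
                )
    return pd.DataFrame(rows)


class TestComparisonTable:
    def test_shape_is_20_by_6(self):
        store = _make_store()
        table = build_comparison_table(store, "bench", "band1")
        assert table.shape[0] == 20
        assert list(table.columns[:6]) == list(HYPOTHESES)

    def test_identical_classes_give_p_one_unmarked(self):
        store = _make_store()
        table = build_comparison_table(store, "bench", "band1")
        assert (table["C>P"] == 1.0).all()
        assert not table["C>P sig"].any()

    def test_uniform_improvement_gives_minimal_exact_p(self):
        store = _make_store(n_instances=20, delta={"C": 0.05, "CI": 0.05})
        table = build_comparison_table(store, "bench", "band1")
        assert np.allclose(table["C>P"].to_numpy(), 1 / 2**20)
        assert table["C>P sig"].all()
        assert (table["CI>C"] == 1.0).all()

    def test_missing_strategy_listed(self):
        store = _make_store()
        store = store[~((store["variation"] == "F.NJ") & (store["cls"] == "I"))]
        with pytest.raises(ValueError, match="F.NJ\\+I"):
            build_comparison_table(store, "bench", "band1")


class TestBestClassFrequencies:
    def test_dominating_class_unique_everywhere(self):
        store = _make_store(delta={"CI": 0.2})
        freqs = best_class_frequencies(store, "bench", "band1")
        assert freqs.loc["CI", "unique_best_pct"] == 100.0
        assert freqs.loc["P", "tied_best_pct"] == 0.0

    def test_two_tied_classes(self):
        store = _make_store(delta={"C": 0.1, "I": 0.1})
        freqs = best_class_frequencies(store, "bench", "band1")
        assert freqs.loc["C", "tied_best_pct"] == 100.0
        assert freqs.loc["I", "tied_best_pct"] == 100.0
        assert freqs.loc["C", "unique_best_pct"] == 0.0

    def test_matches_brute_force_on_random_store(self, rng):
        from msaforge.pipeline import enumerate_variations

        rows = []
        records = []
        for k in range(10):
            for var in enumerate_variations():
                for cls in CLASSES:
                    v = float(np.round(rng.uniform(0, 1), 2))
                    rows.append(
                        {
                            "benchmark": "b",
                            "band": "band2",
                            "instance": f"i{k}",
                            "variation": var,
                            "cls": cls,
                            "strategy": f"{var}+{cls}",
                            "ds": v,
                        }
                    )
                    records.append((f"i{k}", cls, v))
        store = pd.DataFrame(rows)
        freqs = best_class_frequencies(store, "b", "band2")
        tied, unique = oracles.best_class_freqs_brute(records)
        for c in CLASSES:
            assert freqs.loc[c, "tied_best_pct"] == pytest.approx(tied[c])
            assert freqs.loc[c, "unique_best_pct"] == pytest.approx(unique[c])
        # structural invariants
        assert (
            freqs["unique_best_pct"] <= freqs["tied_best_pct"] + 1e-12
        ).all()
        assert freqs["unique_best_pct"].sum() <= 100.0 + 1e-9


class TestSampleSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            SampleSet("b", "band1", "F.NJ+P", ["i1"], [1.5])
        ss = SampleSet("b", "band1", "F.NJ+P", ["i1", "i2"], [0.5, 0.25])
        assert len(ss.values) == 2
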