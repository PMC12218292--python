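"""Logistic-regression comparisons, Wald tests and BH-FDR control."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rad51quant import MODELS, category_proportions, compare_all, fdr_adjust, fit_pair_model
from rad51quant.stats import all_pairs
from rad51quant.synthetic import default_strain_designs, simulate_cell_records


def bh_oracle(pvals):
    """Literal step-up definition: q(i) = min over j>=i of p(j) * m / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q[order[rank]] = min(running, 1.0)
    return q


def null_pair_designs():
    base = default_strain_designs(3)[0]
    return [dataclasses.replace(base, name="A"), dataclasses.replace(base, name="B")]


class TestFdrAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(fdr_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 15))
            q = fdr_adjust(p)
            assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)


class TestFitPairModel:
    def test_separation_flagged_not_nan(self):
        records = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(40)],
            "strain": ["A"] * 20 + ["B"] * 20,
            "batch": ["b0"] * 40,
            "category": ["Simple"] * 20 + ["Nothing"] * 20,
            "hasFilament": [1] * 20 + [0] * 20,
            "filamentLength": np.nan, "filamentIntensity": np.nan,
            "spotIntensity": np.nan,
        })
        results = fit_pair_model(records, ("A", "B"), MODELS["M1"])
        assert results[0].flag == "separation"
        assert np.isnan(results[0].p)

    def test_label_symmetry(self):
        records = simulate_cell_records(default_strain_designs(3)[:2], n_cells=150,
                                        n_batches=3, seed=2)
        pair = tuple(records["strain"].unique()[:2])
        ab = fit_pair_model(records, pair, MODELS["M1"])[0]
        ba = fit_pair_model(records, pair[::-1], MODELS["M1"])[0]
        assert ab.estimate == pytest.approx(-ba.estimate, abs=1e-9)
        assert ab.p == pytest.approx(ba.p, abs=1e-9)

    def test_single_batch_drops_batch_term(self):
        records = simulate_cell_records(null_pair_designs(), n_cells=60,
                                        n_batches=1, seed=3)
        res = fit_pair_model(records, ("A", "B"), MODELS["M1"])[0]
        assert res.flag == "batch_dropped"
        assert np.isfinite(res.p)

    def test_planted_effect_ci_coverage(self):
        """95% Wald CI covers a planted log-odds of 1.0 in >= 93% of reps.

        Strain B's filament probability is shifted so the true hasFilament
        log-odds ratio is exactly 1; n = 500 cells per arm.
        """
        from scipy import stats as sps

        beta = 1.0
        p_a = 0.4
        odds_b = np.exp(beta) * p_a / (1 - p_a)
        p_b = odds_b / (1 + odds_b)
        rng = np.random.default_rng(123)
        covered = 0
        reps = 300
        for _ in range(reps):
            n = 500
            has = np.concatenate([rng.random(n) < p_a, rng.random(n) < p_b])
            records = pd.DataFrame({
                "cell_id": [f"c{i}" for i in range(2 * n)],
                "strain": ["A"] * n + ["B"] * n,
                "batch": "b0",
                "category": np.where(has, "Simple", "Nothing"),
                "hasFilament": has.astype(float),
                "filamentLength": np.nan, "filamentIntensity": np.nan,
                "spotIntensity": np.nan,
            })
            res = fit_pair_model(records, ("A", "B"), MODELS["M1"])[0]
            crit = sps.t.ppf(0.975, 2 * n - 2)
            covered += (res.estimate - crit * res.se <= beta <= res.estimate + crit * res.se)
        assert covered / reps >= 0.93


class TestCompareAll:
    def test_one_pair_three_models_gives_four_rows(self):
        records = simulate_cell_records(null_pair_designs(), n_cells=120,
                                        n_batches=3, seed=5)
        tests = compare_all(records, [("A", "B")])
        assert len(tests) == 4
        assert list(tests["term"]) == ["hasFilament", "filamentLength",
                                       "filamentIntensity", "spotIntensity"]

    def test_thirteen_pairs_give_52_hypotheses(self):
        base = default_strain_designs(3)[0]
        designs = [dataclasses.replace(base, name=f"S{i}") for i in range(13)]
        records = simulate_cell_records(designs, n_cells=60, n_batches=3, seed=6)
        pairs = all_pairs([d.name for d in designs])[:13]
        tests = compare_all(records, pairs)
        assert len(tests) == 52

    def test_unknown_strain_in_pairs_rejected(self):
        records = simulate_cell_records(null_pair_designs(), n_cells=10, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            compare_all(records, [("A", "Z")])

    def test_flagged_rows_keep_nan_q(self):
        # B has no Foci cells at all -> M3 cannot be fitted for the pair
        base = default_strain_designs(3)[0]
        a = dataclasses.replace(base, name="A")
        b = dataclasses.replace(base, name="B",
                                category_probs={"simple": 0.7, "complex": 0.3,
                                                "foci_only": 0.0, "nothing": 0.0})
        records = simulate_cell_records([a, b], n_cells=80, n_batches=3, seed=7)
        tests = compare_all(records, [("A", "B")])
        m3 = tests[tests["model"] == "M3"].iloc[0]
        assert m3["flag"].startswith("no_fit")
        assert np.isnan(m3["q"])


class TestCategoryProportions:
    def test_all_simple(self):
        records = pd.DataFrame({"strain": ["A"] * 10, "category": ["Simple"] * 10})
        out = category_proportions(records)
        assert out.loc[0, "Simple"] == 1.0 and out.loc[0, "n"] == 10

    def test_half_half(self):
        records = pd.DataFrame({"strain": ["A"] * 4,
                                "category": ["Simple", "Simple", "Foci", "Foci"]})
        out = category_proportions(records)
        assert out.loc[0, "Simple"] == 0.5 and out.loc[0, "Foci"] == 0.5

    def test_fractions_sum_to_one_and_counts_integer(self):
        records = simulate_cell_records(default_strain_designs(2), n_cells=50, seed=8)
        out = category_proportions(records)
        sums = out[["Simple", "Complex", "Foci", "Nothing"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        counts = out[["Simple", "Complex", "Foci", "Nothing"]].to_numpy() * \
            out["n"].to_numpy()[:, None]
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
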