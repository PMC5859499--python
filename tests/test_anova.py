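"""Factorial variance decomposition: conservation, oracles, structure."""

import itertools

import numpy as np
import pandas as pd
import pytest

from refmix.anova import factorial_anova, filter_report


def design_matrix_ss(df, factors, response):
    """Sequential least-squares oracle: SS explained as each term enters.

    Builds full-rank dummy design matrices term by term and takes the
    difference of residual sums of squares between nested fits.  On a
    balanced design this equals the classical factorial decomposition.
    """
    y = df[response].to_numpy(dtype=float)
    n = len(y)

    def dummies(term):
        cols = [pd.get_dummies(df[f], drop_first=True).to_numpy(dtype=float) for f in term]
        out = cols[0]
        for c in cols[1:]:
            out = np.einsum("ni,nj->nij", out, c).reshape(n, -1)
        return out

    X = np.ones((n, 1))
    rss_prev = float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())
    result = {}
    terms = [
        t for r in range(1, len(factors) + 1)
        for t in itertools.combinations(factors, r)
    ]
    for term in terms:
        X = np.hstack([X, dummies(term)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        result[":".join(term)] = rss_prev - rss
        rss_prev = rss
    result["residual"] = rss_prev
    return result


def random_balanced(levels, reps, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for combo in itertools.product(*[range(k) for k in levels]):
        for _ in range(reps):
            rows.append({f"f{i}": f"L{v}" for i, v in enumerate(combo)})
    df = pd.DataFrame(rows)
    df["cq"] = rng.normal(25, 2, len(df))
    return df


class TestBalancedDecomposition:
    def test_constant_response_all_ss_zero(self):
        df = random_balanced([2, 3], 2, seed=0)
        df["cq"] = 7.0
        table = factorial_anova(df, ["f0", "f1"])
        assert np.allclose(table["ss"], 0.0)

    def test_pure_main_effects_have_zero_interaction(self):
        # additive 2x2 cell means: interaction exactly zero
        rows = []
        for a, ea in (("A0", -1.0), ("A1", 1.0)):
            for b, eb in (("B0", -0.5), ("B1", 0.5)):
                for r in range(3):
                    rows.append({"f0": a, "f1": b, "cq": 20.0 + ea + eb})
        df = pd.DataFrame(rows)
        table = factorial_anova(df, ["f0", "f1"]).set_index("term")
        # SS(main) = N_level_total * sum of squared level deviations
        assert table.loc["f0", "ss"] == pytest.approx(12 * 1.0, abs=1e-10)
        assert table.loc["f1", "ss"] == pytest.approx(12 * 0.25, abs=1e-10)
        assert table.loc["f0:f1", "ss"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["residual", "ss"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("levels,reps,seed", [([2, 3, 4], 2, 1), ([3, 2, 2], 3, 2)])
    def test_every_term_matches_design_matrix_oracle(self, levels, reps, seed):
        df = random_balanced(levels, reps, seed)
        factors = ["f0", "f1", "f2"]
        table = factorial_anova(df, factors).set_index("term")
        oracle = design_matrix_ss(df, factors, "cq")
        for term, ss in oracle.items():
            assert table.loc[term, "ss"] == pytest.approx(ss, rel=1e-8, abs=1e-8)

    def test_conservation_of_total_ss(self, profiles):
        factors = ["analyte", "sample", "isolation_lab", "isolation_rep", "pcr_lab"]
        table = factorial_anova(profiles, factors)
        y = profiles["cq"].to_numpy()
        total = float(((y - y.mean()) ** 2).sum())
        assert table["ss"].sum() == pytest.approx(total, rel=1e-8)
        assert table["df"].sum() == len(profiles) - 1

    def test_level_relabeling_leaves_ss_unchanged(self):
        df = random_balanced([2, 3], 2, seed=3)
        base = factorial_anova(df, ["f0", "f1"]).set_index("term")["ss"]
        relabeled = df.replace({"f0": {"L0": "ZZZ", "L1": "AAA"}})
        new = factorial_anova(relabeled, ["f0", "f1"]).set_index("term")["ss"]
        assert np.allclose(base.sort_index(), new.sort_index())

    def test_matches_statsmodels_reference(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = random_balanced([2, 2, 3], 2, seed=4)
        table = factorial_anova(df, ["f0", "f1", "f2"]).set_index("term")
        fit = smf.ols("cq ~ C(f0) * C(f1) * C(f2)", data=df).fit()
        ref = anova_lm(fit, typ=1)
        for idx, row in ref.iterrows():
            term = "residual" if idx == "Residual" else idx.replace("C(", "").replace(")", "")
            assert table.loc[term, "ss"] == pytest.approx(row["sum_sq"], rel=1e-8)


class TestUnbalancedFallback:
    def test_sequential_ss_still_conserves_total(self, caplog):
        df = random_balanced([2, 3], 2, seed=5)
        df = df.iloc[:-1]  # drop one observation: unbalanced
        with caplog.at_level("WARNING"):
            table = factorial_anova(df, ["f0", "f1"])
        assert any("Type-I" in r.message for r in caplog.records)
        y = df["cq"].to_numpy()
        total = float(((y - y.mean()) ** 2).sum())
        assert table["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_missing_factor_column_raises(self, profiles):
        with pytest.raises(KeyError):
            factorial_anova(profiles, ["analyte", "nonexistent"])


class TestQualitativeStructure:
    def test_biology_terms_dominate_profiling_variance(self, profiles):
        """Analyte, cell line and their interaction carry the most variance."""
        factors = ["analyte", "sample", "isolation_lab", "isolation_rep", "pcr_lab"]
        table = factorial_anova(profiles, factors)
        top3 = set(table.head(3)["term"])
        assert top3 == {"analyte", "sample", "analyte:sample"}

    def test_dcq_response_supported(self, rna_mixtures):
        from refmix.dcq import delta_cq

        values = delta_cq(rna_mixtures)
        table = factorial_anova(values, ["analyte", "isolation_rep", "pcr_lab"],
                                response="dcq")
        # designed analyte differences dominate the ΔCq decomposition
        assert table.iloc[0]["term"] == "analyte"


class TestFilterReport:
    def test_threshold_keeps_large_terms(self):
        table = pd.DataFrame(
            {"term": ["a", "b"], "df": [1, 1], "ss": [10.0, 0.5], "ms": [10.0, 0.5]}
        )
        out = filter_report(table, 1.0)
        assert out["term"].tolist() == ["a"]

    def test_zero_threshold_is_identity(self):
        table = pd.DataFrame(
            {"term": ["a", "residual"], "df": [1, 0], "ss": [10.0, 0.0],
             "ms": [10.0, np.nan]}
        )
        out = filter_report(table, 0.0)
        assert len(out) == len(table)

    def test_random_table_matches_brute_force(self):
        rng = np.random.default_rng(8)
        ms = rng.uniform(0, 5, 30)
        table = pd.DataFrame(
            {"term": [f"t{i}" for i in range(30)], "df": 1, "ss": ms, "ms": ms}
        )
        out = filter_report(table, 2.0)
        assert out["term"].tolist() == [f"t{i}" for i in range(30) if ms[i] >= 2.0]
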