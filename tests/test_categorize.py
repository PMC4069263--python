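"""Category assignment logic, switch-time estimation and fast-switch curation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from switchscan import (SwitchCategorizer, assign_categories, category_counts,
                        curate_fast_switchers, estimate_switch_time,
                        generate_expression)
from switchscan.categorize import CategorizeError
from switchscan.simulate import ExprSimConfig, logistic_fraction

SIG, NS = 0.01, 0.5


def comparison_table(patterns, diffs=None):
    """Build a long comparison table from per-gene significance patterns.

    ``patterns``: list of (sig_RFvCF, sig_SFvCF, sig_SFvRF) booleans.
    ``diffs``: optional per-gene dict comparison -> mean diff.
    """
    rows = []
    for g, pat in enumerate(patterns):
        gene = f"g{g:03d}"
        for comp, is_sig in zip(("RF_vs_CF", "SF_vs_CF", "SF_vs_RF"), pat):
            diff = 1.0 if diffs is None else diffs[g][comp]
            rows.append({"gene_id": gene, "comparison": comp,
                         "mean_diff_log2": diff, "fold_change": 2.0**diff,
                         "t": 3.0, "p": SIG if is_sig else NS,
                         "q": SIG if is_sig else NS})
    return pd.DataFrame(rows)


class TestAssignmentLogic:
    # pattern -> category map on (RF_vs_CF, SF_vs_CF, SF_vs_RF) significance
    PATTERNS = {
        (True, True, False): "I",     # switching: left CF, matches RF
        (True, False, True): "II",    # refractory: SF = CF, SF != RF
        (True, True, True): "III",    # responsive but non-switching
        (False, True, False): "IV",   # deviating
        (False, True, True): "IV",
        (False, False, False): "V",   # null
        (True, False, False): "VI",   # diet-dependent indeterminate (no matrix)
        (False, False, True): "VIII", # diet-independent indeterminate (no matrix)
    }

    def test_exhaustive_truth_table(self):
        patterns = list(itertools.product([True, False], repeat=3))
        table = comparison_table(patterns)
        out = assign_categories(table, fdr=0.05).set_index("gene_id")
        for g, pat in enumerate(patterns):
            assert out.loc[f"g{g:03d}", "category"] == self.PATTERNS[pat], pat

    def test_partition_is_exhaustive_and_counts_sum(self):
        patterns = list(itertools.product([True, False], repeat=3)) * 5
        out = assign_categories(comparison_table(patterns))
        assert len(out) == len(patterns)
        assert out["gene_id"].is_unique
        assert category_counts(out)["n_genes"].sum() == len(patterns)

    def test_direction_follows_defining_comparison(self):
        diffs = [
            {"RF_vs_CF": -1.0, "SF_vs_CF": -0.9, "SF_vs_RF": 0.1},  # I, down
            {"RF_vs_CF": 0.0, "SF_vs_CF": 1.2, "SF_vs_RF": 1.1},    # IV, up
        ]
        table = comparison_table([(True, True, False), (False, True, True)],
                                 diffs=diffs)
        out = assign_categories(table).set_index("gene_id")
        assert out.loc["g000", ["category", "direction"]].tolist() == ["I", "down"]
        assert out.loc["g001", ["category", "direction"]].tolist() == ["IV", "up"]

    def test_direction_none_iff_not_main_category(self):
        patterns = list(itertools.product([True, False], repeat=3))
        out = assign_categories(comparison_table(patterns))
        main = out["category"].isin(["I", "II", "III", "IV"])
        assert (out.loc[main, "direction"] != "none").all()
        assert (out.loc[~main, "direction"] == "none").all()

    def test_missing_comparison_row_names_gene(self):
        table = comparison_table([(True, True, False), (True, False, True)])
        # drop gene g000's SF_vs_RF row only
        broken = table[~((table.gene_id == "g000") &
                         (table.comparison == "SF_vs_RF"))]
        with pytest.raises(CategorizeError, match="g000"):
            assign_categories(broken)

    def test_stricter_fdr_never_promotes_from_null(self):
        rng = np.random.default_rng(5)
        q = rng.random((60, 3))
        rows = []
        for g in range(60):
            for j, comp in enumerate(("RF_vs_CF", "SF_vs_CF", "SF_vs_RF")):
                rows.append({"gene_id": f"g{g:03d}", "comparison": comp,
                             "mean_diff_log2": 1.0, "fold_change": 2.0,
                             "t": 1.0, "p": q[g, j], "q": q[g, j]})
        table = pd.DataFrame(rows)
        loose = assign_categories(table, fdr=0.5).set_index("gene_id")["category"]
        strict = assign_categories(table, fdr=0.1).set_index("gene_id")["category"]
        was_null = loose[loose == "V"].index
        assert not strict.loc[was_null].isin(["I", "II", "III", "IV"]).any()

    def test_indeterminate_routing_with_matrix(self):
        # three diet-dependent genes with neither SF comparison significant:
        # SF near CF -> VI, SF mid-gap -> VII, noisy replicates -> VIII
        cfg = ExprSimConfig(n_genes=40, archetype_mix={"null": 1.0},
                            sigma=0.1, seed=3)
        matrix, _ = generate_expression(cfg)
        values = matrix.values.copy()
        meta = matrix.metadata
        rf_cols = meta.index[meta.cohort == "RF"]
        sf_cols = meta.index[meta.cohort == "SF"]
        gene_vi, gene_vii, gene_viii = matrix.genes[:3]
        values.loc[[gene_vi, gene_vii, gene_viii], rf_cols] += 2.0
        values.loc[gene_vii, sf_cols] += 1.0  # mid-gap plateau
        noisy = np.random.default_rng(0).normal(0, 2.0, size=len(sf_cols))
        values.loc[gene_viii, sf_cols] += noisy
        from switchscan import ExpressionMatrix
        doctored = ExpressionMatrix(values, meta)
        # force the indeterminate pattern: diet-dependent, nothing else called
        rows = []
        for g in doctored.genes:
            special = g in (gene_vi, gene_vii, gene_viii)
            for comp in ("RF_vs_CF", "SF_vs_CF", "SF_vs_RF"):
                sig = special and comp == "RF_vs_CF"
                rows.append({"gene_id": g, "comparison": comp,
                             "mean_diff_log2": 2.0 if sig else 0.0,
                             "fold_change": 1.0, "t": 0.0,
                             "p": 0.001 if sig else 0.9,
                             "q": 0.001 if sig else 0.9})
        out = assign_categories(pd.DataFrame(rows), matrix=doctored
                                ).set_index("gene_id")
        assert out.loc[gene_vi, "category"] == "VI"
        assert out.loc[gene_vii, "category"] == "VII"
        assert out.loc[gene_viii, "category"] == "VIII"


class TestSwitchTime:
    GRID = pd.Index([2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 32.0, 40.0,
                     48.0, 56.0, 72.0])

    def test_instantaneous_switch_first_hour(self):
        sf = pd.Series(1.0, index=self.GRID)
        assert estimate_switch_time(sf, cf_level=0.0, rf_level=1.0) == 2.0

    def test_logistic_crossing_lands_on_next_sampled_hour(self):
        # f with t0=6, tau=1 crosses 0.9 at 6 + ln 9 ~ 8.197 h -> first
        # sampled hour at which the trajectory has completed is 12 h
        f = logistic_fraction(self.GRID.to_numpy(), t0=6.0, tau=1.0)
        sf = pd.Series(f, index=self.GRID)
        assert 6.0 + np.log(9.0) == pytest.approx(8.197, abs=1e-3)
        assert estimate_switch_time(sf, 0.0, 1.0, completion_fraction=0.9) == 12.0

    def test_refractory_never_switches(self):
        sf = pd.Series(0.0, index=self.GRID)
        assert estimate_switch_time(sf, 0.0, 1.0) is None

    def test_excursion_resets_completion(self):
        sf = pd.Series(1.0, index=self.GRID)
        sf.loc[40.0] = 0.5  # transient departure from the RF level
        assert estimate_switch_time(sf, 0.0, 1.0) == 48.0

    def test_degenerate_gap_warns_none(self):
        sf = pd.Series(0.5, index=self.GRID)
        with pytest.warns(UserWarning):
            assert estimate_switch_time(sf, 1.0, 1.0) is None

    def test_downward_switch_handled(self):
        f = logistic_fraction(self.GRID.to_numpy(), t0=2.0, tau=1.0)
        sf = pd.Series(5.0 - 2.0 * f, index=self.GRID)
        t = estimate_switch_time(sf, cf_level=5.0, rf_level=3.0)
        assert t == 6.0  # f(6) ~ 0.982 >= 0.9, f(4) ~ 0.88 < 0.9


class TestFastSwitchCuration:
    def assignments(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "category", "direction",
                                           "switch_time_h"])

    def test_no_category_one_genes(self):
        a = self.assignments([("g1", "II", "up", np.nan)])
        assert curate_fast_switchers(a) == ([], [])

    def test_fast_vs_slow_construction(self):
        cfg_fast = dict(n_genes=3, delta=2.0, sigma=0.0, seed=0)
        fast, _ = generate_expression(
            ExprSimConfig(archetype_mix={"switch_up": 1.0}, t0_fast=2.0, **cfg_fast))
        sf = fast.time_means("SF")
        cf = fast.time_means("CF").mean(axis=1)
        rows = []
        for g in fast.genes:
            t = estimate_switch_time(sf.loc[g], cf[g], cf[g] + 2.0)
            rows.append((g, "I", "up", t))
        rows.append(("slowgene", "I", "up", 48.0))
        up, down = curate_fast_switchers(self.assignments(rows), cutoff_h=8.0)
        assert set(up) == set(fast.genes)
        assert down == []

    def test_zero_cutoff_empty(self):
        a = self.assignments([("g1", "I", "up", 2.0)])
        assert curate_fast_switchers(a, cutoff_h=0.0) == ([], [])

    def test_split_by_direction(self):
        a = self.assignments([("g1", "I", "up", 4.0), ("g2", "I", "down", 6.0),
                              ("g3", "I", "down", 24.0)])
        up, down = curate_fast_switchers(a, cutoff_h=8.0)
        assert (up, down) == (["g1"], ["g2"])


class TestSwitchCategorizerEstimator:
    def test_fit_sets_attributes_and_recovers_truth(self):
        cfg = ExprSimConfig(n_genes=300, delta=2.0, sigma=0.25, seed=12)
        matrix, truth = generate_expression(cfg)
        model = SwitchCategorizer(fdr=0.05).fit(matrix)
        assert set(model.assignments_["gene_id"]) == set(truth["gene_id"])
        assert model.summary_["n_genes"].sum() == cfg.n_genes
        merged = model.assignments_.merge(truth, on="gene_id")
        switching = merged[merged["archetype"].isin(["switch_up", "switch_down"])]
        assert (switching["category"] == "I").mean() >= 0.9

    def test_get_set_params_roundtrip(self):
        from sklearn.base import clone
        model = SwitchCategorizer(fdr=0.01, late_hours=2)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        cloned.set_params(fdr=0.2)
        assert cloned.fdr == 0.2 and model.fdr == 0.01
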