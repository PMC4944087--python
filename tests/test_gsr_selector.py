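import json

import numpy as np
import pytest

import samgsr
from samgsr import gsr_selector
from samgsr.errors import EmptySelectionError
from samgsr.sam_engine import PermutationEngine

from conftest import balanced_labels, make_study


def planted_study(rng, n_genes=10, n_per_class=8, shift_rows=(0,), shift=6.0):
    values = rng.standard_normal((n_genes, 2 * n_per_class))
    values[np.ix_(list(shift_rows), np.arange(n_per_class, 2 * n_per_class))] += shift
    return make_study(values, balanced_labels(n_per_class))


class TestReduceSet:
    def test_recovers_single_strong_gene(self):
        """One massive gene among nulls: the core is almost always just it."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            study = planted_study(rng, shift=10.0)
            scheme = samgsr.build_permutation_scheme(
                study.labels, n_perm=300, seed=rep
            )
            result = samgsr.reduce_set(
                study, study.gene_ids, scheme, c_threshold=0.05, s0=0.5
            )
            if result.core_genes == ("g1",):
                hits += 1
        assert hits >= 45

    def test_degenerate_constant_set_has_trace_one(self):
        study = make_study(
            np.vstack([np.ones(8), np.full(8, 2.0)]), balanced_labels(4)
        )
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=100, seed=0)
        result = samgsr.reduce_set(study, study.gene_ids, scheme, 0.05, s0=1.0)
        assert result.c_trace[0] == 1.0
        assert result.core_size == 1

    def test_all_strong_genes_keep_full_set(self, rng):
        study = planted_study(rng, n_genes=5, shift_rows=range(5), shift=12.0)
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=300, seed=1)
        result = samgsr.reduce_set(study, study.gene_ids, scheme, 0.05, s0=0.5)
        assert result.core_size == len(study.gene_ids)
        assert result.c_trace[-1] == 1.0

    def test_ordering_is_by_decreasing_abs_d(self, rng):
        study = planted_study(rng, shift_rows=(3,), shift=8.0)
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=100, seed=2)
        result = samgsr.reduce_set(study, study.gene_ids, scheme, 0.2, s0=0.5)
        profile = samgsr.compute_sam(study, s0=0.5)
        idx = study.gene_index(result.ordered_genes)
        abs_d = np.abs(profile.d[idx])
        assert np.all(np.diff(abs_d) <= 1e-12)
        assert sorted(result.ordered_genes) == sorted(study.gene_ids)

    def test_threshold_domain_enforced(self, small_labeled_study):
        scheme = samgsr.build_permutation_scheme(
            small_labeled_study.labels, n_perm=10, seed=0
        )
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                samgsr.reduce_set(
                    small_labeled_study, small_labeled_study.gene_ids, scheme, bad
                )

    def test_core_size_monotone_in_threshold(self, rng):
        """The stopping rule min{k : c_k > c} can only deepen as c grows."""
        study = planted_study(rng, n_genes=20, shift_rows=range(4), shift=2.0)
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=400, seed=3)
        engine = PermutationEngine(study, scheme, s0=0.5)
        sizes = [
            samgsr.reduce_set(
                study, study.gene_ids, scheme, c, engine=engine
            ).core_size
            for c in (0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
        ]
        assert sizes == sorted(sizes)


class TestFitSelection:
    def test_planted_sets_found_null_sets_rare(self):
        both, false_positives = 0, []
        for rep in range(50):
            cfg = samgsr.SimulationConfig(
                n_genes=400, n_sets=20, set_size=20, n_signal_sets=2,
                n_core_per_signal_set=4, effect_size=1.5, n_per_class=15,
                seed=10_000 + rep,
            )
            study, sets, truth = samgsr.simulate_study(cfg)
            scheme = samgsr.build_permutation_scheme(
                study.labels, n_perm=200, seed=rep
            )
            model = samgsr.fit_selection(
                study, sets, alpha=0.05, c_threshold=0.1, scheme=scheme
            )
            sig = set(model.significant_sets)
            if set(truth["signal_sets"]) <= sig:
                both += 1
            false_positives.append(len(sig - set(truth["signal_sets"])))
        assert both >= 45  # >= 90% of replicates find both planted sets
        # null sets pass at about the alpha rate: 18 nulls x 0.05 ~ 0.9 each
        assert np.mean(false_positives) <= 0.9 + 3 * np.std(false_positives) / np.sqrt(50)

    def test_alpha_one_selects_everything(self, rng):
        study = planted_study(rng, n_genes=12)
        sets = samgsr.GeneSetCollection(
            {"A": study.gene_ids[:6], "B": study.gene_ids[6:]}
        )
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=100, seed=4)
        model = samgsr.fit_selection(study, sets, 1.0, 0.2, scheme)
        assert set(model.significant_sets) == {"A", "B"}
        assert model.selected_genes

    def test_shared_core_gene_appears_once(self, rng):
        study = planted_study(rng, n_genes=12, shift_rows=(0,), shift=10.0)
        sets = samgsr.GeneSetCollection(
            {"A": ("g1", "g2", "g3"), "B": ("g1", "g4", "g5")}
        )
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=200, seed=5)
        model = samgsr.fit_selection(study, sets, 1.0, 0.05, scheme)
        assert model.selected_genes.count("g1") == 1

    def test_empty_selection_warns_not_raises(self, rng, caplog):
        study = make_study(rng.standard_normal((10, 12)), balanced_labels(6))
        sets = samgsr.GeneSetCollection({"A": study.gene_ids[:5]})
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=100, seed=6)
        with caplog.at_level("WARNING", logger="samgsr"):
            model = samgsr.fit_selection(study, sets, 1e-6, 0.05, scheme)
        assert model.selected_genes == ()
        assert "empty" in caplog.text

    def test_significant_sets_nest_in_alpha(self, rng):
        study = planted_study(rng, n_genes=40, shift_rows=range(6), shift=1.0)
        sets = samgsr.GeneSetCollection(
            {f"S{i}": study.gene_ids[5 * i : 5 * i + 5] for i in range(8)}
        )
        scheme = samgsr.build_permutation_scheme(study.labels, n_perm=300, seed=7)
        engine = PermutationEngine(study, scheme)
        previous: set = set()
        for alpha in (0.01, 0.05, 0.1, 0.2, 0.5, 1.0):
            model = samgsr.fit_selection(study, sets, alpha, 0.1, scheme, engine=engine)
            current = set(model.significant_sets)
            assert previous <= current
            previous = current


class TestTune:
    def test_best_cell_tiebreak_prefers_sparse_then_small_alpha_then_small_c(self):
        cell = lambda c, a, err, n: {
            "c": c, "alpha": a, "mean_cv_error": err, "mean_n_genes": n
        }
        grid = [cell(0.3, 0.2, 0.1, 40.0), cell(0.05, 0.2, 0.1, 10.0)]
        assert gsr_selector.select_best_cell(grid)["mean_n_genes"] == 10.0
        grid = [cell(0.05, 0.2, 0.1, 10.0), cell(0.05, 0.01, 0.1, 10.0)]
        assert gsr_selector.select_best_cell(grid)["alpha"] == 0.01
        grid = [cell(0.3, 0.05, 0.1, 10.0), cell(0.01, 0.05, 0.1, 10.0)]
        assert gsr_selector.select_best_cell(grid)["c"] == 0.01
        grid = [cell(0.3, 0.2, 0.05, 99.0), cell(0.01, 0.01, 0.2, 1.0)]
        assert gsr_selector.select_best_cell(grid)["mean_cv_error"] == 0.05

    def test_strong_signal_beats_majority_baseline(self):
        cfg = samgsr.SimulationConfig(
            n_genes=200, n_sets=10, set_size=20, n_signal_sets=2,
            n_core_per_signal_set=5, effect_size=2.0, n_per_class=20, seed=42,
        )
        study, sets, _ = samgsr.simulate_study(cfg)
        tuning = samgsr.tune(study, sets, k_folds=5, seed=42, n_perm_cv=150)
        best = [g for g in tuning.grid
                if g["c"] == tuning.best_c and g["alpha"] == tuning.best_alpha][0]
        assert best["mean_cv_error"] <= 0.5

    def test_pure_noise_tracks_majority_rate(self):
        best_errors = []
        for rep in range(20):
            cfg = samgsr.SimulationConfig(
                n_genes=100, n_sets=5, set_size=20, n_signal_sets=0,
                effect_size=0.0, n_per_class=10, seed=500 + rep,
            )
            study, sets, _ = samgsr.simulate_study(cfg)
            tuning = samgsr.tune(
                study, sets, c_grid=(0.05, 0.2), alpha_grid=(0.05, 0.2),
                k_folds=5, seed=rep, n_perm_cv=100,
            )
            best = min(g["mean_cv_error"] for g in tuning.grid)
            best_errors.append(best)
        # mean of per-replicate best CV errors stays near the 0.5 baseline;
        # 3 binomial SEs on one replicate's 20 held-out samples
        se = np.sqrt(0.25 / 20)
        assert abs(np.mean(best_errors) - 0.5) <= 3 * se

    def test_grid_is_complete_and_empty_cells_flagged(self, rng):
        study = planted_study(rng, n_genes=30, shift_rows=range(3), shift=2.0)
        sets = samgsr.GeneSetCollection(
            {"A": study.gene_ids[:10], "B": study.gene_ids[10:20]}
        )
        tuning = samgsr.tune(
            study, sets, c_grid=(0.05, 0.2), alpha_grid=(0.001, 0.2),
            k_folds=3, seed=1, n_perm_cv=100,
        )
        assert len(tuning.grid) == 4
        for g in tuning.grid:
            assert len(g["fold_errors"]) == 3
            assert 0 <= g["empty_folds"] <= 3


class TestRefitFinal:
    def _tuned(self, seed=0):
        cfg = samgsr.SimulationConfig(
            n_genes=200, n_sets=10, set_size=20, n_signal_sets=2,
            n_core_per_signal_set=5, effect_size=2.0, n_per_class=15, seed=seed,
        )
        study, sets, truth = samgsr.simulate_study(cfg)
        tuning = samgsr.tune(
            study, sets, c_grid=(0.05, 0.2), alpha_grid=(0.05, 0.2),
            k_folds=5, seed=seed, n_perm_cv=100,
        )
        return study, sets, truth, tuning

    def test_serialized_model_is_byte_identical_across_refits(self, tmp_path):
        study, sets, _, tuning = self._tuned(seed=11)
        paths = []
        for run in (1, 2):
            selection, clf = samgsr.refit_final(study, sets, tuning, n_perm=200)
            p = tmp_path / f"model{run}.json"
            gsr_selector.serialize_model(selection, clf, tuning, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_recovers_planted_core_genes(self):
        study, sets, truth, tuning = self._tuned(seed=12)
        selection, _ = samgsr.refit_final(study, sets, tuning, n_perm=300)
        cores = {g for v in truth["core_genes"].values() for g in v}
        assert len(cores & set(selection.selected_genes)) / len(cores) >= 0.5

    def test_training_error_not_above_cv_error_on_average(self):
        gaps = []
        for rep in range(10):
            study, sets, _, tuning = self._tuned(seed=100 + rep)
            selection, clf = samgsr.refit_final(study, sets, tuning, n_perm=150)
            report = samgsr.evaluate(clf.predict(study), study.labels)
            best = gsr_selector.select_best_cell(list(tuning.grid))
            gaps.append(report.error_rate - best["mean_cv_error"])
        assert np.mean(gaps) <= 0.0

    def test_empty_final_selection_raises_with_grid(self, rng):
        study = make_study(rng.standard_normal((20, 16)), balanced_labels(8))
        sets = samgsr.GeneSetCollection({"A": study.gene_ids[:10]})
        tuning = gsr_selector.TuningResult(
            grid=({"c": 0.05, "alpha": 1e-9, "mean_cv_error": 0.5,
                   "mean_n_genes": 0.0},),
            best_c=0.05, best_alpha=1e-9, cv_folds=0, seed=0,
        )
        with pytest.raises(EmptySelectionError) as err:
            samgsr.refit_final(study, sets, tuning, n_perm=100)
        assert err.value.grid is not None
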