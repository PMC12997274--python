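"""Benchmark scoring, ratio surface, ranking and thresholding.

These tests use the surrogate-oracle predictor (exact Gaussian
quantiles) so the evaluation layer is checked independently of
training.
"""

import numpy as np
import pandas as pd
import pytest

from dp5q.chem_io import ShiftSpectrum
from dp5q.evaluation import (
    DEFAULT_DP5Q_EDGES,
    DEFAULT_MAE_EDGES,
    rank_candidates,
    ratio_surface,
    score_benchmark,
    threshold_classify,
)
from dp5q.synthetic import (
    SurrogatePredictor,
    SurrogateShiftModel,
    isomer_fixtures,
    make_benchmark,
    simulate_spectrum,
)


@pytest.fixture(scope="module")
def surrogate():
    return SurrogateShiftModel(seed=11)


@pytest.fixture(scope="module")
def predictor(surrogate):
    return SurrogatePredictor(surrogate)


@pytest.fixture(scope="module")
def scored_table(surrogate, predictor):
    pool = isomer_fixtures(12, seed=4)
    pairs = make_benchmark(pool, surrogate)
    return score_benchmark(pairs, predictor)


class TestScoreBenchmark:
    def test_row_count_matches_pairs_minus_excluded(self, scored_table):
        assert len(scored_table) == 12 + 12 * 11
        assert scored_table.attrs["excluded"] == 0

    def test_exact_median_observations_score_one(self, surrogate):
        # spectra placed exactly at the predicted medians: zero error
        # captures zero probability mass, so every atom scores 1
        pool = isomer_fixtures(4, seed=9)
        pairs = []
        for i, mol in enumerate(pool):
            mus = [mu for mu, _ in surrogate.class_params(mol)]
            spec = ShiftSpectrum(mus, assignment={k: k for k in range(len(mus))})
            pairs.append((mol, spec, "correct", i, i))
        table = score_benchmark(pairs, SurrogatePredictor(surrogate))
        assert np.allclose(table["mae"], 0.0, atol=1e-12)
        assert np.all(table["dp5q"] == 1.0)

    def test_deterministic(self, surrogate, predictor):
        pool = isomer_fixtures(5, seed=6)
        pairs = make_benchmark(pool, surrogate)
        a = score_benchmark(pairs, predictor)
        b = score_benchmark(pairs, predictor)
        pd.testing.assert_frame_equal(a, b)

    def test_correct_pairs_separate_from_incorrect(self, scored_table):
        med_c = scored_table.query("label == 'correct'")["dp5q"].median()
        med_i = scored_table.query("label == 'incorrect'")["dp5q"].median()
        assert med_c > med_i


class TestRatioSurface:
    def test_all_correct_bins_are_one(self, surrogate, predictor):
        pool = isomer_fixtures(6, seed=2)
        pairs = [p for p in make_benchmark(pool, surrogate) if p.label == "correct"]
        surf = ratio_surface(score_benchmark(pairs, predictor))
        filled = surf.n_pairs > 0
        assert np.all(surf.ratio[filled] == 1.0)
        assert np.all(np.isnan(surf.ratio[~filled]))  # empty bins undefined

    def test_single_bin_gives_overall_fraction(self, scored_table):
        surf = ratio_surface(scored_table, mae_edges=[0.0, 1e6], dp5q_edges=[0.0, 1.0])
        frac = (scored_table["label"] == "correct").mean()
        assert surf.ratio[0, 0] == pytest.approx(frac)
        assert surf.n_pairs.sum() == len(scored_table)

    def test_matches_per_row_loop_oracle(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "label": rng.choice(["correct", "incorrect"], size=1000),
                "mae": rng.uniform(0, 10, size=1000),
                "dp5q": rng.uniform(0, 1, size=1000),
            }
        )
        surf = ratio_surface(table)
        me, de = surf.mae_edges, surf.dp5q_edges
        for bi in range(len(me) - 1):
            for bj in range(len(de) - 1):
                rows = table[
                    (table["mae"] >= me[bi])
                    & ((table["mae"] < me[bi + 1]) | ((bi == len(me) - 2) & (table["mae"] == me[-1])))
                    & (table["dp5q"] >= de[bj])
                    & ((table["dp5q"] < de[bj + 1]) | ((bj == len(de) - 2) & (table["dp5q"] == de[-1])))
                ]
                assert surf.n_pairs[bi, bj] == len(rows)
                if len(rows):
                    assert surf.ratio[bi, bj] == pytest.approx(
                        (rows["label"] == "correct").mean()
                    )

    def test_pair_conservation(self, scored_table):
        surf = ratio_surface(scored_table)
        in_range = scored_table[
            (scored_table["mae"] <= DEFAULT_MAE_EDGES[-1])
            & (scored_table["dp5q"] <= DEFAULT_DP5Q_EDGES[-1])
        ]
        assert surf.n_pairs.sum() == len(in_range)

    def test_non_monotone_edges_fatal(self, scored_table):
        with pytest.raises(ValueError):
            ratio_surface(scored_table, mae_edges=[0, 2, 1])


class TestRanking:
    def test_generating_structure_beats_decoy(self, surrogate, predictor):
        pool = isomer_fixtures(6, seed=8)
        true_mol = pool[0]
        spec, _ = simulate_spectrum(true_mol, surrogate)
        spec = ShiftSpectrum(shifts=list(spec.shifts))
        report = rank_candidates(pool, spec, predictor)
        assert report.winner == 0
        assert report.winner_by_mae == 0

    def test_identical_candidates_tie_flagged(self, surrogate, predictor):
        pool = isomer_fixtures(3, seed=8)
        spec, _ = simulate_spectrum(pool[0], surrogate)
        report = rank_candidates([pool[0], pool[0]], spec, predictor)
        assert report.tie

    def test_normalisation_divides_by_candidate_count(self, surrogate, predictor):
        pool = isomer_fixtures(8, seed=8)
        spec, _ = simulate_spectrum(pool[0], surrogate)
        report = rank_candidates(pool, spec, predictor)
        assert np.allclose(
            report.table["dp5q_normalised"], report.table["dp5q"] / 8
        )
        assert report.table["dp5q_normalised"].sum() <= 1.0 + 1e-12


class TestThreshold:
    def table(self):
        return pd.DataFrame(
            {
                "label": ["correct", "correct", "incorrect", "incorrect", "incorrect"],
                "dp5q": [0.9, 0.15, 0.05, 0.3, 0.1],
                "mae": [1, 2, 5, 3, 6],
            }
        )

    def test_default_threshold_counts(self):
        counts = threshold_classify(self.table())
        assert counts == {"TP": 1, "FP": 1, "TN": 2, "FN": 1}

    def test_zero_threshold_discards_nothing(self):
        counts = threshold_classify(self.table(), threshold=0.0)
        assert counts["TN"] == 0 and counts["FN"] == 0

    def test_counts_sum_to_table_size(self):
        for thr in (0.0, 0.2, 0.5, 1.0):
            counts = threshold_classify(self.table(), threshold=thr)
            assert sum(counts.values()) == 5
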