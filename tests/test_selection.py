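"""Window-selection rules and two-step feature selection."""

import numpy as np
import pandas as pd
import pytest

from ipsprog.errors import SelectionError
from ipsprog.model import FAST_CONFIG
from ipsprog.select import (
    CorrelationPruner,
    RecursiveBundleEliminator,
    WindowScoreGrid,
    best_start_per_phase,
    best_window_length,
    candidate_start_frames,
    correlation_prune,
    importance_rank_from_trace,
    recursive_eliminate,
    type_correlation,
)
from ipsprog.tracks import FEATURE_TYPES
from ipsprog.windows import TimeWindow, WindowDataset


def make_grid(rows, lengths, phases=None):
    """WindowScoreGrid from {start: [precisions per length]}."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(lengths))
    return WindowScoreGrid(
        precision=df, repeats=1, cv_folds=5, phases=phases or {s: 1 for s in rows}
    )


def toy_dataset(blocks, y, length=3, types=None, seed=0):
    """Dataset whose per-type bundles repeat a per-cell latent value.

    ``blocks[t]`` is a per-cell vector; each of its ``length`` frame
    columns is that vector plus small noise.
    """
    rng = np.random.default_rng(seed)
    types = tuple(types or blocks.keys())
    cols = []
    for t in types:
        base = np.asarray(blocks[t], dtype=float)
        cols.append(
            np.column_stack([base + 0.05 * rng.normal(size=base.size) for _ in range(length)])
        )
    return WindowDataset(
        X=np.hstack(cols),
        y=np.asarray(y),
        cell_ids=[f"c{i}" for i in range(len(y))],
        window=TimeWindow(0, length),
        feature_types=types,
    )


class TestCandidateStartRule:
    def test_simple_qualifying_run(self):
        grid = make_grid({0: [0.60, 0.58, 0.56]}, [7, 9, 11])
        assert candidate_start_frames(grid) == [(0, pytest.approx(0.58))]

    def test_broken_run_does_not_qualify(self):
        grid = make_grid({0: [0.60, 0.50, 0.60, 0.60]}, [7, 9, 11, 13])
        assert candidate_start_frames(grid, min_run=3) == []

    def test_longest_run_used_for_the_mean(self):
        grid = make_grid({0: [0.70, 0.50, 0.60, 0.60, 0.60]}, [7, 9, 11, 13, 15])
        [(start, mean)] = candidate_start_frames(grid, min_run=3)
        assert start == 0 and mean == pytest.approx(0.60)

    def test_all_below_threshold(self):
        grid = make_grid({0: [0.10, 0.20, 0.30]}, [7, 9, 11])
        assert candidate_start_frames(grid) == []

    def test_exhaustive_four_length_grids(self):
        """Brute-force the rule over all above/below patterns of a
        4-length row and compare with the implementation."""
        lengths = [7, 9, 11, 13]
        for mask in range(16):
            vals = [0.80 if mask & (1 << i) else 0.20 for i in range(4)]
            grid = make_grid({0: vals}, lengths)
            got = candidate_start_frames(grid, min_run=3)
            # oracle: longest run of consecutive True
            runs, cur = [], []
            for l, v in zip(lengths, vals):
                cur = cur + [l] if v > 0.55 else []
                runs.append(list(cur))
            best = max(runs, key=len)
            if len(best) >= 3:
                assert got == [(0, pytest.approx(np.mean([0.80] * len(best))))]
            else:
                assert got == []

    def test_best_start_per_phase(self):
        grid = make_grid(
            {0: [0.6] * 3, 10: [0.7] * 3, 100: [0.65] * 3},
            [7, 9, 11],
            phases={0: 1, 10: 1, 100: 2},
        )
        cands = candidate_start_frames(grid)
        assert best_start_per_phase(grid, cands) == {1: 10, 2: 100}


class TestBestWindowLength:
    def test_single_qualifying_length(self):
        grid = make_grid({0: [0.6, 0.4], 10: [0.6, 0.4], 20: [0.6, 0.4]}, [11, 13])
        assert best_window_length(grid, [0, 10, 20]) == 11

    def test_higher_mean_wins(self):
        grid = make_grid(
            {0: [0.62, 0.64], 10: [0.62, 0.64], 20: [0.62, 0.64]}, [11, 13]
        )
        assert best_window_length(grid, [0, 10, 20]) == 13

    def test_sd_breaks_mean_ties(self):
        grid = make_grid(
            {0: [0.63, 0.60], 10: [0.64, 0.64], 20: [0.65, 0.68]}, [11, 13]
        )
        # equal means (0.64); sds 0.01 vs 0.04 -> length 11
        assert best_window_length(grid, [0, 10, 20]) == 11

    def test_shorter_length_breaks_full_ties(self):
        grid = make_grid({0: [0.6, 0.6], 10: [0.6, 0.6], 20: [0.6, 0.6]}, [11, 13])
        assert best_window_length(grid, [0, 10, 20]) == 11

    def test_no_qualifying_length_raises(self):
        grid = make_grid({0: [0.6, 0.6], 10: [0.5, 0.6], 20: [0.6, 0.5]}, [11, 13])
        with pytest.raises(SelectionError):
            best_window_length(grid, [0, 10, 20])


class TestRecursiveElimination:
    def _labels(self, rng, n=120):
        return np.where(rng.random(n) < 1 / 6, "progenitor", "mef")

    def test_informative_type_retained(self):
        """One informative + three noise types: the signal carrier
        survives elimination in >= 9/10 seeded runs."""
        kept = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = self._labels(rng)
            signal = np.where(y == "progenitor", 3.0, 0.0) + rng.normal(size=y.size)
            blocks = {
                "sphericity": signal,
                "volume": rng.normal(size=y.size),
                "speed": rng.normal(size=y.size),
                "displacement": rng.normal(size=y.size),
            }
            ds = toy_dataset(blocks, y, seed=seed)
            trace = recursive_eliminate(
                ds, model_cfg=FAST_CONFIG, repeats=2, folds=3, seed=seed
            )
            kept += "sphericity" in trace.final_types
        assert kept >= 9

    def test_duplicate_informative_types_keep_at_least_one(self):
        """An exactly redundant duplicated signal never loses both
        copies, and accepted scores increase strictly."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y = self._labels(rng)
            signal = np.where(y == "progenitor", 3.0, 0.0) + rng.normal(size=y.size)
            blocks = {
                "sphericity": signal,
                "area": signal.copy(),
                "volume": rng.normal(size=y.size),
                "speed": rng.normal(size=y.size),
            }
            ds = toy_dataset(blocks, y, seed=seed)
            trace = recursive_eliminate(
                ds, model_cfg=FAST_CONFIG, repeats=2, folds=3, seed=seed
            )
            assert {"sphericity", "area"} & set(trace.final_types)
            accepted = [s for _, s in trace.elimination_order]
            assert all(b > a for a, b in zip(accepted, accepted[1:]))

    def test_trace_well_formed_on_pure_noise(self):
        rng = np.random.default_rng(0)
        y = self._labels(rng)
        blocks = {t: rng.normal(size=y.size) for t in ("volume", "area", "speed")}
        ds = toy_dataset(blocks, y)
        trace = recursive_eliminate(ds, model_cfg=FAST_CONFIG, repeats=2, folds=3, seed=1)
        assert set(trace.final_types) | {t for t, _ in trace.elimination_order} == set(
            ds.feature_types
        )
        assert not set(trace.final_types) & {t for t, _ in trace.elimination_order}
        assert len(trace.candidate_scores) >= 1

    def test_determinism(self):
        rng = np.random.default_rng(3)
        y = self._labels(rng)
        blocks = {t: rng.normal(size=y.size) for t in ("volume", "area", "speed")}
        ds = toy_dataset(blocks, y)
        a = recursive_eliminate(ds, model_cfg=FAST_CONFIG, repeats=1, folds=3, seed=9)
        b = recursive_eliminate(ds, model_cfg=FAST_CONFIG, repeats=1, folds=3, seed=9)
        assert a.final_types == b.final_types
        assert a.candidate_scores == b.candidate_scores

    def test_eliminator_estimator_interface(self):
        rng = np.random.default_rng(5)
        y = self._labels(rng)
        signal = np.where(y == "progenitor", 3.0, 0.0) + rng.normal(size=y.size)
        blocks = {
            "sphericity": signal,
            "volume": rng.normal(size=y.size),
        }
        ds = toy_dataset(blocks, y)
        est = RecursiveBundleEliminator(
            feature_types=ds.feature_types, window_length=3,
            model_cfg=FAST_CONFIG, repeats=1, folds=3, random_state=0,
        ).fit(ds.X, ds.y)
        assert set(est.retained_types_) <= set(ds.feature_types)
        assert est.transform(ds.X).shape[1] == 3 * len(est.retained_types_)


class TestTypeCorrelation:
    def test_affine_dependence_gives_unit_coefficient(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        ds = toy_dataset({"area": a, "sphericity": a, "speed": rng.normal(size=50)},
                         ["mef"] * 50, seed=1)
        # rebuild sphericity bundle as an exact affine copy of area's
        ds.X[:, ds.type_columns("sphericity")] = 2 * ds.X[:, ds.type_columns("area")] + 1
        corr = type_correlation(ds)
        assert corr.at["area", "sphericity"] == pytest.approx(1.0)

    def test_independent_types_near_zero(self):
        rng = np.random.default_rng(1)
        ds = toy_dataset(
            {"area": rng.normal(size=1000), "speed": rng.normal(size=1000)},
            ["mef"] * 1000,
        )
        assert abs(type_correlation(ds).at["area", "speed"]) < 0.1

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(2)
        blocks = {t: rng.normal(size=40) for t in ("volume", "area", "speed")}
        ds = toy_dataset(blocks, ["mef"] * 40)
        corr = type_correlation(ds)
        for a in blocks:
            for b in blocks:
                xa = ds.X[:, ds.type_columns(a)].mean(axis=1)
                xb = ds.X[:, ds.type_columns(b)].mean(axis=1)
                expect = (
                    np.sum((xa - xa.mean()) * (xb - xb.mean()))
                    / np.sqrt(np.sum((xa - xa.mean()) ** 2) * np.sum((xb - xb.mean()) ** 2))
                )
                assert corr.at[a, b] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_recorded_as_zero(self):
        ds = toy_dataset({"area": np.arange(10.0), "speed": np.arange(10.0)}, ["mef"] * 10)
        ds.X[:, ds.type_columns("speed")] = 4.0
        with pytest.warns(UserWarning):
            corr = type_correlation(ds)
        assert corr.at["area", "speed"] == 0.0


# Step-1 survivors for the first recording phase with their printed
# importance ordering (ratio most important; sphericity and I-StdDev in
# the top four; area and E-prolate least important of the survivors).
PHASE1_STEP1_TYPES = (
    "area", "sphericity", "ellipsoid_prolate", "nc_volume_ratio",
    "speed", "intensity_stddev", "intensity_max", "intensity_min",
)
PHASE1_IMPORTANCE = [
    "nc_volume_ratio", "sphericity", "intensity_stddev", "intensity_max",
    "intensity_min", "speed", "area", "ellipsoid_prolate",
]


def phase1_corr():
    corr = pd.DataFrame(
        np.eye(len(PHASE1_STEP1_TYPES)),
        index=list(PHASE1_STEP1_TYPES),
        columns=list(PHASE1_STEP1_TYPES),
    )
    for a, b, r in [("sphericity", "area", 0.77), ("sphericity", "ellipsoid_prolate", 0.66)]:
        corr.at[a, b] = corr.at[b, a] = r
    return corr


class TestCorrelationPrune:
    def test_phase1_printed_outcome(self):
        """sphericity-area 0.77 and sphericity-E-prolate 0.66 with
        sphericity more important removes area and E-prolate, keeping
        the six-type set."""
        final, removed = correlation_prune(
            phase1_corr(), PHASE1_STEP1_TYPES, PHASE1_IMPORTANCE
        )
        assert set(final) == {
            "sphericity", "nc_volume_ratio", "speed",
            "intensity_stddev", "intensity_max", "intensity_min",
        }
        assert {t for t, _, _ in removed} == {"area", "ellipsoid_prolate"}

    def test_no_strong_pairs_is_identity(self):
        corr = pd.DataFrame(np.eye(3), index=["a", "b", "c"], columns=["a", "b", "c"])
        final, removed = correlation_prune(corr, ["a", "b", "c"], ["a", "b", "c"])
        assert final == ("a", "b", "c") and removed == []

    def test_chain_resolved_in_descending_correlation_order(self):
        """A-B 0.7, B-C 0.7, A-C 0.1 with importance A>B>C: B falls to
        A, then the B-C pair is moot, so C survives."""
        corr = pd.DataFrame(
            [[1.0, 0.7, 0.1], [0.7, 1.0, 0.7], [0.1, 0.7, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        final, removed = correlation_prune(corr, ["a", "b", "c"], ["a", "b", "c"])
        assert set(final) == {"a", "c"}
        assert removed == [("b", "a", 0.7)]

    def test_no_surviving_strong_pair(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, size=(6, 6))
        corr = pd.DataFrame((m + m.T) / 2, index=list("abcdef"), columns=list("abcdef"))
        np.fill_diagonal(corr.values, 1.0)
        final, _ = correlation_prune(corr, list("abcdef"), list("abcdef"))
        for i, a in enumerate(final):
            for b in final[i + 1:]:
                assert abs(corr.at[a, b]) < 0.60

    def test_pruner_estimator(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=60)
        ds = toy_dataset(
            {"area": a, "sphericity": a + 0.1 * rng.normal(size=60),
             "speed": rng.normal(size=60)},
            ["mef"] * 60,
        )
        pruner = CorrelationPruner(
            feature_types=ds.feature_types, window_length=3,
            importance_rank=["sphericity", "area", "speed"],
        ).fit(ds.X)
        assert "area" not in pruner.retained_types_
        assert "sphericity" in pruner.retained_types_


def test_importance_rank_orders_survivors_before_removed():
    from ipsprog.select import SelectionTrace

    trace = SelectionTrace(
        initial_score=0.5,
        elimination_order=[("volume", 0.55), ("speed", 0.6)],
        candidate_scores=[{"volume": 0.55}, {"speed": 0.6}, {"area": 0.58, "sphericity": 0.61}],
        final_types=("area", "sphericity"),
        final_score=0.6,
    )
    rank = importance_rank_from_trace(trace)
    assert rank == ["area", "sphericity", "speed", "volume"]
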