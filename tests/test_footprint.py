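"""Footprint NES estimation: analytic score, calibration, per-sample mode."""

import numpy as np
import pandas as pd
import pytest

from cosmos.footprint import (
    estimate_activities,
    per_sample_activities,
    permutation_nes,
    scale_rows,
    select_inputs,
)
from cosmos.synthetic import generate_regulon_study


def make_regulon(regulator, targets, modes=None, weights=None):
    n = len(targets)
    return pd.DataFrame(
        {
            "regulator": regulator,
            "target": targets,
            "mode": modes if modes is not None else [1] * n,
            "weight": weights if weights is not None else [1.0] * n,
        }
    )


def test_identical_statistics_give_zero_nes():
    """All ranks tie at the midpoint, so the symmetric score vanishes."""
    stats = pd.Series(2.5, index=[f"F{i}" for i in range(50)])
    regulons = make_regulon("R", [f"F{i}" for i in range(10)])
    act = estimate_activities(regulons, stats, min_targets=5)
    assert act.loc["R", "nes"] == pytest.approx(0.0, abs=1e-12)


def test_top_ranked_activating_targets_give_positive_nes():
    stats = pd.Series(np.arange(100, dtype=float), index=[f"F{i}" for i in range(100)])
    top = [f"F{i}" for i in range(95, 100)]
    act = estimate_activities(make_regulon("R", top), stats, min_targets=5)
    assert act.loc["R", "nes"] > 2.0


def test_min_targets_filter_omits_sparse_regulators():
    stats = pd.Series(np.arange(30, dtype=float), index=[f"F{i}" for i in range(30)])
    regulons = pd.concat(
        [make_regulon("BIG", [f"F{i}" for i in range(10)]),
         make_regulon("SMALL", ["F1", "F2"])]
    )
    act = estimate_activities(regulons, stats, min_targets=5)
    assert list(act.index) == ["BIG"]


def test_regulator_without_measured_targets_warns_not_raises():
    stats = pd.Series([1.0, 2.0, 3.0], index=["F1", "F2", "F3"])
    regulons = make_regulon("GHOST", ["X1", "X2"])
    with pytest.warns(UserWarning, match="GHOST"):
        act = estimate_activities(regulons, stats, min_targets=1)
    assert len(act) == 0


def test_sign_equivariance():
    """Negating every statistic negates every NES."""
    rng = np.random.default_rng(5)
    stats = pd.Series(rng.normal(size=80), index=[f"F{i}" for i in range(80)])
    regulons = make_regulon("R", [f"F{i}" for i in range(12)],
                            modes=rng.choice([-1, 1], 12).tolist())
    up = estimate_activities(regulons, stats, min_targets=5)
    down = estimate_activities(regulons, -stats, min_targets=5)
    assert down.loc["R", "nes"] == pytest.approx(-up.loc["R", "nes"], abs=1e-10)


def test_raising_a_positive_target_never_decreases_nes():
    rng = np.random.default_rng(6)
    values = rng.normal(size=60)
    index = [f"F{i}" for i in range(60)]
    regulons = make_regulon("R", [f"F{i}" for i in range(8)])
    base = estimate_activities(regulons, pd.Series(values, index=index), min_targets=5)
    bumped = values.copy()
    bumped[3] += 2.0  # push one +1-mode target up in rank
    after = estimate_activities(regulons, pd.Series(bumped, index=index), min_targets=5)
    assert after.loc["R", "nes"] >= base.loc["R", "nes"] - 1e-12


def test_analytic_nes_close_to_permutation_z():
    """The analytic normalization tracks a seeded empirical permutation null."""
    rng = np.random.default_rng(42)
    stats = pd.Series(rng.normal(size=200), index=[f"F{i}" for i in range(200)])
    for seed in range(4):
        r = np.random.default_rng(seed)
        targets = [f"F{i}" for i in r.choice(200, size=10, replace=False)]
        modes = r.choice([-1, 1], size=10).tolist()
        regulon = make_regulon("R", targets, modes=modes)
        analytic = estimate_activities(regulon, stats, min_targets=5).loc["R", "nes"]
        empirical = permutation_nes(regulon, stats, n_permutations=20000, seed=seed)
        assert analytic == pytest.approx(empirical, abs=0.15)


def test_null_nes_distribution_is_standard_normal():
    rng = np.random.default_rng(0)
    stats = pd.Series(rng.normal(size=200), index=[f"F{i}" for i in range(200)])
    blocks = []
    for k in range(300):
        targets = [f"F{i}" for i in rng.choice(200, size=10, replace=False)]
        blocks.append(make_regulon(f"R{k:04d}", targets,
                                   modes=rng.choice([-1, 1], 10).tolist()))
    act = estimate_activities(pd.concat(blocks), stats, min_targets=5)
    assert abs(act["nes"].mean()) < 0.1
    assert abs(act["nes"].std() - 1.0) < 0.1


class TestScaling:
    def test_row_scaling_example(self):
        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        scaled = scale_rows(data)
        assert scaled.loc["g"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_rows_dropped(self):
        data = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["c", "v"],
                            columns=list("abc"))
        assert list(scale_rows(data).index) == ["v"]

    def test_fewer_than_three_samples_rejected(self):
        data = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            scale_rows(data)


def test_per_sample_activities_recover_planted_shift():
    """A regulator whose targets are shifted +2 sd in one sample tops that sample."""
    rng = np.random.default_rng(3)
    n_regulators, n_targets, n_samples = 20, 10, 8
    features = [f"F{i:03d}" for i in range(n_regulators * n_targets)]
    data = pd.DataFrame(
        rng.normal(size=(len(features), n_samples)),
        index=features, columns=[f"s{i}" for i in range(n_samples)],
    )
    regulons = pd.concat(
        [make_regulon(f"R{r:02d}", features[r * n_targets:(r + 1) * n_targets])
         for r in range(n_regulators)]
    )
    planted, sample = "R07", "s3"
    data.loc[regulons.query("regulator == @planted")["target"], sample] += 2.0 * data.values.std()
    acts = per_sample_activities(data, regulons, min_targets=5)
    assert acts[sample].idxmax() == planted


class TestInputSelection:
    def test_nes_threshold_is_strict(self):
        activities = pd.DataFrame({"nes": [2.0, 1.5, -1.8, 1.7]},
                                  index=["A", "B", "C", "D"])
        stats = pd.DataFrame(columns=["statistic", "p_value"])
        regs, metabs = select_inputs(activities, stats, nes_cut=1.7)
        assert regs == {"A": 2.0, "C": -1.8}

    def test_metabolite_p_boundary_excluded(self):
        activities = pd.DataFrame({"nes": [3.0]}, index=["A"])
        stats = pd.DataFrame(
            {"statistic": [2.0, -1.0], "p_value": [0.05, 0.01]},
            index=["metab__a", "metab__b"],
        )
        _, metabs = select_inputs(activities, stats, p_cut=0.05)
        assert metabs == {"metab__b": -1}

    def test_empty_selection_warns(self):
        activities = pd.DataFrame({"nes": [0.3]}, index=["A"])
        stats = pd.DataFrame({"statistic": [1.0], "p_value": [0.5]}, index=["m"])
        with pytest.warns(UserWarning, match="empty"):
            regs, metabs = select_inputs(activities, stats)
        assert regs == {} and metabs == {}


def test_planted_regulon_study_recovers_activity_signs():
    hits = 0
    total = 0
    for seed in range(40):
        regulons, stats, truth = generate_regulon_study(
            n_regulators=10, targets_per_regulator=10, noise_sd=1.0,
            n_features=150, seed=seed,
        )
        act = estimate_activities(regulons, stats, min_targets=5)
        strong = truth[abs(truth) >= 2.0]
        total += len(strong)
        hits += sum(
            np.sign(act.loc[r, "nes"]) == np.sign(a) for r, a in strong.items()
        )
    assert hits / total >= 0.95
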