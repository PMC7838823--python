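"""Footprint-based activity estimation.

A regulator's activity is inferred from the differential statistics of its
direct targets (its *regulon*): target transcripts for transcription factors,
substrate phosphosites for kinases and phosphatases.  The estimate is a
normalized enrichment score (NES) expressed in standard deviations of a
permutation null.

The analytic score used here rank-quantile-normalizes the statistics of all
measured features, maps fractional ranks through the standard-normal
quantile function, and averages the targets' z-values weighted by regulon
weight and mode of regulation:

    NES(R) = sum_i w_i * mode_i * z_i / sqrt(sum_i w_i^2)

Under a random permutation of the statistics the z-values are draws (without
replacement) from an approximately standard-normal population, so the score
is approximately standard normal; :func:`permutation_nes` provides the exact
empirical calibration used to validate this approximation.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_TARGETS_TF = 25
DEFAULT_MIN_TARGETS_KINASE = 5
REGULON_COLUMNS = ("regulator", "target", "mode", "weight")


def _check_regulons(regulons: pd.DataFrame) -> pd.DataFrame:
    for col in REGULON_COLUMNS:
        if col not in regulons.columns:
            raise ValueError(f"regulon table lacks column {col!r}")
    if (regulons["weight"] <= 0).any():
        raise ValueError("regulon weights must be positive")
    if not regulons["mode"].isin([-1, 1]).all():
        raise ValueError("regulon modes must be -1 or +1")
    return regulons


def rank_quantile_z(statistics: pd.Series) -> pd.Series:
    """Normal quantiles of fractional ranks (average ties), rank/(N+1)."""
    values = np.asarray(statistics, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("statistics must be finite")
    ranks = stats.rankdata(values, method="average")
    z = stats.norm.ppf(ranks / (len(values) + 1.0))
    return pd.Series(z, index=statistics.index)


def estimate_activities(
    regulons: pd.DataFrame,
    statistics: pd.Series | pd.DataFrame,
    min_targets: int = DEFAULT_MIN_TARGETS_TF,
) -> pd.DataFrame:
    """NES per regulator from a differential-statistics table.

    Parameters
    ----------
    regulons:
        Long-format table with columns ``regulator, target, mode, weight``.
    statistics:
        Either a Series of signed statistics indexed by feature id, or a
        stat-table DataFrame with a ``statistic`` column.  The rank universe
        is every measured feature (no regulon-restricted filtering).
    min_targets:
        Regulators with fewer measured targets are omitted.

    Returns
    -------
    DataFrame indexed by regulator with columns ``nes`` and ``n_targets``.
    """
    if isinstance(statistics, pd.DataFrame):
        statistics = statistics["statistic"]
    if len(statistics) == 0:
        raise ValueError("empty statistics table")
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    regulons = _check_regulons(regulons)
    z = rank_quantile_z(statistics)
    rows = []
    for regulator, block in regulons.groupby("regulator", sort=True):
        block = block.drop_duplicates(subset="target")
        measured = block[block["target"].isin(z.index)]
        if len(measured) == 0:
            warnings.warn(f"regulator {regulator!r} has no measured targets; omitted")
            continue
        if len(measured) < min_targets:
            continue
        w = measured["weight"].to_numpy(dtype=float)
        mode = measured["mode"].to_numpy(dtype=float)
        zt = z.loc[measured["target"]].to_numpy(dtype=float)
        nes = float(np.sum(w * mode * zt) / np.sqrt(np.sum(w**2)))
        rows.append((regulator, nes, len(measured)))
    out = pd.DataFrame(rows, columns=["regulator", "nes", "n_targets"])
    return out.set_index("regulator")


def permutation_nes(
    regulon: pd.DataFrame,
    statistics: pd.Series,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> float:
    """Empirical permutation calibration of one regulator's score.

    Computes the raw weighted score of the observed target z-values and
    standardizes it against the null obtained by permuting the statistic
    vector across features (equivalently: resampling target z-values without
    replacement).  Serves as the model-free check of the analytic NES.
    """
    z = rank_quantile_z(statistics)
    regulon = regulon.drop_duplicates(subset="target")
    measured = regulon[regulon["target"].isin(z.index)]
    w = measured["weight"].to_numpy(dtype=float)
    mode = measured["mode"].to_numpy(dtype=float)
    observed = float(np.sum(w * mode * z.loc[measured["target"]].to_numpy()))
    rng = np.random.default_rng(seed)
    zvals = z.to_numpy()
    n_t = len(measured)
    null = np.empty(n_permutations)
    wm = w * mode
    for i in range(n_permutations):
        draw = zvals[rng.choice(len(zvals), size=n_t, replace=False)]
        null[i] = np.dot(wm, draw)
    return (observed - null.mean()) / null.std(ddof=1)


def scale_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each feature row across samples (sd with ddof=1).

    Constant rows (zero variance) are dropped.
    """
    if data.shape[1] < 3:
        raise ValueError("per-sample scaling needs at least 3 samples")
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    scaled = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[
        keep, None
    ]
    return pd.DataFrame(scaled, index=data.index[keep], columns=data.columns)


def per_sample_activities(
    data: pd.DataFrame,
    regulons: pd.DataFrame,
    min_targets: int = DEFAULT_MIN_TARGETS_TF,
) -> pd.DataFrame:
    """Regulator x sample NES matrix from a features x samples data matrix.

    Each feature row is z-scored across samples; the per-sample z-scores are
    then used as the statistics for :func:`estimate_activities`, column by
    column, so each activity is relative to the other samples.
    """
    scaled = scale_rows(data)
    columns = {}
    for sample in scaled.columns:
        act = estimate_activities(regulons, scaled[sample], min_targets=min_targets)
        columns[sample] = act["nes"]
    out = pd.DataFrame(columns)
    return out.dropna(how="all")


def select_inputs(
    activities: pd.DataFrame,
    metabolite_stats: pd.DataFrame,
    nes_cut: float = 1.7,
    p_cut: float = 0.05,
) -> tuple[dict[str, float], dict[str, int]]:
    """Pick deregulated regulators and metabolites for a causal run.

    Regulators with ``|NES| > nes_cut`` are kept with their NES as value;
    metabolites with uncorrected ``p < p_cut`` are kept with the sign of
    their statistic.  Both comparisons are strict.
    """
    if nes_cut <= 0:
        raise ValueError("nes_cut must be positive")
    regs = {
        str(node): float(nes)
        for node, nes in activities["nes"].items()
        if abs(nes) > nes_cut
    }
    metabs: dict[str, int] = {}
    for node, row in metabolite_stats.iterrows():
        if float(row["p_value"]) < p_cut:
            sign = int(np.sign(row["statistic"]))
            if sign != 0:
                metabs[str(node)] = sign
    if not regs and not metabs:
        warnings.warn("input selection is empty at the given thresholds")
    return regs, metabs
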