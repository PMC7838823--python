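"""Readers and writers for the tool's plain-text table dialects.

Networks travel as 3-column SIF tables (source, sign, target; tab or ``;``
delimited) with a node-kind sidecar; regulons, statistics, counts and
solution pools as TSV; gene sets as GMT; run configuration as TOML.
All writers sort rows and fix float formatting so that reruns are
byte-identical.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import NODE_KINDS, CausalPKN, SignedEdge
from .ilp import SolutionPool

FLOAT_FORMAT = "%.6g"


# -- SIF network -------------------------------------------------------------


def write_sif(pkn: CausalPKN, path: str | Path, sidecar: bool = True) -> None:
    """Write a PKN as SIF TSV plus (by default) a ``<stem>.nodes.tsv`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\tsign\ttarget\tprovenance\n")
        for e in pkn.edges_sorted():
            prov = ",".join(pkn.edge_provenances(e))
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\t{prov}\n")
    if sidecar:
        with open(path.with_suffix(".nodes.tsv"), "w") as fh:
            fh.write("node\tkind\tmembers\n")
            for node in sorted(pkn.node_kind):
                members = ",".join(sorted(pkn.members.get(node, ())))
                fh.write(f"{node}\t{pkn.node_kind[node]}\t{members}\n")


def read_sif(path: str | Path) -> CausalPKN:
    """Read a SIF TSV (tab or ';' delimited), with optional node sidecar."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    pkn = CausalPKN()
    for i, line in enumerate(text):
        sep = "\t" if "\t" in line else ";"
        parts = [p.strip() for p in line.split(sep)]
        if i == 0 and parts[0].lower() == "source":
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}: line {i + 1} has fewer than 3 fields")
        prov = parts[3].split(",")[0] if len(parts) > 3 and parts[3] else ""
        pkn.add_edge(SignedEdge(parts[0], int(parts[1]), parts[2], provenance=prov))
    sidecar = path.with_suffix(".nodes.tsv")
    if sidecar.exists():
        nodes = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("")
        for row in nodes.itertuples(index=False):
            if row.kind not in NODE_KINDS:
                raise ValueError(f"unknown node kind {row.kind!r}")
            members = row.members.split(",") if row.members else None
            pkn.set_kind(row.node, row.kind, members=members)
    return pkn


# -- tabular inputs ----------------------------------------------------------


def read_regulons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["mode"] = df["mode"].astype(int)
    df["weight"] = df["weight"].astype(float)
    return df


def write_regulons(regulons: pd.DataFrame, path: str | Path) -> None:
    regulons.sort_values(["regulator", "target"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().strip().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def regulons_from_gmt(path: str | Path) -> pd.DataFrame:
    """Unsigned GMT sets as regulons (mode +1, weight 1)."""
    rows = [
        (name, target, 1, 1.0)
        for name, targets in read_gmt(path).items()
        for target in sorted(targets)
    ]
    return pd.DataFrame(rows, columns=["regulator", "target", "mode", "weight"])


def read_stat_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "statistic" not in df.columns:
        raise ValueError(f"{path}: stat table needs a 'statistic' column")
    return df


def write_stat_table(stats: pd.DataFrame, path: str | Path) -> None:
    stats.sort_index().to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.sort_index().to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_activities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- solution pools ----------------------------------------------------------


def write_solution_pool(
    pool: SolutionPool,
    out_dir: str | Path,
    inputs: dict[str, int] | None = None,
    measurements: dict[str, tuple[int, float]] | None = None,
) -> None:
    """Write pool edge/node attribute tables plus a small JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = inputs or {}
    measurements = measurements or {}
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("source\tsign\ttarget\tweight\n")
        for (src, sign, tgt), w in sorted(pool.edge_weight.items()):
            fh.write(f"{src}\t{sign}\t{tgt}\t{w:.6g}\n")
    with open(out_dir / "nodes.tsv", "w") as fh:
        fh.write("node\tstate\tfrequency\tis_input\tis_measurement\n")
        for node, (freq, state) in sorted(pool.node_summary().items()):
            fh.write(
                f"{node}\t{state}\t{freq:.6g}\t{int(node in inputs)}"
                f"\t{int(node in measurements)}\n"
            )
    summary = {
        "status": pool.status,
        "objective": pool.objective,
        "n_solutions": len(pool.solutions),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def read_pool_edges(out_dir: str | Path) -> dict[tuple[str, int, str], float]:
    df = pd.read_csv(Path(out_dir) / "edges.tsv", sep="\t")
    return {
        (r.source, int(r.sign), r.target): float(r.weight)
        for r in df.itertuples(index=False)
    }


# -- run configuration -------------------------------------------------------


def read_run_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_run_config(config: dict, path: str | Path) -> None:
    lines = []
    for key in sorted(config):
        value = config[key]
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, (int, float)):
            rendered = repr(value)
        else:
            rendered = json.dumps(str(value))
        lines.append(f"{key} = {rendered}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- study directories -------------------------------------------------------


def write_study(study, out_dir: str | Path, config: dict | None = None) -> None:
    """Write a complete synthetic study directory consumable by the CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_sif(study.pkn, out_dir / "pkn.sif")
    study.activities.to_csv(out_dir / "activities.tsv", sep="\t", float_format=FLOAT_FORMAT)
    write_stat_table(study.metabolite_stats, out_dir / "metabolite_stats.tsv")
    if study.transcript_stats is not None:
        write_stat_table(study.transcript_stats, out_dir / "transcript_stats.tsv")
    write_matrix(study.counts, out_dir / "counts.tsv")
    if len(study.regulons):
        write_regulons(study.regulons, out_dir / "regulons.tsv")
    if study.activity_matrix is not None:
        write_matrix(study.activity_matrix, out_dir / "activity_matrix.tsv")
    truth = {
        "seed": study.seed,
        "beta": study.beta,
        "inputs": study.inputs,
        "measurements": {k: list(v) for k, v in sorted(study.measurements.items())},
        "true_nodes": dict(sorted(study.true_network.node_state.items())),
        "true_edges": sorted(e.key for e in study.true_network.active_edges),
        "objective": study.true_network.objective,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    write_run_config(config or {"beta": study.beta, "seed": study.seed}, out_dir / "run.toml")


def load_study_inputs(study_dir: str | Path):
    """Load (pkn, activities, metabolite_stats, counts, transcript_stats)."""
    study_dir = Path(study_dir)
    pkn = read_sif(study_dir / "pkn.sif")
    activities = read_activities(study_dir / "activities.tsv")
    metab = read_stat_table(study_dir / "metabolite_stats.tsv")
    counts_path = study_dir / "counts.tsv"
    counts = read_matrix(counts_path) if counts_path.exists() else None
    tstats_path = study_dir / "transcript_stats.tsv"
    tstats = read_stat_table(tstats_path) if tstats_path.exists() else None
    return pkn, activities, metab, counts, tstats
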