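"""Configuration, serialization and worked-example fixture generation.

Design files are YAML; stage-wise marginal p values travel as CSV with
columns ``label,stage,p``; interim state and boundary tables are persisted
as JSON so the final analysis can be audited and re-run without repeating
the interim computation.
"""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .cer import BoundaryRow, BoundaryTable
from .combo import AdaptationPlan, DesignSpec
from .graph import GraphSpec, WeightTable, closure_weights
from .numerics import CorrBlock, CorrelationModel

__all__ = ["AnalysisConfig", "boundary_table_from_dict", "boundary_table_to_dict",
           "graph_from_dict", "graph_to_dict", "load_config", "load_adaptation",
           "make_fixtures", "read_pvalues", "write_log", "write_weight_table"]


class ConfigError(ValueError):
    """A configuration file violated the schema; message lists the problems."""


# -------------------------------------------------------------------------
# graph and correlation-model serialization


def graph_to_dict(graph: GraphSpec) -> dict:
    return {
        "labels": list(graph.labels),
        "weights": [float(w) for w in graph.weights],
        "transition": [[float(x) for x in row] for row in graph.transition],
    }


def graph_from_dict(d: dict) -> GraphSpec:
    try:
        return GraphSpec(tuple(d["labels"]), np.asarray(d["weights"], dtype=float),
                         np.asarray(d["transition"], dtype=float))
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid graph specification: {exc}") from exc


def corr_model_from_dict(blocks: list) -> CorrelationModel:
    out = []
    for b in blocks:
        labels = tuple(b["labels"])
        if "rho" in b:
            out.append(CorrBlock.equicorrelated(labels, float(b["rho"])))
        else:
            l1 = tuple(float(x) for x in b["loadings1"])
            l2 = tuple(float(x) for x in b.get("loadings2", b["loadings1"]))
            out.append(CorrBlock(labels, l1, l2))
    return CorrelationModel(tuple(out))


def corr_model_to_dict(model: CorrelationModel) -> list:
    return [{"labels": list(b.labels), "loadings1": list(b.loadings1),
             "loadings2": list(b.loadings2)} for b in model.blocks]


# -------------------------------------------------------------------------
# analysis configuration


@dataclass(frozen=True)
class AnalysisConfig:
    design: DesignSpec
    stage1_csv: str | None = None
    stage2_csv: str | None = None
    adaptation_yaml: str | None = None
    outdir: str = "."
    seed: int = 0
    tolerance: float = 1e-10


def load_config(path) -> AnalysisConfig:
    """Load and validate an analysis configuration (YAML or JSON)."""
    raw = yaml.safe_load(Path(path).read_text())
    problems = []
    if not isinstance(raw, dict) or "design" not in raw:
        raise ConfigError("configuration must be a mapping with a 'design' block")
    d = raw["design"]
    graph = graph_from_dict(d.get("graph", d))
    corr = corr_model_from_dict(d.get("correlation", []))
    alpha = float(d.get("alpha", 0.025))
    t_planned = float(d.get("t_planned", 0.5))
    combo_weights = d.get("combo_weights")
    if combo_weights is not None:
        combo_weights = (float(combo_weights[0]), float(combo_weights[1]))
        if abs(combo_weights[0] ** 2 + combo_weights[1] ** 2 - 1.0) > 1e-9:
            problems.append("combo_weights must satisfy nu1^2 + nu2^2 = 1")
    unknown = set(corr_labels := [l for b in corr.blocks for l in b.labels]) \
        - set(graph.labels)
    if unknown:
        problems.append(f"correlation blocks mention unknown labels {sorted(unknown)}")
    tol = float(raw.get("tolerance", 1e-10))
    if tol <= 0:
        problems.append("tolerance must be positive")
    if problems:
        raise ConfigError("; ".join(problems))
    design = DesignSpec(graph, corr, alpha=alpha, t_planned=t_planned,
                        combo_weights=combo_weights)
    return AnalysisConfig(design,
                          stage1_csv=raw.get("stage1_csv"),
                          stage2_csv=raw.get("stage2_csv"),
                          adaptation_yaml=raw.get("adaptation_yaml"),
                          outdir=raw.get("outdir", "."),
                          seed=int(raw.get("seed", 0)),
                          tolerance=tol)


def load_adaptation(path, design: DesignSpec) -> AdaptationPlan:
    raw = yaml.safe_load(Path(path).read_text())
    selected = tuple(raw["selected"])
    bad = set(selected) - set(design.labels)
    if bad:
        raise ConfigError(f"adaptation selects unknown hypotheses {sorted(bad)}")
    table = None
    if "graph" in raw:
        table = closure_weights(graph_from_dict(raw["graph"]))
    elif "weights" in raw:
        entries = {}
        probe = WeightTable(selected, {})
        for key, wmap in raw["weights"].items():
            labels = tuple(key.split(","))
            entries[probe.mask(labels)] = {l: float(v) for l, v in wmap.items()}
        table = WeightTable(selected, entries)
    tfr = raw.get("info_fractions")
    if tfr is not None:
        tfr = {l: float(v) for l, v in tfr.items()}
        for l, v in tfr.items():
            if not 0.0 < v < 1.0:
                raise ConfigError(f"information fraction for {l} outside (0, 1)")
    corr = corr_model_from_dict(raw["correlation"]) if "correlation" in raw else None
    return AdaptationPlan(selected, weight_table=table, info_fractions=tfr,
                          corr_model=corr)


# -------------------------------------------------------------------------
# tabular IO


def read_pvalues(path, stage: int | None = None) -> dict:
    """Read marginal p values from CSV with columns ``label,stage,p``
    (the stage column is optional when the file holds a single stage)."""
    out: dict = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if stage is not None and "stage" in row and int(row["stage"]) != stage:
                continue
            p = float(row["p"])
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"p value {p} for {row['label']} outside [0, 1]")
            out[row["label"]] = p
    if not out:
        raise ConfigError(f"no p values found in {path}")
    return out


def write_weight_table(table: WeightTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subset", "label", "weight"])
        for subset, wmap in table.subsets():
            for l in subset:
                w.writerow([",".join(subset), l, repr(wmap[l])])


def boundary_table_to_dict(table: BoundaryTable) -> dict:
    rows = []
    for J, r in sorted(table.rows.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        rows.append({
            "subset": sorted(J), "weights": r.weights, "regime": r.regime,
            "c1": r.c1, "c2": r.c2, "B": r.B, "c2_adapted": r.c2_adapted,
            "adapted_weights": r.adapted_weights,
            "effective": sorted(r.effective) if r.effective else None,
            "status": r.status,
        })
    return {"labels": list(table.labels), "alpha": table.alpha,
            "alpha1": table.alpha1, "t_planned": table.t_planned, "rows": rows}


def boundary_table_from_dict(d: dict) -> BoundaryTable:
    rows = {}
    for r in d["rows"]:
        J = frozenset(r["subset"])
        rows[J] = BoundaryRow(
            J, dict(r["weights"]), r["regime"], float(r["c1"]), float(r["c2"]),
            B=r["B"], c2_adapted=r["c2_adapted"],
            adapted_weights=r["adapted_weights"],
            effective=frozenset(r["effective"]) if r["effective"] else None,
            status=r["status"])
    return BoundaryTable(tuple(d["labels"]), float(d["alpha"]),
                         float(d["alpha1"]), float(d["t_planned"]), rows)


def write_log(outdir, command: str, seed=None, tolerance=None, inputs=()) -> Path:
    """Append a run record with package version, seeds and input digests."""
    from . import __version__
    rec = {
        "time": datetime.now(timezone.utc).isoformat(),
        "command": command,
        "gamcp": __version__,
        "numpy": np.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "tolerance": tolerance,
        "inputs": {str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
                   for p in inputs if p and Path(p).exists()},
    }
    path = Path(outdir) / "gamcp_run.log"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(json.dumps(rec) + "\n")
    return path


# -------------------------------------------------------------------------
# fixtures: the worked-example inputs


def _schizophrenia_design() -> dict:
    graph = {
        "labels": ["H1", "H2", "H3", "H4"],
        "weights": [0.5, 0.5, 0.0, 0.0],
        "transition": [[0.0, 0.5, 0.5, 0.0],
                       [0.5, 0.0, 0.0, 0.5],
                       [0.0, 1.0, 0.0, 0.0],
                       [1.0, 0.0, 0.0, 0.0]],
    }
    corr = [{"labels": ["H1", "H2"], "rho": 0.5},
            {"labels": ["H3", "H4"], "rho": 0.5}]
    return {"design": {"graph": graph, "correlation": corr,
                       "alpha": 0.025, "t_planned": 0.5}}


def make_fixtures(name: str, outdir) -> list:
    """Write the named worked-example fixture files; returns the paths.

    ``schizophrenia_combo`` / ``schizophrenia_cer``: the two-dose
    two-endpoint design with its stage-one and stage-two p values.
    ``fourarm_sim``: the four-arm two-endpoint simulation design graph.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def put(fname: str, text: str) -> None:
        p = outdir / fname
        p.write_text(text)
        paths.append(p)

    if name == "schizophrenia_combo":
        cfg = _schizophrenia_design()
        cfg.update(stage1_csv=str(outdir / "stage1.csv"),
                   stage2_csv=str(outdir / "stage2.csv"))
        put("design.yaml", yaml.safe_dump(cfg, sort_keys=False))
        put("stage1.csv", "label,stage,p\nH1,1,0.00045\nH2,1,0.0952\n"
                          "H3,1,0.0225\nH4,1,0.1104\n")
        put("stage2.csv", "label,stage,p\nH2,2,0.1121\nH3,2,0.0112\nH4,2,0.1153\n")
        put("adaptation.yaml", yaml.safe_dump(
            {"selected": ["H2", "H3", "H4"]}, sort_keys=False))
    elif name == "schizophrenia_cer":
        cfg = _schizophrenia_design()
        cfg.update(stage1_csv=str(outdir / "stage1.csv"),
                   stage2_csv=str(outdir / "stage2.csv"),
                   adaptation_yaml=str(outdir / "adaptation.yaml"))
        put("design.yaml", yaml.safe_dump(cfg, sort_keys=False))
        put("stage1.csv", "label,stage,p\nH1,1,0.00045\nH2,1,0.0952\n"
                          "H3,1,0.0225\nH4,1,0.1104\n")
        put("stage2.csv", "label,stage,p\nH2,2,0.0299\nH4,2,0.0586\n")
        # drop H3, treat the low-dose endpoints as co-primaries, t~ = 0.4
        put("adaptation.yaml", yaml.safe_dump({
            "selected": ["H2", "H4"],
            "weights": {"H2": {"H2": 1.0}, "H4": {"H4": 1.0},
                        "H2,H4": {"H2": 0.5, "H4": 0.5}},
            "info_fractions": {"H2": 0.4, "H4": 0.4},
        }, sort_keys=False))
    elif name == "fourarm_sim":
        from .simulate import multiarm_graph
        g = multiarm_graph(4)
        put("design.yaml", yaml.safe_dump({
            "design": {"graph": graph_to_dict(g),
                       "correlation": [
                           {"labels": [f"H{i}" for i in range(1, 5)], "rho": 0.5},
                           {"labels": [f"H{i}" for i in range(5, 9)], "rho": 0.5}],
                       "alpha": 0.025, "t_planned": 0.5}}, sort_keys=False))
    else:
        raise ConfigError(f"unknown fixture name {name!r}")
    return paths
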