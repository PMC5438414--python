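"""Result rendering and end-to-end experiment orchestration.

Turns an :class:`~multiroi.classify.EvaluationResult` into the tabular
artifacts of the analysis: selection-frequency rankings (per feature class),
a connection edge list for the selected similarity pairs (loadable by Circos
or any graph tool), a weighting-factor sweep, and a one-call
``run_experiment`` that drives simulation -> features -> nested CV -> files
from a single config mapping with a mandatory seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasTable, builtin_atlas
from .classify import (
    EvaluationResult,
    ExperimentConfig,
    KernelConfig,
    repeated_nested_cv,
)
from .cohort import Cohort, read_cohort, write_cohort
from .features import extract_features, feature_label
from .selection import SelectionConfig
from .simulate import EffectSpec, generate_cohort

log = logging.getLogger("multiroi")

__all__ = [
    "ConnectionEdge",
    "frequency_table",
    "connection_edges",
    "weight_sweep",
    "run_experiment",
    "feature_id_to_str",
    "feature_id_from_str",
]


@dataclass(frozen=True)
class ConnectionEdge:
    """One selected ROI pair with its selection frequency."""

    roi_a: str  # e.g. "ACG_L"
    roi_b: str
    frequency: int
    intra_hemisphere: bool


def _is_similarity_id(fid) -> bool:
    return isinstance(fid[1], (int, np.integer))


def frequency_table(
    result: EvaluationResult,
    feature_class: str = "roi",
    top_n: int = 15,
    atlas: AtlasTable | None = None,
) -> pd.DataFrame:
    """Rank features of one class by how often the cascade selected them.

    Rows are sorted by frequency descending, ties by feature id; ROI
    features render as ``<Region name>_<L|R>_<G|W|C|T|A>`` and similarity
    features as ``<Name>_<hemi>-<Name>_<hemi>``.
    """
    if feature_class not in ("roi", "similarity"):
        raise ValueError("feature_class must be 'roi' or 'similarity'")
    atlas = atlas or builtin_atlas()
    counts = result.selection_counts
    if not counts:
        raise ValueError("no selection counts in result")
    want_sim = feature_class == "similarity"
    items = [(f, c) for f, c in counts.items() if _is_similarity_id(f) == want_sim]
    items.sort(key=lambda fc: (-fc[1], fc[0]))
    rows = [
        {
            "rank": k + 1,
            "feature": feature_label(f, atlas, style="long"),
            "feature_id": feature_id_to_str(f),
            "frequency": c,
        }
        for k, (f, c) in enumerate(items[:top_n])
    ]
    return pd.DataFrame(rows, columns=["rank", "feature", "feature_id", "frequency"])


def connection_edges(
    result: EvaluationResult, atlas: AtlasTable | None = None
) -> list[ConnectionEdge]:
    """One edge per selected similarity pair, flagged intra/inter-hemisphere."""
    atlas = atlas or builtin_atlas()
    edges = []
    pairs = [fc for fc in result.selection_counts.items() if _is_similarity_id(fc[0])]
    for fid, freq in sorted(pairs, key=lambda fc: (-fc[1], fc[0])):
        ea, eb = atlas[fid[0]], atlas[fid[1]]
        edges.append(
            ConnectionEdge(
                roi_a=ea.label,
                roi_b=eb.label,
                frequency=int(freq),
                intra_hemisphere=ea.hemisphere == eb.hemisphere,
            )
        )
    return edges


def edges_to_frame(edges: list[ConnectionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_a": e.roi_a,
                "roi_b": e.roi_b,
                "frequency": e.frequency,
                "intra_hemisphere": e.intra_hemisphere,
            }
            for e in edges
        ],
        columns=["roi_a", "roi_b", "frequency", "intra_hemisphere"],
    )


def weight_sweep(
    features,
    config: ExperimentConfig,
    beta_grid,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Re-run the full protocol at each kernel weight, sharing outer splits.

    All betas see identical outer splits (same seed), so the rows are
    directly comparable; the endpoints are exactly the single-kernel runs.
    """
    beta_grid = list(beta_grid)
    if not beta_grid:
        raise ValueError("beta grid must be non-empty")
    rows = []
    for beta in beta_grid:
        cfg = replace(config, kernel=replace(config.kernel, beta=float(beta)))
        res = repeated_nested_cv(features, cfg, n_repeats=n_repeats)
        s = res.summary()
        rows.append(
            {
                "beta": float(beta),
                "mean_acc": s["acc"][0],
                "sd_acc": s["acc"][1],
                "mean_auc": s["auc"][0],
                "sd_auc": s["auc"][1],
            }
        )
        log.info("beta=%.2f mean ACC %.3f", beta, s["acc"][0])
    return pd.DataFrame(rows)


# --- feature id serialization -------------------------------------------------

def feature_id_to_str(fid) -> str:
    """``(7, 'gmv') -> '7:gmv'``; ``(31, 47) -> '31-47'``."""
    a, b = fid
    return f"{a}-{b}" if _is_similarity_id(fid) else f"{a}:{b}"


def feature_id_from_str(s: str):
    if ":" in s:
        a, b = s.split(":")
        return (int(a), b)
    a, b = s.split("-")
    return (int(a), int(b))


# --- config-driven end-to-end run ---------------------------------------------

_DEFAULT_CONFIG = {
    "n_repeats": 10,
    "top_n": 15,
    "beta_grid": None,  # e.g. [0.0, 0.25, 0.5, 0.65, 0.75, 1.0]
    "selection": {},
    "kernel": {},
}


def _experiment_config(raw: dict, seed: int) -> ExperimentConfig:
    sel = SelectionConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("selection", {}).items()
    })
    ker = KernelConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("kernel", {}).items()
    })
    return ExperimentConfig(selection=sel, kernel=ker, seed=seed)


def _load_cohort(raw: dict, seed: int) -> Cohort:
    if "cohort_path" in raw:
        return read_cohort(raw["cohort_path"])
    sim = raw.get("simulate")
    if sim is None:
        raise ValueError("config must provide either 'cohort_path' or 'simulate'")
    spec = EffectSpec(
        roi_effects=tuple(tuple(e) for e in sim.get("roi_effects", [])),
        connection_effects=tuple(tuple(e) for e in sim.get("connection_effects", [])),
        n_high=int(sim.get("n_high", 34)),
        n_low=int(sim.get("n_low", 34)),
        seed=seed,
    )
    cohort, _ = generate_cohort(spec)
    return cohort


def run_experiment(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the whole pipeline from a config mapping (or YAML/JSON path).

    Writes into *outdir*: the cohort echo, per-run and summary metric TSVs,
    ROI and similarity frequency tables, the connection edge list, an
    optional weight-sweep table, and the fully resolved config (JSON, seed
    included) so the run can be reproduced bit-for-bit.  Returns a dict of
    output paths plus the in-memory :class:`EvaluationResult`.
    """
    if not isinstance(config, dict):
        config = _read_config_file(config)
    if "seed" not in config:
        raise ValueError("config must set an explicit 'seed' (no silent randomness)")
    raw = {**_DEFAULT_CONFIG, **config}
    seed = int(raw["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _load_cohort(raw, seed)
    cfg = _experiment_config(raw, seed)
    n_repeats = int(raw["n_repeats"])
    log.info("cohort: %d subjects (%s); %d repeats, seed %d",
             len(cohort), cohort.group_counts(), n_repeats, seed)

    write_cohort(cohort, outdir / "cohort.csv")
    features = extract_features(cohort)
    result = repeated_nested_cv(features, cfg, n_repeats=n_repeats)

    runs = pd.DataFrame([m.as_dict() for m in result.per_run])
    runs.insert(0, "run", np.arange(1, len(runs) + 1))
    runs.to_csv(outdir / "metrics_runs.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [{"metric": m, "mean": mu, "sd": sd} for m, (mu, sd) in result.summary().items()]
    )
    summary.to_csv(outdir / "metrics_summary.tsv", sep="\t", index=False)

    top_n = int(raw["top_n"])
    frequency_table(result, "roi", top_n).to_csv(
        outdir / "roi_frequency.tsv", sep="\t", index=False
    )
    frequency_table(result, "similarity", top_n).to_csv(
        outdir / "similarity_frequency.tsv", sep="\t", index=False
    )
    edges_to_frame(connection_edges(result)).to_csv(
        outdir / "edges.tsv", sep="\t", index=False
    )

    paths = {
        "cohort": outdir / "cohort.csv",
        "metrics_runs": outdir / "metrics_runs.tsv",
        "metrics_summary": outdir / "metrics_summary.tsv",
        "roi_frequency": outdir / "roi_frequency.tsv",
        "similarity_frequency": outdir / "similarity_frequency.tsv",
        "edges": outdir / "edges.tsv",
    }

    if raw["beta_grid"]:
        sweep = weight_sweep(features, cfg, raw["beta_grid"], n_repeats=n_repeats)
        sweep.to_csv(outdir / "weight_sweep.tsv", sep="\t", index=False)
        paths["weight_sweep"] = outdir / "weight_sweep.tsv"

    resolved = {k: v for k, v in raw.items() if k != "beta_grid" or v}
    (outdir / "config_resolved.json").write_text(json.dumps(resolved, indent=2, default=str))
    paths["config"] = outdir / "config_resolved.json"
    return {"result": result, **paths}


def _read_config_file(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
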