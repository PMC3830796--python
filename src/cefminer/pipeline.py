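"""End-to-end orchestration: preprocess → GA search → evaluation → synergy.

``run_full_pipeline`` sequences the whole analysis and writes a bundle of
CSV reports plus a JSON manifest (seed, configuration hash, record counts)
so that a run is fully reproducible from its manifest.  Any stage failure
aborts the run, removes partial outputs and re-raises with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import evaluation, metrics, simulate, synergy
from .ga import FitnessConfig, GAConfig, run_ga
from .records import (
    AnalysisTable,
    HerbVocabulary,
    ValidationError,
    build_analysis_table,
    read_visits_csv,
    write_analysis_csv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "load_config"]

ARTIFACTS = (
    "analysis_table.csv",
    "cef_table.csv",
    "ztest_report.csv",
    "lopo_report.csv",
    "herb_ranking.csv",
    "network_edges.csv",
    "synergy_report.csv",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run."""

    input_csv: str | None = None  # visit CSV; None -> synthetic preset
    preset: str = "study"  # "tiny" or "study" when input_csv is None
    out_dir: str = "cefminer_out"
    seed: int = 0
    n_symptoms: int = 15
    ga: GAConfig = field(default_factory=GAConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    synergy_n_perm: int = 2000
    lopo: bool = True
    network_threshold: int = 1
    write_graphml: bool = True

    def config_hash(self) -> str:
        payload = _to_jsonable(self)
        payload.pop("out_dir", None)  # output location is not part of the run
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) mapping.

    Top-level keys map to :class:`PipelineConfig` fields; nested ``ga`` and
    ``fitness`` mappings to their config dataclasses.  Unknown keys raise.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "ga" in kwargs:
        kwargs["ga"] = GAConfig(**kwargs["ga"])
    if "fitness" in kwargs:
        kwargs["fitness"] = FitnessConfig(**kwargs["fitness"])
    return PipelineConfig(**kwargs)


def _load_table(cfg: PipelineConfig) -> AnalysisTable:
    if cfg.input_csv is not None:
        visits = read_visits_csv(cfg.input_csv, n_symptoms=cfg.n_symptoms)
        vocab = HerbVocabulary.from_visits(visits)
        return build_analysis_table(visits, vocab)
    if cfg.preset == "tiny":
        sim = simulate.tiny_config(seed=cfg.seed)
    elif cfg.preset == "study":
        planted = (
            simulate.PlantedCEF(herb_indices=tuple(range(2, 10)),
                                support=0.05, group_ep=0.6),
        )
        sim = simulate.study_config(seed=cfg.seed, planted_cefs=planted)
    else:
        raise ValidationError(f"unknown preset: {cfg.preset!r}")
    return simulate.generate_analysis_table(sim)


def _cef_table(results, vocab: HerbVocabulary) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results, start=1):
        rows.append(
            {
                "cef_id": i,
                "herbs": ";".join(r.candidate.herb_names(vocab)),
                "n_herbs": r.n_herbs,
                "fitness": r.fitness,
                "ev": r.ev,
                "alpha": r.alpha,
                "s_0.7": r.support_at[0.7],
                "s_0.8": r.support_at[0.8],
                "s_0.9": r.support_at[0.9],
                "s_1": r.support_at[1.0],
                "pbs": r.pbs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cef_id", "herbs", "n_herbs", "fitness", "ev", "alpha",
                 "s_0.7", "s_0.8", "s_0.9", "s_1", "pbs"],
    )


def run_full_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": _to_jsonable(cfg),
    }

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        table = _load_table(cfg)
        manifest["n_records"] = table.n
        manifest["n_patients"] = table.n_patients
        manifest["n_herbs"] = table.m
        manifest["effective_proportion"] = table.effective_proportion
        _write("analysis_table.csv", lambda p: write_analysis_csv(table, p))
        timings[stage] = time.perf_counter() - t0

        stage = "search"
        t0 = time.perf_counter()
        ga_cfg = dataclasses.replace(cfg.ga, seed=cfg.seed)
        results = run_ga(table, ga_cfg, cfg.fitness)
        cef_df = _cef_table(results, table.vocab)
        _write("cef_table.csv", lambda p: cef_df.to_csv(p, index=False))
        manifest["n_cef"] = len(results)
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        zrows, lrows = [], []
        for i, r in enumerate(results, start=1):
            split = metrics.split_groups(r.candidate, table, level=cfg.fitness.level)
            try:
                zt = evaluation.two_proportion_ztest(split.k1, split.n1, split.k0, split.n0)
                z, p = zt.z, zt.p_two_sided
            except (evaluation.UndefinedTestError, ValidationError):
                z, p = float("nan"), float("nan")
            zrows.append({"cef_id": i, "ep_noncef": split.ep0, "ep_cef": split.ep1,
                          "z": z, "p_value": p})
            if cfg.lopo:
                lopo = evaluation.leave_one_patient_out(table, r.candidate,
                                                        level=cfg.fitness.level)
                s = lopo.summary()
                lrows.append(
                    {
                        "cef_id": i,
                        "ep_noncef_mean": s["ep0_mean"],
                        "ep_noncef_range": f"[{s['ep0_min']:.3f}, {s['ep0_max']:.3f}]",
                        "ep_cef_mean": s["ep1_mean"],
                        "ep_cef_range": f"[{s['ep1_min']:.3f}, {s['ep1_max']:.3f}]",
                        "neglog_p_mean": s["neglog_p_mean"],
                        "neglog_p_range": f"[{s['neglog_p_min']:.3f}, {s['neglog_p_max']:.3f}]",
                        "n_undefined": int(s["n_undefined"]),
                    }
                )
        zcols = ["cef_id", "ep_noncef", "ep_cef", "z", "p_value"]
        lcols = ["cef_id", "ep_noncef_mean", "ep_noncef_range", "ep_cef_mean",
                 "ep_cef_range", "neglog_p_mean", "neglog_p_range", "n_undefined"]
        _write("ztest_report.csv",
               lambda p: pd.DataFrame(zrows, columns=zcols).to_csv(p, index=False))
        _write("lopo_report.csv",
               lambda p: pd.DataFrame(lrows, columns=lcols).to_csv(p, index=False))

        stage = "network"
        G = evaluation.build_herb_network(table, threshold=cfg.network_threshold)
        ranking = evaluation.rank_herbs(G, table.vocab)
        _write("herb_ranking.csv", lambda p: ranking.to_csv(p, index=False))
        edges = pd.DataFrame(
            [
                {"herb_a": table.vocab.herbs[u], "herb_b": table.vocab.herbs[v],
                 "count": d["weight"]}
                for u, v, d in G.edges(data=True)
            ],
            columns=["herb_a", "herb_b", "count"],
        )
        _write("network_edges.csv", lambda p: edges.to_csv(p, index=False))
        if cfg.write_graphml:
            import networkx as nx

            H = nx.relabel_nodes(G, {j: table.vocab.herbs[j] for j in G.nodes})
            _write("network.graphml", lambda p: nx.write_graphml(H, p))
        timings[stage] = time.perf_counter() - t0

        stage = "synergy"
        t0 = time.perf_counter()
        core_herbs = sorted(
            {int(j) for r in results for j in r.candidate.herb_indices()}
        )
        rng = np.random.default_rng(cfg.seed + 1)
        if len(core_herbs) >= 2:
            syn = synergy.screen_pairs(table, core_herbs, n_perm=cfg.synergy_n_perm,
                                       rng=rng, vocab=table.vocab)
        else:
            syn = pd.DataFrame(
                columns=["herb_a", "herb_b", "e11", "e01", "e10", "si",
                         "p_perm", "n11", "n01", "n10", "significant"]
            )
        _write("synergy_report.csv", lambda p: syn.to_csv(p, index=False))
        timings[stage] = time.perf_counter() - t0

        manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
        manifest["artifacts"] = [p.name for p in written]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
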