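"""End-to-end orchestration: simulate -> normalize -> DE -> contingency ->
network -> enrichment, with a reproducibility manifest.

A run is driven by a :class:`RunConfig` that either points at on-disk inputs
(expression TSVs + sample sheets, target-map edge lists, a GMT) or embeds a
:class:`~cerna_scope.synthetic.SimulationConfig`; in the synthetic mode two
time points are simulated with seeds fanned out from the master seed and the
target maps shared between them.  Every output file is recorded in the
manifest with a SHA-256 hash so that a re-run with the same config can be
checked for byte-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (
    DIRECTION_RULES,
    adjusted_logistic,
    build_contingency,
    odds_ratio_test,
    relevant_direction,
    results_table,
    targeted_set,
)
from .diffexpr import call_de, dysregulated_ids, quantile_normalize, time_specificity
from .enrichment import AnnotationCollection, enrich, read_gmt, top_terms, write_gmt
from .matrix import ExpressionMatrix
from .network import build_network, export_network, summarize_network
from .synthetic import SimulationConfig, generate_annotations, generate_expression, generate_target_maps
from .targets import downstream_mrna_set, read_edge_list

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one of ``simulation`` or the real-input path block
    (``matrices``/``maps_path``) must be supplied.  ``matrices`` maps a time
    label to a dict with per-layer ``{"circ": (matrix, samples), ...}`` TSV
    path pairs.
    """

    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    matrices: dict | None = None
    circ2mir_path: str | None = None
    mir2mrna_path: str | None = None
    annotations_path: str | None = None
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    direction_rules: dict = dataclasses.field(default_factory=lambda: dict(DIRECTION_RULES))
    time_labels: tuple[str, ...] = ("7M", "12M")
    normalize: bool = True

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_real = self.matrices is not None
        if has_sim == has_real:
            raise ValueError("supply exactly one of simulation config or input paths")
        if has_real and (self.circ2mir_path is None or self.mir2mrna_path is None):
            raise ValueError("real-input mode needs both target-map paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig.from_dict(sim)
        if "time_labels" in raw:
            raw["time_labels"] = tuple(raw["time_labels"])
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sub_seed(master: int, index: int) -> int:
    """Per-time-point seed derived from the master seed (stays below 2^31)."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "direction_rules": config.direction_rules,
            "normalize": config.normalize,
            "mode": "synthetic" if config.simulation else "real",
        },
        "stages": {},
        "files": {},
    }
    if config.simulation is not None:
        manifest["parameters"]["simulation"] = dataclasses.asdict(config.simulation)

    files: dict[str, Path] = {}

    # ---------------------------------------------------------- stage: inputs
    try:
        matrices, maps, annotations, truths = _load_inputs(config, outdir, files)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    circ2mir, mir2mrna = maps
    manifest["stages"]["inputs"] = {
        "time_points": list(matrices),
        "n_circ2mir_edges": len(circ2mir),
        "n_mir2mrna_edges": len(mir2mrna),
        "n_features": {
            t: {layer: int(m.values.shape[0]) for layer, m in layers.items()}
            for t, layers in matrices.items()
        },
    }

    # ------------------------------------------------- stage: normalization+DE
    de_tables: dict[str, dict[str, pd.DataFrame]] = {}
    de_counts: dict = {}
    for t, layers in matrices.items():
        de_tables[t] = {}
        de_counts[t] = {}
        for layer, mat in layers.items():
            try:
                if config.normalize:
                    mat = quantile_normalize(mat)
                de = call_de(mat, config.fc_threshold, config.p_threshold)
            except Exception as exc:
                raise RuntimeError(f"stage 'de' failed on {layer}@{t}: {exc}") from exc
            de_tables[t][layer] = de
            path = outdir / f"de_{layer}_{t}.tsv"
            de.to_csv(path, sep="\t", index=False)
            files[f"de_{layer}_{t}"] = path
            de_counts[t][layer] = {
                "up": int((de["direction"] == "up").sum()),
                "down": int((de["direction"] == "down").sum()),
            }
    manifest["stages"]["differential_expression"] = de_counts

    # ------------------------------------------------ stage: time specificity
    if len(matrices) == 2:
        t1, t2 = list(matrices)
        spec = {}
        for layer in ("circ", "mirna", "mrna"):
            s = time_specificity(de_tables[t1][layer], de_tables[t2][layer])
            spec[layer] = dataclasses.asdict(s)
        manifest["stages"]["time_specificity"] = spec

    # ---------------------------------------------------- stage: contingency
    stat_rows = []
    for t in matrices:
        circ_de = de_tables[t]["circ"]
        mir_de = de_tables[t]["mirna"]
        mrna_de = de_tables[t]["mrna"]
        for direction in ("up", "down"):
            # miRNA -> mRNA (inverse rule)
            mir_dys = dysregulated_ids(mir_de, direction)
            rel = relevant_direction(direction, "miRNA->mRNA", config.direction_rules)
            tab = build_contingency(targeted_set(mir_dys, mir2mrna), mrna_de, rel)
            stat_rows.append(
                {"analysis": "miRNA->mRNA", "time": t, "direction": direction,
                 "table": tab, "odds": odds_ratio_test(tab)}
            )
            # circRNA -> miRNA (inverse rule)
            circ_dys = dysregulated_ids(circ_de, direction)
            rel = relevant_direction(direction, "circRNA->miRNA", config.direction_rules)
            tab = build_contingency(targeted_set(circ_dys, circ2mir), mir_de, rel)
            stat_rows.append(
                {"analysis": "circRNA->miRNA", "time": t, "direction": direction,
                 "table": tab, "odds": odds_ratio_test(tab)}
            )
            # circRNA -> mRNA via bridging miRNA (same-direction rule),
            # with the miRNA-adjusted logistic OR
            rel = relevant_direction(direction, "circRNA->mRNA", config.direction_rules)
            circ_targets = downstream_mrna_set(circ_dys, circ2mir, mir2mrna)
            tab = build_contingency(circ_targets, mrna_de, rel)
            adjusting_mirnas = dysregulated_ids(mir_de, _inverse(rel))
            mir_targets = targeted_set(adjusting_mirnas, mir2mrna)
            adj = adjusted_logistic(mrna_de, rel, circ_targets, mir_targets)
            stat_rows.append(
                {"analysis": "circRNA->mRNA", "time": t, "direction": direction,
                 "table": tab, "odds": odds_ratio_test(tab), "adjusted": adj}
            )
    stats_df = results_table(stat_rows)
    path = outdir / "concordance_stats.tsv"
    stats_df.to_csv(path, sep="\t", index=False)
    files["concordance_stats"] = path
    manifest["stages"]["concordance"] = {
        "n_analyses": len(stats_df),
        "n_significant": int((stats_df["p_value"] < 0.05).sum()),
    }

    # -------------------------------------------------------- stage: network
    networks = {}
    net_counts = {}
    for t in matrices:
        for direction in ("up", "down"):
            triples = build_network(
                de_tables[t]["circ"], de_tables[t]["mrna"], circ2mir, mir2mrna, direction
            )
            networks[(t, direction)] = triples
            summary = summarize_network(triples)
            net_counts[f"{t}_{direction}"] = {
                "n_triples": summary.n_triples,
                "n_circ": summary.n_circ,
                "n_mirna": summary.n_mirna,
                "n_mrna": summary.n_mrna,
            }
            for p in export_network(
                triples, outdir / "networks", f"network_{t}_{direction}",
                de_tables[t]["circ"], de_tables[t]["mrna"],
            ):
                files[p.name] = p
    manifest["stages"]["networks"] = net_counts

    # ----------------------------------------------------- stage: enrichment
    enrich_counts = {}
    for (t, direction), triples in networks.items():
        query = {tr.mrna_id for tr in triples}
        background = set(de_tables[t]["mrna"]["feature_id"])
        if not query:
            enrich_counts[f"{t}_{direction}"] = {"n_terms": 0, "n_significant": 0}
            continue
        res = enrich(query, annotations, background)
        top = top_terms(res)
        path = outdir / f"enrichment_{t}_{direction}.tsv"
        res.to_csv(path, sep="\t", index=False)
        files[f"enrichment_{t}_{direction}"] = path
        path = outdir / f"enrichment_top_{t}_{direction}.tsv"
        top.to_csv(path, sep="\t", index=False)
        files[f"enrichment_top_{t}_{direction}"] = path
        enrich_counts[f"{t}_{direction}"] = {
            "n_terms": int(len(res)),
            "n_significant": int(((res["p_value"] < 0.05) & (res["fdr"] < 0.05)).sum()),
        }
    manifest["stages"]["enrichment"] = enrich_counts

    manifest["files"] = {name: {"path": str(p), "sha256": _sha256(p)}
                         for name, p in sorted(files.items())}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d files, manifest at %s", len(files), manifest_path)
    return manifest


def _inverse(direction: str) -> str:
    return {"up": "down", "down": "up"}[direction]


def _load_inputs(config: RunConfig, outdir: Path, files: dict[str, Path]):
    """Simulate or read matrices, maps and annotations; record written files."""
    matrices: dict[str, dict[str, ExpressionMatrix]] = {}
    truths = {}
    if config.simulation is not None:
        base = dataclasses.replace(config.simulation, seed=_sub_seed(config.seed, 0))
        maps = generate_target_maps(base)
        affected_pool: set[str] = set()
        for i, t in enumerate(config.time_labels):
            sim = dataclasses.replace(config.simulation, seed=_sub_seed(config.seed, i))
            circ, mir, mrna, truth = generate_expression(sim, maps, time_label=t)
            matrices[t] = {"circ": circ, "mirna": mir, "mrna": mrna}
            truths[t] = truth
            truth_path = outdir / f"truth_{t}.json"
            truth.to_json(truth_path)
            files[f"truth_{t}"] = truth_path
            affected_pool |= set(truth.affected_mrna_up) | set(truth.affected_mrna_down)
        if config.annotations_path:
            annotations = read_gmt(config.annotations_path)
        else:
            mrna_ids = base.feature_ids("mrna")
            planted = affected_pool or set(mrna_ids[:20])
            annotations = generate_annotations(mrna_ids, planted, seed=_sub_seed(config.seed, 99))
            gmt_path = outdir / "annotations.gmt"
            write_gmt(annotations, gmt_path)
            files["annotations"] = gmt_path
    else:
        for t, layers in config.matrices.items():
            matrices[t] = {}
            for layer_key, (m_path, s_path) in layers.items():
                layer_name = {"circ": "circRNA", "mirna": "miRNA", "mrna": "mRNA"}[layer_key]
                matrices[t][layer_key] = ExpressionMatrix.from_tsv(
                    m_path, s_path, layer=layer_name, time_label=t
                )
        maps = (
            read_edge_list(config.circ2mir_path, "circRNA", "miRNA"),
            read_edge_list(config.mir2mrna_path, "miRNA", "mRNA"),
        )
        if not config.annotations_path:
            raise ValueError("real-input mode needs annotations_path")
        annotations = read_gmt(config.annotations_path)
    return matrices, maps, annotations, truths
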