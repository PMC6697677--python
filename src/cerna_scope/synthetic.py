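"""Tri-layer expression simulator with planted circRNA sponge effects.

The generator emulates a two-group (n=4 vs n=4 by default) microarray study
of three RNA layers.  Control intensities are log2-normal around per-feature
baselines.  A chosen fraction of circRNAs is planted as up- or down-regulated
(case means multiplied or divided by ``circ_effect_fc``).  miRNA abundance is
never shifted — sequestration by a sponge changes miRNA *activity*, not its
level — while each mRNA downstream of a planted circRNA (through the
composed circRNA->miRNA->mRNA maps) receives a concordant, same-direction
fold change with probability ``penetrance``.  Non-downstream mRNAs are
independently dysregulated at ``background_de_rate`` with random direction.
A machine-readable truth record makes parameter-recovery testing possible
without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import NAMESPACES, AnnotationCollection, AnnotationTerm
from .matrix import ExpressionMatrix
from .targets import TargetMap

_ID_WIDTH = {"circ": 5, "mir": 4, "mrna": 5}


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-sponge simulation.

    Layer sizes default to a scaled-down array (1,000 circRNAs / 100 miRNAs /
    5,000 mRNAs); group sizes to 4 vs 4.  ``circ_effect_fc``/``mrna_effect_fc``
    are linear fold changes >= 1 applied to planted circRNAs and their
    affected downstream mRNAs; ``mre_cap`` caps the number of miRNA targets
    per circRNA at 5 by default.
    """

    n_circ: int = 1000
    n_mirna: int = 100
    n_mrna: int = 5000
    n_case: int = 4
    n_control: int = 4
    baseline_log2_mean_range: tuple[float, float] = (6.0, 12.0)
    noise_sd: float = 0.25
    frac_circ_up: float = 0.02
    frac_circ_down: float = 0.02
    circ_effect_fc: float = 4.0
    penetrance: float = 0.5
    mrna_effect_fc: float = 2.0
    background_de_rate: float = 0.01
    mre_cap: int = 5
    mirna_outdegree_range: tuple[int, int] = (10, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_circ", "n_mirna", "n_mrna", "n_case", "n_control", "mre_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_circ_up", "frac_circ_down", "penetrance", "background_de_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_circ_up + self.frac_circ_down > 1.0:
            raise ValueError("frac_circ_up + frac_circ_down must be <= 1")
        for name in ("circ_effect_fc", "mrna_effect_fc"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValueError("baseline_log2_mean_range must be (low, high)")
        lo, hi = self.mirna_outdegree_range
        if lo < 1 or hi < lo:
            raise ValueError("mirna_outdegree_range must be (low, high) with low >= 1")

    def feature_ids(self, layer: str) -> list[str]:
        n = {"circ": self.n_circ, "mir": self.n_mirna, "mrna": self.n_mrna}[layer]
        return [f"{layer}_{i:0{_ID_WIDTH[layer]}d}" for i in range(1, n + 1)]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("baseline_log2_mean_range", "mirna_outdegree_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Record of every planted or propagated effect, for recovery testing."""

    planted_circ_up: frozenset[str]
    planted_circ_down: frozenset[str]
    affected_mrna_up: frozenset[str]
    affected_mrna_down: frozenset[str]
    background_de_mrna: dict[str, str]  # mrna id -> "up" | "down"
    seed: int

    def __post_init__(self) -> None:
        if self.planted_circ_up & self.planted_circ_down:
            raise ValueError("planted circ sets overlap")
        if self.affected_mrna_up & self.affected_mrna_down:
            raise ValueError("affected mRNA sets overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_circ_up": sorted(self.planted_circ_up),
            "planted_circ_down": sorted(self.planted_circ_down),
            "affected_mrna_up": sorted(self.affected_mrna_up),
            "affected_mrna_down": sorted(self.affected_mrna_down),
            "background_de_mrna": dict(sorted(self.background_de_mrna.items())),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            frozenset(d["planted_circ_up"]),
            frozenset(d["planted_circ_down"]),
            frozenset(d["affected_mrna_up"]),
            frozenset(d["affected_mrna_down"]),
            dict(d["background_de_mrna"]),
            int(d["seed"]),
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named RNG streams split from the master seed, one per concern.

    Separate streams keep, e.g., circRNA draws invariant to changes of
    n_mrna.
    """
    names = ["map_c2m", "map_m2g", "expr_circ", "expr_mir", "expr_mrna", "effects"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# --------------------------------------------------------------------------
# target maps


def generate_target_maps(config: SimulationConfig) -> tuple[TargetMap, TargetMap]:
    """Random target maps consistent with the simulation config.

    Each circRNA gets 1..mre_cap distinct miRNA partners; each miRNA gets a
    number of distinct mRNA targets drawn uniformly from
    ``mirna_outdegree_range``.  Deterministic given the config seed.
    """
    if config.mre_cap > config.n_mirna:
        raise ValueError(
            f"mre_cap={config.mre_cap} exceeds n_mirna={config.n_mirna}"
        )
    lo, hi = config.mirna_outdegree_range
    if hi > config.n_mrna:
        raise ValueError(
            f"mirna_outdegree_range upper bound {hi} exceeds n_mrna={config.n_mrna}"
        )
    rngs = _streams(config.seed)
    circ_ids = config.feature_ids("circ")
    mir_ids = np.array(config.feature_ids("mir"))
    mrna_ids = np.array(config.feature_ids("mrna"))

    rng = rngs["map_c2m"]
    c2m_edges = set()
    for c in circ_ids:
        k = int(rng.integers(1, config.mre_cap + 1))
        for m in rng.choice(mir_ids, size=k, replace=False):
            c2m_edges.add((c, str(m)))

    rng = rngs["map_m2g"]
    m2g_edges = set()
    for m in mir_ids:
        k = int(rng.integers(lo, hi + 1))
        for g in rng.choice(mrna_ids, size=k, replace=False):
            m2g_edges.add((str(m), str(g)))

    return (
        TargetMap("circRNA", "miRNA", frozenset(c2m_edges)),
        TargetMap("miRNA", "mRNA", frozenset(m2g_edges)),
    )


# --------------------------------------------------------------------------
# expression


def _layer_matrix(
    rng: np.random.Generator,
    config: SimulationConfig,
    layer: str,
    feature_ids: list[str],
    log2_shift_case: np.ndarray,
    time_label: str,
) -> ExpressionMatrix:
    lo, hi = config.baseline_log2_mean_range
    n = len(feature_ids)
    baselines = rng.uniform(lo, hi, size=n)
    n_samples = config.n_case + config.n_control
    noise = rng.normal(0.0, config.noise_sd, size=(n, n_samples))
    log2_vals = baselines[:, None] + noise
    log2_vals[:, : config.n_case] += log2_shift_case[:, None]
    sample_ids = [f"case_{i+1}" for i in range(config.n_case)] + [
        f"ctrl_{i+1}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=sample_ids
    )
    values = pd.DataFrame(2.0 ** log2_vals, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(layer, time_label, values, groups)


def generate_expression(
    config: SimulationConfig,
    maps: tuple[TargetMap, TargetMap],
    time_label: str = "7M",
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate the three layers plus the truth record.

    Returns (circRNA matrix, miRNA matrix, mRNA matrix, truth).  Planted
    circRNAs shift case means by +/- log2(circ_effect_fc); miRNA case and
    control means differ only by noise; downstream mRNAs of planted circRNAs
    receive a same-direction log2(mrna_effect_fc) shift with probability
    ``penetrance`` (mRNAs reachable from both an up- and a down-planted
    circRNA are left untouched to keep the truth record unambiguous);
    non-downstream mRNAs are background-dysregulated at
    ``background_de_rate``.
    """
    circ2mir, mir2mrna = maps
    rngs = _streams(config.seed)
    eff = rngs["effects"]

    circ_ids = config.feature_ids("circ")
    mrna_ids = config.feature_ids("mrna")

    n_up = round(config.frac_circ_up * config.n_circ)
    n_down = round(config.frac_circ_down * config.n_circ)
    planted = eff.choice(np.array(circ_ids), size=n_up + n_down, replace=False)
    circ_up = frozenset(str(c) for c in planted[:n_up])
    circ_down = frozenset(str(c) for c in planted[n_up:])

    c2m = circ2mir.adjacency()
    m2g = mir2mrna.adjacency()

    def closure(circ_set):
        out: set[str] = set()
        for c in circ_set:
            for m in c2m.get(c, ()):
                out |= m2g.get(m, set())
        return out

    down_up = closure(circ_up)
    down_down = closure(circ_down)
    ambiguous = down_up & down_down
    affected_up = {
        g for g in sorted(down_up - ambiguous) if eff.random() < config.penetrance
    }
    affected_down = {
        g for g in sorted(down_down - ambiguous) if eff.random() < config.penetrance
    }
    downstream_any = down_up | down_down
    background: dict[str, str] = {}
    for g in mrna_ids:
        if g in downstream_any:
            continue
        if eff.random() < config.background_de_rate:
            background[g] = "up" if eff.random() < 0.5 else "down"

    circ_shift = np.zeros(config.n_circ)
    log2_circ_fc = np.log2(config.circ_effect_fc)
    for i, c in enumerate(circ_ids):
        if c in circ_up:
            circ_shift[i] = log2_circ_fc
        elif c in circ_down:
            circ_shift[i] = -log2_circ_fc

    mrna_shift = np.zeros(config.n_mrna)
    log2_mrna_fc = np.log2(config.mrna_effect_fc)
    for i, g in enumerate(mrna_ids):
        if g in affected_up:
            mrna_shift[i] = log2_mrna_fc
        elif g in affected_down:
            mrna_shift[i] = -log2_mrna_fc
        elif g in background:
            mrna_shift[i] = log2_mrna_fc if background[g] == "up" else -log2_mrna_fc

    circ_mat = _layer_matrix(rngs["expr_circ"], config, "circRNA", circ_ids, circ_shift, time_label)
    mir_mat = _layer_matrix(
        rngs["expr_mir"], config, "miRNA", config.feature_ids("mir"),
        np.zeros(config.n_mirna), time_label,
    )
    mrna_mat = _layer_matrix(rngs["expr_mrna"], config, "mRNA", mrna_ids, mrna_shift, time_label)

    truth = SyntheticTruth(
        planted_circ_up=circ_up,
        planted_circ_down=circ_down,
        affected_mrna_up=frozenset(affected_up),
        affected_mrna_down=frozenset(affected_down),
        background_de_mrna=background,
        seed=config.seed,
    )
    return circ_mat, mir_mat, mrna_mat, truth


# --------------------------------------------------------------------------
# annotation collections with a planted term


def generate_annotations(
    mrna_ids,
    planted_members,
    seed: int,
    n_terms: int = 30,
    term_size_range: tuple[int, int] = (20, 80),
) -> AnnotationCollection:
    """Random flat annotation terms plus one term enriched for a planted set.

    ``term_0000`` (namespace BP) contains every id of ``planted_members``
    padded with random background ids to ~1.5x that size; the remaining
    terms are uniform random draws with namespaces cycling over BP, MF, CC
    and pathway.  Useful for enrichment-recovery experiments.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pool = np.array(sorted(mrna_ids))
    planted = sorted(set(planted_members))
    if not planted:
        raise ValueError("planted_members must be nonempty")
    pad = max(len(planted) // 2, 1)
    others = np.array(sorted(set(pool) - set(planted)))
    fill = rng.choice(others, size=min(pad, len(others)), replace=False)
    terms = [
        AnnotationTerm("term_0000", "term_0000", "BP", frozenset(planted) | frozenset(map(str, fill)))
    ]
    lo, hi = term_size_range
    for i in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(map(str, rng.choice(pool, size=min(size, len(pool)), replace=False)))
        terms.append(
            AnnotationTerm(f"term_{i:04d}", f"term_{i:04d}", NAMESPACES[i % len(NAMESPACES)], members)
        )
    return AnnotationCollection(tuple(terms))


# --------------------------------------------------------------------------
# dataset writer


def write_dataset(config: SimulationConfig, outdir: str | Path,
                  time_label: str = "7M") -> dict[str, Path]:
    """Generate and write a full synthetic dataset; return the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maps = generate_target_maps(config)
    circ, mir, mrna, truth = generate_expression(config, maps, time_label)
    files: dict[str, Path] = {}
    for mat, tag in ((circ, "circ"), (mir, "mirna"), (mrna, "mrna")):
        m_path = outdir / f"{tag}_expression_{time_label}.tsv"
        s_path = outdir / f"{tag}_samples_{time_label}.tsv"
        mat.to_tsv(m_path, s_path)
        files[f"{tag}_matrix"] = m_path
        files[f"{tag}_samples"] = s_path
    files["circ2mir_map"] = outdir / "circ2mir_edges.tsv"
    files["mir2mrna_map"] = outdir / "mir2mrna_edges.tsv"
    maps[0].to_tsv(files["circ2mir_map"])
    maps[1].to_tsv(files["mir2mrna_map"])
    files["truth"] = outdir / f"truth_{time_label}.json"
    truth.to_json(files["truth"])
    return files
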