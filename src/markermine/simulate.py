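"""Synthetic knowledge bases and qPCR data with a planted disease module.

The generator emulates the structure that guilt-by-association expansion
assumes: a planted module of disease genes is wired to two disjoint seed
sets through shared upstream transcription factors (every module gene is
a target of at least one TF that also targets a seed) and through shared
pathway membership (every module gene co-occurs with a seed in a
kept-size pathway).  Single-track decoys land in exactly one track and
must be removed by the intersection; optional shared decoys land in both
tracks and quantify the method's false-positive contract.  Oversized and
disease-unrelated pathways are emitted to exercise the relevance filter,
and co-expression edges connect a known fraction of the module to the
seeds.  Ct data follow the Livak measurement model: the cancer tissue
template of a gene with true fold f is shifted by -log2(f) cycles, with
independent Gaussian replicate noise, and reference genes are constant
across tissues up to that noise.

All randomness flows from a single master seed through named substreams,
so regenerating one artifact never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from markermine.expansion import SeedSet
from markermine.io import (
    validate_ct_frame,
    write_coexpression,
    write_ct_csv,
    write_gmt,
    write_tf_interactions,
)
from markermine.model import (
    CoexpressionEdge,
    PathwayDB,
    PathwayRecord,
    RegulatoryNetwork,
    TFInteraction,
)

_SUBSTREAMS = ("network", "pathways", "coexpr", "ct", "folds")

REFERENCE_GENES = ("GAPDH", "RNA18S", "RNA28S")

UNRELATED_PATHWAY_NAME = "Olfactory transduction"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline targets: two disjoint
    seed sets of 10 validated markers, triplicate qPCR with three
    reference genes, and a planted module about one third of which is
    co-expressed with the seeds.
    """

    n_tfs: int = 40
    n_genes: int = 400
    n_pathways: int = 24
    module_size: int = 25
    planted_module: frozenset[str] | None = None
    n_seeds: int = 10
    decoy_rate: float = 0.2
    n_shared_decoys: int = 0
    pathway_size_range: tuple[int, int] = (10, 60)
    coexpr_fraction: float = 0.32
    true_fold_changes: Mapping[str, float] | None = None
    ct_noise_sd: float = 0.1
    n_replicates: int = 3
    n_patients: int = 3
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    ct_baseline_range: tuple[float, float] = (18.0, 30.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size < 1 or self.n_seeds < 1:
            raise ValueError("module_size and n_seeds must be positive")
        if not (0.0 <= self.decoy_rate <= 1.0):
            raise ValueError("decoy_rate must be in [0, 1]")
        if not (0.0 <= self.coexpr_fraction <= 1.0):
            raise ValueError("coexpr_fraction must be in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    def substream(self, name: str) -> np.random.Generator:
        """Independent RNG for one named artifact."""
        idx = _SUBSTREAMS.index(name)
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=(idx,))
        return np.random.default_rng(ss)


class SimulatedKnowledge(NamedTuple):
    network: RegulatoryNetwork
    pathways: PathwayDB
    coexpression: list[CoexpressionEdge]
    seeds_training: SeedSet
    seeds_validation: SeedSet
    truth: dict


def _names(prefix: str, n: int, width: int = 4) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _mode(rng: np.random.Generator) -> str:
    return str(rng.choice(["activation", "repression", "unknown"]))


def simulate_knowledge_bases(cfg: SimulationConfig) -> SimulatedKnowledge:
    """Build the regulatory network, pathway DB, co-expression edges and
    seed sets around a planted module, plus a ground-truth record."""
    module = sorted(
        cfg.planted_module
        if cfg.planted_module is not None
        else _names("MKR", cfg.module_size)
    )
    m = len(module)
    seeds = {
        "training": _names("SEEDA", cfg.n_seeds, 2),
        "validation": _names("SEEDB", cfg.n_seeds, 2),
    }
    n_decoys = int(round(cfg.decoy_rate * m))
    decoys_tf = {
        "training": _names("DTFA", n_decoys, 3),
        "validation": _names("DTFB", n_decoys, 3),
    }
    decoys_pw = {
        "training": _names("DPWA", n_decoys, 3),
        "validation": _names("DPWB", n_decoys, 3),
    }
    shared_decoys = _names("DBOTH", cfg.n_shared_decoys, 3)

    n_special = m + 2 * cfg.n_seeds + 4 * n_decoys + cfg.n_shared_decoys
    n_background = cfg.n_genes - n_special
    if n_background < 10:
        raise ValueError(
            f"infeasible config: universe of {cfg.n_genes} genes cannot hold "
            f"{n_special} module/seed/decoy genes plus background"
        )
    background = _names("BG", n_background)

    n_bridge = max(2, cfg.n_tfs // 4)
    if cfg.n_tfs < 2 * n_bridge + 1:
        raise ValueError("infeasible config: too few TFs for two bridge groups")
    bridges = {
        "training": _names("TFA", n_bridge, 3),
        "validation": _names("TFB", n_bridge, 3),
    }
    background_tfs = _names("TFBG", cfg.n_tfs - 2 * n_bridge, 3)

    rng = cfg.substream("network")
    interactions: list[TFInteraction] = []
    for label in ("training", "validation"):
        br, sd = bridges[label], seeds[label]
        # every bridge TF regulates >=1 seed; every seed has >=1 regulator
        for i, tf in enumerate(br):
            interactions.append(TFInteraction(tf, sd[i % len(sd)], _mode(rng)))
        for j, seed in enumerate(sd):
            interactions.append(TFInteraction(br[j % len(br)], seed, _mode(rng)))
        # every module gene is a target of >=1 bridge TF of this seed set
        for gene in module:
            for tf in rng.choice(br, size=1 + rng.integers(0, 2), replace=False):
                interactions.append(TFInteraction(str(tf), gene, _mode(rng)))
        for decoy in decoys_tf[label]:
            interactions.append(
                TFInteraction(str(rng.choice(br)), decoy, _mode(rng))
            )
        for decoy in shared_decoys:
            interactions.append(
                TFInteraction(str(rng.choice(br)), decoy, _mode(rng))
            )
    for tf in background_tfs:
        k = int(rng.integers(3, 9))
        for gene in rng.choice(background, size=k, replace=False):
            interactions.append(TFInteraction(tf, str(gene), _mode(rng)))
    network = RegulatoryNetwork(interactions)

    rng = cfg.substream("pathways")
    records: list[PathwayRecord] = []
    kept_ids: dict[str, list[str]] = {"training": [], "validation": []}
    olf_ids: dict[str, str] = {}
    big_ids: dict[str, str] = {}
    n_module_pw = max(2, min(4, cfg.n_pathways // 6))
    for label, tag in (("training", "A"), ("validation", "B")):
        sd = seeds[label]
        chunks = np.array_split(np.array(module), n_module_pw)
        pw_decoy_chunks = np.array_split(np.array(decoys_pw[label]), n_module_pw)
        for i, (chunk, dchunk) in enumerate(zip(chunks, pw_decoy_chunks), 1):
            # distribute all seeds across the module pathways (round robin)
            # so every seed co-occurs with module genes in a kept pathway
            members = (
                set(map(str, chunk))
                | set(map(str, dchunk))
                | set(sd[i - 1 :: n_module_pw])
                | set(shared_decoys)
            )
            pid = f"PW{tag}{i:02d}"
            records.append(
                PathwayRecord(pid, f"disease module pathway {tag}{i}", frozenset(members))
            )
            kept_ids[label].append(pid)
        # oversized pathway: must be dropped by the size filter
        big = set(map(str, rng.choice(background, size=85, replace=False)))
        big.add(str(sd[0]))
        big_ids[label] = f"PW{tag}BIG"
        records.append(
            PathwayRecord(big_ids[label], f"top-level catch-all {tag}", frozenset(big))
        )
        # disease-unrelated pathway: dropped only by name-pattern curation
        olf = set(
            map(str, rng.choice(background, size=int(rng.integers(*cfg.pathway_size_range)), replace=False))
        )
        olf.add(str(sd[-1]))
        olf_ids[label] = f"PW{tag}OLF"
        records.append(
            PathwayRecord(olf_ids[label], UNRELATED_PATHWAY_NAME, frozenset(olf))
        )
    n_left = cfg.n_pathways - len(records)
    for i in range(1, n_left + 1):
        size = int(rng.integers(*cfg.pathway_size_range))
        members = frozenset(map(str, rng.choice(background, size=size, replace=False)))
        records.append(PathwayRecord(f"PWBG{i:02d}", f"background pathway {i}", members))
    pathways = PathwayDB(records)

    rng = cfg.substream("coexpr")
    k = int(round(cfg.coexpr_fraction * m))
    coexpressed = sorted(map(str, rng.choice(module, size=k, replace=False)))
    all_seeds = seeds["training"] + seeds["validation"]
    edges: list[CoexpressionEdge] = []
    for gene in coexpressed:
        n_nb = int(rng.integers(1, 4))
        for seed in rng.choice(all_seeds, size=n_nb, replace=False):
            edges.append(
                CoexpressionEdge(gene, str(seed), float(np.round(rng.uniform(0.2, 1.0), 3)))
            )
    for _ in range(n_background // 10):
        a, b = rng.choice(background, size=2, replace=False)
        edges.append(
            CoexpressionEdge(str(a), str(b), float(np.round(rng.uniform(0.2, 1.0), 3)))
        )

    truth = {
        "module": module,
        "seeds": {k2: sorted(v) for k2, v in seeds.items()},
        "decoys_tf_track": {k2: sorted(v) for k2, v in decoys_tf.items()},
        "decoys_pathway_track": {k2: sorted(v) for k2, v in decoys_pw.items()},
        "shared_decoys": sorted(shared_decoys),
        "bridge_tfs": {k2: sorted(v) for k2, v in bridges.items()},
        "expected": {},
        "recommended_exclusion_patterns": [UNRELATED_PATHWAY_NAME.split()[0].lower()],
        "coexpressed_module_genes": coexpressed,
        "n_coexpressed_retained": k,
    }
    for label in ("training", "validation"):
        tf_targets = sorted(
            set(seeds[label]) | set(module) | set(decoys_tf[label]) | set(shared_decoys)
        )
        predicted = sorted(set(module) | set(seeds[label]) | set(shared_decoys))
        truth["expected"][label] = {
            "n_tfs": len(bridges[label]),
            "tf_targets": tf_targets,
            "n_tf_targets": len(tf_targets),
            "pathways_found": sorted(
                kept_ids[label] + [big_ids[label], olf_ids[label]]
            ),
            "pathways_kept_default": sorted(kept_ids[label] + [olf_ids[label]]),
            "pathways_kept_curated": sorted(kept_ids[label]),
            "predicted_with_seeds": predicted,
            "predicted_novel": sorted(set(module) | set(shared_decoys)),
        }
    truth["expected"]["overlap_novel"] = sorted(set(module) | set(shared_decoys))

    return SimulatedKnowledge(
        network=network,
        pathways=pathways,
        coexpression=edges,
        seeds_training=SeedSet("training", frozenset(seeds["training"])),
        seeds_validation=SeedSet("validation", frozenset(seeds["validation"])),
        truth=truth,
    )


def draw_fold_changes(
    cfg: SimulationConfig, genes: list[str]
) -> dict[str, float]:
    """Draw plausible true fold changes (|log2 fold| in [0.5, 3.5])."""
    rng = cfg.substream("folds")
    folds = {}
    for gene in sorted(genes):
        log2f = float(rng.uniform(0.5, 3.5)) * (1 if rng.random() < 0.75 else -1)
        folds[gene] = float(np.round(2.0 ** log2f, 4))
    return folds


def simulate_ct_data(
    cfg: SimulationConfig,
    fold_changes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate triplicate qPCR Ct measurements for a gene panel.

    Mucosa Ct of a target gene is its baseline plus Gaussian noise; the
    cancer Ct is shifted by -log2(true fold) so the Livak pipeline should
    recover the configured fold.  Reference genes share one baseline per
    patient across both tissues (stable normalizers).  The same true
    fold applies to every patient; replicates are i.i.d.
    """
    folds = dict(fold_changes or cfg.true_fold_changes or {})
    if not folds:
        raise ValueError("no true fold changes given (cfg.true_fold_changes empty)")
    bad = {g: f for g, f in folds.items() if not f > 0}
    if bad:
        raise ValueError(f"true fold changes must be positive: {bad}")
    rng = cfg.substream("ct")
    lo, hi = cfg.ct_baseline_range
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, cfg.ct_noise_sd)) if cfg.ct_noise_sd else 0.0

    for p in range(1, cfg.n_patients + 1):
        patient = f"P{p}"
        for ref in cfg.reference_genes:
            baseline = float(rng.uniform(14.0, 22.0))
            for tissue in ("cancer", "mucosa"):
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append((ref, patient, tissue, rep, baseline + noise()))
        for gene in sorted(folds):
            baseline = float(rng.uniform(lo, hi))
            shift = float(np.log2(folds[gene]))
            for tissue in ("cancer", "mucosa"):
                mean = baseline - shift if tissue == "cancer" else baseline
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append((gene, patient, tissue, rep, mean + noise()))
    df = pd.DataFrame(
        rows, columns=["gene", "patient", "tissue", "replicate", "ct"]
    )
    df["ct"] = df["ct"].round(6)
    return validate_ct_frame(df, source="simulate_ct_data")


def write_bundle(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic input bundle in the pipeline's formats.

    Produces trrust.tsv, pathways.gmt, coexpression.tsv, two seed lists,
    ct.csv and truth.json.  Byte-identical for identical configs.  When
    ``cfg.true_fold_changes`` is unset, fold changes are drawn for the
    co-expressed module genes (the panel the pipeline would prioritize).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_knowledge_bases(cfg)
    folds = dict(cfg.true_fold_changes or {})
    if not folds:
        folds = draw_fold_changes(cfg, sim.truth["coexpressed_module_genes"])
    ct = simulate_ct_data(cfg, folds)

    write_tf_interactions(sim.network, outdir / "trrust.tsv")
    write_gmt(sim.pathways, outdir / "pathways.gmt")
    write_coexpression(sim.coexpression, outdir / "coexpression.tsv")
    for label, seeds in (
        ("training", sim.seeds_training),
        ("validation", sim.seeds_validation),
    ):
        with open(outdir / f"seeds_{label}.txt", "w", encoding="utf-8") as fh:
            for gene in seeds:
                fh.write(gene + "\n")
    write_ct_csv(ct, outdir / "ct.csv")
    truth = dict(sim.truth)
    truth["true_fold_changes"] = folds
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a flat dict (e.g. parsed YAML)."""
    cfg = SimulationConfig()
    kwargs = {}
    for key, value in d.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown simulation parameter {key!r}")
        if key in ("pathway_size_range", "ct_baseline_range", "reference_genes"):
            value = tuple(value)
        if key == "planted_module" and value is not None:
            value = frozenset(value)
        kwargs[key] = value
    return replace(cfg, **kwargs)
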