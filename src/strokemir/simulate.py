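"""Seeded synthetic-data generators with known ground truth.

Every generator is deterministic given (config, seed) and emits exactly the
formats the analysis modules read, so the whole pipeline is testable without
any download.  The ``paper`` Ct calibration preset plants the published
group-mean differences and scales per-sample noise so group SEMs match the
published validation table by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SPECIMENS
from .qpcr import GROUPS, REFERENCE_TARGETS
from .datasets import load_validation_summaries

# Specimen frequencies of the curated catalog (14 serum / 7 plasma /
# 6 whole blood / 2 PBMC of 29 studies).
CATALOG_SPECIMEN_PROBS = {
    "serum": 14 / 29, "plasma": 7 / 29, "whole_blood": 6 / 29, "pbmc": 2 / 29,
}


@dataclass(frozen=True)
class CatalogSimConfig:
    n_studies: int = 29
    n_mirnas: int = 20
    specimen_probs: dict = field(default_factory=lambda: dict(CATALOG_SPECIMEN_PROBS))
    report_prob: float = 0.2
    agreement: float = 1.0
    size_range: tuple[int, int] = (10, 300)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.agreement <= 1.0 and 0.0 <= self.report_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_studies < 1 or self.n_mirnas < 1 or self.size_range[0] < 1:
            raise ValueError("counts and sizes must be >= 1")


def simulate_catalog(config: CatalogSimConfig) -> tuple[pd.DataFrame, dict]:
    """Synthetic study catalog in the catalog reader's column layout.

    Each miRNA gets a planted consensus direction; each study reports each
    miRNA with ``report_prob`` and agrees with the consensus with probability
    ``agreement`` (otherwise flips).  Truth records the planted directions.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = [f"hsa-miR-sim-{i:03d}" for i in range(config.n_mirnas)]
    consensus = {m: ("up" if rng.random() < 0.5 else "down") for m in mirnas}
    specimens = list(config.specimen_probs)
    probs = np.array([config.specimen_probs[s] for s in specimens], dtype=float)
    probs = probs / probs.sum()
    rows = []
    lo, hi = config.size_range
    for i in range(config.n_studies):
        sid = f"sim{i:03d}"
        specimen = specimens[rng.choice(len(specimens), p=probs)]
        n_case = int(rng.integers(lo, hi + 1))
        n_control = int(rng.integers(lo, hi + 1))
        reported = [m for m in mirnas if rng.random() < config.report_prob]
        if not reported:  # every study reports at least one miRNA
            reported = [mirnas[int(rng.integers(config.n_mirnas))]]
        for m in reported:
            agree = rng.random() < config.agreement
            direction = consensus[m] if agree else ("down" if consensus[m] == "up" else "up")
            rows.append({
                "study_id": sid, "pmid": 10_000_000 + i, "first_author": f"Sim, {i}",
                "year": 2000 + i % 23, "country": "Simulandia", "specimen": specimen,
                "n_case": n_case, "n_control": n_control, "technique": "simulated",
                "mirna_reported": m, "direction": direction,
            })
    truth = {"consensus_direction": consensus}
    return pd.DataFrame(rows), truth


def identity_aliases(catalog_df: pd.DataFrame) -> pd.DataFrame:
    names = sorted(catalog_df["mirna_reported"].unique())
    return pd.DataFrame({"reported_name": names, "canonical_name": names})


@dataclass(frozen=True)
class CtSimConfig:
    n_case: int = 20
    n_control: int = 20
    effects: dict = field(default_factory=dict)  # target -> planted ddCt (log2)
    bio_sd: dict = field(default_factory=dict)   # target -> sd or (sd_stroke, sd_healthy)
    ref_mean_ct: float = 20.0
    ref_between_sd: float = 0.5
    tech_sd: float = 0.1
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if min(self.ref_between_sd, self.tech_sd, 0.0) < 0:
            raise ValueError("standard deviations must be >= 0")


def paper_ct_config(seed: int = 0, tech_sd: float = 0.1, replicates: int = 3) -> CtSimConfig:
    """Calibrate the generator to the published 20 vs 20 plasma validation:
    planted ddCt = stroke mean - healthy mean, per-group biological sd chosen
    so the total per-sample sd equals SEM * sqrt(n)."""
    summaries = load_validation_summaries()
    by_target: dict[str, dict[str, tuple[float, float, int]]] = {}
    for s in summaries:
        by_target.setdefault(s.target_name, {})[s.group] = (s.mean, s.sem, s.n)
    effects, bio_sd = {}, {}
    for target, groups in by_target.items():
        (m1, s1, n1), (m0, s0, n0) = groups["stroke"], groups["healthy"]
        effects[target] = m1 - m0
        sds = []
        for sem, n in ((s1, n1), (s0, n0)):
            total_var = (sem ** 2) * n
            sds.append(math.sqrt(max(total_var - tech_sd ** 2 / replicates, 0.0)))
        bio_sd[target] = tuple(sds)
    return CtSimConfig(
        n_case=20, n_control=20, effects=effects, bio_sd=bio_sd,
        tech_sd=tech_sd, replicates=replicates, seed=seed,
    )


def simulate_ct(config: CtSimConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format per-well Ct table with spike-in reference wells.

    Per sample: a reference Ct level ~ N(ref_mean_ct, ref_between_sd); each
    spike-in well adds technical noise around that level.  Per target:
    Ct = ref level - (planted group effect + biological sample effect) +
    technical noise, so downstream spike-in normalization recovers the
    planted log2 effect.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    samples = [("stroke", f"IS{i + 1:02d}") for i in range(config.n_case)] + [
        ("healthy", f"HC{i + 1:02d}") for i in range(config.n_control)
    ]
    targets = sorted(config.effects)
    for group, sample in samples:
        ref_level = rng.normal(config.ref_mean_ct, config.ref_between_sd)
        for ref in REFERENCE_TARGETS:
            for rep in range(1, config.replicates + 1):
                rows.append({
                    "sample_id": sample, "group": group, "target": ref,
                    "replicate": rep,
                    "ct": ref_level + rng.normal(0.0, config.tech_sd),
                })
        for target in targets:
            effect = config.effects[target] if group == "stroke" else 0.0
            sd = config.bio_sd.get(target, 0.0)
            if isinstance(sd, (tuple, list)):
                sd = sd[0] if group == "stroke" else sd[1]
            bio = rng.normal(0.0, sd) if sd > 0 else 0.0
            level = ref_level - (effect + bio)
            for rep in range(1, config.replicates + 1):
                rows.append({
                    "sample_id": sample, "group": group, "target": target,
                    "replicate": rep,
                    "ct": level + rng.normal(0.0, config.tech_sd),
                })
    truth = {"planted_ddct": dict(config.effects)}
    return pd.DataFrame(rows), truth


@dataclass(frozen=True)
class TargetSimConfig:
    n_mirnas: int = 4
    targets_per_mirna: int = 50
    universe_size: int = 2000
    n_sets: int = 20
    set_size: int = 40
    bias: float = 10.0  # planted set's sampling weight toward the target union
    seed: int = 0

    def __post_init__(self):
        if self.bias < 1.0:
            raise ValueError("bias must be >= 1 (1 = no enrichment)")
        if self.set_size > self.universe_size:
            raise ValueError("set size exceeds universe")


def simulate_targets_and_sets(config: TargetSimConfig):
    """(target map, gene-set collection, truth) with one planted enriched set.

    Non-planted sets are uniform draws from the universe; the planted set
    samples genes with weight ``bias`` on the miRNA target union.
    """
    from .enrichment import GeneSet, GeneSetCollection

    rng = np.random.default_rng(config.seed)
    universe = np.array([f"GENE{i:05d}" for i in range(config.universe_size)])
    target_map = {}
    for i in range(config.n_mirnas):
        picks = rng.choice(universe, size=config.targets_per_mirna, replace=False)
        target_map[f"hsa-miR-sim-{i:03d}"] = frozenset(picks)
    union = set().union(*target_map.values())
    in_union = np.isin(universe, sorted(union))
    weights = np.where(in_union, config.bias, 1.0)
    weights = weights / weights.sum()
    sets = []
    planted = rng.choice(universe, size=config.set_size, replace=False, p=weights)
    sets.append(GeneSet("SET_PLANTED", "planted enriched set", frozenset(planted)))
    for j in range(config.n_sets - 1):
        draw = rng.choice(universe, size=config.set_size, replace=False)
        sets.append(GeneSet(f"SET_{j:03d}", "background set", frozenset(draw)))
    truth = {"planted_set": "SET_PLANTED", "bias": config.bias}
    return target_map, GeneSetCollection(tuple(sets)), truth


def simulate_tissue_matrix(
    n_tissues: int = 31,
    samples_per_tissue: int = 2,
    mirnas=("hsa-miR-sim-000", "hsa-miR-sim-001", "hsa-miR-sim-002"),
    specific_tissue: str = "brain",
    specific_shift: float = 3.0,
    seed: int = 0,
):
    """(samples x miRNA matrix, sample->tissue map, truth).

    The first miRNA is planted as specific to ``specific_tissue`` (mean
    shifted up by ``specific_shift``); everything else is exchangeable noise.
    """
    rng = np.random.default_rng(seed)
    tissues = [specific_tissue] + [f"tissue_{i:02d}" for i in range(n_tissues - 1)]
    sample_ids, tissue_of_sample, rows = [], {}, []
    for t in tissues:
        for j in range(samples_per_tissue):
            sid = f"{t}_s{j + 1}"
            sample_ids.append(sid)
            tissue_of_sample[sid] = t
            base = rng.normal(0.0, 1.0, size=len(mirnas))
            if t == specific_tissue:
                base[0] += specific_shift
            rows.append(base)
    matrix = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                          columns=list(mirnas))
    truth = {"specific_mirna": mirnas[0], "specific_tissue": specific_tissue}
    return matrix, tissue_of_sample, truth


def write_catalog(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_aliases(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_ct(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_target_map(target_map: dict, path) -> None:
    rows = [(m, g) for m in sorted(target_map) for g in sorted(target_map[m])]
    pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(path, sep="\t", index=False)


def write_tissue_matrix(matrix: pd.DataFrame, tissue_of_sample: dict, matrix_path,
                        map_path) -> None:
    matrix.to_csv(matrix_path, sep="\t")
    pd.DataFrame(sorted(tissue_of_sample.items()), columns=["sample_id", "tissue"]).to_csv(
        map_path, sep="\t", index=False)
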