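"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates pan-cancer proteome matrices: log-normal intensities,
block-correlated protein modules (complexes/pathways) with a tunable
within-module Spearman correlation, abundance-dependent missingness down to
the extreme sparsity regime where most samples lack a protein, term maps
aligned to the planted modules plus random decoys, synthetic-lethal pairs
enriched within modules, and two-condition replicate experiments with a
planted fold change on a protein set.

Correlation structure uses a Gaussian-copula latent-factor construction:
protein i in module m has latent value sqrt(w)·factor_m + sqrt(1−w)·noise,
so any two module members have latent Pearson correlation w. Because
Spearman depends only on the copula, w is calibrated from the target rank
correlation through the bivariate-normal relation
rho_S = (6/π)·arcsin(rho_P/2), i.e. w = 2·sin(π·rho_S/6). Intensities are
exp(location + scale·latent), a strictly monotone map that leaves Spearman
untouched (missingness aside).

All randomness flows through one explicitly seeded numpy Generator (PCG64);
identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    AbundanceMatrix,
    PairSet,
    ReplicateExperiment,
    TermMap,
    canonical_pair,
)


def spearman_to_pearson_weight(rho_s: float) -> float:
    """Latent Pearson correlation producing a target Spearman under a Gaussian copula."""
    if not 0.0 <= rho_s < 1.0:
        raise ValueError(f"target Spearman must be in [0, 1), got {rho_s}")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass
class MissingnessModel:
    """Either a uniform missing rate or an abundance-dependent detection limit.

    ``kind='uniform'``: each cell missing independently with probability
    ``rate``. ``kind='detection'``: the probability a cell is detected is a
    logistic function of its natural-log intensity,
    sigmoid(steepness·(ln v − floor)) — low-abundance cells drop out first,
    the way detection limits behave in mass-spec cohorts.
    """

    kind: str = "uniform"
    rate: float = 0.1
    floor: float = 6.0
    steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "detection", "none"):
            raise ValueError(f"unknown missingness kind {self.kind!r}")
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("uniform rate must be in [0, 1)")

    def missing_probability(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(values)
        if self.kind == "uniform":
            return np.full_like(values, self.rate)
        with np.errstate(divide="ignore"):
            logv = np.log(np.maximum(values, 1e-300))
        detect = 1.0 / (1.0 + np.exp(-self.steepness * (logv - self.floor)))
        return 1.0 - detect


@dataclass
class CohortSpec:
    """Parameters of a synthetic abundance cohort.

    Defaults describe the standard benchmark cohort: 10 modules of 8
    proteins at target within-module Spearman 0.7, 200 background proteins,
    300 samples, 10% uniform missingness, 50 random decoy terms and 100
    lethal pairs of which 80% fall within modules.
    """

    n_modules: int = 10
    module_sizes: Sequence[int] | int = 8
    module_rho: Sequence[float] | float = 0.7
    n_background: int = 200
    n_samples: int = 300
    log_loc_range: tuple[float, float] = (4.0, 10.0)
    log_scale_range: tuple[float, float] = (0.5, 1.5)
    missingness: MissingnessModel = field(default_factory=MissingnessModel)
    n_decoy_terms: int = 50
    decoy_term_size: int = 8
    n_lethal_pairs: int = 100
    within_module_pair_fraction: float = 0.8
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.module_sizes, int):
            return [self.module_sizes] * self.n_modules
        return list(self.module_sizes)

    def rhos(self) -> list[float]:
        if isinstance(self.module_rho, (int, float)):
            return [float(self.module_rho)] * self.n_modules
        return list(self.module_rho)

    def __post_init__(self) -> None:
        if self.n_modules < 0 or self.n_background < 0 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        sizes, rhos = self.sizes(), self.rhos()
        if len(sizes) != self.n_modules or len(rhos) != self.n_modules:
            raise ValueError("module_sizes/module_rho length must equal n_modules")
        if any(s < 2 for s in sizes):
            raise ValueError("module sizes must be ≥ 2")
        for r in rhos:
            spearman_to_pearson_weight(r)  # range check
        if not 0.0 <= self.within_module_pair_fraction <= 1.0:
            raise ValueError("within_module_pair_fraction must be in [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, checkable against the emitted files."""

    modules: dict[str, list[str]]  # module id -> ordered member proteins
    module_of: dict[str, str | None]  # protein -> module id (None = background)
    term_map: TermMap
    lethal_pairs: PairSet
    within_module_pair: dict[tuple[str, str], bool]
    missing_mask: np.ndarray


def generate_cohort(
    spec: CohortSpec,
) -> tuple[AbundanceMatrix, TermMap, PairSet, CohortTruth]:
    """Generate an abundance cohort plus aligned annotations and pair lists."""
    rng = np.random.default_rng(spec.seed)
    sizes, rhos = spec.sizes(), spec.rhos()
    n_module_proteins = sum(sizes)
    n_proteins = n_module_proteins + spec.n_background
    if n_proteins < 1:
        raise ValueError("cohort has no proteins")

    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    sample_ids = [f"S{j:04d}" for j in range(spec.n_samples)]

    modules: dict[str, list[str]] = {}
    module_of: dict[str, str | None] = {p: None for p in protein_ids}
    latent = np.empty((n_proteins, spec.n_samples))
    offset = 0
    for m, (size, rho_s) in enumerate(zip(sizes, rhos)):
        mod_id = f"MOD{m:03d}"
        members = protein_ids[offset : offset + size]
        modules[mod_id] = members
        for p in members:
            module_of[p] = mod_id
        w = spearman_to_pearson_weight(rho_s)
        factor = rng.standard_normal(spec.n_samples)
        noise = rng.standard_normal((size, spec.n_samples))
        latent[offset : offset + size] = np.sqrt(w) * factor + np.sqrt(1.0 - w) * noise
        offset += size
    if spec.n_background:
        latent[offset:] = rng.standard_normal((spec.n_background, spec.n_samples))

    loc = rng.uniform(*spec.log_loc_range, size=n_proteins)
    scale = rng.uniform(*spec.log_scale_range, size=n_proteins)
    values = np.exp(loc[:, None] + scale[:, None] * latent)

    p_missing = spec.missingness.missing_probability(values)
    mask = rng.random(values.shape) < p_missing
    values = values.copy()
    values[mask] = 0.0

    matrix = AbundanceMatrix(protein_ids, sample_ids, values, mask)

    # term map: one term per planted module plus random decoy terms
    terms: dict[str, set[str]] = {
        f"TERM_{mod_id}": set(members) for mod_id, members in modules.items()
    }
    for d in range(spec.n_decoy_terms):
        size = min(spec.decoy_term_size, n_proteins)
        picks = rng.choice(n_proteins, size=size, replace=False)
        terms[f"DECOY{d:03d}"] = {protein_ids[i] for i in picks}
    term_map = TermMap(terms)

    # lethal pairs enriched within modules
    pairs: dict[tuple[str, str], str] = {}
    within_flags: dict[tuple[str, str], bool] = {}
    module_list = list(modules)
    attempts = 0
    while len(pairs) < spec.n_lethal_pairs and attempts < spec.n_lethal_pairs * 50:
        attempts += 1
        draw_within = (
            bool(module_list) and rng.random() < spec.within_module_pair_fraction
        )
        if draw_within:
            mod = module_list[rng.integers(len(module_list))]
            members = modules[mod]
            i, j = rng.choice(len(members), size=2, replace=False)
            pair = canonical_pair(members[i], members[j])
        else:
            i, j = rng.choice(n_proteins, size=2, replace=False)
            pair = canonical_pair(protein_ids[i], protein_ids[j])
        if pair in pairs:
            continue
        pairs[pair] = "CRISPR" if rng.random() < 0.5 else "low-throughput"
        within_flags[pair] = module_of[pair[0]] is not None and (
            module_of[pair[0]] == module_of[pair[1]]
        )
    pair_set = PairSet(pairs)

    truth = CohortTruth(
        modules=modules,
        module_of=module_of,
        term_map=term_map,
        lethal_pairs=pair_set,
        within_module_pair=within_flags,
        missing_mask=mask,
    )
    return matrix, term_map, pair_set, truth


def generate_depletion(
    n_proteins: int,
    set_size: int,
    fold: float,
    n_reps: int = 4,
    noise_sd: float = 0.2,
    seed: int = 0,
    conditions: tuple[str, str] = ("depleted", "control"),
) -> tuple[ReplicateExperiment, list[str]]:
    """Two-condition replicate experiment with a planted fold change on a set.

    Baseline log2 intensities are drawn per protein; the first condition's
    set members are shifted by log2(fold); i.i.d. normal replicate noise of
    sd ``noise_sd`` is added on the log2 scale; values are exponentiated to
    intensities. Returns the experiment and the true member list.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if not 0 <= set_size <= n_proteins:
        raise ValueError(f"set_size {set_size} outside 0..{n_proteins}")
    if n_reps < 2:
        raise ValueError("need ≥2 replicates per condition")
    rng = np.random.default_rng(seed)
    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    members = list(rng.choice(protein_ids, size=set_size, replace=False))
    member_idx = np.isin(protein_ids, members)

    baseline = rng.uniform(10.0, 20.0, size=n_proteins)
    shifted = baseline + np.where(member_idx, np.log2(fold), 0.0)
    log_a = shifted[:, None] + noise_sd * rng.standard_normal((n_proteins, n_reps))
    log_b = baseline[:, None] + noise_sd * rng.standard_normal((n_proteins, n_reps))
    experiment = ReplicateExperiment(
        protein_ids,
        conditions,
        {conditions[0]: 2.0**log_a, conditions[1]: 2.0**log_b},
    )
    return experiment, sorted(members)


def generate_sparsity_panel(
    n_samples: int,
    detect_probability: Sequence[float],
    seed: int = 0,
    log_loc: float = 6.0,
    log_scale: float = 1.0,
) -> AbundanceMatrix:
    """Per-protein Bernoulli detection: each cell detected independently.

    Emulates the extreme-sparsity regime where a protein is detectable in
    only a handful of samples; undetected cells are masked.
    """
    probs = np.asarray(detect_probability, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("detection probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_proteins = probs.size
    values = np.exp(
        log_loc + log_scale * rng.standard_normal((n_proteins, n_samples))
    )
    mask = rng.random((n_proteins, n_samples)) >= probs[:, None]
    values[mask] = 0.0
    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    return AbundanceMatrix(protein_ids, sample_ids, values, mask)
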