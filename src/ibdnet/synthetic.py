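"""Synthetic inputs with the statistical structure the pipeline assumes.

No genotype data are distributed with the package, so every stage is
exercised on simulated inputs that emulate the study design:

* case/control genotypes drawn under Hardy-Weinberg equilibrium within
  each group, with per-SNP control allele-1 frequencies and allelic odds
  ratios setting the case frequency, plus uniform random missingness;
* modular protein-association networks (planted partitions) whose
  within-module confidences sit above the 0.400 medium-confidence
  threshold and whose between-module confidences largely fall below it;
* gene-set databases with one planted enriched set sharing a chosen
  number of genes with a query while background sets share at most one.

All generators are pure functions of their seed. The default cohort
mirrors the study: 364 CD + 209 UC cases and 445 controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GeneSetDB,
    GenotypeMatrix,
    InteractionTable,
    SnpMeta,
    build_interaction_table,
    read_table2_fixture,
)

__all__ = [
    "SnpSimSpec",
    "NetworkSimSpec",
    "case_frequency",
    "simulate_genotypes",
    "simulate_ppa",
    "simulate_genesets",
    "table2_sim_specs",
    "DEFAULT_COHORT",
]

#: study cohort sizes (cases per phenotype, plus healthy controls)
DEFAULT_COHORT = {"CD": 364, "UC": 209, "HC": 445}


@dataclass(frozen=True)
class SnpSimSpec:
    """Per-SNP generative spec: control frequency, allelic OR, missingness."""

    snp_id: str
    f_U: float
    target_or: float = 1.0
    missing_rate: float = 0.0
    locus: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.f_U < 1.0:
            raise ValueError("f_U must be in (0, 1)")
        if self.target_or <= 0:
            raise ValueError("target_or must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class NetworkSimSpec:
    """Planted-partition association network spec.

    ``module_sizes`` plants the ground-truth clusters; edges appear with
    probability ``p_in`` within and ``p_out`` between modules. Confidence
    scores are uniform on ``conf_in`` for within-module edges; a fraction
    ``frac_low_between`` of between-module edges draw from ``conf_low``
    (below the 0.400 threshold, removed on load), the rest from
    ``conf_in``.
    """

    module_sizes: tuple[int, ...] = (10, 10, 10, 10)
    p_in: float = 0.8
    p_out: float = 0.02
    conf_in: tuple[float, float] = (0.45, 0.95)
    conf_low: tuple[float, float] = (0.15, 0.399)
    frac_low_between: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")


def case_frequency(f_U: float, target_or: float) -> float:
    """Case allele-1 frequency implied by a control frequency and allelic OR.

    Inverts OR = (f_A/(1-f_A)) / (f_U/(1-f_U)):
    f_A = OR*f_U / (1 - f_U + OR*f_U).
    """
    return target_or * f_U / (1.0 - f_U + target_or * f_U)


def simulate_genotypes(
    n_case: int,
    n_ctrl: int,
    specs: list[SnpSimSpec],
    seed: int,
    case_label: str = "CD",
    control_label: str = "HC",
) -> GenotypeMatrix:
    """Draw a case/control genotype matrix under HWE within each group.

    Each individual's genotype at each SNP is Binomial(2, f) with f the
    group's allele-1 frequency; calls are masked missing independently at
    the SNP's missing rate.
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("sample sizes must be positive")
    rng = np.random.default_rng(seed)
    n = n_case + n_ctrl
    f_case = np.array([case_frequency(s.f_U, s.target_or) for s in specs])
    f_ctrl = np.array([s.f_U for s in specs])
    freqs = np.vstack(
        [np.tile(f_case, (n_case, 1)), np.tile(f_ctrl, (n_ctrl, 1))]
    )
    calls = rng.binomial(2, freqs).astype(np.int8)
    miss_rate = np.array([s.missing_rate for s in specs])
    if miss_rate.any():
        mask = rng.random((n, len(specs))) < miss_rate
        calls[mask] = -1
    samples = [f"case_{i:05d}" for i in range(n_case)] + [
        f"ctrl_{i:05d}" for i in range(n_ctrl)
    ]
    groups = {s: (case_label if i < n_case else control_label) for i, s in enumerate(samples)}
    metas = [
        SnpMeta(snp_id=s.snp_id, locus=s.locus or s.snp_id.upper(), a1="A", a2="G")
        for s in specs
    ]
    return GenotypeMatrix(samples=samples, groups=groups, snps=metas, calls=calls)


def simulate_ppa(spec: NetworkSimSpec) -> tuple[InteractionTable, dict[str, int]]:
    """Planted-partition interaction table plus the ground-truth membership.

    Node names encode nothing about the modules; the returned membership
    dict (protein -> module index) is the truth for recovery experiments.
    """
    rng = np.random.default_rng(spec.seed)
    names: list[str] = []
    membership: dict[str, int] = {}
    for m, size in enumerate(spec.module_sizes):
        for i in range(size):
            name = f"P{len(names):04d}"
            names.append(name)
            membership[name] = m
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            same = membership[names[i]] == membership[names[j]]
            p = spec.p_in if same else spec.p_out
            if rng.random() >= p:
                continue
            if same or rng.random() >= spec.frac_low_between:
                lo, hi = spec.conf_in
            else:
                lo, hi = spec.conf_low
            rows.append(
                {
                    "protein_a": names[i],
                    "protein_b": names[j],
                    "combined_score": round(float(rng.uniform(lo, hi)), 3),
                }
            )
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    return build_interaction_table(df), membership


def simulate_genesets(
    n_sets: int,
    set_size_range: tuple[int, int],
    planted: tuple[list[str], str, int],
    seed: int,
) -> GeneSetDB:
    """Gene-set database with one planted enriched set.

    ``planted`` is (query genes, planted set id, overlap k): the planted
    set shares exactly k genes with the query; every background set shares
    at most one (a realistic low-level leak). Background genes come from a
    disjoint universe.
    """
    query, planted_id, k = planted
    lo, hi = set_size_range
    if not 0 <= k <= min(hi, len(query)):
        raise ValueError("overlap k must fit in the set size and query")
    rng = np.random.default_rng(seed)
    universe = [f"BG{i:05d}" for i in range(max(200, n_sets * hi))]
    sets: dict[str, tuple[str, list[str]]] = {}

    size = int(rng.integers(max(lo, k or 1), hi + 1))
    core = list(rng.choice(len(query), size=k, replace=False)) if k else []
    members = [query[i] for i in core]
    members += [universe[i] for i in rng.choice(len(universe), size=size - k, replace=False)]
    sets[planted_id] = ("planted enriched set", members)

    for s in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        leak = int(rng.integers(0, 2)) if query else 0  # 0 or 1 query gene
        leak = min(leak, len(query))
        members = [query[int(rng.integers(0, len(query)))]] if leak else []
        need = size - len(members)
        members += [universe[i] for i in rng.choice(len(universe), size=need, replace=False)]
        # dedupe while keeping order (choice is without replacement, but the
        # leaked query gene cannot collide with BG names anyway)
        sets[f"SET{s:03d}"] = ("background set", list(dict.fromkeys(members)))
    return GeneSetDB(sets=sets)


def table2_sim_specs(
    phenotype: str = "IBD", missing_rate: float = 0.0
) -> list[SnpSimSpec]:
    """Generative specs mirroring the packaged risk-SNP panel for a phenotype.

    Each spec carries the panel's control allele-1 frequency and printed
    odds ratio, so a simulated cohort reproduces the panel's effect-size
    structure (up to sampling noise).
    """
    specs = []
    for rec in read_table2_fixture(phenotype):
        if rec.or_ <= 0 or not 0 < rec.f_U < 1:
            continue  # zero-frequency / zero-OR rows cannot be parameterized
        specs.append(
            SnpSimSpec(
                snp_id=rec.snp.snp_id,
                f_U=rec.f_U,
                target_or=rec.or_,
                missing_rate=missing_rate,
                locus=rec.snp.locus,
            )
        )
    return specs
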