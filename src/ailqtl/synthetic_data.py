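"""Synthetic study populations: AIL genotypes, trait architectures, expression.

The generator emulates the structure of an advanced intercross line (AIL)
descended from two fully inbred, nearly isogenic founder lines (S1 and S2):
an F1 cross followed by repeated random mating.  Each gamete is built by a
crossover process per chromosome — crossover count Poisson in the physical
length, positions uniform, no interference — so linkage disequilibrium
decays with both physical distance and generation number, which is the
property the downstream mapping machinery depends on.

Trait values are built from planted QTL with additive and dominance effects
plus optional mediated (causal-chain) contributions, so that a locus can
affect one trait directly and a second trait only through the first.  This
is the generative counterpart of the causal/reactive/independent model
comparison in :mod:`ailqtl.causal_modeling`.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GenotypeMatrix, trait_columns

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AilDesign:
    """Design of an AIL population.

    Parameters
    ----------
    n_individuals
        Number of individuals per generation (and in the returned cohort).
    n_generations
        AIL generation number: 1 is the F1; generation ``g`` has undergone
        ``g - 1`` rounds of random mating after the initial cross.
    chromosomes
        ``(name, length_bp)`` pairs; all treated as autosomes.
    marker_positions
        Per-chromosome sorted 1-based bp positions of the typed markers.
    recombination_rate
        Expected crossovers per 100 Mb per meiosis (default 0.5, a
        mouse-like genome-wide average of ~0.5 cM/Mb).
    """

    n_individuals: int
    n_generations: int
    chromosomes: tuple[tuple[str, int], ...]
    marker_positions: Mapping[str, Sequence[int]]
    recombination_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            pos = np.asarray(self.marker_positions[name])
            if len(pos) and not (np.diff(pos) > 0).all():
                raise ValueError(f"marker positions on {name} not strictly increasing")


def evenly_spaced_design(
    n_individuals: int = 397,
    n_generations: int = 10,
    chromosomes: Sequence[tuple[str, int]] = (
        ("1", 150_000_000),
        ("2", 150_000_000),
        ("3", 150_000_000),
        ("4", 150_000_000),
        ("5", 150_000_000),
    ),
    markers_per_chromosome: int = 200,
    recombination_rate: float = 0.5,
    seed: int = 0,
) -> AilDesign:
    """Convenience constructor with evenly spaced markers.

    Defaults mirror the study population this package models: 397 males of
    AIL generation 10, with on the order of a thousand informative markers
    spread over the genome (the real array yielded ~5,000 informative SNPs;
    a thousand evenly spaced markers preserve the ~0.75 Mb spacing relevant
    for mapping resolution at desk scale).
    """
    positions = {
        name: np.linspace(1, length, markers_per_chromosome).astype(np.int64)
        for name, length in chromosomes
    }
    return AilDesign(
        n_individuals=n_individuals,
        n_generations=n_generations,
        chromosomes=tuple(chromosomes),
        marker_positions=positions,
        recombination_rate=recombination_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class QtlSpec:
    """One planted QTL (or pure mediation edge) acting on a target trait.

    ``additive_effect`` is in trait units per S1-allele copy; ``dominance_effect``
    is added to heterozygotes only.  ``mediation = (mediator_trait, slope)``
    adds ``slope * mediator_value`` to the target, building causal chains.
    ``marker_id`` may be None for a pure mediation edge.
    """

    marker_id: str | None
    target_trait: str
    additive_effect: float = 0.0
    dominance_effect: float = 0.0
    mediation: tuple[str, float] | None = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mediation is not None and self.mediation[0] == self.target_trait:
            raise ValueError("mediator and target trait must be distinct")


@dataclass(frozen=True)
class CovariateSpec:
    """Litter size as a small-integer covariate with additive effect.

    Litter size is drawn uniformly from ``low..high`` pups per individual
    and adds ``effect * litter_size`` to each trait in ``affected_traits``
    (in the study, liver weight was the litter-size-influenced trait).
    """

    affected_traits: tuple[str, ...] = ()
    effect: float = 0.0
    low: int = 4
    high: int = 12


@dataclass(frozen=True)
class ExpressionDesign:
    """Two-line expression experiment with a planted DE fraction."""

    n_probes: int = 1000
    n_samples_per_line: Mapping[str, int] = field(
        default_factory=lambda: {"S1": 7, "S2": 8}
    )
    de_fraction: float = 0.1
    effect_size_log2: float = 1.0
    noise_sd: float = 0.3
    tissue: str = "gonadal_adipose"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if any(n < 2 for n in self.n_samples_per_line.values()):
            raise ValueError("need >= 2 samples per line for testability")


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


def _gamete(
    parent_haps: list[np.ndarray],
    chrom_lengths: np.ndarray,
    marker_pos: list[np.ndarray],
    rate_per_bp: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One recombinant gamete: per chromosome a mosaic of the two parent haplotypes."""
    out = []
    for c, pos in enumerate(marker_pos):
        hap_pair = parent_haps[c]  # (2, n_markers) uint8
        n_x = rng.poisson(chrom_lengths[c] * rate_per_bp)
        start = rng.integers(0, 2)
        if n_x == 0:
            out.append(hap_pair[start].copy())
            continue
        xpos = np.sort(rng.uniform(0, chrom_lengths[c], size=n_x))
        phase = (np.searchsorted(xpos, pos, side="right") + start) % 2
        out.append(np.where(phase == 0, hap_pair[0], hap_pair[1]).astype(np.uint8))
    return out


def simulate_ail_genotypes(design: AilDesign) -> GenotypeMatrix:
    """Simulate AIL genotypes by gamete dropping through random-mating generations.

    Founders are fully inbred and opposite-homozygous at every marker (S1
    carries the "1" allele everywhere, S2 the "0" allele), so the F1 is
    heterozygous at every marker and later generations mosaic.  Each
    offspring draws two distinct parents uniformly from the previous
    generation.  Genotype codes count S1 alleles.
    """
    rng = np.random.default_rng(design.seed)
    chrom_names = [name for name, _ in design.chromosomes]
    chrom_lengths = np.array([length for _, length in design.chromosomes], dtype=float)
    marker_pos = [np.asarray(design.marker_positions[name], dtype=float) for name in chrom_names]
    n_markers = [len(p) for p in marker_pos]
    rate_per_bp = design.recombination_rate / 1e8

    # F1: every individual carries one all-S1 and one all-S2 haplotype
    f1 = [
        np.stack([np.ones(m, dtype=np.uint8), np.zeros(m, dtype=np.uint8)]) for m in n_markers
    ]
    pop = [[hap.copy() for hap in f1] for _ in range(design.n_individuals)]

    for _generation in range(design.n_generations - 1):
        new_pop = []
        n = len(pop)
        for _ in range(design.n_individuals):
            i = rng.integers(0, n)
            j = rng.integers(0, n - 1)
            if j >= i:
                j += 1
            gam_a = _gamete(pop[i], chrom_lengths, marker_pos, rate_per_bp, rng)
            gam_b = _gamete(pop[j], chrom_lengths, marker_pos, rate_per_bp, rng)
            new_pop.append([np.stack([a, b]) for a, b in zip(gam_a, gam_b)])
        pop = new_pop

    codes = np.concatenate(
        [np.stack([ind[c].sum(axis=0) for ind in pop], axis=1) for c in range(len(chrom_names))],
        axis=0,
    ).astype(float)

    ids, chroms, poss = [], [], []
    for name, pos in zip(chrom_names, marker_pos):
        for p in pos.astype(np.int64):
            ids.append(f"m{name}_{p}")
            chroms.append(name)
            poss.append(int(p))
    markers = pd.DataFrame({"chrom": chroms, "pos": poss}, index=pd.Index(ids, name="marker"))
    individuals = [f"ind{i:04d}" for i in range(design.n_individuals)]
    calls = pd.DataFrame(codes, index=markers.index, columns=individuals)
    return GenotypeMatrix(markers, calls)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtl_specs: Sequence[QtlSpec],
    covariate_spec: CovariateSpec | None = None,
    baselines: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build trait values from planted QTL effects, mediation, and noise.

    Each trait is ``baseline + sum(additive * code + dominance * [code == 1])
    + sum(slope * mediator) + litter effect + N(0, noise_sd)``.  Traits are
    evaluated in topological order of the mediation graph, so chains like
    Q -> T1 -> T2 are well defined; a cyclic graph raises
    :class:`graphlib.CycleError`.
    """
    rng = np.random.default_rng(seed)
    baselines = dict(baselines or {})
    n = len(genotypes.individuals)

    by_trait: dict[str, list[QtlSpec]] = {}
    for spec in qtl_specs:
        if spec.marker_id is not None and spec.marker_id not in genotypes.markers.index:
            raise KeyError(f"unknown marker {spec.marker_id!r} in QtlSpec")
        by_trait.setdefault(spec.target_trait, []).append(spec)

    sorter = graphlib.TopologicalSorter()
    for trait, specs in by_trait.items():
        deps = [s.mediation[0] for s in specs if s.mediation is not None]
        for d in deps:
            if d not in by_trait and d not in baselines:
                raise KeyError(f"mediator trait {d!r} is never generated")
        sorter.add(trait, *deps)
    order = list(sorter.static_order())

    noise_sd: dict[str, float] = {}
    for trait, specs in by_trait.items():
        sds = {s.noise_sd for s in specs}
        if len(sds) > 1:
            raise ValueError(f"conflicting noise_sd values for trait {trait!r}: {sorted(sds)}")
        noise_sd[trait] = sds.pop()

    table = pd.DataFrame(index=pd.Index(genotypes.individuals, name="id"))
    values: dict[str, np.ndarray] = {}
    for trait in order:
        y = np.full(n, baselines.get(trait, 0.0))
        for spec in by_trait.get(trait, []):
            if spec.marker_id is not None:
                code = genotypes.codes(spec.marker_id).to_numpy()
                y = y + spec.additive_effect * code + spec.dominance_effect * (code == 1)
            if spec.mediation is not None:
                med, slope = spec.mediation
                y = y + slope * values[med]
        if trait in by_trait and noise_sd[trait] > 0:
            y = y + rng.normal(0.0, noise_sd[trait], size=n)
        values[trait] = y
        table[trait] = y

    if covariate_spec is not None:
        litter = rng.integers(covariate_spec.low, covariate_spec.high + 1, size=n)
        for trait in covariate_spec.affected_traits:
            if trait not in table.columns:
                raise KeyError(f"covariate affects unknown trait {trait!r}")
            table[trait] = table[trait] + covariate_spec.effect * litter
        table["litter_size"] = litter
    return table


# ---------------------------------------------------------------------------
# Tail selection (selective genotyping)
# ---------------------------------------------------------------------------


def select_tails(phenotypes: pd.DataFrame, traits: Sequence[str], n_select: int) -> list[str]:
    """Pick the union of phenotypic-tail individuals for selective genotyping.

    Individuals are ranked per trait by standardized score; the low and high
    tail of each trait contribute alternately (round-robin over
    (trait, tail) pairs in the given trait order) until ``n_select`` distinct
    ids are collected.  Deterministic: ties are broken by id order.
    """
    if not traits:
        raise ValueError("at least one trait required")
    if n_select > len(phenotypes):
        raise ValueError("n_select exceeds number of individuals")
    orderings = []
    for t in traits:
        if t not in phenotypes.columns:
            raise KeyError(f"trait {t!r} not in phenotype table")
        vals = phenotypes[t].dropna()
        sd = vals.std(ddof=1)
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        low = sorted(z.index, key=lambda i: (z[i], str(i)))
        high = sorted(z.index, key=lambda i: (-z[i], str(i)))
        orderings.append(low)
        orderings.append(high)

    selected: list[str] = []
    chosen: set[str] = set()
    cursors = [0] * len(orderings)
    while len(selected) < n_select:
        progressed = False
        for k, order in enumerate(orderings):
            if len(selected) >= n_select:
                break
            while cursors[k] < len(order) and order[cursors[k]] in chosen:
                cursors[k] += 1
            if cursors[k] < len(order):
                ind = order[cursors[k]]
                selected.append(ind)
                chosen.add(ind)
                cursors[k] += 1
                progressed = True
        if not progressed:
            break
    return selected


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(design: ExpressionDesign) -> tuple[ExpressionMatrix, np.ndarray]:
    """Group-structured expression intensities with a planted DE subset.

    Probe baselines are N(8, 1.5) on the log2 scale; a ``de_fraction``
    subset receives a between-line mean shift of ``effect_size_log2``
    (sign alternating), and i.i.d. N(0, noise_sd) sample noise is added
    before transforming back to raw intensities (so inputs to
    :func:`ailqtl.expression_de.normalize` are positive, un-logged values).

    Returns the matrix and the boolean mask of truly shifted probes.
    """
    rng = np.random.default_rng(design.seed)
    lines = list(design.n_samples_per_line)
    sample_ids, sample_lines = [], []
    for line in lines:
        for k in range(design.n_samples_per_line[line]):
            sample_ids.append(f"{line}_{design.tissue}_{k}")
            sample_lines.append(line)
    n_samples = len(sample_ids)

    base = rng.normal(8.0, 1.5, size=design.n_probes)
    n_de = int(round(design.de_fraction * design.n_probes))
    de_mask = np.zeros(design.n_probes, dtype=bool)
    de_mask[rng.choice(design.n_probes, size=n_de, replace=False)] = True
    signs = np.where(np.arange(design.n_probes) % 2 == 0, 1.0, -1.0)

    log2 = np.tile(base[:, None], (1, n_samples))
    is_s1 = np.array([ln == lines[0] for ln in sample_lines])
    shift = np.where(de_mask, signs * design.effect_size_log2, 0.0)
    log2[:, is_s1] += shift[:, None]
    log2 += rng.normal(0.0, design.noise_sd, size=log2.shape)

    probes = pd.Index([f"probe{i:05d}" for i in range(design.n_probes)], name="probe")
    values = pd.DataFrame(2.0**log2, index=probes, columns=sample_ids)
    samples = pd.DataFrame(
        {"line": sample_lines, "tissue": design.tissue},
        index=pd.Index(sample_ids, name="sample"),
    )
    probe_genes = pd.Series([f"gene{i:05d}" for i in range(design.n_probes)], index=probes)
    return ExpressionMatrix(values, samples, probe_genes), de_mask


# ---------------------------------------------------------------------------
# Gene models and variant annotations (pipeline plumbing)
# ---------------------------------------------------------------------------


def simulate_gene_models(
    chromosomes: Sequence[tuple[str, int]],
    n_genes_per_chromosome: int = 50,
    gene_length: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly tiled protein-coding gene models for prioritization demos."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for name, length in chromosomes:
        starts = np.linspace(1, max(1, length - gene_length), n_genes_per_chromosome).astype(
            np.int64
        )
        for s in starts:
            rows.append(
                {
                    "gene": f"ENSMUSGS{k:07d}",
                    "name": f"Gene{k}",
                    "chrom": name,
                    "start": int(s),
                    "end": int(s + gene_length - 1),
                    "biotype": "protein_coding",
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_variant_annotations(
    genes: pd.DataFrame,
    polymorphic_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """VEP-style annotation rows for a random subset of genes.

    Each polymorphic gene receives 1-4 variants with consequence categories
    drawn from the scoring tree's vocabulary; SIFT classes and domain flags
    are attached to missense rows only.
    """
    rng = np.random.default_rng(seed)
    cats = ["missense", "promoter", "utr", "enhancer", "ctcf_binding_site", "splice_site", "other"]
    weights = np.array([0.2, 0.1, 0.2, 0.15, 0.1, 0.05, 0.2])
    rows = []
    v = 0
    for _, g in genes.iterrows():
        if rng.random() > polymorphic_fraction:
            continue
        for _ in range(rng.integers(1, 5)):
            cat = rng.choice(cats, p=weights / weights.sum())
            pos = int(rng.integers(g["start"] - 1000, g["end"] + 1001))
            row = {
                "variant": f"v{v:06d}",
                "chrom": g["chrom"],
                "pos": pos,
                "gene": g["gene"],
                "consequence": cat,
                "in_functional_domain": False,
                "sift_class": "none",
            }
            if cat == "missense":
                row["in_functional_domain"] = bool(rng.random() < 0.5)
                row["sift_class"] = "deleterious" if rng.random() < 0.4 else "tolerated"
            rows.append(row)
            v += 1
    return pd.DataFrame(rows)
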