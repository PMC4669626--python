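"""Synthetic haploid SNP datasets with the nannandrous-moss study design.

The generator emulates a hierarchical sample: populations hold colonies,
each colony is sampled as five female shoots (one centre shoot plus four
satellites 50 cm away), and the centre shoot carries a cohort of epiphytic
dwarf males.  Female shoots within a colony are clonal copies of a small
number of founder haplotypes, with one dominant clone occupying most shoots.
Dwarf males are single-generation meiotic spores: a mother shoot is drawn
from the host / colony / population / elsewhere according to configurable
origin weights, a father haplotype from the mother's population (or the
mother's own clone, modelling inbred or self-like matings), and each unlinked
locus inherits the maternal or paternal allele with probability 1/2.

Population allele frequencies follow the Balding-Nichols island model:
for ancestral frequency p and differentiation F, each population's frequency
is Beta-distributed with mean p and variance p(1-p)F.

Everything is deterministic under a seed, and the generator returns the
hidden ground truth (clone membership, spore parentage, origin category)
alongside the dataset so that estimators can be validated by parameter
recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import DWARF_MALE, FEMALE, MISSING, Dataset, GenotypeMatrix

ORIGIN_CATEGORIES = ("host", "same_colony", "same_population", "other_population")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the hierarchical spore-dispersal simulation.

    The defaults reproduce the study design this generator emulates:
    4 populations of 5 colonies (6 in the last), 5 female shoots per colony,
    10 dwarf males on each centre shoot, 68 biallelic loci, differentiation
    F = 0.3 between populations, host-biased spore origins and ~1.1 %
    missing genotype calls.
    """

    n_populations: int = 4
    colonies_per_population: int | Sequence[int] = (5, 5, 5, 6)
    females_per_colony: int = 5
    #: probability that a sampled shoot belongs to founder lineage k; the
    #: first (dominant) lineage occupies most shoots.  The implied expected
    #: number of distinct clones per colony is `expected_clones_per_colony`.
    clone_dominance_weights: Sequence[float] = (0.72, 0.07, 0.07, 0.07, 0.07)
    dwarf_males_per_host: int = 10
    n_loci: int = 68
    #: ancestral allele-frequency law, ("uniform", low, high)
    ancestral_freq_distribution: tuple = ("uniform", 0.1, 0.9)
    #: target differentiation F in [0, 1) (Balding-Nichols)
    fst_level: float = 0.3
    #: P(spore mother is the host / another colony shoot / another colony in
    #: the population / another population)
    origin_weights: Sequence[float] = (0.6, 0.25, 0.1, 0.05)
    #: probability the father haplotype is the mother's own clone
    selfing_prob: float = 0.3
    missing_rate: float = 0.011
    isolation_by_distance: bool = False
    #: spacing between colony grid points within a population, metres
    colony_spacing_m: float = 30.0
    #: spacing between population grid points, metres
    population_spacing_m: float = 5000.0
    #: decay length of the mother-colony choice kernel when
    #: isolation_by_distance is on, metres
    ibd_decay_m: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if not (0.0 <= self.fst_level < 1.0):
            raise ConfigError("fst_level must be in [0, 1)")
        for name in ("selfing_prob", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        w = np.asarray(self.origin_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError("origin_weights must be 4 non-negative values summing to 1")
        cw = np.asarray(self.clone_dominance_weights, dtype=float)
        if (cw < 0).any() or cw.sum() <= 0:
            raise ConfigError("clone_dominance_weights must be non-negative, not all 0")
        if len(cw) > self.females_per_colony:
            raise ConfigError(
                "more founder lineages than sampled shoots per colony"
            )

    @property
    def colony_counts(self) -> tuple[int, ...]:
        c = self.colonies_per_population
        if isinstance(c, int):
            return (c,) * self.n_populations
        c = tuple(int(v) for v in c)
        if len(c) != self.n_populations:
            raise ConfigError("colonies_per_population length != n_populations")
        return c

    @property
    def expected_clones_per_colony(self) -> float:
        """E[# distinct founder lineages among the sampled shoots].

        With shoot-to-lineage weights w_k and S shoots,
        E = sum_k (1 - (1 - w_k)^S).
        """
        w = np.asarray(self.clone_dominance_weights, dtype=float)
        w = w / w.sum()
        return float(np.sum(1.0 - (1.0 - w) ** self.females_per_colony))


def study_design_config(**overrides) -> SimulationConfig:
    """The default study-design preset (see :class:`SimulationConfig`)."""
    return SimulationConfig(**overrides)


@dataclass
class PopulationFrequencies:
    """Per-locus ancestral and per-population allele-1 frequencies."""

    population_ids: list[str]
    ancestral: np.ndarray  # (L,)
    by_population: np.ndarray  # (P, L)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.by_population,
            index=pd.Index(self.population_ids, name="population"),
        )


@dataclass
class SimulationTruth:
    """Hidden labels of a simulated dataset, for parameter-recovery tests."""

    #: per-female clone id (founder lineage), indexed by sample_id
    female_clones: pd.Series
    #: per-dwarf-male origin_category, mother_id, father_id
    dwarf_males: pd.DataFrame
    frequencies: PopulationFrequencies

    def to_frame(self) -> pd.DataFrame:
        fem = pd.DataFrame(
            {
                "clone_id": self.female_clones,
                "origin_category": "",
                "mother_id": "",
                "father_id": "",
            }
        )
        dm = self.dwarf_males.copy()
        dm.insert(0, "clone_id", "")
        out = pd.concat([fem, dm])
        out.index.name = "sample_id"
        return out


def draw_population_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> PopulationFrequencies:
    """Draw ancestral and per-population allele frequencies.

    Population frequencies follow Beta(p(1-F)/F, (1-p)(1-F)/F) with mean p
    and variance p(1-p)F (Balding-Nichols); F = 0 short-circuits to the
    ancestral frequencies.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    kind, *params = cfg.ancestral_freq_distribution
    if kind != "uniform":
        raise ConfigError(f"unknown ancestral frequency law {kind!r}")
    low, high = params
    p = rng.uniform(low, high, size=cfg.n_loci)
    pop_ids = [f"P{i + 1}" for i in range(cfg.n_populations)]
    if cfg.fst_level == 0.0:
        freqs = np.tile(p, (cfg.n_populations, 1))
    else:
        c = (1.0 - cfg.fst_level) / cfg.fst_level
        freqs = rng.beta(p * c, (1.0 - p) * c, size=(cfg.n_populations, cfg.n_loci))
    return PopulationFrequencies(pop_ids, p, freqs)


@dataclass
class _Colony:
    colony_id: str
    population_id: str
    pop_index: int
    centre_xy: tuple[float, float]
    founders: np.ndarray  # (K, L) haplotypes of the founder lineages
    founder_ids: list[str]
    shoot_ids: list[str] = field(default_factory=list)  # shoot_ids[0] = centre
    shoot_clone_idx: list[int] = field(default_factory=list)
    shoot_xy: list[tuple[float, float]] = field(default_factory=list)


def _colony_layout(cfg: SimulationConfig) -> list[tuple[str, str, int, float, float]]:
    """(colony_id, population_id, pop_index, x, y) on nested square grids."""
    out = []
    pop_side = max(1, math.ceil(math.sqrt(cfg.n_populations)))
    for p, n_col in enumerate(cfg.colony_counts):
        px = (p % pop_side) * cfg.population_spacing_m
        py = (p // pop_side) * cfg.population_spacing_m
        col_side = max(1, math.ceil(math.sqrt(n_col)))
        pop_id = f"P{p + 1}"
        for c in range(n_col):
            cx = px + (c % col_side) * cfg.colony_spacing_m
            cy = py + (c // col_side) * cfg.colony_spacing_m
            out.append((f"{pop_id}-C{c + 1}", pop_id, p, cx, cy))
    return out


#: within-colony shoot offsets: centre plus four satellites at 0.5 m
_SHOOT_OFFSETS = [(0.0, 0.0), (0.0, 0.5), (0.5, 0.0), (0.0, -0.5), (-0.5, 0.0)]


def simulate_females(
    cfg: SimulationConfig,
    freqs: PopulationFrequencies,
    rng: np.random.Generator,
) -> tuple[list[_Colony], pd.Series]:
    """Simulate colony founder clones and the sampled female shoots.

    Each colony draws K distinct founder haplotypes (loci independent
    Bernoulli at the population frequency) and assigns each sampled shoot to
    a lineage by the dominance weights; the first shoot is the centre shoot.
    Returns the colonies and the per-shoot clone-id truth.
    """
    weights = np.asarray(cfg.clone_dominance_weights, dtype=float)
    weights = weights / weights.sum()
    K = len(weights)
    colonies: list[_Colony] = []
    clone_truth: dict[str, str] = {}
    for colony_id, pop_id, p, cx, cy in _colony_layout(cfg):
        f = freqs.by_population[p]
        founders = (rng.random((K, cfg.n_loci)) < f).astype(np.int8)
        # founder lineages should be distinct haplotypes; redraw collisions
        for _ in range(100):
            _, first = np.unique(founders, axis=0, return_index=True)
            dup = np.setdiff1d(np.arange(K), first)
            if dup.size == 0:
                break
            founders[dup] = (rng.random((dup.size, cfg.n_loci)) < f).astype(np.int8)
        founder_ids = [f"{colony_id}-K{k + 1}" for k in range(K)]
        col = _Colony(colony_id, pop_id, p, (cx, cy), founders, founder_ids)
        n_off = len(_SHOOT_OFFSETS)
        for s in range(cfg.females_per_colony):
            k = int(rng.choice(K, p=weights))
            sid = f"{colony_id}-F{s + 1}"
            dx, dy = _SHOOT_OFFSETS[s % n_off]
            col.shoot_ids.append(sid)
            col.shoot_clone_idx.append(k)
            col.shoot_xy.append((cx + dx, cy + dy))
            clone_truth[sid] = founder_ids[k]
        colonies.append(col)
    return colonies, pd.Series(clone_truth, name="clone_id")


def _effective_origin_weights(cfg: SimulationConfig) -> np.ndarray:
    w = np.asarray(cfg.origin_weights, dtype=float).copy()
    counts = cfg.colony_counts
    impossible = []
    if all(c < 2 for c in counts) and w[2] > 0:
        impossible.append("same_population")
        w[2] = 0.0
    if cfg.n_populations < 2 and w[3] > 0:
        impossible.append("other_population")
        w[3] = 0.0
    if impossible:
        warnings.warn(
            f"origin categories impossible under this layout, renormalising: "
            f"{impossible}",
            stacklevel=3,
        )
    if w.sum() <= 0:
        raise ConfigError("no feasible origin category has positive weight")
    return w / w.sum()


def simulate_dwarf_males(
    cfg: SimulationConfig,
    colonies: list[_Colony],
    freqs: PopulationFrequencies,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Simulate dwarf-male spores on each centre shoot.

    For each spore: the origin category fixes the mother shoot (host shoot,
    a satellite shoot of the colony, a shoot of another colony in the
    population, or a shoot of another population); the father haplotype is
    the mother's own clone with probability ``selfing_prob``, otherwise the
    haplotype of a random sampled shoot of the mother's population; each
    locus then inherits the maternal or paternal allele with probability 1/2.

    Returns per-dwarf-male genotypes and the parentage truth table.
    """
    w = _effective_origin_weights(cfg)
    by_pop: dict[str, list[_Colony]] = {}
    for col in colonies:
        by_pop.setdefault(col.population_id, []).append(col)
    all_pops = sorted(by_pop)

    def shoot_haplotype(col: _Colony, s: int) -> np.ndarray:
        return col.founders[col.shoot_clone_idx[s]]

    genotypes: dict[str, np.ndarray] = {}
    truth_rows = []
    for col in colonies:
        host_idx = 0  # centre shoot hosts the dwarf males
        host_id = col.shoot_ids[host_idx]
        others_in_pop = [c for c in by_pop[col.population_id] if c is not col]
        if cfg.isolation_by_distance and others_in_pop:
            d = np.array(
                [math.dist(col.centre_xy, c.centre_xy) for c in others_in_pop]
            )
            colony_kernel = np.exp(-d / cfg.ibd_decay_m)
            colony_kernel = colony_kernel / colony_kernel.sum()
        else:
            colony_kernel = None
        for m in range(cfg.dwarf_males_per_host):
            cat_idx = int(rng.choice(4, p=w))
            # redraw if the category is impossible for this colony's layout
            for _ in range(100):
                if (cat_idx == 2 and not others_in_pop) or (
                    cat_idx == 3 and len(all_pops) < 2
                ):
                    cat_idx = int(rng.choice(4, p=w))
                else:
                    break
            else:
                cat_idx = 0
            category = ORIGIN_CATEGORIES[cat_idx]
            if category == "host":
                mother_col, mother_s = col, host_idx
            elif category == "same_colony":
                mother_col = col
                mother_s = int(rng.integers(1, cfg.females_per_colony))
            elif category == "same_population":
                if colony_kernel is not None:
                    mother_col = others_in_pop[int(rng.choice(len(others_in_pop), p=colony_kernel))]
                else:
                    mother_col = others_in_pop[int(rng.integers(len(others_in_pop)))]
                mother_s = int(rng.integers(cfg.females_per_colony))
            else:
                other = [p for p in all_pops if p != col.population_id]
                pop = other[int(rng.integers(len(other)))]
                cands = by_pop[pop]
                mother_col = cands[int(rng.integers(len(cands)))]
                mother_s = int(rng.integers(cfg.females_per_colony))
            mother_id = mother_col.shoot_ids[mother_s]
            mother_hap = shoot_haplotype(mother_col, mother_s)
            if rng.random() < cfg.selfing_prob:
                father_id = mother_id
                father_hap = mother_hap
            else:
                pool = by_pop[mother_col.population_id]
                fc = pool[int(rng.integers(len(pool)))]
                fs = int(rng.integers(cfg.females_per_colony))
                father_id = fc.shoot_ids[fs]
                father_hap = shoot_haplotype(fc, fs)
            from_mother = rng.random(cfg.n_loci) < 0.5
            spore = np.where(from_mother, mother_hap, father_hap).astype(np.int8)
            sid = f"{col.colony_id}-D{m + 1:02d}"
            genotypes[sid] = spore
            truth_rows.append(
                {
                    "sample_id": sid,
                    "origin_category": category,
                    "mother_id": mother_id,
                    "father_id": father_id,
                }
            )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return genotypes, truth


def simulate_dataset(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[Dataset, SimulationTruth]:
    """Simulate a full dataset plus its ground truth.

    Composes frequency draws, female colonies and dwarf-male spores, then
    injects missing calls independently at ``cfg.missing_rate``.  ``seed``
    overrides ``cfg.seed``.
    """
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    freqs = draw_population_frequencies(cfg, rng)
    colonies, clone_truth = simulate_females(cfg, freqs, rng)
    dm_genotypes, dm_truth = simulate_dwarf_males(cfg, colonies, freqs, rng)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for col in colonies:
        host_id = col.shoot_ids[0]
        for s, sid in enumerate(col.shoot_ids):
            sample_ids.append(sid)
            rows.append(col.founders[col.shoot_clone_idx[s]])
            meta_rows.append(
                {
                    "sample_id": sid,
                    "category": FEMALE,
                    "population": col.population_id,
                    "colony": col.colony_id,
                    "host_id": None,
                    "x": col.shoot_xy[s][0],
                    "y": col.shoot_xy[s][1],
                }
            )
        for m in range(cfg.dwarf_males_per_host):
            sid = f"{col.colony_id}-D{m + 1:02d}"
            sample_ids.append(sid)
            rows.append(dm_genotypes[sid])
            meta_rows.append(
                {
                    "sample_id": sid,
                    "category": DWARF_MALE,
                    "population": col.population_id,
                    "colony": col.colony_id,
                    "host_id": host_id,
                    "x": col.shoot_xy[0][0],
                    "y": col.shoot_xy[0][1],
                }
            )
    calls = np.array(rows, dtype=np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)
    locus_ids = [f"L{j + 1:03d}" for j in range(cfg.n_loci)]
    geno = GenotypeMatrix(sample_ids, locus_ids, calls, [("0", "1")] * cfg.n_loci)
    ds = Dataset(geno, pd.DataFrame(meta_rows))
    truth = SimulationTruth(clone_truth, dm_truth, freqs)
    return ds, truth
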