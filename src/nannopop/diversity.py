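"""Genetic diversity: Nei's unbiased gene diversity (uh) and %P.

uh at one locus is (n/(n-1)) * (1 - sum rho_i^2) where rho_i are allele
frequencies among the n non-missing haploid calls; the group value is the
mean over loci, with monomorphic loci contributing 0.  %P is the percentage
of loci with at least two observed alleles, over the full locus panel.

Because shoots within a colony are clonal and dwarf males share a host,
individuals within colonies are not independent draws from the population.
Population-level diversity is therefore estimated by repeatedly drawing one
individual per colony and averaging the per-draw estimates
(:func:`subsampled_diversity`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, Dataset, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversityEstimate:
    """uh and %P for one group, optionally averaged over permuted subsamples."""

    group: str
    n: int
    uh: float
    pct_polymorphic: float
    uh_sd: float = 0.0
    pct_polymorphic_sd: float = 0.0
    n_permutations: int = 0


def locus_uh(allele_counts) -> float:
    """Nei's unbiased diversity at one locus from per-allele counts."""
    counts = np.asarray(allele_counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("locus_uh needs at least 2 non-missing alleles")
    rho = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(rho**2)))


def _calls_diversity(calls: np.ndarray, label: str) -> tuple[float, float]:
    """(mean locus uh, %P) for a calls sub-matrix; skips loci with <2 calls."""
    n1 = (calls == 1).sum(axis=0).astype(float)
    n0 = (calls == 0).sum(axis=0).astype(float)
    nn = n0 + n1
    usable = nn >= 2
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning(
            "%s: %d loci with <2 non-missing calls skipped from uh", label, n_skipped
        )
    if not usable.any():
        raise ValueError(f"{label}: no locus with >=2 non-missing calls")
    rho1 = n1[usable] / nn[usable]
    h = 1.0 - rho1**2 - (1.0 - rho1) ** 2
    uh = nn[usable] / (nn[usable] - 1.0) * h
    poly = (n0 > 0) & (n1 > 0)
    return float(uh.mean()), float(100.0 * poly.sum() / calls.shape[1])


def group_diversity(g: GenotypeMatrix, group, label: str = "group") -> DiversityEstimate:
    """Single-pass uh and %P over a set of sample ids (no subsampling)."""
    group = list(group)
    if len(group) < 2:
        raise ValueError("group size must be >= 2")
    calls = g.take(group).calls
    uh, pct = _calls_diversity(calls, label)
    return DiversityEstimate(label, len(group), uh, pct)


def subsampled_diversity(
    ds: Dataset,
    population: str,
    category: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DiversityEstimate:
    """Population-level uh and %P from one-individual-per-colony draws.

    Each permutation draws one individual of ``category`` uniformly from
    every colony of ``population`` (independently across permutations) and
    computes uh and %P on the draw; the estimate is the mean over
    permutations with its SD.  Colonies lacking the category are dropped
    with a warning; fewer than two usable colonies is an error.
    """
    rng = np.random.default_rng(seed)
    meta = ds.metadata
    mask = (meta["population"] == population) & (meta["category"] == category)
    sub = meta[mask]
    pools: list[np.ndarray] = []
    for colony, csub in sub.groupby("colony"):
        pools.append(ds.genotypes.sample_index(list(csub.index)))
    all_colonies = meta[meta["population"] == population]["colony"].nunique()
    if len(pools) < all_colonies:
        logger.warning(
            "%s/%s: %d colonies lack the category and were dropped",
            population,
            category,
            all_colonies - len(pools),
        )
    if len(pools) < 2:
        raise ValueError(
            f"{population}/{category}: fewer than 2 colonies with this category"
        )
    calls = ds.genotypes.calls
    uhs = np.empty(n_perm)
    pcts = np.empty(n_perm)
    for k in range(n_perm):
        idx = [pool[rng.integers(len(pool))] for pool in pools]
        uhs[k], pcts[k] = _calls_diversity(calls[idx], f"{population}/{category}")
    return DiversityEstimate(
        group=f"{population}/{category}",
        n=len(pools),
        uh=float(uhs.mean()),
        pct_polymorphic=float(pcts.mean()),
        uh_sd=float(uhs.std(ddof=1)) if n_perm > 1 else 0.0,
        pct_polymorphic_sd=float(pcts.std(ddof=1)) if n_perm > 1 else 0.0,
        n_permutations=n_perm,
    )
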