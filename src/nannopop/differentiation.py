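"""Genetic differentiation for haploid data: AMOVA-based PhiPT.

PhiPT partitions the squared pairwise genetic distances into among- and
within-group molecular variance, analogously to F_ST but defined directly on
distances, which makes it applicable to haploid/binary genotypes.  With N
individuals in G groups of sizes n_g and squared distances d2:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    SS_among  = SS_total - SS_within
    MS        = SS / df,  df_among = G-1,  df_within = N-G
    sigma2_W  = MS_within
    sigma2_A  = (MS_among - MS_within) / n0,  n0 = (N - sum n_g^2 / N) / (G-1)
    PhiPT     = sigma2_A / (sigma2_A + sigma2_W)

PhiPT is not truncated at zero: when within-group distances exceed
between-group distances the estimate is negative.  Significance comes from
permuting individuals among groups; the p-value uses the
(exceedances + 1) / (permutations + 1) convention, so 999 permutations give
a minimum attainable p of 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import Dataset
from .dist_clone import DistanceMatrix, amova_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    phi_pt: float
    p_value: float | None
    n_permutations: int


@dataclass(frozen=True)
class SubsamplePhiSet:
    """PhiPT over repeated one-individual-per-colony subsamples."""

    category: str
    phi_values: np.ndarray
    results: list[AmovaResult]
    subsample_ids: list[list[str]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.phi_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.phi_values, ddof=1)) if len(self.phi_values) > 1 else 0.0


def _group_indices(sample_ids, groups) -> list[np.ndarray]:
    """Resolve a sample->group mapping into per-group index arrays."""
    labels = [groups[s] for s in sample_ids]
    uniq = sorted(set(labels))
    lab_arr = np.asarray(labels)
    return [np.flatnonzero(lab_arr == u) for u in uniq]


def _phi_from_groups(d2: np.ndarray, idx_groups: list[np.ndarray], consts) -> tuple[float, float, float, float, float]:
    """(phi, ss_among, ss_within, sigma2_a, sigma2_w) for one grouping."""
    N, G, ss_total, n0, df_among, df_within = consts
    ss_within = 0.0
    for idx in idx_groups:
        ss_within += d2[np.ix_(idx, idx)].sum() / 2.0 / len(idx)
    ss_among = ss_total - ss_within
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    s2w = ms_within
    s2a = (ms_among - ms_within) / n0
    denom = s2a + s2w
    phi = s2a / denom if denom > 0 else 0.0
    return phi, ss_among, ss_within, s2a, s2w


def amova_phipt(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA variance components and PhiPT with a permutation test.

    ``groups`` maps each sample id in ``d`` to a group label (dict-like or
    pandas Series).  ``n_perm = 0`` skips the test (``p_value = None``).
    If the total molecular variance is zero, PhiPT is defined as 0 with
    p = 1.

    The sums of squares are built from squared Euclidean distances.  For
    0/1 haplotypes the per-locus difference is 0 or 1, so the allele
    mismatch *count* already equals the squared Euclidean distance:
    ``count``-mode matrices enter the sums as-is, while any other mode is
    squared first.
    """
    ids = d.sample_ids
    N = d.n
    if d.undefined_pairs().any():
        raise ValueError("distance matrix has undefined pairs")
    idx_groups = _group_indices(ids, groups)
    G = len(idx_groups)
    if G < 2:
        raise ValueError("need at least two groups")
    if N - G < 1:
        raise ValueError("no within-group degrees of freedom")
    d2 = d.values if d.mode == "count" else d.values**2
    ss_total = d2.sum() / 2.0 / N
    sizes = np.array([len(ix) for ix in idx_groups], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / (G - 1)
    df_among, df_within = G - 1, N - G
    consts = (N, G, ss_total, n0, df_among, df_within)

    if ss_total <= 1e-12:
        return AmovaResult(
            df_among,
            df_within,
            0.0,
            0.0,
            0.0,
            0.0,
            0.0,
            0.0,
            1.0 if n_perm else None,
            n_perm,
        )

    phi, ss_a, ss_w, s2a, s2w = _phi_from_groups(d2, idx_groups, consts)

    p_value: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes_i = [len(ix) for ix in idx_groups]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            start = 0
            perm_groups = []
            for sz in sizes_i:
                perm_groups.append(perm[start : start + sz])
                start += sz
            phi_star = _phi_from_groups(d2, perm_groups, consts)[0]
            if phi_star >= phi - 1e-12:
                exceed += 1
        p_value = (exceed + 1) / (n_perm + 1)

    return AmovaResult(
        df_among, df_within, ss_a, ss_w, ss_total, s2a, s2w, phi, p_value, n_perm
    )


def phipt_between_colonies(
    ds: Dataset,
    population: str,
    category: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """PhiPT between colonies within one population, all individuals included."""
    ids = ds.samples_where(category=category, population=population)
    if len(ids) < 3:
        raise ValueError(f"too few {category} samples in {population}")
    d = amova_distance(ds.genotypes.take(ids))
    return amova_phipt(d, ds.metadata.loc[ids, "colony"], n_perm=n_perm, seed=seed)


def colony_subsample_phipt(
    ds: Dataset,
    category: str,
    n_subsamples: int = 5,
    n_perm: int = 0,
    seed: int | None = None,
) -> SubsamplePhiSet:
    """Between-population PhiPT over one-individual-per-colony subsamples.

    Individuals within colonies are not independent (clonal shoots, shared
    host), so each subsample takes exactly one individual of ``category``
    per colony; groups are the populations.  Subsamples are disjoint when
    the colony pool allows it (each colony's pool is shuffled once and
    consumed in order); exhausted pools are refilled with replacement and
    logged.
    """
    rng = np.random.default_rng(seed)
    meta = ds.metadata[ds.metadata["category"] == category]
    if meta.empty:
        raise ValueError(f"no samples of category {category!r}")
    pools: dict[str, list[str]] = {}
    for colony, sub in meta.groupby("colony"):
        ids = list(sub.index)
        order = rng.permutation(len(ids))
        pools[colony] = [ids[i] for i in order]
    short = [c for c, p in pools.items() if len(p) < n_subsamples]
    if short:
        logger.warning(
            "colony pools smaller than %d subsamples, reusing individuals: %s",
            n_subsamples,
            short,
        )
    results = []
    memberships: list[list[str]] = []
    for s in range(n_subsamples):
        chosen = []
        for colony in sorted(pools):
            pool = pools[colony]
            if s < len(pool):
                chosen.append(pool[s])
            else:
                chosen.append(pool[int(rng.integers(len(pool)))])
        chosen = [sid for sid in ds.sample_ids if sid in set(chosen)]
        d = amova_distance(ds.genotypes.take(chosen))
        res = amova_phipt(
            d,
            ds.metadata.loc[chosen, "population"],
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        results.append(res)
        memberships.append(chosen)
    phis = np.array([r.phi_pt for r in results])
    return SubsamplePhiSet(category, phis, results, memberships)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, df, two-sided p).

    Degenerate case: both samples constant with equal means gives t = 0,
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 values per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), float(
            len(x) + len(y) - 2
        ), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
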