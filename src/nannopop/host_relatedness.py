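"""Dwarf-male-to-female relatedness: GD profiles, paired tests, origin calls.

For every dwarf male three genetic distances (proportion of differing
alleles, pairwise deletion) are computed:

* ``gd_host`` — distance to its own host shoot;
* ``gd_col``  — mean distance to the other sampled female shoots of its
  colony (the four satellites under the standard design);
* ``gd_pop``  — mean distance to the sampled female shoots of its population
  outside its own colony (excluding the whole focal colony keeps the
  colony and population contrasts on disjoint female sets).

Restricted spore dispersal predicts gd_host < gd_col < gd_pop.  The paired
contrasts are tested with a sign-flip permutation test on the per-dwarf-male
differences, which respects the pairing and makes no distributional
assumptions; an optional colony-stratified variant flips whole colonies to
respect non-independence of dwarf males sharing a host.

:func:`assign_origin` names, for each dwarf male, the genetically nearest
sampled female and classifies her as host / own colony / own population /
other population — a simple putative-origin call; calls that one genotyping
error could overturn are flagged ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core_io import DWARF_MALE, FEMALE, Dataset
from .dist_clone import pairwise_genetic_distance

logger = logging.getLogger(__name__)

ORIGIN_PRIORITY = {"host": 0, "own_colony": 1, "own_population": 2, "other_population": 3}


@dataclass(frozen=True)
class PairedPermutationResult:
    """Mean paired difference with its sign-flip permutation p-value."""

    contrast: str
    mean_difference: float
    p_value: float
    n_pairs: int
    n_permutations: int
    exact: bool = False


def gd_profile(ds: Dataset) -> pd.DataFrame:
    """GD_HOST / GD_COL / GD_POP for every dwarf male.

    Returns a frame indexed by dwarf-male sample id with columns host_id,
    colony, population, gd_host, gd_col, gd_pop and the number of females
    averaged into each mean.  Undefined pairwise distances (no comparable
    locus) drop that female from the mean with a warning.
    """
    males = ds.samples_where(category=DWARF_MALE)
    females = ds.samples_where(category=FEMALE)
    if not males:
        raise ValueError("dataset has no dwarf males")
    d = pairwise_genetic_distance(ds.genotypes, mode="proportion")
    dv = d.to_frame()
    meta = ds.metadata
    fem_meta = meta.loc[females]
    rows = []
    for sid in males:
        host = meta.loc[sid, "host_id"]
        colony = meta.loc[sid, "colony"]
        pop = meta.loc[sid, "population"]
        col_females = fem_meta.index[(fem_meta["colony"] == colony) & (fem_meta.index != host)]
        pop_females = fem_meta.index[
            (fem_meta["population"] == pop) & (fem_meta["colony"] != colony)
        ]
        gd_host = dv.loc[sid, host]
        col_d = dv.loc[sid, col_females].astype(float)
        pop_d = dv.loc[sid, pop_females].astype(float)
        for name, vals in (("gd_col", col_d), ("gd_pop", pop_d)):
            if vals.isna().any():
                logger.warning(
                    "%s: %d undefined female distances dropped from %s",
                    sid,
                    int(vals.isna().sum()),
                    name,
                )
        rows.append(
            {
                "sample_id": sid,
                "host_id": host,
                "colony": colony,
                "population": pop,
                "gd_host": float(gd_host),
                "gd_col": float(col_d.mean(skipna=True)),
                "gd_pop": float(pop_d.mean(skipna=True)),
                "n_col_females": int(col_d.notna().sum()),
                "n_pop_females": int(pop_d.notna().sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


_CONTRASTS = {
    "host_vs_col": ("gd_host", "gd_col"),
    "col_vs_pop": ("gd_col", "gd_pop"),
}


def gd_compare(
    profile: pd.DataFrame,
    contrast: str = "host_vs_col",
    n_perm: int = 9999,
    seed: int | None = None,
    stratify_by_colony: bool = False,
) -> PairedPermutationResult:
    """Paired sign-flip permutation test of a GD contrast.

    The statistic is the mean over dwarf males of (first - second) for the
    chosen contrast.  The null distribution flips the sign of each
    difference independently (equivalently, swaps the two values within each
    dwarf male); with ``stratify_by_colony`` whole colonies flip together,
    which is conservative when dwarf males on one host are correlated.
    Two-sided p with the (exceedances + 1)/(permutations + 1) convention;
    fewer than 5 pairs triggers exact enumeration of all sign patterns.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    a, b = _CONTRASTS[contrast]
    diffs = (profile[a] - profile[b]).to_numpy(dtype=float)
    ok = np.isfinite(diffs)
    diffs = diffs[ok]
    n = diffs.size
    if n == 0:
        raise ValueError("no complete pairs")
    stat = float(diffs.mean())

    if stratify_by_colony:
        codes, _ = pd.factorize(profile.loc[ok, "colony"])
        n_units = codes.max() + 1
        unit_sums = np.zeros(n_units)
        np.add.at(unit_sums, codes, diffs)
        contributions = unit_sums
    else:
        contributions = diffs
    n_units = contributions.size

    if n_units < 5:
        # exact: all 2^k sign patterns
        exceed = 0
        total = 0
        for signs in product((-1.0, 1.0), repeat=n_units):
            s = float(np.dot(signs, contributions)) / n
            total += 1
            if abs(s) >= abs(stat) - 1e-15:
                exceed += 1
        return PairedPermutationResult(contrast, stat, exceed / total, n, total, True)

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_units))
    stats_star = signs @ contributions / n
    exceed = int(np.sum(np.abs(stats_star) >= abs(stat) - 1e-15))
    p = (exceed + 1) / (n_perm + 1)
    return PairedPermutationResult(contrast, stat, p, n, n_perm, False)


def assign_origin(ds: Dataset, margin_threshold: float | None = None) -> pd.DataFrame:
    """Putative origin of each dwarf male: its genetically nearest female.

    A spore carries alleles from both its mother and its father, so the
    nearest sampled female identifies a close relative of *either* parent;
    with outbred matings the call reflects the location of one parent, not
    necessarily the mother.

    Ties are resolved toward the most local candidate (host, then own
    colony, then own population, then other population), then the lowest
    sample id.  ``margin`` is the distance gap to the best female of any
    other category; calls with margin <= ``margin_threshold`` (default: one
    locus, 1/L) are flagged ambiguous.
    """
    if margin_threshold is None:
        margin_threshold = 1.0 / ds.genotypes.n_loci
    males = ds.samples_where(category=DWARF_MALE)
    females = ds.samples_where(category=FEMALE)
    d = pairwise_genetic_distance(ds.genotypes, mode="proportion")
    dv = d.to_frame().loc[males, females]
    meta = ds.metadata
    rows = []
    for sid in males:
        host = meta.loc[sid, "host_id"]
        colony = meta.loc[sid, "colony"]
        pop = meta.loc[sid, "population"]

        def category_of(fid: str) -> str:
            if fid == host:
                return "host"
            if meta.loc[fid, "colony"] == colony:
                return "own_colony"
            if meta.loc[fid, "population"] == pop:
                return "own_population"
            return "other_population"

        dists = dv.loc[sid]
        cand = [
            (float(dists[fid]), ORIGIN_PRIORITY[category_of(fid)], fid)
            for fid in females
            if np.isfinite(dists[fid])
        ]
        if not cand:
            raise ValueError(f"{sid}: no defined distance to any female")
        cand.sort()
        best_d, best_prio, best_id = cand[0]
        best_cat = category_of(best_id)
        others = [c for c in cand if category_of(c[2]) != best_cat]
        margin = (others[0][0] - best_d) if others else float("inf")
        rows.append(
            {
                "sample_id": sid,
                "nearest_female": best_id,
                "distance": best_d,
                "call": best_cat,
                "margin": margin,
                "ambiguous": bool(margin <= margin_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
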