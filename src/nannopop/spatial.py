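"""Spatial genetic structure: Loiselle kinship, geographic distances, Mantel.

The pairwise kinship coefficient F_ij estimates the correlation of allele
state between two individuals relative to the allele frequencies of a
reference group, with a small-sample bias correction.  For haploid biallelic
data with allele-1 indicator x_il and reference frequency pbar_l estimated
from n_l non-missing reference individuals, summing over both alleles
a in {0, 1} and over the loci called in both individuals:

    F_ij = [ sum_l sum_a (x_ila - pbar_la)(x_jla - pbar_la)
             + sum_l sum_a pbar_la (1 - pbar_la) / (n_l - 1) ]
           / sum_l sum_a pbar_la (1 - pbar_la)

(a ratio of multilocus sums, not an average of per-locus ratios).  Kinship
is expected to decay with geographic distance under restricted dispersal;
the association between the kinship matrix and the geographic distance
matrix is tested with a Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Dataset, GenotypeMatrix
from .dist_clone import DistanceMatrix


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship F_ij with its reference-frequency group."""

    sample_ids: list[str]
    values: np.ndarray
    reference: str

    def undefined_pairs(self) -> np.ndarray:
        out = ~np.isfinite(self.values)
        np.fill_diagonal(out, False)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_upper: float
    p_lower: float
    p_two_sided: float
    n_permutations: int


def loiselle_kinship(
    g: GenotypeMatrix,
    reference_group=None,
    reference_label: str = "all samples",
) -> KinshipMatrix:
    """Pairwise kinship for all samples in ``g``.

    ``reference_group`` (sample ids, default: all samples of ``g``) defines
    the per-locus allele frequencies pbar_l and sample sizes n_l.  Loci with
    fewer than two non-missing reference calls are excluded.  Only loci
    called in both members of a pair contribute to its sums; a pair whose
    comparable loci are all monomorphic in the reference has an undefined
    (NaN) kinship.
    """
    ids = list(g.sample_ids)
    ref_ids = ids if reference_group is None else list(reference_group)
    if len(ref_ids) < 3:
        raise ValueError("reference group needs at least 3 individuals")
    ref_calls = g.take(ref_ids).calls
    n_l = (ref_calls != -1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(n_l > 0, (ref_calls == 1).sum(axis=0) / np.maximum(n_l, 1), np.nan)
    usable = n_l >= 2
    # per-locus weights; the sum over both alleles doubles them
    w = np.where(usable, 2.0 * pbar * (1.0 - pbar), 0.0)
    bias = np.where(usable, w / np.maximum(n_l - 1.0, 1.0), 0.0)
    if not (w > 0).any():
        raise ValueError("no polymorphic locus in the reference group")

    calls = g.calls
    valid = ((calls != -1) & usable).astype(float)
    x = (calls == 1).astype(float)
    z = np.where(valid > 0, x - pbar, 0.0)
    # cross-products over jointly called loci (factor 2 = sum over alleles)
    num_cross = 2.0 * (z @ z.T)
    pair_bias = (valid * bias) @ valid.T
    denom = (valid * w) @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, (num_cross + pair_bias) / denom, np.nan)
    return KinshipMatrix(ids, vals, reference_label)


def geographic_distances(ds: Dataset, group=None) -> DistanceMatrix:
    """Planar Euclidean distances in metres between samples.

    Samples on the same host shoot share coordinates and are at distance 0.
    """
    ids = list(ds.sample_ids) if group is None else list(group)
    meta = ds.metadata.loc[ids]
    xy = meta[["x", "y"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        raise ValueError(f"sample {ids[int(np.flatnonzero(bad)[0])]!r} lacks coordinates")
    diff = xy[:, None, :] - xy[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(ids, vals, "metres")


def _matrix_values(m) -> np.ndarray:
    if isinstance(m, (DistanceMatrix, KinshipMatrix)):
        return m.values
    return np.asarray(m, dtype=float)


def mantel_test(
    A,
    B,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test of association between two square matrices.

    r is the Pearson correlation over the off-diagonal upper triangle.
    Permutations jointly relabel rows and columns of ``B``; all three tails
    are reported with the (exceedances + 1)/(permutations + 1) convention.
    Zero variance in either matrix gives r = NaN and p = 1.
    """
    a = _matrix_values(A)
    b = _matrix_values(B)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    av = a[iu]
    if av.std() == 0 or b[iu].std() == 0:
        return MantelResult(float("nan"), 1.0, 1.0, 1.0, n_perm)
    az = (av - av.mean()) / av.std()

    def corr(bm: np.ndarray) -> float:
        bv = bm[iu]
        return float(np.mean(az * (bv - bv.mean()) / bv.std()))

    r = corr(b)
    rng = np.random.default_rng(seed)
    ge = le = abs_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = corr(b[np.ix_(perm, perm)])
        if r_star >= r - 1e-12:
            ge += 1
        if r_star <= r + 1e-12:
            le += 1
        if abs(r_star) >= abs(r) - 1e-12:
            abs_ge += 1
    m1 = n_perm + 1
    return MantelResult(r, (ge + 1) / m1, (le + 1) / m1, (abs_ge + 1) / m1, n_perm)


def kinship_distance_mantel(
    ds: Dataset,
    category: str,
    population: str | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[int, MantelResult]:
    """Mantel test of kinship against geographic distance for one category.

    ``population=None`` analyses all populations together with reference
    frequencies from the whole category; otherwise the analysis and the
    reference frequencies are restricted to that population.  Returns the
    sample size and the Mantel result.
    """
    ids = ds.samples_where(category=category, population=population)
    if len(ids) < 4:
        raise ValueError("too few samples for a Mantel test")
    scope = population or "all populations"
    kin = loiselle_kinship(
        ds.genotypes.take(ids), reference_label=f"{category}/{scope}"
    )
    if kin.undefined_pairs().any():
        raise ValueError("kinship undefined for some pairs")
    geo = geographic_distances(ds, ids)
    return len(ids), mantel_test(kin, geo, n_perm=n_perm, seed=seed)
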