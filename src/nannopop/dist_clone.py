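"""Pairwise genetic distances, haplotype (clone) assignment, and PCoA.

Distances between haploid multilocus genotypes are allele mismatches under
pairwise deletion: only loci called in both samples are compared.  Two modes
are exposed — the raw mismatch ``count`` and the ``proportion`` of differing
alleles among comparable loci.  With pairwise deletion the proportion
distance need not satisfy the triangle inequality; this is reported by
:func:`triangle_violations`, not enforced.

Samples that match at every jointly called locus are treated as the same
haplotype (clone).  Because missing data make this relation non-transitive,
clones are the connected components of the zero-mismatch graph
(single linkage), which is the most inclusive deterministic completion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import Dataset, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance matrix.

    ``comparable[i, j]`` counts the loci called in both samples; where it is
    0 the distance is undefined and stored as NaN.  ``mode`` is ``count``
    (mismatch count), ``proportion`` (mismatches / comparable loci) or
    ``metres`` (geographic).
    """

    sample_ids: list[str]
    values: np.ndarray
    mode: str
    comparable: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite], self.values.T[finite], rtol=0, atol=1e-12
        ):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def undefined_pairs(self) -> np.ndarray:
        """Boolean matrix of pairs with no comparable locus."""
        if self.comparable is None:
            return ~np.isfinite(self.values)
        out = self.comparable == 0
        np.fill_diagonal(out, False)
        return out

    def submatrix(self, ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids], dtype=int)
        comp = None if self.comparable is None else self.comparable[np.ix_(idx, idx)]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.mode, comp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def _mismatch_and_comparable(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts and comparable-locus counts for all sample pairs.

    For 0/1 haploid calls the mismatch count between samples i and j is
    sum_l [x_i != x_j] over jointly called loci, computed as two rank-L
    matrix products.
    """
    valid = (g.calls != -1).astype(np.float64)
    ones = ((g.calls == 1).astype(np.float64)) * valid
    zeros = valid - ones
    mism = ones @ zeros.T + zeros @ ones.T
    comp = valid @ valid.T
    return np.rint(mism).astype(np.int64), np.rint(comp).astype(np.int64)


def pairwise_genetic_distance(g: GenotypeMatrix, mode: str = "proportion") -> DistanceMatrix:
    """Allele-mismatch distance between all sample pairs (pairwise deletion).

    ``mode='count'`` returns the raw number of differing loci;
    ``mode='proportion'`` divides by the per-pair comparable-locus count.
    Pairs sharing zero comparable loci get NaN.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    if mode not in ("count", "proportion"):
        raise ValueError(f"unknown mode {mode!r}")
    mism, comp = _mismatch_and_comparable(g)
    if mode == "count":
        vals = mism.astype(float)
        vals[comp == 0] = np.nan
    else:
        with np.errstate(invalid="ignore"):
            vals = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(g.sample_ids), vals, mode, comp)


def amova_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Mismatch-count distance rescaled to the full locus count.

    Pairwise-deletion counts are inflated by L / (comparable loci) so that
    pairs with missing data sit on the same scale as complete pairs; this
    keeps AMOVA sums of squares comparable across pairs.
    """
    mism, comp = _mismatch_and_comparable(g)
    L = g.n_loci
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(comp > 0, mism * (L / np.maximum(comp, 1)), np.nan)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(g.sample_ids), vals, "count", comp)


def triangle_violations(d: DistanceMatrix, tol: float = 1e-9) -> int:
    """Number of ordered triples violating d(i,k) <= d(i,j) + d(j,k)."""
    v = d.values
    n = d.n
    count = 0
    for j in range(n):
        through_j = v[:, [j]] + v[[j], :]
        bad = v > through_j + tol
        count += int(np.nansum(bad)) - int(np.nansum(np.diag(bad)))
    return count // 2


@dataclass
class CloneAssignment:
    """Partition of samples into clones (shared multilocus haplotypes).

    ``clone_of`` maps sample id -> clone id; the clone id is the
    lexicographically smallest member sample id, making the assignment
    invariant to input order.
    """

    clone_of: pd.Series
    members: dict[str, list[str]]

    @property
    def n_clones(self) -> int:
        return len(self.members)

    def sizes(self) -> pd.Series:
        return pd.Series({c: len(m) for c, m in self.members.items()}).sort_index()


def assign_clones(g: GenotypeMatrix) -> CloneAssignment:
    """Group samples that share a haplotype wherever both are called.

    Samples are linked when their mismatch count over jointly called loci is
    zero; clones are the connected components of this graph.  A pair with no
    jointly called locus matches vacuously and is linked.
    """
    if g.n_samples == 0:
        raise ValueError("no samples")
    mism, _comp = _mismatch_and_comparable(g)
    adj = csr_matrix(mism == 0)
    n_comp, labels = connected_components(adj, directed=False)
    members: dict[str, list[str]] = {}
    rep: dict[int, str] = {}
    for lab in range(n_comp):
        ids = [g.sample_ids[i] for i in np.flatnonzero(labels == lab)]
        rep[lab] = min(ids)
        members[rep[lab]] = sorted(ids)
    clone_of = pd.Series(
        {g.sample_ids[i]: rep[labels[i]] for i in range(g.n_samples)},
        name="clone_id",
    ).loc[g.sample_ids]
    return CloneAssignment(clone_of, dict(sorted(members.items())))


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    Axes are ordered by decreasing eigenvalue; axes with non-positive
    eigenvalues are dropped and excluded from the variance-explained
    denominator.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    variance_explained_pct: np.ndarray

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.variance_explained_pct)


def pcoa(d: DistanceMatrix, standardize: bool = False) -> PcoaResult:
    """Principal coordinates analysis (classical metric MDS).

    With ``standardize`` the distances are first divided by sqrt(n-1).  The
    (possibly standardized) distances are squared, double-centred
    (B = -1/2 J D2 J) and eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).
    """
    if d.undefined_pairs().any():
        raise ValueError("distance matrix has undefined pairs")
    n = d.n
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    vals = d.values / np.sqrt(n - 1) if standardize else d.values
    d2 = vals**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * abs(eigval[0])) if eigval.size else 0.0
    keep = eigval > tol
    if not keep.any():
        coords = pd.DataFrame(
            np.zeros((n, 1)), index=d.sample_ids, columns=["PCo1"]
        )
        return PcoaResult(coords, np.zeros(1), np.zeros(1))
    lam = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lam)
    cols = [f"PCo{k + 1}" for k in range(lam.size)]
    return PcoaResult(
        pd.DataFrame(coords, index=d.sample_ids, columns=cols),
        lam,
        100.0 * lam / lam.sum(),
    )


def clone_summary(ds: Dataset, category: str | None = None) -> pd.DataFrame:
    """Per-population haplotype counts and per-colony means for a category."""
    ids = ds.samples_where(category=category)
    if not ids:
        raise ValueError("no samples in selection")
    clones = assign_clones(ds.genotypes.take(ids)).clone_of
    meta = ds.metadata.loc[ids]
    rows = []
    for pop, msub in meta.groupby("population"):
        per_colony = [
            clones.loc[list(csub.index)].nunique()
            for _, csub in msub.groupby("colony")
        ]
        rows.append(
            {
                "population": pop,
                "n_samples": len(msub),
                "n_haplotypes": clones.loc[list(msub.index)].nunique(),
                "colony_mean_haplotypes": float(np.mean(per_colony)),
                "colony_sd_haplotypes": float(np.std(per_colony, ddof=1))
                if len(per_colony) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("population")
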