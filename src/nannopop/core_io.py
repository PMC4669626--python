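"""Data model and I/O for haploid SNP genotype tables with sampling metadata.

The native format is a single delimited text table with one row per sample:

    sample_id  category  population  colony  host_id  x  y  locus_1 ... locus_L

``category`` is ``female`` or ``dwarf_male`` (``sporophyte`` rows are skipped
on read); ``host_id`` names the female host shoot and is required exactly for
dwarf males; ``x``/``y`` are planar coordinates in metres.  Genotype calls are
arbitrary single-token allele labels (e.g. ``A``/``B`` or ``0``/``1``) with a
configurable missing token (default ``NA``).  Each locus is biallelic: calls
are coded internally to {0, 1} per locus, missing as -1, and the original
labels are retained so that writing reproduces the input byte for byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

FEMALE = "female"
DWARF_MALE = "dwarf_male"
CATEGORIES = (FEMALE, DWARF_MALE)

#: metadata columns preceding the locus columns in the native table
META_COLUMNS = ["sample_id", "category", "population", "colony", "host_id", "x", "y"]


class DataError(ValueError):
    """Malformed or inconsistent genotype/metadata content."""


@dataclass(frozen=True)
class Dialect:
    """Options controlling how the native table is parsed and written."""

    delimiter: str = "\t"
    missing_token: str = "NA"
    #: optional per-locus label to code as allele 0 (default: first seen)
    reference_alleles: dict[str, str] | None = None


@dataclass
class GenotypeMatrix:
    """Samples x loci haploid biallelic calls.

    ``calls`` holds 0/1 for the two alleles and -1 for missing.
    ``allele_labels[j]`` maps the internal codes of locus ``j`` back to the
    original tokens ``(label_for_0, label_for_1)``; a label is ``None`` when
    the corresponding allele was never observed at that locus.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    allele_labels: list[tuple[str | None, str | None]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.allele_labels is None:
            self.allele_labels = [("0", "1")] * len(self.locus_ids)
        self.validate()

    def validate(self) -> None:
        n, L = len(self.sample_ids), len(self.locus_ids)
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicated sample ids")
        if len(set(self.locus_ids)) != L:
            raise DataError("duplicated locus ids")
        if self.calls.shape != (n, L):
            raise DataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{n} samples x {L} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]}, locus {self.locus_ids[j]}"
            )
        if len(self.allele_labels) != L:
            raise DataError("allele_labels length differs from locus count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take(self, ids) -> "GenotypeMatrix":
        """Sub-matrix restricted to ``ids``, in the given order."""
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            self.calls[idx].copy(),
            list(self.allele_labels),
        )

    def labels_frame(self) -> pd.DataFrame:
        """Calls resolved to original allele labels (missing -> ``None``).

        Coding-invariant representation: two matrices that differ only in
        which observed allele is coded 0 resolve to the same frame.
        """
        out = {}
        for j, locus in enumerate(self.locus_ids):
            lab0, lab1 = self.allele_labels[j]
            col = np.where(
                self.calls[:, j] == 0, lab0, np.where(self.calls[:, j] == 1, lab1, None)
            )
            out[locus] = col
        return pd.DataFrame(out, index=pd.Index(self.sample_ids, name="sample_id"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and self.labels_frame().equals(other.labels_frame())
        )


def validate_metadata(meta: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Check the sampling-hierarchy invariants and return metadata indexed by sample.

    Enforces: category in {female, dwarf_male}; host_id present exactly for
    dwarf males and pointing at a female of the same colony; colony nested in
    exactly one population; coordinates numeric.
    """
    meta = meta.copy()
    if meta.index.name != "sample_id":
        meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise DataError(f"duplicated sample id {dup!r} in metadata")
    missing = set(sample_ids) - set(meta.index)
    extra = set(meta.index) - set(sample_ids)
    if missing or extra:
        raise DataError(
            f"metadata does not cover exactly the genotyped samples "
            f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
        )
    meta = meta.loc[sample_ids]

    bad_cat = ~meta["category"].isin(CATEGORIES)
    if bad_cat.any():
        sid = meta.index[bad_cat][0]
        raise DataError(f"sample {sid!r} has unknown category {meta.loc[sid, 'category']!r}")

    meta["x"] = pd.to_numeric(meta["x"])
    meta["y"] = pd.to_numeric(meta["y"])

    # one population per colony
    nest = meta.groupby("colony")["population"].nunique()
    if (nest > 1).any():
        raise DataError(f"colony {nest.idxmax()!r} spans more than one population")

    is_dm = meta["category"] == DWARF_MALE
    has_host = meta["host_id"].notna() & (meta["host_id"] != "")
    if (is_dm & ~has_host).any():
        sid = meta.index[is_dm & ~has_host][0]
        raise DataError(f"dwarf male {sid!r} has no host_id")
    if (~is_dm & has_host).any():
        sid = meta.index[~is_dm & has_host][0]
        raise DataError(f"female {sid!r} must not carry a host_id")
    for sid, host in meta.loc[is_dm, "host_id"].items():
        if host not in meta.index:
            raise DataError(f"dwarf male {sid!r}: host {host!r} absent from the dataset")
        if meta.loc[host, "category"] != FEMALE:
            raise DataError(f"dwarf male {sid!r}: host {host!r} is not a female")
        if meta.loc[host, "colony"] != meta.loc[sid, "colony"]:
            raise DataError(
                f"dwarf male {sid!r}: host {host!r} belongs to a different colony"
            )
    return meta


@dataclass
class Dataset:
    """A validated genotype matrix plus the metadata covering its samples."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = validate_metadata(self.metadata, self.genotypes.sample_ids)

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    def samples_where(
        self,
        category: str | None = None,
        population: str | None = None,
        colony: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given metadata filters, in dataset order."""
        mask = pd.Series(True, index=self.metadata.index)
        if category is not None:
            mask &= self.metadata["category"] == category
        if population is not None:
            mask &= self.metadata["population"] == population
        if colony is not None:
            mask &= self.metadata["colony"] == colony
        return list(self.metadata.index[mask])

    @property
    def populations(self) -> list[str]:
        return sorted(self.metadata["population"].unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.genotypes == other.genotypes and self.metadata.equals(other.metadata)


@dataclass(frozen=True)
class MissingnessReport:
    overall_rate: float
    per_sample_rate: pd.Series
    per_locus_rate: pd.Series

    @property
    def max_sample_rate(self) -> float:
        return float(self.per_sample_rate.max())

    @property
    def max_locus_rate(self) -> float:
        return float(self.per_locus_rate.max())


def read_dataset(path, dialect: Dialect = Dialect()) -> Dataset:
    """Read the native delimited table into a validated :class:`Dataset`.

    Allele tokens at each locus are mapped to internal codes {0, 1} in
    first-seen order, unless ``dialect.reference_alleles`` pins the token to
    code as 0.  Rows whose category is ``sporophyte`` are skipped (diploid
    samples from companion material fall outside the haploid analysis).
    """
    try:
        table = pd.read_csv(
            path, sep=dialect.delimiter, dtype=str, keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed table: {exc}") from exc
    for col in META_COLUMNS:
        if col not in table.columns:
            raise DataError(f"missing required column {col!r}")
    if list(table.columns[: len(META_COLUMNS)]) != META_COLUMNS:
        raise DataError(f"first columns must be {META_COLUMNS}")
    locus_ids = [c for c in table.columns if c not in META_COLUMNS]
    if not locus_ids:
        raise DataError("no locus columns found")

    table = table[table["category"] != "sporophyte"].reset_index(drop=True)

    sample_ids = list(table["sample_id"])
    n, L = len(sample_ids), len(locus_ids)
    calls = np.full((n, L), MISSING, dtype=np.int8)
    allele_labels: list[tuple[str | None, str | None]] = []
    ref = dialect.reference_alleles or {}
    for j, locus in enumerate(locus_ids):
        tokens = table[locus].to_numpy()
        seen: list[str] = [] if locus not in ref else [ref[locus]]
        for tok in tokens:
            if tok == dialect.missing_token or tok not in seen:
                if tok != dialect.missing_token:
                    seen.append(tok)
            if len(seen) > 2:
                raise DataError(f"locus {locus!r} has more than two alleles: {seen}")
        lab0 = seen[0] if len(seen) >= 1 else None
        lab1 = seen[1] if len(seen) >= 2 else None
        allele_labels.append((lab0, lab1))
        code = {lab: k for k, lab in enumerate(seen)}
        for i, tok in enumerate(tokens):
            if tok != dialect.missing_token:
                calls[i, j] = code[tok]

    meta = table[META_COLUMNS].copy()
    meta["host_id"] = meta["host_id"].replace({dialect.missing_token: None, "": None})
    geno = GenotypeMatrix(sample_ids, locus_ids, calls, allele_labels)
    return Dataset(geno, meta)


def write_dataset(ds: Dataset, path, dialect: Dialect = Dialect()) -> None:
    """Write a dataset back to the native table using the original allele labels."""
    g = ds.genotypes
    meta = ds.metadata.reset_index()
    out = meta[META_COLUMNS].copy()
    out["host_id"] = out["host_id"].fillna(dialect.missing_token)
    fr = g.labels_frame().reset_index(drop=True)
    for locus in g.locus_ids:
        out[locus] = fr[locus].where(fr[locus].notna(), dialect.missing_token)
    # coordinates: repr() keeps floats round-trippable
    out["x"] = out["x"].map(lambda v: format(float(v), "g"))
    out["y"] = out["y"].map(lambda v: format(float(v), "g"))
    csv = out.to_csv(sep=dialect.delimiter, index=False, lineterminator="\n")
    if isinstance(path, io.TextIOBase):
        path.write(csv)
    else:
        with open(path, "w") as fh:
            fh.write(csv)


def missingness_summary(ds: Dataset) -> MissingnessReport:
    """Fractions of missing calls overall and per sample / per locus."""
    g = ds.genotypes
    if g.n_samples == 0 or g.n_loci == 0:
        raise DataError("empty dataset")
    miss = g.missing_mask()
    return MissingnessReport(
        overall_rate=float(miss.mean()),
        per_sample_rate=pd.Series(miss.mean(axis=1), index=g.sample_ids),
        per_locus_rate=pd.Series(miss.mean(axis=0), index=g.locus_ids),
    )


def polymorphic_locus_count(ds: Dataset, group) -> int:
    """Number of loci with >=2 distinct non-missing alleles within ``group``.

    ``group`` is an iterable of sample ids.
    """
    group = list(group)
    if not group:
        raise DataError("empty sample selection")
    sub = ds.genotypes.take(group).calls
    has0 = (sub == 0).any(axis=0)
    has1 = (sub == 1).any(axis=0)
    return int((has0 & has1).sum())


def export_structure(ds: Dataset, path) -> None:
    """Write genotypes in one-row-per-haploid-individual STRUCTURE format.

    Columns: label, integer population index (dataset-order of first
    appearance), then one integer allele per locus (codes 1/2, missing -9).
    Output is byte-stable for a fixed dataset.
    """
    g = ds.genotypes
    pops: dict[str, int] = {}
    for p in ds.metadata["population"]:
        pops.setdefault(p, len(pops) + 1)
    lines = []
    for i, sid in enumerate(g.sample_ids):
        row = g.calls[i]
        alleles = np.where(row == MISSING, -9, row + 1)
        pop = pops[ds.metadata.loc[sid, "population"]]
        lines.append("\t".join([sid, str(pop), *map(str, alleles)]))
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def parse_structure(path) -> tuple[list[str], list[int], np.ndarray]:
    """Parse the STRUCTURE export back (labels, population indices, calls)."""
    labels: list[str] = []
    pops: list[int] = []
    rows: list[list[int]] = []
    fh = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            pops.append(int(parts[1]))
            rows.append([MISSING if t == "-9" else int(t) - 1 for t in parts[2:]])
    finally:
        if fh is not path:
            fh.close()
    return labels, pops, np.array(rows, dtype=np.int8)
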