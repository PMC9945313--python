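"""Data model, TSV/Newick readers and writers, and cohort validation.

All tabular formats are UTF-8, tab-delimited, "." decimal. Count tables are
taxa-by-samples with the taxon identifier in the first column and an optional
``lineage`` column holding a ";"-separated rank string (phylum -> species,
rank prefixes such as ``f__`` allowed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "CountTable",
    "CohortMetadata",
    "PhyloTree",
    "PhenotypeTable",
    "QpcrTable",
    "ValidationReport",
    "RANKS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "read_phenotypes",
    "write_phenotypes",
    "read_qpcr",
    "write_qpcr",
    "validate_cohort",
    "lineage_at_rank",
]

RANKS = ("phylum", "class", "order", "family", "genus", "species")

METADATA_COLUMNS = ("sample_id", "animal_id", "sex", "treatment", "timepoint", "cage_id")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "d__")


class ValidationError(ValueError):
    """Raised when a parsed structure violates a model invariant."""


@dataclass
class CountTable:
    """Integer taxa-by-samples count matrix with lineage labels.

    Attributes
    ----------
    taxon_ids : list of str
        Unique taxon identifiers (row order preserved from input).
    lineages : list of str
        ";"-separated lineage strings, one per taxon. May equal the id.
    sample_ids : list of str
        Unique sample identifiers (column order preserved).
    counts : numpy.ndarray
        Non-negative integer matrix of shape (n_taxa, n_samples).
    """

    taxon_ids: list[str]
    lineages: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(self.lineages) != len(self.taxon_ids):
            raise ValidationError("one lineage required per taxon")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="taxon_id"),
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.taxon_ids, self.lineages, list(sample_ids),
                          self.counts[:, idx].copy())

    def subset_taxa(self, taxon_ids: list[str]) -> "CountTable":
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in taxon_ids]
        return CountTable(list(taxon_ids), [self.lineages[i] for i in idx],
                          self.sample_ids, self.counts[idx, :].copy())


@dataclass
class CohortMetadata:
    """Per-sample design descriptors enabling paired pre/post lookup."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        f = self.frame
        if f["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        bad_sex = set(f["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"sex values must be F/M, got {sorted(bad_sex)}")
        bad_trt = set(f["treatment"]) - {"live", "HK"}
        if bad_trt:
            raise ValidationError(f"treatment values must be live/HK, got {sorted(bad_trt)}")
        bad_tp = set(f["timepoint"]) - {"pre", "post"}
        if bad_tp:
            raise ValidationError(f"timepoint values must be pre/post, got {sorted(bad_tp)}")
        dup = f.duplicated(subset=["animal_id", "timepoint"])
        if dup.any():
            raise ValidationError(
                f"animal(s) with more than one sample at a timepoint: "
                f"{sorted(set(f.loc[dup, 'animal_id']))}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching equality conditions on metadata columns."""
        mask = pd.Series(True, index=self.frame.index)
        for key, value in conditions.items():
            mask &= self.frame[key] == value
        return list(self.frame.loc[mask, "sample_id"])

    def animals_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        for key, value in conditions.items():
            mask &= self.frame[key] == value
        return sorted(set(self.frame.loc[mask, "animal_id"]))

    def sample_for(self, animal_id: str, timepoint: str) -> str | None:
        sel = self.frame[(self.frame["animal_id"] == animal_id)
                         & (self.frame["timepoint"] == timepoint)]
        if sel.empty:
            return None
        return sel["sample_id"].iloc[0]

    def animal_info(self) -> pd.DataFrame:
        """One row per animal with sex/treatment/cage."""
        return (self.frame[["animal_id", "sex", "treatment", "cage_id"]]
                .drop_duplicates(subset="animal_id")
                .set_index("animal_id"))

    def labels_for(self, sample_ids: list[str], column: str) -> list[str]:
        lookup = self.frame.set_index("sample_id")[column]
        return [lookup[s] for s in sample_ids]


@dataclass
class PhyloTree:
    """Rooted phylogeny over taxon ids with non-negative branch lengths."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf labels in tree")
        for node in self.tree.traverse(include_self=False):
            length = node.length if node.length is not None else 0.0
            if not np.isfinite(length) or length < 0:
                raise ValidationError(f"invalid branch length {node.length!r}")

    def leaf_names(self) -> list[str]:
        return [tip.name for tip in self.tree.tips()]

    def total_length(self) -> float:
        return sum((n.length or 0.0) for n in self.tree.traverse(include_self=False))

    def require_leaves(self, taxon_ids) -> None:
        missing = set(taxon_ids) - set(self.leaf_names())
        if missing:
            raise ValidationError(f"taxa absent from tree: {sorted(missing)[:5]}")

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class PhenotypeTable:
    """Per-animal continuous phenotypes; NaN marks missing values."""

    frame: pd.DataFrame  # index animal_id, columns phenotype names

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate animal ids in phenotype table")
        self.frame.index.name = "animal_id"

    @property
    def phenotypes(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, phenotype: str, animal_ids: list[str]) -> np.ndarray:
        return self.frame.reindex(animal_ids)[phenotype].to_numpy(dtype=float)


@dataclass
class QpcrTable:
    """Long-format qPCR Ct table: one row per (animal, timepoint, assay)."""

    frame: pd.DataFrame  # columns animal_id, timepoint, assay, ct_target, ct_reference

    REQUIRED = ("animal_id", "timepoint", "assay", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"qPCR table missing columns: {missing}")
        ct = self.frame[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.isfinite(ct).all():
            raise ValidationError("non-finite Ct value in qPCR table")
        if self.frame.duplicated(subset=["animal_id", "timepoint", "assay"]).any():
            raise ValidationError("duplicate (animal, timepoint, assay) rows")

    def assays(self) -> list[str]:
        return sorted(set(self.frame["assay"]))


@dataclass
class ValidationReport:
    """Cohort design findings; empty iff the design is complete."""

    unpaired_animals: list[str] = field(default_factory=list)
    missing_cells: list[tuple[str, str, str]] = field(default_factory=list)
    orphan_samples: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.unpaired_animals or self.missing_cells
                    or self.orphan_samples or self.messages)

    def summary(self) -> str:
        if self.is_empty:
            return "cohort OK"
        lines = []
        if self.unpaired_animals:
            lines.append(f"unpaired animals: {', '.join(self.unpaired_animals)}")
        if self.missing_cells:
            lines.append("missing design cells: "
                         + "; ".join("x".join(c) for c in self.missing_cells))
        if self.orphan_samples:
            lines.append(f"orphan samples: {', '.join(self.orphan_samples)}")
        lines.extend(self.messages)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# lineage helpers

def _strip_prefix(token: str) -> str:
    token = token.strip()
    for p in _RANK_PREFIXES:
        if token.startswith(p):
            return token[len(p):]
    return token


def lineage_at_rank(lineage: str, rank: str) -> str:
    """Truncate a ";"-separated lineage at ``rank``.

    Ranks run phylum -> species. When the lineage is unclassified at the
    requested rank, the deepest classified rank is kept and marked
    ``unclassified``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    tokens = [_strip_prefix(t) for t in lineage.split(";")]
    tokens = [t for t in tokens if t]
    if len(tokens) >= depth:
        return ";".join(tokens[:depth])
    return ";".join(tokens) + ";unclassified"


# ---------------------------------------------------------------------------
# readers / writers

def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a taxa-by-samples TSV into a :class:`CountTable`.

    First column is the taxon id; a column named ``lineage`` (if present)
    carries the rank string; all remaining columns are integer counts.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("count table needs a taxon column and >=1 sample column")
    taxon_col = df.columns[0]
    taxon_ids = df[taxon_col].astype(str).tolist()
    if "lineage" in df.columns[1:]:
        lineages = df["lineage"].astype(str).tolist()
        sample_cols = [c for c in df.columns[1:] if c != "lineage"]
    else:
        lineages = list(taxon_ids)
        sample_cols = list(df.columns[1:])
    counts = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"malformed numeric cell {cell!r} at row {taxon_ids[i]!r}, "
                    f"column {col!r}") from None
            if value != int(value):
                raise ValidationError(
                    f"non-integral count {cell!r} at row {taxon_ids[i]!r}, column {col!r}")
            counts[i, j] = int(value)
    return CountTable(taxon_ids, lineages, sample_cols, counts)


def write_count_table(table: CountTable, path) -> None:
    df = table.to_dataframe().reset_index()
    if table.lineages != table.taxon_ids:
        df.insert(1, "lineage", table.lineages)
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> CohortMetadata:
    return CohortMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: CohortMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_newick(path) -> PhyloTree:
    """Parse a rooted Newick tree with branch lengths."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.frame.to_csv(path, sep="\t")


def read_qpcr(path) -> QpcrTable:
    return QpcrTable(pd.read_csv(path, sep="\t"))


def write_qpcr(qpcr: QpcrTable, path) -> None:
    qpcr.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation

def validate_cohort(table: CountTable, meta: CohortMetadata,
                    n_per_cell: int | None = None) -> ValidationReport:
    """Report design problems without raising.

    Lists samples in the table absent from metadata, animals missing a pre or
    post sample, and (when ``n_per_cell`` is given) sex-by-treatment cells
    with fewer animals than expected.
    """
    report = ValidationReport()
    known = set(meta.sample_ids)
    report.orphan_samples = [s for s in table.sample_ids if s not in known]

    in_table = set(table.sample_ids)
    f = meta.frame[meta.frame["sample_id"].isin(in_table)]
    for animal_id, grp in f.groupby("animal_id"):
        tps = set(grp["timepoint"])
        if tps != {"pre", "post"}:
            report.unpaired_animals.append(str(animal_id))
    report.unpaired_animals.sort()

    for sex in ("F", "M"):
        for trt in ("live", "HK"):
            for tp in ("pre", "post"):
                cell = f[(f["sex"] == sex) & (f["treatment"] == trt)
                         & (f["timepoint"] == tp)]
                n = cell["animal_id"].nunique()
                if n == 0 or (n_per_cell is not None and n < n_per_cell):
                    report.missing_cells.append((sex, trt, tp))
    return report
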