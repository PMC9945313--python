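"""Median-of-ratios size factors, relative abundance, and abundance quartiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CountTable, CohortMetadata, lineage_at_rank

__all__ = [
    "SizeFactors",
    "QuartileAnnotation",
    "size_factors",
    "normalize",
    "relative_abundance",
    "abundance_quartiles",
]

logger = logging.getLogger(__name__)


@dataclass
class SizeFactors:
    """Per-sample scaling constants from the median-of-ratios method."""

    factors: pd.Series  # index sample_id, values > 0
    used_pseudo_reference: bool = False

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("size factors must be finite and > 0")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])

    def to_frame(self) -> pd.DataFrame:
        return self.factors.rename("size_factor").rename_axis("sample_id").reset_index()


@dataclass
class QuartileAnnotation:
    """Per-taxon abundance quartile (4 = most abundant) of mean pre-treatment raw counts."""

    quartiles: pd.Series  # index taxon_id, values in {1,2,3,4}

    def __getitem__(self, taxon_id: str) -> int:
        return int(self.quartiles[taxon_id])


def size_factors(table: CountTable, allow_pseudo_reference: bool = True) -> SizeFactors:
    """Median-of-ratios size factors.

    Reference taxa are those with nonzero counts in every sample; for each
    sample the factor is the median over reference taxa of
    count / per-taxon geometric mean. When no taxon is ubiquitous, a +0.5
    pseudocount on the whole table substitutes for the reference set (logged),
    unless ``allow_pseudo_reference`` is False.
    """
    counts = table.counts.astype(float)
    all_nonzero = (counts > 0).all(axis=1)
    used_pseudo = False
    if all_nonzero.any():
        ref = counts[all_nonzero]
    elif allow_pseudo_reference:
        ref = counts + 0.5
        used_pseudo = True
        logger.warning(
            "no taxon has nonzero counts in all %d samples; "
            "falling back to +0.5 pseudocount reference", len(table.sample_ids))
    else:
        raise ValueError(
            "no reference taxon with nonzero counts in every sample; the table "
            "is too sparse for plain median-of-ratios (enable the pseudo-"
            "reference fallback or filter samples)")
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    series = pd.Series(factors, index=table.sample_ids, dtype=float)
    return SizeFactors(series, used_pseudo_reference=used_pseudo)


def normalize(table: CountTable, s: SizeFactors) -> pd.DataFrame:
    """Divide each sample column by its size factor; returns a real-valued frame."""
    missing = [sid for sid in table.sample_ids if sid not in s.factors.index]
    if missing:
        raise ValueError(f"size factors missing for samples: {missing}")
    df = table.to_dataframe().astype(float)
    return df / s.factors.reindex(df.columns).to_numpy()


def relative_abundance(table: CountTable, meta: CohortMetadata,
                       group_by: list[str], rank: str,
                       prune_below: float = 0.01) -> pd.DataFrame:
    """Per-group relative abundance agglomerated to ``rank``.

    Samples are merged (counts summed) per group defined by the metadata keys,
    each group's counts are converted to fractions summing to 1, taxa are
    agglomerated to the requested rank, and taxa whose total fraction summed
    across groups is below ``prune_below`` are dropped.
    """
    lookup = meta.frame.set_index("sample_id")
    group_labels = {}
    for sid in table.sample_ids:
        if sid not in lookup.index:
            raise ValueError(f"sample {sid!r} absent from metadata")
        group_labels[sid] = "/".join(str(lookup.loc[sid, k]) for k in group_by)

    glom = [lineage_at_rank(lin, rank) for lin in table.lineages]
    df = pd.DataFrame(table.counts.astype(float), index=glom, columns=table.sample_ids)
    merged = df.T.groupby(pd.Series(group_labels)).sum().T  # rank-taxa x groups
    merged = merged.groupby(level=0, sort=False).sum()
    fractions = merged / merged.sum(axis=0)
    keep = fractions.sum(axis=1) >= prune_below
    return fractions.loc[keep]


def abundance_quartiles(pre_table: CountTable) -> QuartileAnnotation:
    """Quartile labels 1-4 from mean raw counts across pre-treatment samples.

    Quartile 4 holds the most abundant taxa. Ties are broken by the stable
    input taxon order so the partition is deterministic.
    """
    if len(pre_table.taxon_ids) == 0:
        raise ValueError("empty count table")
    means = pre_table.counts.mean(axis=1)
    order = np.argsort(means, kind="stable")
    n = len(means)
    labels = np.empty(n, dtype=int)
    positions = np.arange(n)
    labels[order] = positions * 4 // n + 1
    return QuartileAnnotation(pd.Series(labels, index=pre_table.taxon_ids))
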