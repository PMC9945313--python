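"""Prevalence-filtered Spearman correlations with Fisher-transform CIs and a
community-level significance gate.

Per-taxon correlations are only reported when the community as a whole shows
more nonzero-CI correlations than the CI's alpha would produce by chance:
at level 0.95 the fraction of taxa whose CI excludes zero must exceed 0.05
(0.01 at 0.99) for the phenotype's correlations to stand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CountTable, CohortMetadata, PhenotypeTable, QpcrTable

__all__ = [
    "GatedCorrelations",
    "prevalence_filter",
    "spearman_rho",
    "bonett_wright_ci",
    "community_gate",
    "correlate_features",
]


@dataclass
class GatedCorrelations:
    """Per-taxon correlations against one phenotype with the community verdict."""

    phenotype: str
    frame: pd.DataFrame  # index (taxon, feature_kind); rho, n, ci bounds, flags
    verdict95: bool = False
    verdict99: bool = False
    fraction_nonzero95: float = 0.0
    fraction_nonzero99: float = 0.0
    significant95: list = field(default_factory=list)
    significant99: list = field(default_factory=list)


def prevalence_filter(table: CountTable, min_frac: float = 0.10) -> CountTable:
    """Keep taxa with nonzero counts in at least ceil(min_frac * n) samples."""
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must lie in (0, 1]")
    need = math.ceil(min_frac * len(table.sample_ids))
    nonzero = (table.counts > 0).sum(axis=1)
    keep = [t for t, nz in zip(table.taxon_ids, nonzero) if nz >= need]
    return table.subset_taxa(keep)


def spearman_rho(x, y) -> tuple[float, int]:
    """Spearman rho via Pearson correlation of mid-ranks.

    Pairs with a missing value are dropped; returns (rho, n_pairs). A
    constant vector yields (nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), n
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, n


def bonett_wright_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-transform CI for Spearman's rho with SE sqrt((1+rho^2/2)/(n-3))."""
    if n <= 3:
        raise ValueError("need n >= 4 for a CI")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    z = np.arctanh(rho)
    se = np.sqrt((1.0 + rho ** 2 / 2.0) / (n - 3))
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - z_crit * se)), float(np.tanh(z + z_crit * se))


def community_gate(rhos: pd.DataFrame, level: float = 0.95):
    """Community-level verdict over per-taxon correlations.

    ``rhos`` needs columns ``rho`` and ``n``. A taxon is flagged when its CI
    at ``level`` excludes zero; the verdict is true when the flagged fraction
    exceeds the CI alpha (1 - level). When the verdict is false the
    significant-taxa list is emptied: individual correlations are rejected.

    Returns (verdict, fraction_nonzero, significant_index_list, flags).
    """
    flags = []
    for _, row in rhos.iterrows():
        rho, n = row["rho"], int(row["n"])
        if not np.isfinite(rho) or abs(rho) >= 1.0:
            flags.append(bool(np.isfinite(rho)))  # |rho| == 1 always excludes 0
            continue
        lo, hi = bonett_wright_ci(rho, n, level)
        flags.append(lo > 0 or hi < 0)
    flags = pd.Series(flags, index=rhos.index, dtype=bool)
    if len(flags) == 0:
        raise ValueError("no defined rho values")
    fraction = float(flags.mean())
    verdict = fraction > (1.0 - level)
    significant = list(flags.index[flags]) if verdict else []
    return verdict, fraction, significant, flags


def _feature_matrix(table: CountTable, meta: CohortMetadata,
                    features: tuple[str, ...], pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-animal taxon features: post-treatment abundance and/or paired log2fc.

    Rows are (taxon, feature_kind); columns are animal ids. Abundances are
    relative within each sample to remove depth differences.
    """
    rel = table.counts / table.counts.sum(axis=0, keepdims=True)
    rel = pd.DataFrame(rel, index=table.taxon_ids, columns=table.sample_ids)
    scaled = rel * 1e4  # depth-free pseudo-counts so the pseudocount is comparable
    animals = meta.animals_where()
    blocks = {}
    for kind in features:
        cols = {}
        for a in animals:
            pre = meta.sample_for(a, "pre")
            post = meta.sample_for(a, "post")
            if kind == "post_abundance":
                if post in rel.columns:
                    cols[a] = rel[post]
            elif kind == "log2fc":
                if pre in rel.columns and post in rel.columns:
                    cols[a] = np.log2((scaled[post] + pseudocount)
                                      / (scaled[pre] + pseudocount))
            else:
                raise ValueError(f"unknown feature kind {kind!r}")
        blocks[kind] = pd.DataFrame(cols)
    out = pd.concat(blocks, names=["feature_kind", "taxon"])
    return out.swaplevel().sort_index()


def correlate_features(table: CountTable, phenotypes: PhenotypeTable,
                       meta: CohortMetadata, qpcr: QpcrTable | None = None,
                       qpcr_assay: str | None = None,
                       features: tuple[str, ...] = ("post_abundance", "log2fc"),
                       levels: tuple[float, ...] = (0.95, 0.99),
                       ) -> dict[str, GatedCorrelations]:
    """Gated Spearman correlations of taxon features against each phenotype.

    When a qPCR table and assay are supplied, the assay's per-animal
    post-treatment dCt-derived abundance (2^-dCt_post) and ddCt fold change
    are appended as extra phenotype columns.
    """
    feats = _feature_matrix(table, meta, features)
    pheno = phenotypes.frame.copy()
    if qpcr is not None and qpcr_assay is not None:
        from .cohort_stats import ddct_fold_change
        res = ddct_fold_change(qpcr, qpcr_assay, meta)
        pheno[f"{qpcr_assay}_post"] = (2.0 ** -res.per_animal["dct_post"]).reindex(pheno.index)
        pheno[f"{qpcr_assay}_log2fc"] = (-res.per_animal["ddct"]).reindex(pheno.index)

    shared = [a for a in feats.columns if a in pheno.index]
    if not shared:
        raise ValueError("no shared animal ids between feature and phenotype tables")
    feats = feats[shared]

    results = {}
    for phenotype in pheno.columns:
        y = pheno.loc[shared, phenotype].to_numpy(dtype=float)
        rows = []
        for (taxon, kind), x in feats.iterrows():
            try:
                rho, n = spearman_rho(x.to_numpy(dtype=float), y)
            except ValueError:
                continue
            row = {"taxon": taxon, "feature_kind": kind, "rho": rho, "n": n}
            for level in levels:
                tag = f"{level:.2f}".replace("0.", "")
                if np.isfinite(rho) and abs(rho) < 1.0:
                    lo, hi = bonett_wright_ci(rho, n, level)
                elif np.isfinite(rho):
                    lo = hi = rho
                else:
                    lo = hi = float("nan")
                row[f"ci{tag}_lo"], row[f"ci{tag}_hi"] = lo, hi
            rows.append(row)
        frame = pd.DataFrame(rows).set_index(["taxon", "feature_kind"])
        defined = frame[np.isfinite(frame["rho"])]
        gated = GatedCorrelations(phenotype, frame)
        if not defined.empty:
            v95, f95, sig95, flags95 = community_gate(defined, 0.95)
            v99, f99, sig99, flags99 = community_gate(defined, 0.99)
            frame["flag95"] = flags95.reindex(frame.index, fill_value=False)
            frame["flag99"] = flags99.reindex(frame.index, fill_value=False)
            gated.verdict95, gated.fraction_nonzero95, gated.significant95 = v95, f95, sig95
            gated.verdict99, gated.fraction_nonzero99, gated.significant99 = v99, f99, sig99
        results[phenotype] = gated
    return results


def wide_table(results: dict[str, GatedCorrelations], level: float = 0.95,
               decimals: int = 1) -> pd.DataFrame:
    """Publication-style wide layout: rows (taxon, feature kind), columns
    phenotypes, entries rho rounded to ``decimals``; only gated-in cells."""
    flag_col = "flag95" if level == 0.95 else "flag99"
    columns = {}
    for phenotype, res in results.items():
        verdict = res.verdict95 if level == 0.95 else res.verdict99
        if not verdict or flag_col not in res.frame:
            continue
        sub = res.frame[res.frame[flag_col]]
        columns[phenotype] = sub["rho"].round(decimals)
    if not columns:
        return pd.DataFrame()
    return pd.DataFrame(columns)
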