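"""Per-animal paired differential representation ("vole-by-vole") and a
whole-group negative-binomial test with BH-FDR.

The per-animal route selects taxa whose paired pre-to-post log2 fold changes
satisfy two criteria simultaneously: a supermajority of animals individually
cross a per-animal threshold in the same direction, and the group mean over
ALL animals crosses a (larger) average threshold in that direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CountTable, CohortMetadata
from .normalization import QuartileAnnotation

__all__ = [
    "PairedLog2FC",
    "VBVCriteria",
    "VBVResult",
    "GroupTestResult",
    "paired_log2fc",
    "vbv_select",
    "group_test",
    "posttreatment_contrast",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedLog2FC:
    """Per-animal pre-to-post log2 fold changes on normalized counts.

    ``values`` is taxa x animals; ``animal_info`` maps animal_id to its
    (sex, treatment) grouping keys.
    """

    values: pd.DataFrame
    animal_info: pd.DataFrame  # index animal_id; columns sex, treatment
    pseudocount: float

    def animals_in(self, sex: str, treatment: str) -> list[str]:
        info = self.animal_info
        mask = (info["sex"] == sex) & (info["treatment"] == treatment)
        return [a for a in self.values.columns if a in info.index[mask]]


@dataclass
class VBVCriteria:
    """Selection thresholds for the per-animal procedure.

    Defaults follow the printed rule: individual |log2fc| >= 0.693 for a
    supermajority of 5 of 8 animals in the same direction, and group-average
    |log2fc| >= 1.25 over all animals. ``family_display_avg`` is the stricter
    average used when reporting family-level changes.
    """

    theta_ind: float = 0.693
    theta_avg: float = 1.25
    supermajority: int = 5
    group_size: int = 8
    family_display_avg: float = 1.8

    def __post_init__(self) -> None:
        if self.theta_ind < 0 or self.theta_avg < 0:
            raise ValueError("thresholds must be non-negative")
        if self.supermajority > self.group_size:
            raise ValueError("supermajority cannot exceed group size")

    def supermajority_for(self, n_animals: int) -> int:
        """Scale the 5-of-8 fraction to other group sizes (ceiling)."""
        if n_animals == self.group_size:
            return self.supermajority
        return math.ceil(self.supermajority / self.group_size * n_animals)


@dataclass
class VBVResult:
    """Selected taxa with direction, supermajority count, mean log2fc, quartile."""

    frame: pd.DataFrame  # index taxon_id; direction, n_supermajority, mean_log2fc, quartile
    group: tuple[str, str]
    criteria: VBVCriteria
    n_animals: int = 0

    @property
    def selected(self) -> list[str]:
        return list(self.frame.index)


def paired_log2fc(norm_table: pd.DataFrame, meta: CohortMetadata,
                  pseudocount: float = 0.5) -> PairedLog2FC:
    """log2((post + c) / (pre + c)) per animal and taxon on normalized counts.

    Animals missing either timepoint are excluded with a logged warning.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    info = meta.animal_info()
    cols = {}
    for animal_id in info.index:
        pre = meta.sample_for(animal_id, "pre")
        post = meta.sample_for(animal_id, "post")
        if (pre not in norm_table.columns) or (post not in norm_table.columns):
            logger.warning("animal %s lacks a pre or post sample; excluded", animal_id)
            continue
        cols[animal_id] = np.log2((norm_table[post] + pseudocount)
                                  / (norm_table[pre] + pseudocount))
    values = pd.DataFrame(cols)
    values.index = norm_table.index
    return PairedLog2FC(values, info.loc[list(cols)], pseudocount)


def vbv_select(l: PairedLog2FC, group: tuple[str, str],
               criteria: VBVCriteria | None = None,
               quartiles: QuartileAnnotation | None = None) -> VBVResult:
    """Apply the supermajority + group-average selection within one
    sex-by-treatment group.

    A taxon is selected upward when at least ``supermajority`` animals have
    log2fc >= theta_ind AND the mean over all group animals is >= theta_avg;
    the downward case is the mirror image. The supermajority must agree in
    direction with the mean.
    """
    criteria = criteria or VBVCriteria()
    sex, treatment = group
    animals = l.animals_in(sex, treatment)
    if len(animals) < criteria.supermajority:
        raise ValueError(
            f"group {group} has {len(animals)} animals; fewer than the "
            f"required supermajority {criteria.supermajority}")
    need = criteria.supermajority_for(len(animals))
    sub = l.values[animals]
    mean = sub.mean(axis=1)
    n_up = (sub >= criteria.theta_ind).sum(axis=1)
    n_down = (sub <= -criteria.theta_ind).sum(axis=1)

    up = (n_up >= need) & (mean >= criteria.theta_avg)
    down = (n_down >= need) & (mean <= -criteria.theta_avg)

    records = []
    for taxon in l.values.index:
        if up[taxon]:
            direction, n_sup = "up", int(n_up[taxon])
        elif down[taxon]:
            direction, n_sup = "down", int(n_down[taxon])
        else:
            continue
        records.append({
            "taxon_id": taxon,
            "direction": direction,
            "n_supermajority": n_sup,
            "mean_log2fc": float(mean[taxon]),
            "quartile": quartiles[taxon] if quartiles is not None else pd.NA,
        })
    frame = pd.DataFrame(records, columns=["taxon_id", "direction", "n_supermajority",
                                           "mean_log2fc", "quartile"])
    frame = frame.set_index("taxon_id")
    return VBVResult(frame, group, criteria, n_animals=len(animals))


# ---------------------------------------------------------------------------
# whole-group test

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class GroupTestResult:
    """Per-taxon group-level estimates with BH adjustment.

    ``passes`` requires padj < alpha_adj AND |log2fc| >= min_abs_l2fc.
    """

    frame: pd.DataFrame  # index taxon_id; log2fc, p, padj, passes
    contrast: str
    alpha_adj: float
    min_abs_l2fc: float

    @property
    def passing(self) -> list[str]:
        return list(self.frame.index[self.frame["passes"]])


def _nb_wald(a: np.ndarray, b: np.ndarray, pseudocount: float,
             shrink_weight: float = 0.35):
    """Simplified per-taxon negative-binomial Wald test on normalized counts.

    Dispersion is method-of-moments from within-group residuals, shrunk toward
    the across-taxa median by a fixed weight; p-values use a t reference with
    n_a + n_b - 2 degrees of freedom. This is an approximation calibrated by
    simulation, not a replica of any particular tool.
    """
    n_a, n_b = a.shape[1], b.shape[1]
    m_a = a.mean(axis=1)
    m_b = b.mean(axis=1)
    l2fc = np.log2((m_a + pseudocount) / (m_b + pseudocount))

    resid_ss = ((a - m_a[:, None]) ** 2).sum(axis=1) + ((b - m_b[:, None]) ** 2).sum(axis=1)
    pooled_var = resid_ss / (n_a + n_b - 2)
    m_all = (a.sum(axis=1) + b.sum(axis=1)) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - m_all) / np.where(m_all > 0, m_all ** 2, np.nan)
    disp = np.nan_to_num(disp, nan=0.0)
    disp = np.clip(disp, 0.0, None)
    trend = np.median(disp[m_all > 0]) if (m_all > 0).any() else 0.0
    disp = shrink_weight * disp + (1.0 - shrink_weight) * trend

    v_a = (m_a + disp * m_a ** 2) / n_a
    v_b = (m_b + disp * m_b ** 2) / n_b
    ln2sq = np.log(2.0) ** 2
    se2 = (v_a / (m_a + pseudocount) ** 2 + v_b / (m_b + pseudocount) ** 2) / ln2sq
    se = np.sqrt(np.maximum(se2, 1e-12))
    t = l2fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n_a + n_b - 2)
    return l2fc, np.minimum(p, 1.0)


def group_test(norm_table: pd.DataFrame, meta: CohortMetadata,
               contrast: tuple[str, str, str], alpha_adj: float = 0.1,
               min_abs_l2fc: float = 0.693,
               pseudocount: float = 0.5) -> GroupTestResult:
    """Whole-group differential representation between two factor levels.

    ``contrast`` is (column, level_a, level_b); log2fc is positive when a
    taxon is higher in ``level_a``. BH adjustment runs across all tested taxa.
    """
    column, level_a, level_b = contrast
    ids_a = meta.samples_where(**{column: level_a})
    ids_b = meta.samples_where(**{column: level_b})
    ids_a = [s for s in ids_a if s in norm_table.columns]
    ids_b = [s for s in ids_b if s in norm_table.columns]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"contrast {column}: {level_a} vs {level_b} needs >=2 samples per level "
            f"(got {len(ids_a)}, {len(ids_b)})")
    a = norm_table[ids_a].to_numpy(dtype=float)
    b = norm_table[ids_b].to_numpy(dtype=float)
    l2fc, p = _nb_wald(a, b, pseudocount)
    padj = bh_adjust(p)
    frame = pd.DataFrame({
        "log2fc": l2fc, "p": p, "padj": padj,
        "passes": (padj < alpha_adj) & (np.abs(l2fc) >= min_abs_l2fc),
    }, index=norm_table.index)
    return GroupTestResult(frame, f"{column}:{level_a}_vs_{level_b}",
                           alpha_adj, min_abs_l2fc)


def posttreatment_contrast(norm_table: pd.DataFrame, meta: CohortMetadata,
                           sex: str, alpha_adj: float = 0.1,
                           min_abs_l2fc: float = 0.693) -> GroupTestResult:
    """HK vs live contrast on post-treatment samples of one sex.

    Positive log2fc means higher relative abundance in HK-treated animals.
    """
    post_sex = meta.frame[(meta.frame["timepoint"] == "post")
                          & (meta.frame["sex"] == sex)]
    sub_meta = CohortMetadata(post_sex.reset_index(drop=True))
    keep = [s for s in norm_table.columns if s in set(sub_meta.sample_ids)]
    result = group_test(norm_table[keep], sub_meta, ("treatment", "HK", "live"),
                        alpha_adj=alpha_adj, min_abs_l2fc=min_abs_l2fc)
    result = GroupTestResult(result.frame, f"post_{sex}:HK_vs_live",
                             alpha_adj, min_abs_l2fc)
    return result
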