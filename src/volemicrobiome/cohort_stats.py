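"""Rank tests with |Z|/sqrt(N) effect sizes, qPCR ddCt fold changes,
behavioral composites, two-way ANOVA and SNK letters.

The Mann-Whitney effect size convention here is r = |Z_cc| / sqrt(n1 + n2)
with Z_cc the continuity-corrected normal approximation computed from the
smaller U; this is the convention that reproduces the printed values the
package is calibrated against (see tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CohortMetadata, PhenotypeTable, QpcrTable

__all__ = [
    "MWResult",
    "WilcoxonResult",
    "DdctResult",
    "AnxietyComposite",
    "mann_whitney",
    "effect_size_r",
    "wilcoxon_signed_rank",
    "ddct_fold_change",
    "anxiety_zscore",
    "two_way_anova",
    "snk_posthoc",
]


@dataclass
class MWResult:
    u: float
    z: float
    p_two_tailed: float
    r: float
    n1: int
    n2: int
    exact: bool


@dataclass
class WilcoxonResult:
    w: float
    p_two_tailed: float
    n: int
    exact: bool


@dataclass
class DdctResult:
    per_animal: pd.DataFrame   # index animal_id; dct_pre, dct_post, ddct, fold_change
    assay: str

    def group_mean_fold_change(self, animal_ids=None) -> float:
        df = self.per_animal
        if animal_ids is not None:
            df = df.loc[[a for a in animal_ids if a in df.index]]
        return float(df["fold_change"].mean())


@dataclass
class AnxietyComposite:
    frame: pd.DataFrame  # index animal_id; z_epm, z_of, composite


# ---------------------------------------------------------------------------
# Mann-Whitney

def _u_and_sigma(x: np.ndarray, y: np.ndarray):
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    has_ties = (tie_counts > 1).any()
    return u, sigma, has_ties


def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact tie-free null pmf of U1 over 0..n1*n2.

    The count of rank arrangements with U1 = u is the coefficient of q^u in
    the Gaussian binomial [n1+n2, n1]_q = prod_{i=1..n1} (1-q^{n2+i})/(1-q^i).
    """
    max_u = n1 * n2
    coeffs = np.zeros(max_u + 1)
    coeffs[0] = 1.0
    for i in range(1, n1 + 1):
        nxt = coeffs.copy()
        if n2 + i <= max_u:                      # multiply by (1 - q^(n2+i))
            nxt[n2 + i:] -= coeffs[: max_u + 1 - (n2 + i)]
        for k in range(i, max_u + 1):            # divide by (1 - q^i)
            nxt[k] += nxt[k - i]
        coeffs = nxt
    counts = np.round(coeffs)
    return counts / counts.sum()


def _exact_u_p(u: float, n1: int, n2: int) -> float:
    """Two-tailed exact p = 2 * P(U1 <= u) with U the smaller statistic."""
    pmf = _u_null_pmf(n1, n2)
    lower = pmf[: int(np.floor(u + 1e-9)) + 1].sum()
    return min(1.0, 2.0 * float(lower))


def mann_whitney(x, y, mode: str = "auto") -> MWResult:
    """Two-tailed Mann-Whitney U for two independent samples.

    U is the smaller of U1/U2. Z uses the continuity-corrected normal
    approximation with tie-adjusted sigma; r = |Z| / sqrt(n1 + n2). The exact
    p is used when mode="exact", or in auto mode when n1 + n2 <= 20 with no
    ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    u, sigma, has_ties = _u_and_sigma(x, y)
    mu = n1 * n2 / 2.0
    z = (mu - u - 0.5) / sigma
    r = abs(z) / np.sqrt(n1 + n2)
    exact = mode == "exact" or (mode == "auto" and n1 + n2 <= 20 and not has_ties)
    if exact:
        if has_ties:
            raise ValueError("exact Mann-Whitney p undefined with ties")
        p = _exact_u_p(u, n1, n2)
    else:
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return MWResult(float(u), float(z), float(p), float(r), n1, n2, exact)


def effect_size_r(u: float, n1: int, n2: int) -> float:
    """r = |Z_cc| / sqrt(n1 + n2) from the U statistic alone (no ties)."""
    if not 0 <= u <= n1 * n2:
        raise ValueError(f"U={u} outside [0, {n1 * n2}]")
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (mu - u - 0.5) / sigma
    return float(abs(z) / np.sqrt(n1 + n2))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank

def wilcoxon_signed_rank(pre, post) -> WilcoxonResult:
    """Two-tailed matched-pairs signed-rank test; exact p for n <= 25.

    W is the sum of ranks of positive differences (post - pre); zero
    differences are dropped before ranking.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    w_max = n * (n + 1) / 2.0
    if n <= 25:
        # exact distribution over 2^n sign patterns; double ranks so midranks
        # (x.5) become integers for the polynomial DP
        scale = 2
        sizes = np.round(ranks * scale).astype(int)
        dist = np.zeros(int(w_max * scale) + 1)
        dist[0] = 1.0
        for s in sizes:
            shifted = np.zeros_like(dist)
            shifted[s:] = dist[:len(dist) - s]
            dist = dist + shifted
        dist /= dist.sum()
        k = int(round(w * scale))
        p = min(1.0, 2.0 * min(dist[: k + 1].sum(), dist[k:].sum()))
        exact = True
    else:
        mu = w_max / 2.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = (abs(w - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * stats.norm.sf(z))
        exact = False
    return WilcoxonResult(w, float(p), n, exact)


# ---------------------------------------------------------------------------
# qPCR ddCt

def ddct_fold_change(qpcr: QpcrTable, assay: str,
                     meta: CohortMetadata | None = None) -> DdctResult:
    """Per-animal ddCt fold change 2^-(dCt_post - dCt_pre) for one assay.

    dCt = Ct_target - Ct_reference at each timepoint. The group mean is the
    arithmetic mean of the per-animal fold changes.
    """
    sub = qpcr.frame[qpcr.frame["assay"] == assay]
    if sub.empty:
        raise ValueError(f"assay {assay!r} absent from qPCR table")
    rows = {}
    for animal_id, grp in sub.groupby("animal_id"):
        by_tp = grp.set_index("timepoint")
        for tp in ("pre", "post"):
            if tp not in by_tp.index:
                raise ValueError(f"animal {animal_id} missing {tp} Ct for {assay!r}")
        dct_pre = float(by_tp.loc["pre", "ct_target"] - by_tp.loc["pre", "ct_reference"])
        dct_post = float(by_tp.loc["post", "ct_target"] - by_tp.loc["post", "ct_reference"])
        ddct = dct_post - dct_pre
        rows[animal_id] = {"dct_pre": dct_pre, "dct_post": dct_post,
                           "ddct": ddct, "fold_change": 2.0 ** (-ddct)}
    frame = pd.DataFrame.from_dict(rows, orient="index").rename_axis("animal_id")
    return DdctResult(frame, assay)


# ---------------------------------------------------------------------------
# behavioral composites & ANOVA

def anxiety_zscore(phenotypes: PhenotypeTable,
                   epm_column: str = "EPM_open_pct",
                   of_column: str = "OF_center_s") -> AnxietyComposite:
    """Composite anxiety score: mean of the z-scored EPM open-arm percentage
    and OF center duration over animals with both measurements."""
    df = phenotypes.frame[[epm_column, of_column]].dropna()
    if len(df) < 2:
        raise ValueError("need >=2 animals with both phenotypes")
    def z(col):
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in {col.name!r}")
        return (col - col.mean()) / sd
    z_epm = z(df[epm_column])
    z_of = z(df[of_column])
    out = pd.DataFrame({"z_epm": z_epm, "z_of": z_of,
                        "composite": (z_epm + z_of) / 2.0})
    return AnxietyComposite(out)


def two_way_anova(values, sex, treatment) -> pd.DataFrame:
    """Two-way ANOVA (sex x treatment), Type II sums of squares.

    Returns a frame indexed by effect (sex, treatment, sex:treatment,
    residual) with columns sum_sq, df, F, p.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "sex": np.asarray(sex, dtype=object),
                       "treatment": np.asarray(treatment, dtype=object)})
    if df["sex"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise ValueError("both factors need >=2 levels")
    if df["y"].std(ddof=1) == 0:
        raise ValueError("response has zero variance")
    model = ols("y ~ C(sex) * C(treatment)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = ["sex", "treatment", "sex:treatment", "residual"]
    return table.rename(columns={"PR(>F)": "p"})


def snk_posthoc(values, groups, alpha: float = 0.05) -> pd.Series:
    """Student-Newman-Keuls letters from stepwise studentized-range tests.

    Group means are ordered and compared at ranges p = k..2 with critical
    values q(alpha, p, df_within); once a range is found homogeneous, no
    subrange inside it is tested. Groups sharing a letter do not differ.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    k = len(uniq)
    if k < 2:
        raise ValueError("need >=2 groups")
    sizes = {g: (groups == g).sum() for g in uniq}
    if min(sizes.values()) < 2:
        raise ValueError("each group needs >=2 observations")
    means = {g: values[groups == g].mean() for g in uniq}
    n_total = len(values)
    ss_w = sum(((values[groups == g] - means[g]) ** 2).sum() for g in uniq)
    df_w = n_total - k
    ms_w = ss_w / df_w
    nh = k / sum(1.0 / sizes[g] for g in uniq)  # harmonic mean group size

    ordered = sorted(uniq, key=lambda g: means[g])
    homogeneous: list[tuple[int, int]] = []

    def covered(i, j):
        return any(a <= i and j <= b for a, b in homogeneous)

    if ms_w == 0:
        # degenerate: identical within-group values; separate unequal means
        for i in range(k):
            j = i
            while j + 1 < k and means[ordered[j + 1]] == means[ordered[i]]:
                j += 1
            if j > i:
                homogeneous.append((i, j))
    else:
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                if covered(i, j):
                    continue
                diff = means[ordered[j]] - means[ordered[i]]
                q = diff / np.sqrt(ms_w / nh)
                q_crit = stats.studentized_range.ppf(1 - alpha, span, df_w)
                if q <= q_crit:
                    homogeneous.append((i, j))

    # letter assignment: each maximal homogeneous run gets one letter
    runs = [(i, j) for i, j in homogeneous
            if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in homogeneous)]
    for i in range(k):
        if not any(a <= i <= b for a, b in runs):
            runs.append((i, i))
    runs.sort()
    letters = {g: "" for g in uniq}
    for letter_idx, (a, b) in enumerate(runs):
        letter = chr(ord("a") + letter_idx)
        for idx in range(a, b + 1):
            letters[ordered[idx]] += letter
    return pd.Series({g: "".join(sorted(letters[g])) for g in uniq})
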