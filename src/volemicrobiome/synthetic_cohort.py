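"""Synthetic paired pre/post cohorts with planted effects and associations.

The generator mirrors the study design: a 2 sex x 2 treatment grid of animals
each sampled pre and post, a heavy-tailed (log-normal) community profile
shared across animals, large per-animal multiplicative random effects, and
multinomial resampling at a per-sample depth. Treatment effects and
taxon-phenotype monotone associations are planted with known ground truth so
every downstream stage can be tested against the construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import skbio

from .io_model import (CohortMetadata, CountTable, PhenotypeTable, PhyloTree,
                       QpcrTable)

__all__ = [
    "CohortDesign",
    "PlantedEffect",
    "PlantedAssociation",
    "CohortBundle",
    "generate_cohort",
    "generate_tree",
    "generate_qpcr",
]

DEFAULT_PHENOTYPES = ("CRF_AMY", "CRFR2_NAcc", "V1aR_PVN", "OF_center_s",
                      "EPM_open_pct", "SA_interaction_s", "SA_anxiety_s")


@dataclass
class CohortDesign:
    """Cohort shape and noise parameters.

    ``dispersion`` is the natural-log SD of per-animal multiplicative random
    effects on taxon abundances; ``profile_sd`` shapes the log-normal
    rank-abundance profile shared across animals.
    """

    n_per_cell: int = 8
    n_taxa: int = 50
    dispersion: float = 1.0
    depth_range: tuple[int, int] = (20_000, 60_000)
    seed: int = 0
    profile_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("depth_range must be positive and ordered")


@dataclass
class PlantedEffect:
    """Treatment-induced per-animal log2 fold change on designated taxa."""

    taxa: list[str]
    sex: str
    treatment: str
    mu_log2fc: float
    sd_log2fc: float = 0.0
    fraction_affected: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ValueError("fraction_affected must lie in [0, 1]")
        if not np.isfinite(self.mu_log2fc):
            raise ValueError("mu_log2fc must be finite")


@dataclass
class PlantedAssociation:
    """Monotone taxon-phenotype link with a target Spearman rho."""

    taxon: str
    phenotype: str
    rho: float
    noise_sd: float = 1.0
    feature: str = "log2fc"  # or "post_abundance"

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("target rho must lie in (-1, 1)")
        if self.feature not in ("log2fc", "post_abundance"):
            raise ValueError("feature must be log2fc or post_abundance")


@dataclass
class CohortBundle:
    table: CountTable
    metadata: CohortMetadata
    tree: PhyloTree
    phenotypes: PhenotypeTable
    qpcr: QpcrTable
    truth: dict = field(default_factory=dict)

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)


def _split_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_tree(taxa: list[str], seed: int = 0) -> PhyloTree:
    """Random bifurcating rooted tree with exponential branch lengths."""
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=t, length=float(rng.exponential(1.0)))
             for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = skbio.TreeNode(length=float(rng.exponential(1.0)),
                                children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = skbio.TreeNode(children=nodes)
    return PhyloTree(root)


def generate_qpcr(meta: CohortMetadata, true_fold_changes: dict[str, float] | float,
                  seed: int = 0, assay: str = "L_reuteri",
                  ct_noise_sd: float = 0.0) -> QpcrTable:
    """Ct tables whose ddCt analysis recovers the target per-animal fold
    changes (exactly when ``ct_noise_sd`` is 0)."""
    rng = np.random.default_rng(seed)
    animals = meta.animals_where()
    if np.isscalar(true_fold_changes):
        targets = {a: float(true_fold_changes) for a in animals}
    else:
        targets = {a: float(v) for a, v in true_fold_changes.items()}
    rows = []
    for animal_id in animals:
        fold = targets.get(animal_id, 1.0)
        if fold <= 0:
            raise ValueError(f"fold change for {animal_id} must be positive")
        ct_ref_pre = 15.0 + rng.uniform(-1, 1)
        ct_ref_post = 15.0 + rng.uniform(-1, 1)
        dct_pre = rng.uniform(4.0, 8.0)
        dct_post = dct_pre - np.log2(fold)
        for tp, ct_ref, dct in (("pre", ct_ref_pre, dct_pre),
                                ("post", ct_ref_post, dct_post)):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append({"animal_id": animal_id, "timepoint": tp, "assay": assay,
                         "ct_target": ct_ref + dct + noise,
                         "ct_reference": ct_ref})
    return QpcrTable(pd.DataFrame(rows))


def _make_metadata(design: CohortDesign) -> CohortMetadata:
    rows = []
    counter = 0
    for sex in ("F", "M"):
        for trt in ("live", "HK"):
            for k in range(design.n_per_cell):
                counter += 1
                animal_id = f"{sex}{trt}{k + 1:02d}"
                for tp in ("pre", "post"):
                    rows.append({
                        "sample_id": f"{animal_id}_{tp}",
                        "animal_id": animal_id,
                        "sex": sex,
                        "treatment": trt,
                        "timepoint": tp,
                        "cage_id": f"cage{(counter - 1) // 2 + 1:02d}",
                    })
    return CohortMetadata(pd.DataFrame(rows))


def generate_cohort(design: CohortDesign,
                    effects: list[PlantedEffect] | None = None,
                    associations: list[PlantedAssociation] | None = None,
                    phenotype_names: tuple[str, ...] = DEFAULT_PHENOTYPES,
                    qpcr_fold_changes: dict[str, float] | float = 1.0) -> CohortBundle:
    """Generate a full synthetic cohort; deterministic given ``design.seed``.

    Pre-treatment latent abundances are a shared log-normal community profile
    times per-animal log-normal random effects; post abundances multiply the
    planted-effect taxa by 2^log2fc (drawn per animal); counts are multinomial
    at a per-sample uniform depth. Phenotypes are Gaussian noise plus planted
    monotone links to the latent per-animal taxon features.
    """
    effects = effects or []
    associations = associations or []
    taxa = [f"taxon{i + 1:03d}" for i in range(design.n_taxa)]
    lineages = [_fake_lineage(i) for i in range(design.n_taxa)]
    taxon_index = {t: i for i, t in enumerate(taxa)}
    for eff in effects:
        unknown = set(eff.taxa) - set(taxa)
        if unknown:
            raise ValueError(f"planted effect references unknown taxa: {sorted(unknown)}")
    for assoc in associations:
        if assoc.taxon not in taxon_index:
            raise ValueError(f"planted association references unknown taxon {assoc.taxon!r}")
        if assoc.phenotype not in phenotype_names:
            raise ValueError(f"unknown phenotype {assoc.phenotype!r}")

    meta = _make_metadata(design)
    animals = meta.animals_where()
    info = meta.animal_info()

    (rng_profile, rng_animal, rng_effect, rng_depth,
     rng_count, rng_pheno, rng_qpcr, rng_assoc) = _split_seeds(design.seed, 8)

    # shared heavy-tailed community profile
    log_profile = rng_profile.normal(0.0, design.profile_sd, size=design.n_taxa)
    # per-animal multiplicative random effects (log-scale SD = dispersion)
    animal_effects = {
        a: rng_animal.normal(0.0, design.dispersion, size=design.n_taxa)
        for a in animals
    }

    # planted per-animal log2 fold changes (latent truth)
    latent_l2fc = {a: np.zeros(design.n_taxa) for a in animals}
    for eff in effects:
        cell_animals = [a for a in animals
                        if info.loc[a, "sex"] == eff.sex
                        and info.loc[a, "treatment"] == eff.treatment]
        n_affected = int(round(eff.fraction_affected * len(cell_animals)))
        affected = list(rng_effect.choice(cell_animals, size=n_affected,
                                          replace=False)) if n_affected else []
        for a in affected:
            for t in eff.taxa:
                latent_l2fc[a][taxon_index[t]] += rng_effect.normal(
                    eff.mu_log2fc, eff.sd_log2fc)

    # a log2fc association needs per-animal fold-change variation on its
    # taxon; inject unit-SD latent log2fc noise where none was planted
    for assoc in associations:
        if assoc.feature != "log2fc":
            continue
        idx = taxon_index[assoc.taxon]
        spread = np.std([latent_l2fc[a][idx] for a in animals])
        if spread < 1e-9:
            for a in animals:
                latent_l2fc[a][idx] += rng_assoc.normal(0.0, 1.0)

    # multinomial sampling at per-sample depth
    sample_ids = meta.sample_ids
    counts = np.zeros((design.n_taxa, len(sample_ids)), dtype=np.int64)
    lam_pre = {}
    lam_post = {}
    for a in animals:
        lam = np.exp(log_profile + animal_effects[a])
        lam_pre[a] = lam
        lam_post[a] = lam * np.exp2(latent_l2fc[a])
    for j, sid in enumerate(sample_ids):
        row = meta.frame[meta.frame["sample_id"] == sid].iloc[0]
        lam = (lam_pre if row["timepoint"] == "pre" else lam_post)[row["animal_id"]]
        depth = int(rng_depth.integers(design.depth_range[0],
                                       design.depth_range[1] + 1))
        counts[:, j] = rng_count.multinomial(depth, lam / lam.sum())
    table = CountTable(list(taxa), lineages, list(sample_ids), counts)

    tree = generate_tree(taxa, seed=design.seed + 1)

    # phenotypes: noise plus Gaussian-copula links achieving the target
    # Spearman rho in expectation (rho_pearson = 2 sin(pi * rho_s / 6))
    pheno = pd.DataFrame(
        rng_pheno.normal(0.0, 1.0, size=(len(animals), len(phenotype_names))),
        index=pd.Index(animals, name="animal_id"), columns=list(phenotype_names))
    for assoc in associations:
        idx = taxon_index[assoc.taxon]
        if assoc.feature == "log2fc":
            feature = np.array([latent_l2fc[a][idx] for a in animals])
        else:
            feature = np.array([np.log(lam_post[a][idx] / lam_post[a].sum())
                                for a in animals])
        ranks = pd.Series(feature).rank(method="average").to_numpy()
        z_feat = (ranks - ranks.mean()) / max(ranks.std(ddof=0), 1e-12)
        rho_p = 2.0 * np.sin(np.pi * assoc.rho / 6.0)
        noise = rng_pheno.normal(0.0, 1.0, size=len(animals))
        pheno[assoc.phenotype] = (rho_p * z_feat
                                  + np.sqrt(1.0 - rho_p ** 2) * noise) * assoc.noise_sd
    phenotypes = PhenotypeTable(pheno)

    qpcr = generate_qpcr(meta, qpcr_fold_changes,
                         seed=int(rng_qpcr.integers(0, 2 ** 31)))

    truth = {
        "design": asdict(design),
        "effects": [asdict(e) for e in effects],
        "associations": [asdict(a) for a in associations],
        "latent_log2fc": {a: latent_l2fc[a].tolist() for a in animals},
        "taxa": taxa,
    }
    return CohortBundle(table, meta, tree, phenotypes, qpcr, truth)


def _fake_lineage(i: int) -> str:
    phylum = f"Phylum{i % 4 + 1}"
    family = f"Family{i % 12 + 1}"
    genus = f"Genus{i % 25 + 1}"
    return (f"{phylum};Class{i % 6 + 1};Order{i % 8 + 1};{family};"
            f"{genus};Species{i + 1}")
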