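"""Synthetic generators for every pipeline input, with planted ground truth.

Each generator is a pure function of its arguments: a master seed is fanned
out into an independent per-generator stream (``default_rng([seed, TAG])``),
so adding a generator never perturbs the others and identical configs give
bit-identical outputs.  The planted truth (kept compounds, Venn regions,
module nodes, differential taxa, expected severity) is always returned next
to the data; consumers never have to re-derive it.

Defaults emulate the study design the pipeline targets: a six-herb formula,
five disease-gene databases, a STRING-like confidence-scored PPI layer, 16S
OTU tables for two mouse groups (Dirichlet-multinomial, lognormal baseline
abundances, library sizes in the tens of thousands) and DAI cohorts of 15
mice per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dai import BLOOD_SCORES, STOOL_SCORES, DAIObservation
from .hit import CompoundRecord, DiseaseGeneSource
from .microbiome import FeatureTable

__all__ = [
    "gen_hit_tables",
    "gen_disease_sources",
    "gen_ppi_with_planted_module",
    "gen_feature_table",
    "gen_dai_cohort",
    "SEVERITY_PROFILES",
]

# fixed stream tags: fan one master seed out into independent streams
_TAG_HIT, _TAG_DISEASE, _TAG_PPI, _TAG_OTU, _TAG_DAI = 11, 23, 37, 53, 71

DEFAULT_HERBS = ("Mf", "Zr", "Ar", "CRr", "CPr", "Pp")


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), tag])


def gen_hit_tables(
    n_herbs: int = 6,
    compounds_per_herb: int = 20,
    target_universe_size: int = 300,
    shared_compound_rate: float = 0.15,
    targets_per_compound: tuple[int, int] = (3, 25),
    seed: int = 0,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Compound tables emulating an ADME-annotated herb export.

    OB is Gamma(2, 12) clipped to [0, 100] (right-skewed, mode well below the
    20% cutoff); DL is Beta(1.5, 4).  A ``shared_compound_rate`` fraction of
    each herb's compounds is drawn from a common pool, so some compounds
    recur across herbs under the same id.  Returns the records and a
    ground-truth frame with a ``kept`` flag per record (True iff OB >= 20 and
    DL >= 0.18).
    """
    if n_herbs < 1 or compounds_per_herb < 1 or target_universe_size < 1:
        raise ValueError("sizes must be >= 1")
    rng = _rng(seed, _TAG_HIT)
    herbs = [DEFAULT_HERBS[i] if i < len(DEFAULT_HERBS) else f"H{i + 1}"
             for i in range(n_herbs)]
    universe = [f"G{i:04d}" for i in range(target_universe_size)]

    n_shared_pool = max(1, int(round(compounds_per_herb * shared_compound_rate * 2)))
    shared_pool = {}
    for i in range(n_shared_pool):
        cid = f"SHARED{i:03d}"
        shared_pool[cid] = _draw_compound(rng, cid, universe, targets_per_compound)

    records: list[CompoundRecord] = []
    truth_rows = []
    for hi, herb in enumerate(herbs):
        seen: set[str] = set()
        for ci in range(compounds_per_herb):
            if shared_pool and rng.random() < shared_compound_rate:
                cid = list(shared_pool)[rng.integers(len(shared_pool))]
                if cid in seen:
                    continue
                name, ob, dl, targets = shared_pool[cid]
            else:
                cid = f"C{hi:02d}{ci:03d}"
                name, ob, dl, targets = _draw_compound(
                    rng, cid, universe, targets_per_compound
                )
            seen.add(cid)
            rec = CompoundRecord(herb, cid, name, ob, dl, set(targets))
            records.append(rec)
            truth_rows.append(
                {
                    "herb_id": herb,
                    "compound_id": cid,
                    "kept": ob >= 20.0 and dl >= 0.18,
                }
            )
    return records, pd.DataFrame(truth_rows)


def _draw_compound(rng, cid, universe, targets_per_compound):
    ob = float(min(rng.gamma(2.0, 12.0), 100.0))
    dl = float(rng.beta(1.5, 4.0))
    lo, hi = targets_per_compound
    k = int(rng.integers(lo, hi + 1))
    targets = rng.choice(len(universe), size=min(k, len(universe)), replace=False)
    return f"cmpd-{cid}", ob, dl, [universe[i] for i in targets]


def gen_disease_sources(
    n_sources: int = 5,
    per_source_size: int = 400,
    pairwise_overlap: float = 0.4,
    pool: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[DiseaseGeneSource], set[str], dict[frozenset[str], int]]:
    """Disease-gene pulls with a planted Venn structure.

    Each source samples ``per_source_size`` genes without replacement from a
    shared pool of size ``per_source_size / pairwise_overlap`` (overlap 0 ->
    disjoint pools, 1 -> identical sources).  ``pool`` may supply the shared
    gene universe explicitly (e.g. to make disease sources overlap a compound
    target universe); it must be at least the implied pool size.  Returns the
    sources, the realized union and the realized Venn region counts (the
    planted truth recorded at generation time).
    """
    if not 0.0 <= pairwise_overlap <= 1.0:
        raise ValueError("pairwise_overlap must lie in [0, 1]")
    if n_sources < 1 or per_source_size < 1:
        raise ValueError("sizes must be >= 1")
    rng = _rng(seed, _TAG_DISEASE)
    names = ["GeneCards", "DrugBank", "OMIM", "PharmGkb", "TTD"][:n_sources]
    names += [f"DB{i + 1}" for i in range(len(names), n_sources)]

    sources: list[DiseaseGeneSource] = []
    if pairwise_overlap == 0.0:
        if pool is not None and len(pool) < n_sources * per_source_size:
            raise ValueError("pool too small for disjoint sources")
        for i, name in enumerate(names):
            if pool is None:
                genes = {f"D{i}_{j:05d}" for j in range(per_source_size)}
            else:
                genes = set(pool[i * per_source_size:(i + 1) * per_source_size])
            sources.append(DiseaseGeneSource(name, genes))
    else:
        pool_size = max(per_source_size, int(round(per_source_size / pairwise_overlap)))
        if pool is None:
            pool = [f"D{j:06d}" for j in range(pool_size)]
        elif len(pool) < pool_size:
            raise ValueError(
                f"pool of {len(pool)} genes is smaller than the "
                f"{pool_size} implied by overlap {pairwise_overlap}"
            )
        for name in names:
            idx = rng.choice(pool_size, size=per_source_size, replace=False)
            sources.append(DiseaseGeneSource(name, {pool[j] for j in idx}))

    union: set[str] = set().union(*(s.genes for s in sources))
    regions: dict[frozenset[str], int] = {}
    for g in union:
        key = frozenset(s.source_name for s in sources if g in s.genes)
        regions[key] = regions.get(key, 0) + 1
    return sources, union, regions


def gen_ppi_with_planted_module(
    n: int = 200,
    p_background: float = 0.03,
    module_size: int = 12,
    module_density: float = 1.0,
    conf_range: tuple[float, float] = (0.3, 1.0),
    module_conf_range: tuple[float, float] = (0.75, 1.0),
    seed: int = 0,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Erdős–Rényi background with a planted dense module.

    Background edges get confidences uniform on ``conf_range`` (so the 0.7
    cutoff thins them); module edges uniform on ``module_conf_range`` (all
    above the cutoff, keeping the module intact after filtering).  Returns
    the edge list and the planted node labels.
    """
    if module_size > n:
        raise ValueError("module_size cannot exceed n")
    rng = _rng(seed, _TAG_PPI)
    nodes = [f"P{i:04d}" for i in range(n)]
    planted = nodes[:module_size]
    edges: list[tuple[str, str, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            in_module = i < module_size and j < module_size
            if in_module:
                if rng.random() < module_density:
                    c = rng.uniform(*module_conf_range)
                    edges.append((nodes[i], nodes[j], float(c)))
            elif p_background > 0 and rng.random() < p_background:
                c = rng.uniform(*conf_range)
                edges.append((nodes[i], nodes[j], float(c)))
    return edges, planted


_PHYLA = (
    "Bacteroidetes", "Firmicutes", "Proteobacteria",
    "Actinobacteria", "Verrucomicrobia", "Fusobacteria",
)
_GENERA = (
    ("Bacteroides", "Bacteroidetes"), ("Muribaculum", "Bacteroidetes"),
    ("Lachnoclostridium", "Firmicutes"), ("Ruminiclostridium", "Firmicutes"),
    ("Lactobacillus", "Firmicutes"), ("Roseburia", "Firmicutes"),
    ("Escherichia", "Proteobacteria"), ("Desulfovibrio", "Proteobacteria"),
    ("Bifidobacterium", "Actinobacteria"), ("Akkermansia", "Verrucomicrobia"),
    ("Fusobacterium", "Fusobacteria"), ("Helicobacter", "Proteobacteria"),
)


def _lineage(genus: str, phylum: str) -> str:
    return (
        f"k__Bacteria;p__{phylum};c__{phylum}_c;o__{phylum}_o;"
        f"f__{genus}_f;g__{genus}"
    )


def gen_feature_table(
    n_samples_per_group: int = 10,
    n_features: int = 15,
    base_concentration: float = 100.0,
    n_diff_features: int = 5,
    fold_change: float = 10.0,
    library_size_mean: int = 20000,
    library_size_sigma: float = 0.25,
    group_labels: tuple[str, str] = ("DSS", "DSS-GCZX"),
    planted_share_band: tuple[float, float] = (1e-3, 2e-2),
    seed: int = 0,
) -> tuple[FeatureTable, list[str]]:
    """Dirichlet-multinomial OTU tables with planted differential taxa.

    Baseline proportions are lognormal(0, 2.5) renormalized — the long-
    tailed, few-dominants-many-rare abundance profile typical of 16S data.
    The default table is genus-like in resolution (15 taxa over the 12-genus
    taxonomy model), the scale at which biomarker calls are usually read.
    Per-sample compositions are Dirichlet with total concentration
    ``base_concentration`` (overdispersed, as in real stool samples); group
    B multiplies the concentration of the planted features by
    ``fold_change``.  Library sizes are lognormal around
    ``library_size_mean``.  Planted features are drawn from the moderately
    rare baseline-share band ``planted_share_band`` (falling back to the
    features nearest the band when it holds fewer than requested), so a
    fold change on them is detectable without redistributing much of the
    community's mass through compositional closure.  Returns the table and
    the planted feature ids.
    """
    if n_diff_features > n_features:
        raise ValueError("n_diff_features cannot exceed n_features")
    if library_size_mean < 1:
        raise ValueError("library size must be >= 1")
    rng = _rng(seed, _TAG_OTU)
    features = [f"OTU{i:04d}" for i in range(n_features)]
    base = rng.lognormal(0.0, 2.5, n_features)
    base /= base.sum()
    alpha_a = base_concentration * base

    lo, hi = planted_share_band
    band = np.flatnonzero((base >= lo) & (base <= hi))
    if len(band) < n_diff_features:
        # nearest features to the band centre, by log-share distance
        centre = np.sqrt(lo * hi)
        band = np.argsort(np.abs(np.log(base) - np.log(centre)))[
            : max(n_diff_features, 1)
        ]
    diff_idx = rng.choice(band, size=n_diff_features, replace=False)
    planted = [features[i] for i in sorted(diff_idx)]

    # Split the fold change symmetrically (x sqrt(F) in one group, / sqrt(F)
    # in the other) and alternate direction across planted taxa: treatment
    # effects raise some taxa and suppress others, and the balance keeps
    # compositional closure from shifting every null feature.
    alpha_b = alpha_a.copy()
    root = np.sqrt(fold_change)
    for rank, i in enumerate(diff_idx):
        if rank % 2 == 0:  # enriched in group B
            alpha_b[i] *= root
            alpha_a[i] /= root
        else:  # depleted in group B
            alpha_b[i] /= root
            alpha_a[i] *= root

    rows, sample_ids, groups = [], [], []
    for gi, (label, alpha) in enumerate(zip(group_labels, (alpha_a, alpha_b))):
        for si in range(n_samples_per_group):
            lib = int(round(rng.lognormal(np.log(library_size_mean),
                                          library_size_sigma)))
            lib = max(lib, 1)
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(lib, p))
            sample_ids.append(f"{label}-{si + 1:02d}")
            groups.append(label)
    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=features)

    genus_idx = rng.integers(0, len(_GENERA), n_features)
    taxonomy = pd.Series(
        [_lineage(*_GENERA[i]) for i in genus_idx], index=features
    )
    table = FeatureTable(counts, pd.Series(groups, index=sample_ids), taxonomy)
    return table, planted


@dataclass
class SeverityProfile:
    """Per-group sampling distributions for DAI readouts."""

    stool_probs: dict[str, float]
    blood_probs: dict[str, float]
    weight_loss_mean: float  # percent
    weight_loss_sd: float
    histology_mean: float  # per-criterion mean on the 0-3 scale
    histology_sd: float = 0.8


SEVERITY_PROFILES: dict[str, SeverityProfile] = {
    "control": SeverityProfile(
        {"normal": 1.0}, {"negative_2min": 1.0}, 0.0, 0.0, 0.0, 0.0
    ),
    "dss": SeverityProfile(
        {"soft": 0.1, "very_soft_semiformed": 0.4, "liquid_or_sticky": 0.5},
        {"light_purple_within_10s": 0.4, "heavy_purple_within_10s": 0.6},
        15.0, 4.0, 2.2,
    ),
    "dss_treated": SeverityProfile(
        {"normal": 0.2, "soft": 0.5, "very_soft_semiformed": 0.3},
        {"negative_2min": 0.4, "purple_after_10s": 0.4,
         "light_purple_within_10s": 0.2},
        6.0, 3.0, 1.0,
    ),
}


def _sample_cat(rng, probs: dict[str, float]) -> str:
    cats = sorted(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p /= p.sum()
    return cats[rng.choice(len(cats), p=p)]


def gen_dai_cohort(
    n_per_group: int = 15,
    profiles: dict[str, SeverityProfile] | None = None,
    seed: int = 0,
) -> dict[str, list[DAIObservation]]:
    """Sample a DAI cohort per group from severity profiles.

    Defaults to the three-arm design (control / dss / dss_treated, 15 mice
    each).  Weight loss is normal, clipped at 0; histology subscores are
    rounded clipped normals on the 0-3 scale.
    """
    if profiles is None:
        profiles = SEVERITY_PROFILES
    rng = _rng(seed, _TAG_DAI)
    cohort: dict[str, list[DAIObservation]] = {}
    for group in profiles:
        prof = profiles[group]
        obs = []
        for _ in range(n_per_group):
            hist = {
                f: int(np.clip(round(rng.normal(prof.histology_mean,
                                                prof.histology_sd)), 0, 3))
                for f in ("epithelial_destruction", "edema",
                          "crypt_loss", "mucosa_infiltration")
            }
            obs.append(
                DAIObservation(
                    stool=_sample_cat(rng, prof.stool_probs),
                    weight_loss=float(max(rng.normal(prof.weight_loss_mean,
                                                     prof.weight_loss_sd), 0.0)),
                    blood=_sample_cat(rng, prof.blood_probs),
                    **hist,
                )
            )
        cohort[group] = obs
    return cohort
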