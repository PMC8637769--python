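"""Pipeline orchestration: simulate inputs, run both analysis branches,
write a deterministic report bundle with a checksummed manifest.

The network-pharmacology branch runs hit assembly -> PPI hub extraction ->
enrichment; the animal-study branch runs microbiome statistics and DAI
scoring.  The two branches are independent DAGs.  With a fixed seed and
fixed inputs the output bundle is byte-identical across runs (the manifest
carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dai, enrich, hit, io, microbiome, ppi, synth

__all__ = ["PipelineConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run.

    Thresholds default to the published workflow: OB >= 20%, DL >= 0.18,
    PPI confidence >= 0.7, three hub-extraction rounds, adjusted p < 0.05,
    OTU filtration at 0.005% of total reads, LDA effect >= 2.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    ob_min: float = 20.0
    dl_min: float = 0.18
    conf_min: float = 0.7
    rounds: int = 3
    alpha: float = 0.05
    lda_min: float = 2.0
    min_fraction: float = microbiome.DEFAULT_MIN_FRACTION
    # input paths (all TSV/GMT); filled by `simulate` or by the user
    compounds: str | None = None
    compound_targets: str | None = None
    disease_genes: str | None = None
    ppi_edges: str | None = None
    gene_sets: str | None = None
    feature_table: str | None = None
    group_map: str | None = None
    dai_table: str | None = None

    def validate(self) -> None:
        if not (0 <= self.conf_min <= 1):
            raise ValueError("conf_min must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.min_fraction < 0:
            raise ValueError("min_fraction must be >= 0")
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValueError("ADME cutoffs must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Write the study-like synthetic preset (six herbs, five disease-gene
    sources, a planted-module PPI layer, a GMT collection, two 16S groups and
    three DAI arms of 15 mice) and return a config pointing at the files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed)

    records, _ = synth.gen_hit_tables(seed=seed)
    io.write_compound_records(
        records, out / "compounds.tsv", out / "compound_targets.tsv"
    )

    # disease pool shares the compound-target universe plus disease-only
    # genes, so the formula and the disease genuinely intersect
    target_universe = sorted({t for r in records for t in r.targets})
    pool = target_universe + [
        f"D{j:06d}" for j in range(max(0, 1000 - len(target_universe)))
    ]
    sources, _, _ = synth.gen_disease_sources(pool=pool, seed=seed)
    io.write_disease_sources(sources, out / "disease_genes.tsv")

    edges, planted = synth.gen_ppi_with_planted_module(seed=seed)
    io.write_ppi_edges(edges, out / "ppi_edges.tsv")
    (out / "ppi_planted_module.txt").write_text("\n".join(planted) + "\n")

    # gene sets over the compound-target universe, one planted enriched term
    # drawn 80% from the ADME-active compounds' targets (the eventual query)
    rng = np.random.default_rng([seed, 97])
    universe = pool  # genome-like background, wider than the target universe
    terms: dict[str, enrich.GeneSetTerm] = {}
    cats = ("BP", "CC", "MF", "pathway")
    for i in range(40):
        size = int(rng.integers(10, 60))
        members = set(rng.choice(universe, size=min(size, len(universe)),
                                 replace=False))
        terms[f"T{i:03d}"] = enrich.GeneSetTerm(
            f"term {i}", cats[i % 4], members
        )
    active = hit.filter_adme(records)
    pooled = sorted(set().union(*(r.targets for r in active))) if active else []
    if pooled:
        n_hit = min(24, len(pooled))
        decoys = sorted(set(universe) - set(pooled))
        members = set(rng.choice(pooled, size=n_hit, replace=False))
        if decoys:
            members |= set(rng.choice(decoys, size=min(6, len(decoys)),
                                      replace=False))
        terms["T_PLANTED"] = enrich.GeneSetTerm("planted term", "pathway",
                                                members)
    io.write_gmt(enrich.GeneSetCollection(terms), out / "gene_sets.gmt")

    table, planted_taxa = synth.gen_feature_table(seed=seed)
    io.write_feature_table(table, out / "otu_table.tsv", out / "group_map.tsv")
    (out / "otu_planted_taxa.txt").write_text("\n".join(planted_taxa) + "\n")

    cohort = synth.gen_dai_cohort(seed=seed)
    io.write_dai_observations(cohort, out / "dai_observations.tsv")

    return PipelineConfig(
        out_dir=str(out / "results"),
        seed=seed,
        compounds=str(out / "compounds.tsv"),
        compound_targets=str(out / "compound_targets.tsv"),
        disease_genes=str(out / "disease_genes.tsv"),
        ppi_edges=str(out / "ppi_edges.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        feature_table=str(out / "otu_table.tsv"),
        group_map=str(out / "group_map.tsv"),
        dai_table=str(out / "dai_observations.tsv"),
    )


def _require(cfg: PipelineConfig, stage: str, *names: str) -> None:
    for name in names:
        path = getattr(cfg, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"stage {stage!r}: required input {name!r} "
                f"missing ({path!r})"
            )


ALL_STAGES = ("hit_assembly", "ppi_hub", "enrichment", "microbiome_stats",
              "dai_score")


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages (default: all five).

    ``enrichment`` pulls in ``hit_assembly`` (it consumes the shared-target
    query).  Returns the summary dict, which is also written to the bundle.
    """
    cfg.validate()
    if stages is None:
        stages = ALL_STAGES
    stages = set(stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "enrichment" in stages:
        stages.add("hit_assembly")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    # --- branch 1: network pharmacology -----------------------------------
    shared: set = set()
    pooled: set = set()
    if "hit_assembly" in stages:
        _require(cfg, "hit_assembly", "compounds", "compound_targets",
                 "disease_genes")
        records = io.read_compound_records(cfg.compounds, cfg.compound_targets)
        active = hit.filter_adme(records, cfg.ob_min, cfg.dl_min)
        sources = io.read_disease_sources(cfg.disease_genes)
        union, regions = hit.collate_disease_genes(sources)
        pooled = set().union(*(r.targets for r in active)) if active else set()
        shared = hit.intersect_targets(pooled, union)
        net = hit.build_hit_network(active, shared)
        io.write_network_tables(net, out / "hit_nodes.tsv", out / "hit_edges.tsv")
        share = hit.herb_target_share(net) if net.number_of_nodes() else {}
        io.write_json(
            {
                "n_compounds": len(records),
                "n_active_compounds": len(active),
                "n_disease_genes": len(union),
                "n_pooled_targets": len(pooled),
                "n_shared_targets": len(shared),
                "venn_regions": {
                    "&".join(sorted(k)): v for k, v in regions.items()
                },
                "herb_target_share": {
                    h: {"n_targets": n, "fraction": f}
                    for h, (n, f) in share.items()
                },
            },
            out / "hit_summary.json",
        )
        summary["stages"].append("hit_assembly")
        summary["n_active_compounds"] = len(active)
        summary["n_disease_genes"] = len(union)
        summary["n_shared_targets"] = len(shared)

    if "ppi_hub" in stages:
        _require(cfg, "ppi_hub", "ppi_edges")
        edges = io.read_ppi_edges(cfg.ppi_edges)
        g = ppi.build_ppi_graph(edges, cfg.conf_min)
        table = ppi.compute_centralities(g)
        table.round(6).to_csv(out / "centralities.tsv", sep="\t",
                              index_label="node")
        hub, trace = ppi.extract_hub_subnetwork(g, rounds=cfg.rounds)
        io.write_network_tables(hub, out / "hub_nodes.tsv",
                                out / "hub_edges.tsv")
        io.write_json(trace.to_dict(), out / "hub_trace.json")
        summary["stages"].append("ppi_hub")
        summary["ppi_nodes"] = g.number_of_nodes()
        summary["hub_nodes"] = hub.number_of_nodes()

    if "enrichment" in stages:
        _require(cfg, "enrichment", "gene_sets")
        collection = io.read_gmt(cfg.gene_sets)
        query = shared if shared else pooled
        enr = enrich.enrich_gene_set(
            query & collection.universe(), collection, alpha=cfg.alpha
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        summary["stages"].append("enrichment")
        summary["n_significant_terms"] = int(enr["significant"].sum())

    # --- branch 2: microbiome + disease activity --------------------------
    if "microbiome_stats" in stages:
        _require(cfg, "microbiome_stats", "feature_table", "group_map")
        ft = io.read_feature_table(cfg.feature_table, cfg.group_map)
        ft = microbiome.filter_low_abundance(ft, cfg.min_fraction)
        alpha_rows = {
            s: microbiome.alpha_diversity(ft.counts.loc[s].to_numpy())
            for s in ft.samples
        }
        pd.DataFrame(alpha_rows).T.round(6).to_csv(
            out / "alpha_diversity.tsv", sep="\t", index_label="sample_id"
        )
        dm = microbiome.jaccard_distance_matrix(ft)
        pd.DataFrame(
            dm.data, index=list(dm.ids), columns=list(dm.ids)
        ).round(6).to_csv(out / "jaccard.tsv", sep="\t",
                          index_label="sample_id")
        pc = microbiome.pcoa(dm)
        pc.coordinates.round(6).to_csv(out / "pcoa.tsv", sep="\t",
                                       index_label="sample_id")
        nm = microbiome.nmds(dm, seed=cfg.seed)
        nm.coordinates.round(6).to_csv(out / "nmds.tsv", sep="\t",
                                       index_label="sample_id")
        newick, _ = microbiome.upgma(dm)
        (out / "upgma.nwk").write_text(newick + "\n")
        for rank in ("phylum", "genus"):
            prof = microbiome.composition_profile(ft, rank=rank)
            prof.round(6).to_csv(out / f"composition_{rank}.tsv", sep="\t",
                                 index_label="taxon")
        lef = microbiome.lefse(ft, alpha=cfg.alpha, lda_min=cfg.lda_min,
                               seed=cfg.seed)
        lef.round(6).to_csv(out / "lefse.tsv", sep="\t")
        summary["stages"].append("microbiome_stats")
        summary["nmds_stress"] = round(float(nm.stress), 6)
        summary["nmds_valid"] = bool(nm.valid)
        summary["n_lefse_significant"] = int(lef["significant"].sum())

    if "dai_score" in stages:
        _require(cfg, "dai_score", "dai_table")
        cohort = io.read_dai_observations(cfg.dai_table)
        dai_table = dai.cohort_summary(cohort)
        dai_table.round(4).to_csv(out / "dai_summary.tsv", sep="\t")
        summary["stages"].append("dai_score")
        summary["dai_group_means"] = {
            g: round(float(v), 4) for g, v in dai_table["total_mean"].items()
        }

    # --- manifest ----------------------------------------------------------
    inputs = {
        name: {"path": getattr(cfg, name),
               "sha256": _sha256(Path(getattr(cfg, name)))}
        for name in ("compounds", "compound_targets", "disease_genes",
                     "ppi_edges", "gene_sets", "feature_table", "group_map",
                     "dai_table")
        if getattr(cfg, name) is not None and Path(getattr(cfg, name)).exists()
    }
    io.write_json(summary, out / "summary.json")
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "ob_min": cfg.ob_min, "dl_min": cfg.dl_min,
            "conf_min": cfg.conf_min, "rounds": cfg.rounds,
            "alpha": cfg.alpha, "lda_min": cfg.lda_min,
            "min_fraction": cfg.min_fraction,
        },
        "inputs": inputs,
        "outputs": outputs,
        "stages": summary["stages"],
    }
    io.write_json(manifest, out / "manifest.json")
    return summary
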