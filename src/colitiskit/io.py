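"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular inputs are TSV with headers; gene-set collections are standard
GMT.  PPI edge lists in the STRING export dialect (integer scores 0-1000)
are detected automatically and rescaled to [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .dai import DAIObservation
from .enrich import GeneSetCollection, GeneSetTerm
from .hit import CompoundRecord, DiseaseGeneSource, normalize_gene_symbols
from .microbiome import FeatureTable

__all__ = [
    "read_compound_records",
    "write_compound_records",
    "read_disease_sources",
    "write_disease_sources",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_gmt",
    "write_gmt",
    "read_feature_table",
    "write_feature_table",
    "read_dai_observations",
    "write_dai_observations",
    "write_network_tables",
    "write_json",
]


def read_compound_records(
    compounds_path: str | Path, targets_path: str | Path
) -> list[CompoundRecord]:
    """Read the compound TSV (``herb_id, compound_id, compound_name, ob, dl``)
    and target-map TSV (``compound_id, gene_symbol``)."""
    comp = pd.read_csv(compounds_path, sep="\t", dtype=str)
    targ = pd.read_csv(targets_path, sep="\t", dtype=str)
    tmap: dict[str, set[str]] = {}
    for cid, sym in zip(targ["compound_id"], targ["gene_symbol"]):
        tmap.setdefault(cid, set()).update(normalize_gene_symbols([sym]))
    records = []
    for row in comp.itertuples(index=False):
        records.append(
            CompoundRecord(
                herb_id=row.herb_id,
                compound_id=row.compound_id,
                compound_name=row.compound_name,
                ob=float(row.ob),
                dl=float(row.dl),
                targets=set(tmap.get(row.compound_id, set())),
            )
        )
    return records


def write_compound_records(
    records: list[CompoundRecord],
    compounds_path: str | Path,
    targets_path: str | Path,
) -> None:
    comp = pd.DataFrame(
        [
            {
                "herb_id": r.herb_id,
                "compound_id": r.compound_id,
                "compound_name": r.compound_name,
                "ob": f"{r.ob:.6g}",
                "dl": f"{r.dl:.6g}",
            }
            for r in records
        ]
    )
    comp.to_csv(compounds_path, sep="\t", index=False)
    rows = []
    seen = set()
    for r in records:
        if r.compound_id in seen:
            continue
        seen.add(r.compound_id)
        for t in sorted(r.targets):
            rows.append({"compound_id": r.compound_id, "gene_symbol": t})
    pd.DataFrame(rows, columns=["compound_id", "gene_symbol"]).to_csv(
        targets_path, sep="\t", index=False
    )


def read_disease_sources(path: str | Path) -> list[DiseaseGeneSource]:
    """TSV ``source_name, gene_symbol`` -> one source per distinct name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for name, grp in df.groupby("source_name", sort=True):
        out.append(
            DiseaseGeneSource(name, normalize_gene_symbols(grp["gene_symbol"]))
        )
    return out


def write_disease_sources(
    sources: list[DiseaseGeneSource], path: str | Path
) -> None:
    rows = [
        {"source_name": s.source_name, "gene_symbol": g}
        for s in sources
        for g in sorted(s.genes)
    ]
    pd.DataFrame(rows, columns=["source_name", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def read_ppi_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """TSV ``protein1, protein2, combined_score``; STRING-style 0-1000 integer
    scores are detected (any score > 1) and divided by 1000."""
    df = pd.read_csv(path, sep="\t")
    scores = df["combined_score"].astype(float)
    if (scores > 1.0).any():
        scores = scores / 1000.0
    return [
        (str(a), str(b), float(c))
        for a, b, c in zip(df["protein1"], df["protein2"], scores)
    ]


def write_ppi_edges(
    edges: list[tuple[str, str, float]], path: str | Path
) -> None:
    pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_gmt(path: str | Path, category: str = "pathway") -> GeneSetCollection:
    """Standard GMT: ``term_id <tab> description <tab> gene...`` per line.

    The description field may override the collection-level ``category`` by
    carrying one of ``BP|CC|MF|pathway``.
    """
    terms: dict[str, GeneSetTerm] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_id, desc, genes = parts[0], parts[1], parts[2:]
        cat = desc if desc in ("BP", "CC", "MF", "pathway") else category
        name = term_id if desc in ("BP", "CC", "MF", "pathway", "") else desc
        if term_id in terms:
            raise ValueError(f"duplicate term id {term_id!r}")
        terms[term_id] = GeneSetTerm(name, cat, normalize_gene_symbols(genes))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for term_id, term in collection.terms.items():
        lines.append(
            "\t".join([term_id, term.category, *sorted(term.genes)])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(
    table_path: str | Path, groups_path: str | Path
) -> FeatureTable:
    """Features-by-samples TSV with a ``taxonomy`` column, plus a group map
    TSV ``sample_id, group``."""
    df = pd.read_csv(table_path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str)
        df = df.drop(columns=["taxonomy"])
    counts = df.T.astype(int)  # -> samples x features
    gmap = pd.read_csv(groups_path, sep="\t", dtype=str)
    groups = pd.Series(
        gmap["group"].to_numpy(), index=gmap["sample_id"].to_numpy()
    )
    return FeatureTable(counts, groups, taxonomy)


def write_feature_table(
    t: FeatureTable, table_path: str | Path, groups_path: str | Path
) -> None:
    df = t.counts.T.copy()  # features x samples
    if t.taxonomy is not None:
        df["taxonomy"] = t.taxonomy.loc[df.index]
    df.to_csv(table_path, sep="\t", index_label="feature_id")
    pd.DataFrame(
        {"sample_id": t.groups.index, "group": t.groups.to_numpy()}
    ).to_csv(groups_path, sep="\t", index=False)


_DAI_COLS = [
    "group", "stool", "weight_loss", "blood",
    "epithelial_destruction", "edema", "crypt_loss", "mucosa_infiltration",
]


def read_dai_observations(path: str | Path) -> dict[str, list[DAIObservation]]:
    df = pd.read_csv(path, sep="\t", dtype={"group": str})
    out: dict[str, list[DAIObservation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.group, []).append(
            DAIObservation(
                stool=row.stool,
                weight_loss=float(row.weight_loss),
                blood=row.blood,
                epithelial_destruction=int(row.epithelial_destruction),
                edema=int(row.edema),
                crypt_loss=int(row.crypt_loss),
                mucosa_infiltration=int(row.mucosa_infiltration),
            )
        )
    return out


def write_dai_observations(
    cohort: dict[str, list[DAIObservation]], path: str | Path
) -> None:
    rows = []
    for group, obs_list in cohort.items():
        for o in obs_list:
            rows.append(
                {
                    "group": group,
                    "stool": o.stool,
                    "weight_loss": f"{o.weight_loss:.4f}",
                    "blood": o.blood,
                    "epithelial_destruction": o.epithelial_destruction,
                    "edema": o.edema,
                    "crypt_loss": o.crypt_loss,
                    "mucosa_infiltration": o.mucosa_infiltration,
                }
            )
    pd.DataFrame(rows, columns=_DAI_COLS).to_csv(path, sep="\t", index=False)


def write_network_tables(
    g: nx.Graph, nodes_path: str | Path, edges_path: str | Path
) -> None:
    """Node table (id + attributes) and edge table (pair + attributes)."""
    nrows = [{"node": n, **d} for n, d in sorted(g.nodes(data=True))]
    pd.DataFrame(nrows).to_csv(nodes_path, sep="\t", index=False)
    erows = [
        {"source": a, "target": b, **d}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(erows).to_csv(edges_path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
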