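"""Pathway-crosstalk disruption on a differential-coexpression scaffold.

Correlation-decreased differential links form a global gene-gene scaffold;
for every pair of focused pathways, the number of scaffold edges spanning
the two (overlap genes removed) is tested for over-representation against a
hypergeometric null: drawing |A'|*|B'| gene-pair slots from all C(n, 2)
pairs of the universe, with the scaffold edges as successes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexrewire.compendium import Pathway
from coexrewire.datamodel import AnalysisConfig, DegenerateOutputError
from coexrewire.meta import pairs_universe

logger = logging.getLogger(__name__)


@dataclass
class Scaffold:
    """Deduplicated set of unordered gene pairs over a gene universe."""

    edges: set[tuple[str, str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.edges = {tuple(sorted(e)) for e in self.edges}
        bad = [e for e in self.edges if not set(e) <= self.universe]
        if bad:
            raise ValueError(f"scaffold edges outside universe: {bad[:3]}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class CrosstalkEdge:
    pathway_a: str
    pathway_b: str
    n_possible: int
    n_observed: int
    p: float
    significant: bool
    status: str = "ok"  # "skipped" when a side is empty after overlap removal


def build_scaffold(links: pd.DataFrame, universe: set[str] | None = None,
                   mode: str = "decreased_only") -> Scaffold:
    """Scaffold of differential links.

    ``decreased_only`` keeps decreased_positive DCLs plus diff_signed DCLs
    whose magnitude fell (|r2| < |r1|); ``all`` keeps every DCL.
    """
    dcl = links[links["is_dcl"]]
    if mode == "decreased_only":
        keep = (dcl["category"] == "decreased_positive") | (
            (dcl["category"] == "diff_signed")
            & (dcl["r2"].abs() < dcl["r1"].abs()))
        dcl = dcl[keep]
    elif mode != "all":
        raise ValueError(f"unknown scaffold mode {mode!r}")
    if dcl.empty:
        raise DegenerateOutputError("no links qualify for the scaffold")
    edges = {tuple(sorted((a, b)))
             for a, b in zip(dcl["gene_a"], dcl["gene_b"])}
    if universe is None:
        universe = set(links["gene_a"]) | set(links["gene_b"])
    logger.info("scaffold: %d edges over %d genes", len(edges), len(universe))
    return Scaffold(edges=edges, universe=set(universe))


def union_scaffolds(scaffolds: list[Scaffold]) -> Scaffold:
    """Union of per-dataset scaffolds (edge sets and universes)."""
    if not scaffolds:
        raise ValueError("no scaffolds to union")
    edges: set[tuple[str, str]] = set()
    universe: set[str] = set()
    for s in scaffolds:
        edges |= s.edges
        universe |= s.universe
    return Scaffold(edges=edges, universe=universe)


def crosstalk_test(scaffold: Scaffold, pathway_a: Pathway, pathway_b: Pathway,
                   p_threshold: float = 0.05) -> CrosstalkEdge:
    """Hypergeometric over-representation of scaffold edges between two pathways.

    Genes shared by both pathways are removed from each side, so a link
    inside the overlap never counts as crosstalk. The population is all
    C(|universe|, 2) gene pairs, successes are the scaffold edges, and the
    draw is the |A'| * |B'| inter-pathway slots.
    """
    a = (pathway_a.genes & scaffold.universe) - pathway_b.genes
    b = (pathway_b.genes & scaffold.universe) - pathway_a.genes
    if not a or not b:
        logger.warning("crosstalk %s~%s skipped: empty side after overlap "
                       "removal", pathway_a.name, pathway_b.name)
        return CrosstalkEdge(pathway_a.name, pathway_b.name, 0, 0, 1.0,
                             False, status="skipped")
    n_possible = len(a) * len(b)
    n_observed = sum(1 for u, v in scaffold.edges
                     if (u in a and v in b) or (u in b and v in a))
    population = pairs_universe(len(scaffold.universe))
    p = float(stats.hypergeom.sf(n_observed - 1, population,
                                 scaffold.n_edges, n_possible))
    return CrosstalkEdge(pathway_a.name, pathway_b.name, n_possible,
                         n_observed, p, p < p_threshold)


def crosstalk_map(scaffold: Scaffold, focused: list[Pathway],
                  cfg: AnalysisConfig | None = None,
                  dcgs: pd.DataFrame | None = None,
                  hubs: set[str] | None = None,
                  bh_adjust: bool = False,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test all focused-pathway pairs and export the disrupted-crosstalk map.

    Returns the pathway-pair table (pathway_a, pathway_b, n_possible,
    n_observed, p, significant) and the gene-level table of scaffold links
    contributing to significant pairs, with an ``in_subnetwork`` flag
    restricting to links incident to a DCG or a hub gene. Raw p-values are
    thresholded by default; set ``bh_adjust`` for BH correction instead.
    """
    if not focused:
        raise ValueError("empty focused pathway list")
    cfg = cfg or AnalysisConfig()
    results = []
    for i, pa in enumerate(focused):
        for pb in focused[i + 1:]:
            results.append(crosstalk_test(scaffold, pa, pb,
                                          cfg.crosstalk_p_threshold))
    table = pd.DataFrame([vars(e) for e in results])
    if bh_adjust and len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < cfg.crosstalk_p_threshold
    n_sig = int(table["significant"].sum()) if len(table) else 0
    logger.info("crosstalk map: %d significant of %d pathway pairs",
                n_sig, len(table))

    by_name = {p.name: p for p in focused}
    marked = set(dcgs.loc[dcgs["is_dcg"], "gene"]) if dcgs is not None else set()
    if hubs:
        marked |= set(hubs)
    gene_rows = []
    if n_sig:
        for _, row in table[table["significant"]].iterrows():
            pa, pb = by_name[row["pathway_a"]], by_name[row["pathway_b"]]
            a = (pa.genes & scaffold.universe) - pb.genes
            b = (pb.genes & scaffold.universe) - pa.genes
            for u, v in sorted(scaffold.edges):
                if (u in a and v in b) or (u in b and v in a):
                    gene_rows.append({
                        "pathway_a": row["pathway_a"],
                        "pathway_b": row["pathway_b"],
                        "gene_a": u, "gene_b": v,
                        "in_subnetwork": bool({u, v} & marked),
                    })
    gene_table = pd.DataFrame(
        gene_rows, columns=["pathway_a", "pathway_b", "gene_a", "gene_b",
                            "in_subnetwork"])
    return table, gene_table
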