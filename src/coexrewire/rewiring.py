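"""Per-pathway correlation-rewiring test, hubs, and wiring networks.

The test follows the gene-sets net-correlations idea: within a pathway each
gene receives a "weight" — its entry in the dominant eigenvector of the
absolute-correlation matrix (diagonal zeroed), scaled so the weights sum to
the pathway size. The L1 distance between the two conditions' weight
vectors is the rewiring statistic; significance comes from permuting sample
condition labels. The pathway hub is the maximum-weight gene, and the
wiring network is the union of the first and second minimum spanning trees
of the correlation-distance graph (d = 1 - |r|).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexrewire.compendium import Pathway, PathwayCompendium
from coexrewire.datamodel import AnalysisConfig, ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class RewiringResult:
    pathway: str
    d_obs: float
    p: float
    weights1: pd.Series
    weights2: pd.Series
    hub1: str
    hub2: str
    wiring1: list[tuple[str, str, float]]
    wiring2: list[tuple[str, str, float]]
    dissolution: str = "maintained"
    status: str = "ok"  # "skipped" when too few usable genes


def weight_vector(corr: pd.DataFrame | np.ndarray,
                  tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Dominant-eigenvector gene weights of an absolute correlation matrix.

    ``A = |r|`` with zeroed diagonal; the weight vector is the (positive)
    dominant eigenvector found by power iteration, scaled to sum to the
    number of genes. An identically zero matrix yields uniform weights.
    """
    a = np.abs(np.asarray(corr, dtype=float)).copy()
    p = a.shape[0]
    if p < 3:
        raise ValueError("need at least 3 genes for a weight vector")
    np.fill_diagonal(a, 0.0)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("correlation matrix is not symmetric")
    if np.all(a == 0):
        logger.warning("all-zero correlation matrix; uniform weights returned")
        return np.ones(p)
    w = np.full(p, 1.0 / np.sqrt(p))
    for _ in range(max_iter):
        nxt = a @ w
        norm = np.linalg.norm(nxt)
        if norm == 0:  # w in the null space; restart from a perturbed vector
            nxt = a @ (w + 1.0 / p)
            norm = np.linalg.norm(nxt)
        nxt /= norm
        if np.linalg.norm(nxt - w) <= tol * np.linalg.norm(w):
            w = nxt
            break
        w = nxt
    # Perron-Frobenius: the dominant eigenvector of a nonnegative matrix can
    # be taken nonnegative; fix the sign and rescale.
    if w.sum() < 0:
        w = -w
    w = np.abs(w)
    return w * (p / w.sum())


def _condition_corr(values: np.ndarray, cond_mask: np.ndarray) -> np.ndarray:
    r = np.corrcoef(values[:, cond_mask])
    np.fill_diagonal(r, 1.0)
    return r


def _weight_distance(values: np.ndarray, mask1: np.ndarray,
                     mask2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    w1 = weight_vector(_condition_corr(values, mask1))
    w2 = weight_vector(_condition_corr(values, mask2))
    return float(np.abs(w1 - w2).sum()), w1, w2


def _pathway_seed(base_seed: int, pathway_name: str) -> np.random.Generator:
    # stable per-pathway stream: results reproducible and parallelizable
    tag = zlib.crc32(pathway_name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([base_seed & 0x7FFFFFFF, tag]))


def _kruskal(edges: list[tuple[float, str, str]],
             nodes: list[str]) -> list[tuple[str, str, float]]:
    """Minimum spanning forest, edges pre-sorted by (distance, gene_a, gene_b)."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for d, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v, d))
            if len(tree) == len(nodes) - 1:
                break
    return tree


def wiring_network(corr: pd.DataFrame) -> list[tuple[str, str, float]]:
    """Union of the first and second minimum spanning trees.

    Distances are 1 - |r|; MST1 is the Kruskal tree of the complete graph
    (ties broken by (distance, gene_a, gene_b)), MST2 the tree of the
    complete graph with MST1's edges removed. Each returned edge carries
    |r|. For 3 genes only MST1 is returned (the remainder graph cannot
    span).
    """
    genes = list(corr.index)
    p = len(genes)
    if p < 3:
        raise ValueError("need at least 3 genes")
    a = np.abs(corr.to_numpy())
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            u, v = sorted((genes[i], genes[j]))
            edges.append((1.0 - a[i, j], u, v))
    edges.sort()
    mst1 = _kruskal(edges, genes)
    if p == 3:
        logger.warning("3-gene pathway: second MST undefined, returning MST1")
        return [(u, v, 1.0 - d) for u, v, d in mst1]
    used = {(u, v) for u, v, _ in mst1}
    rest = [(d, u, v) for d, u, v in edges if (u, v) not in used]
    mst2 = _kruskal(rest, genes)
    union = mst1 + mst2
    return [(u, v, 1.0 - d) for u, v, d in union]


def _hub(weights: pd.Series) -> str:
    """Maximum-weight gene; ties go to the lexicographically smallest name."""
    top = weights[weights == weights.max()]
    return min(top.index)


def gsnca_test(dataset: ExpressionDataset, pathway: Pathway,
               cfg: AnalysisConfig | None = None,
               links: pd.DataFrame | None = None) -> RewiringResult:
    """Label-permutation rewiring test of one pathway.

    The observed statistic is the L1 distance between condition-wise weight
    vectors; the p-value is the add-one permutation estimator over
    ``cfg.n_perm_gsnca`` relabelings preserving group sizes, on a stream
    seeded from ``cfg.rng_seed`` plus a stable hash of the pathway name.
    """
    cfg = cfg or AnalysisConfig()
    genes = sorted(g for g in pathway.genes if g in dataset.matrix.index)
    sub = dataset.matrix.loc[genes]
    values = sub.to_numpy(dtype=float)
    samples = list(dataset.matrix.columns)
    labels = np.asarray([dataset.design[s] for s in samples])
    mask1 = labels == dataset.conditions[0]
    mask2 = labels == dataset.conditions[1]
    # zero variance in either condition makes r undefined: drop the gene
    usable = ((values[:, mask1].std(axis=1) > 0)
              & (values[:, mask2].std(axis=1) > 0))
    if usable.sum() < 3:
        logger.warning("pathway %r reduced below 3 usable genes; skipped",
                       pathway.name)
        empty = pd.Series(dtype=float)
        return RewiringResult(pathway=pathway.name, d_obs=np.nan, p=1.0,
                              weights1=empty, weights2=empty,
                              hub1="", hub2="", wiring1=[], wiring2=[],
                              status="skipped")
    genes = [g for g, u in zip(genes, usable) if u]
    values = values[usable]

    d_obs, w1, w2 = _weight_distance(values, mask1, mask2)
    rng = _pathway_seed(cfg.rng_seed, pathway.name)
    n1 = int(mask1.sum())
    n_total = len(samples)
    count = 0
    for _ in range(cfg.n_perm_gsnca):
        perm = rng.permutation(n_total)
        pm1 = np.zeros(n_total, dtype=bool)
        pm1[perm[:n1]] = True
        d_perm, _, _ = _weight_distance(values, pm1, ~pm1)
        if d_perm >= d_obs:
            count += 1
    p = (1 + count) / (1 + cfg.n_perm_gsnca)

    weights1 = pd.Series(w1, index=genes)
    weights2 = pd.Series(w2, index=genes)
    c1 = pd.DataFrame(_condition_corr(values, mask1), index=genes, columns=genes)
    c2 = pd.DataFrame(_condition_corr(values, mask2), index=genes, columns=genes)
    result = RewiringResult(
        pathway=pathway.name, d_obs=d_obs, p=p,
        weights1=weights1, weights2=weights2,
        hub1=_hub(weights1), hub2=_hub(weights2),
        wiring1=wiring_network(c1), wiring2=wiring_network(c2),
    )
    if links is not None:
        result.dissolution = classify_dissolution(pathway, links)
    return result


def classify_dissolution(pathway: Pathway, links: pd.DataFrame,
                         tolerance: int = 0) -> str:
    """Dissolved / consolidated / maintained by intra-pathway DCL balance.

    Over DCLs with both endpoints in the pathway, a link counts as decreased
    when |r2| < |r1| (or a sign-switch with |r2| <= |r1|); dissolved when
    decreased links outnumber increased ones by more than ``tolerance``,
    consolidated in the opposite case, maintained otherwise (including the
    zero-DCL case).
    """
    genes = pathway.genes
    dcl = links[links["is_dcl"]
                & links["gene_a"].isin(genes) & links["gene_b"].isin(genes)]
    if dcl.empty:
        return "maintained"
    a1 = dcl["r1"].abs().to_numpy()
    a2 = dcl["r2"].abs().to_numpy()
    switch = (dcl["category"] == "diff_signed").to_numpy()
    dec = np.where(switch, a2 <= a1, a2 < a1)
    n_dec = int(dec.sum())
    n_inc = len(dcl) - n_dec
    if n_dec > n_inc + tolerance:
        return "dissolved"
    if n_inc > n_dec + tolerance:
        return "consolidated"
    return "maintained"


def rewire_all(dataset: ExpressionDataset, compendium: PathwayCompendium,
               cfg: AnalysisConfig | None = None,
               links: pd.DataFrame | None = None,
               ) -> tuple[pd.DataFrame, dict[str, RewiringResult]]:
    """Run the rewiring test over a whole compendium.

    Returns a summary table (pathway, size, d_obs, p, hub1, hub2,
    dissolution, status) and the per-pathway result objects.
    """
    cfg = cfg or AnalysisConfig()
    rows, results = [], {}
    for pathway in compendium:
        res = gsnca_test(dataset, pathway, cfg, links=links)
        results[pathway.name] = res
        rows.append({"pathway": pathway.name, "size": pathway.size,
                     "d_obs": res.d_obs, "p": res.p,
                     "hub1": res.hub1, "hub2": res.hub2,
                     "dissolution": res.dissolution, "status": res.status})
    return pd.DataFrame(rows), results
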