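"""Multi-dataset aggregation and reproducibility statistics.

Per-pathway permutation p-values from independent datasets are combined by
Fisher's method (-2 sum(ln p) against chi-square with 2k df); "focused"
pathways are those significant in at least two datasets and in aggregate.
Agreement between result lists is scored with hypergeometric tail tests.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def fisher_combined(p_values: Sequence[float],
                    floor: float | None = None) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns ``(chi2, df, aggregate_p)`` with chi2 = -2 sum(ln p_i) and
    df = 2k. Zero p-values (possible only if a caller bypasses the add-one
    permutation estimator) are clamped to ``floor`` with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if floor is not None and (p == 0).any():
        logger.warning("clamping %d zero p-values to %g", int((p == 0).sum()), floor)
        p = np.maximum(p, floor)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def combine_datasets(per_dataset_p: pd.DataFrame,
                     p_threshold: float = 0.01) -> pd.DataFrame:
    """Aggregate a pathways-by-datasets p-value table.

    Missing/skipped tests are treated conservatively as p = 1 so degrees of
    freedom stay constant across pathways. Adds chi2, aggregate_p, and the
    focused flag (>= 2 datasets below ``p_threshold`` AND aggregate below
    it); rows ordered by increasing aggregate_p.
    """
    filled = per_dataset_p.fillna(1.0)
    rows = []
    for pathway, ps in filled.iterrows():
        chi2, df, agg = fisher_combined(ps.to_numpy())
        n_sig = int((ps < p_threshold).sum())
        rows.append({"pathway": pathway, "chi2": chi2, "df": df,
                     "aggregate_p": agg,
                     "focused": (n_sig >= 2) and (agg < p_threshold)})
    out = pd.DataFrame(rows).set_index("pathway")
    out = pd.concat([filled, out], axis=1)
    return out.sort_values("aggregate_p")


def select_focused(per_dataset_p: pd.DataFrame,
                   p_threshold: float = 0.01) -> list[str]:
    """Focused pathway names, ordered by increasing aggregate p."""
    table = combine_datasets(per_dataset_p, p_threshold)
    return list(table.index[table["focused"]])


def pairs_universe(n_genes: int) -> int:
    """Number of unordered gene pairs, C(n, 2)."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return n_genes * (n_genes - 1) // 2


def overlap_significance(universe_size: int, list_a_size: int,
                         list_b_size: int, shared: int) -> float:
    """Hypergeometric tail P(X >= shared) for the overlap of two lists."""
    if not (0 <= shared <= min(list_a_size, list_b_size)
            <= max(list_a_size, list_b_size) <= universe_size):
        raise ValueError("inconsistent counts for overlap test")
    return float(stats.hypergeom.sf(shared - 1, universe_size,
                                    list_a_size, list_b_size))


def topk_agreement(rankings: dict[str, Sequence[str]],
                   k_grid: Sequence[int] | None = None) -> pd.DataFrame:
    """Top-k list agreement between every dataset pair.

    ``rankings`` maps dataset name to its pathway names ordered by
    increasing p (ties at rank k broken by name within each ranking, which
    the caller guarantees by a stable (p, name) sort). Returns a long-format
    table (dataset_a, dataset_b, k, overlap, p) whose log10(p) is ready for
    a heatmap; k values beyond the universe are clipped with a warning.
    """
    names = list(rankings)
    universe = set().union(*[set(r) for r in rankings.values()])
    n = len(universe)
    for ds, r in rankings.items():
        if set(r) != universe:
            raise ValueError(f"ranking {ds!r} not over the common universe")
    if k_grid is None:
        k_grid = range(5, 151, 5)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for k in k_grid:
                kk = min(int(k), n)
                if kk != k:
                    logger.warning("k=%d clipped to universe size %d", k, n)
                top_a = set(rankings[a][:kk])
                top_b = set(rankings[b][:kk])
                shared = len(top_a & top_b)
                rows.append({"dataset_a": a, "dataset_b": b, "k": kk,
                             "overlap": shared,
                             "p": overlap_significance(n, kk, kk, shared)})
    return pd.DataFrame(rows)


def rank_pathways(p_table: pd.DataFrame) -> dict[str, list[str]]:
    """Per-dataset pathway rankings by (p, name) for topk_agreement."""
    out = {}
    for col in p_table.columns:
        s = p_table[col].fillna(1.0)
        out[col] = [name for name, _ in
                    sorted(s.items(), key=lambda kv: (kv[1], kv[0]))]
    return out
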