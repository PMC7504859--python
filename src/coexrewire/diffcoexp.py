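"""Differentially coexpressed links (DCLs) and genes (DCGs).

For every unordered gene pair the Pearson correlation is computed in each
condition. A link universe is selected at a target network density; links
whose correlation fold-change escapes a magnitude-stratified limit-fold-change
(LFC) envelope, or whose correlation flips sign at high magnitude in both
conditions, are called DCLs. Genes accumulating more incident DCLs than a
binomial null expects are called DCGs.

DCL categories
--------------
``diff_signed``
    extreme correlations of opposite sign in the two conditions.
``same_signed_negative``
    both correlations negative.
``increased_positive`` / ``decreased_positive``
    both positive, magnitude rising / falling from condition 1 to 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexrewire.datamodel import AnalysisConfig, ExpressionDataset

logger = logging.getLogger(__name__)

FOLD_EPS = 1e-4  # guards fold division when min(|r1|, |r2|) = 0

CATEGORIES = ("diff_signed", "same_signed_negative",
              "increased_positive", "decreased_positive")


@dataclass
class DiffCoexpResult:
    """Link table, DCG table, and summary shares of one dataset comparison.

    ``links`` columns: gene_a, gene_b (gene_a < gene_b), r1, r2, is_link,
    is_dcl, category. ``dcgs`` columns: gene, k, d, dcl_rate, p, q, is_dcg.
    """

    links: pd.DataFrame
    dcgs: pd.DataFrame
    pi_global: float
    category_shares: dict[str, float] = field(default_factory=dict)

    @property
    def dcls(self) -> pd.DataFrame:
        return self.links[self.links["is_dcl"]]


def _sign(r: np.ndarray) -> np.ndarray:
    """Sign with zero treated as positive."""
    return np.where(np.asarray(r) >= 0, 1, -1)


def condition_correlations(dataset: ExpressionDataset,
                           genes: list[str] | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Pearson correlation matrix over ``genes`` for each condition.

    Genes with zero variance in either condition have undefined correlations
    and are excluded with a warning.
    """
    genes = list(genes) if genes is not None else dataset.genes
    missing = [g for g in genes if g not in dataset.matrix.index]
    if missing:
        raise KeyError(f"genes absent from dataset: {missing[:5]}")
    mats = [dataset.condition_matrix(c).loc[genes] for c in dataset.conditions]
    usable = np.ones(len(genes), dtype=bool)
    for m in mats:
        usable &= m.to_numpy().std(axis=1) > 0
    if not usable.all():
        dropped = [g for g, u in zip(genes, usable) if not u]
        logger.warning("excluding %d zero-variance genes: %s",
                       len(dropped), dropped[:5])
        genes = [g for g, u in zip(genes, usable) if u]
        mats = [m.loc[genes] for m in mats]
    out = []
    for m in mats:
        r = np.corrcoef(m.to_numpy())
        np.fill_diagonal(r, 1.0)
        out.append(pd.DataFrame(r, index=genes, columns=genes))
    return out[0], out[1]


def _pair_table(r1: pd.DataFrame, r2: pd.DataFrame) -> pd.DataFrame:
    genes = list(r1.index)
    if list(r2.index) != genes:
        raise ValueError("correlation matrices not aligned on the same genes")
    iu = np.triu_indices(len(genes), k=1)
    ga = np.asarray(genes, dtype=object)[iu[0]]
    gb = np.asarray(genes, dtype=object)[iu[1]]
    # canonical unordered-pair storage: gene_a < gene_b lexicographically
    swap = ga > gb
    ga2 = np.where(swap, gb, ga)
    gb2 = np.where(swap, ga, gb)
    return pd.DataFrame({
        "gene_a": ga2, "gene_b": gb2,
        "r1": r1.to_numpy()[iu], "r2": r2.to_numpy()[iu],
    })


def select_links(r1: pd.DataFrame, r2: pd.DataFrame,
                 cfg: AnalysisConfig) -> pd.DataFrame:
    """Select the coexpression link universe at the configured density.

    Per condition the cutoff is the (1 - density) empirical quantile of all
    pairwise |r| (upper interpolation, so quantile ties are included and the
    realized density is at least the target); a pair is a link when it passes
    the cutoff in either condition.
    """
    if len(r1) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    pairs = _pair_table(r1, r2)
    cutoffs = []
    for col in ("r1", "r2"):
        v = np.abs(pairs[col].to_numpy())
        t = np.quantile(v, 1.0 - cfg.density, method="higher")
        cutoffs.append(t)
    pairs["is_link"] = ((np.abs(pairs["r1"]) >= cutoffs[0])
                        | (np.abs(pairs["r2"]) >= cutoffs[1]))
    pairs.attrs["cutoffs"] = tuple(float(t) for t in cutoffs)
    logger.info("link universe: %d of %d pairs (t1=%.3f, t2=%.3f)",
                int(pairs["is_link"].sum()), len(pairs), *cutoffs)
    return pairs


def classify_dcl(r1: float, r2: float) -> str:
    """Four-way DCL category from the paired correlation values."""
    s1, s2 = (1 if r1 >= 0 else -1), (1 if r2 >= 0 else -1)
    if s1 != s2:
        return "diff_signed"
    if s1 < 0:
        return "same_signed_negative"
    if abs(r2) > abs(r1):
        return "increased_positive"
    if abs(r2) < abs(r1):
        return "decreased_positive"
    raise RuntimeError("|r1| == |r2| cannot occur for an LFC-selected DCL")


def _lfc_envelope(x: np.ndarray, fold: np.ndarray, order: np.ndarray,
                  q: float, n_bins: int) -> np.ndarray:
    """Fit the per-bin limit-fold-change envelope and evaluate it at x.

    Pairs are split into ``n_bins`` equal-count bins by x = max(|r1|, |r2|)
    (``order`` supplies the deterministic sort); within each bin the cutoff
    is the largest fold NOT in the top-q, and a power law y = a * x^b is
    least-squares fitted to (bin median x, cutoff) in log space. With a
    single usable bin the envelope is the constant bin cutoff.
    """
    n = len(x)
    bins = np.array_split(order, n_bins)
    xs, ys = [], []
    for idx in bins:
        if len(idx) == 0:
            continue
        k = int(np.ceil(q * len(idx)))
        f = fold[idx]
        sel = np.argsort(-f, kind="stable")
        if k >= len(idx):
            cutoff = 1.0  # every pair selected: envelope floor
        else:
            cutoff = float(f[sel[k:]].max())
        xs.append(float(np.median(x[idx])))
        ys.append(max(cutoff, 1.0))
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    ok = xs_a > 0
    if ok.sum() >= 2 and np.ptp(np.log(xs_a[ok])) > 1e-12:
        ly = np.log(np.maximum(ys_a[ok], 1.0 + 1e-9))
        b, la = np.polyfit(np.log(xs_a[ok]), ly, 1)
        env = np.exp(la) * np.maximum(x, FOLD_EPS) ** b
        # a fold of exactly 1 (|r1| = |r2|) must never pass the envelope
        return np.maximum(env, 1.0)
    return np.full(n, max(ys_a[ok].mean() if ok.any() else ys_a.mean(), 1.0))


def call_dcls(pairs: pd.DataFrame, cfg: AnalysisConfig,
              n_bins: int = 20) -> pd.DataFrame:
    """Flag DCLs within the link universe.

    Sign-switch pairs strong in both conditions (|r| above the density
    cutoff of each condition) are DCLs outright. Remaining same-signed links
    are ranked by fold = max(|r1|,|r2|) / max(min(|r1|,|r2|), eps) inside
    equal-count magnitude bins; a pair is a DCL when its fold strictly
    exceeds the fitted power-law envelope. The a-priori DCL share is
    ``cfg.dcl_fraction``.
    """
    links = pairs[pairs["is_link"]]
    if links.empty:
        raise ValueError("empty link universe")
    t1, t2 = pairs.attrs.get("cutoffs", (0.0, 0.0))
    out = pairs.copy()
    out["is_dcl"] = False
    out["category"] = "none"

    r1 = links["r1"].to_numpy()
    r2 = links["r2"].to_numpy()
    a1, a2 = np.abs(r1), np.abs(r2)
    sign_switch = _sign(r1) != _sign(r2)
    dcl_switch = sign_switch & (a1 >= t1) & (a2 >= t2)

    same = ~sign_switch
    idx_same = links.index[same]
    if cfg.dcl_fraction > 0 and len(idx_same) > 0:
        x = np.maximum(a1[same], a2[same])
        fold = x / np.maximum(np.minimum(a1[same], a2[same]), FOLD_EPS)
        n_pairs = len(idx_same)
        b_eff = int(min(n_bins, max(1, int(np.ceil(n_pairs / 50)))))
        # deterministic ordering by (x, gene_a, gene_b) for binning/ties
        sub = links.loc[idx_same]
        order = np.lexsort((sub["gene_b"].to_numpy(),
                            sub["gene_a"].to_numpy(), x))
        env = _lfc_envelope(x, fold, order, cfg.dcl_fraction, b_eff)
        dcl_same = fold > env
        out.loc[idx_same[dcl_same], "is_dcl"] = True

    out.loc[links.index[dcl_switch], "is_dcl"] = True
    mask = out["is_dcl"]
    out.loc[mask, "category"] = [
        classify_dcl(a, b) for a, b in zip(out.loc[mask, "r1"],
                                           out.loc[mask, "r2"])]
    return out


def call_dcgs(links: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Binomial tail test for genes with excess incident DCLs.

    For each gene with k incident links of which d are DCLs,
    p = P(X >= d), X ~ Binomial(k, pi) with pi the global DCL fraction;
    q by Benjamini-Hochberg; DCG iff q < ``cfg.dcg_q_threshold``.
    """
    universe = links[links["is_link"]]
    if universe.empty:
        raise ValueError("empty link universe")
    pi = float(universe["is_dcl"].mean())
    melted = pd.concat([
        universe[["gene_a", "is_dcl"]].rename(columns={"gene_a": "gene"}),
        universe[["gene_b", "is_dcl"]].rename(columns={"gene_b": "gene"}),
    ])
    grouped = melted.groupby("gene")["is_dcl"].agg(k="size", d="sum")
    k = grouped["k"].to_numpy()
    d = grouped["d"].to_numpy()
    p = stats.binom.sf(d - 1, k, pi)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame({
        "gene": grouped.index, "k": k, "d": d,
        "dcl_rate": d / k, "p": p, "q": q,
        "is_dcg": q < cfg.dcg_q_threshold,
    }).reset_index(drop=True)
    out.attrs["pi_global"] = pi
    return out


def diff_coexpression(dataset: ExpressionDataset,
                      genes: list[str] | None = None,
                      cfg: AnalysisConfig | None = None) -> DiffCoexpResult:
    """Full DCL/DCG analysis of one two-condition dataset."""
    cfg = cfg or AnalysisConfig()
    r1, r2 = condition_correlations(dataset, genes)
    pairs = select_links(r1, r2, cfg)
    links = call_dcls(pairs, cfg)
    dcgs = call_dcgs(links, cfg)
    n_link = int(links["is_link"].sum())
    n_dcl = int(links["is_dcl"].sum())
    pi = n_dcl / n_link if n_link else 0.0
    shares = {}
    if n_dcl:
        counts = links.loc[links["is_dcl"], "category"].value_counts()
        shares = {c: float(counts.get(c, 0)) / n_dcl for c in CATEGORIES}
    logger.info("DCLs: %d of %d links (pi=%.3f); DCGs: %d",
                n_dcl, n_link, pi, int(dcgs["is_dcg"].sum()))
    return DiffCoexpResult(links=links, dcgs=dcgs, pi_global=pi,
                           category_shares=shares)
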