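"""Hub-gene dynamics: constancy, retention, vanishing hubs, permutation nulls.

A pathway hub is the maximum-weight gene of the pathway's condition-specific
correlation structure. Two summary rates are tracked across a condition
transition: the *constancy rate* (fraction of focused pathways whose hub is
identical in both conditions) and the *retention rate* (fraction of
baseline-condition hub genes, restricted to differentially coexpressed
genes, that keep hub status in the perturbed condition). Their rarity is
assessed against two empirical nulls: shuffling sample condition labels, and
shuffling the gene-to-pathway annotation while preserving pathway sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexrewire.compendium import Pathway, PathwayCompendium
from coexrewire.datamodel import AnalysisConfig, ExpressionDataset
from coexrewire.diffcoexp import diff_coexpression
from coexrewire.rewiring import _condition_corr, _hub, weight_vector

logger = logging.getLogger(__name__)


@dataclass
class HubDynamics:
    constancy_numerator: int
    constancy_denominator: int
    retention_numerator: int
    retention_denominator: int
    vanishing_hubs: list[str]
    null_constancy: np.ndarray | None = None
    null_retention: np.ndarray | None = None
    p_constancy: float | None = None
    p_retention: float | None = None

    @property
    def constancy_rate(self) -> float:
        if self.constancy_denominator == 0:
            return float("nan")
        return self.constancy_numerator / self.constancy_denominator

    @property
    def retention_rate(self) -> float:
        if self.retention_denominator == 0:
            return float("nan")
        return self.retention_numerator / self.retention_denominator


def compute_hubs(dataset: ExpressionDataset,
                 compendium: PathwayCompendium) -> pd.DataFrame:
    """Condition-wise hub gene of every pathway (no permutation testing)."""
    samples = list(dataset.matrix.columns)
    labels = np.asarray([dataset.design[s] for s in samples])
    mask1 = labels == dataset.conditions[0]
    mask2 = labels == dataset.conditions[1]
    rows = []
    for pathway in compendium:
        genes = sorted(g for g in pathway.genes if g in dataset.matrix.index)
        values = dataset.matrix.loc[genes].to_numpy(dtype=float)
        usable = ((values[:, mask1].std(axis=1) > 0)
                  & (values[:, mask2].std(axis=1) > 0))
        if usable.sum() < 3:
            rows.append({"pathway": pathway.name, "hub1": "", "hub2": "",
                         "status": "skipped"})
            continue
        genes = [g for g, u in zip(genes, usable) if u]
        values = values[usable]
        w1 = pd.Series(weight_vector(_condition_corr(values, mask1)), index=genes)
        w2 = pd.Series(weight_vector(_condition_corr(values, mask2)), index=genes)
        rows.append({"pathway": pathway.name, "hub1": _hub(w1),
                     "hub2": _hub(w2), "status": "ok"})
    return pd.DataFrame(rows)


def hub_rates(hubs: pd.DataFrame, dcgs: pd.DataFrame,
              focused: list[str]) -> HubDynamics:
    """Observed constancy and retention rates plus the vanishing-hub list.

    ``hubs`` is a table with pathway/hub1/hub2/status (from
    :func:`compute_hubs` or :func:`coexrewire.rewiring.rewire_all`).
    Constancy is evaluated over the focused pathways; retention over the
    distinct baseline hubs (all pathways) flagged as DCGs, counting a gene
    retained when it is also the perturbed-condition hub of at least one
    pathway it hubbed at baseline. Retention bookkeeping is per gene.
    """
    ok = hubs[hubs["status"] == "ok"]
    foc = ok[ok["pathway"].isin(set(focused))]
    if foc.empty:
        logger.debug("no focused pathways with computed hubs; "
                     "constancy rate undefined")
    c_num = int((foc["hub1"] == foc["hub2"]).sum())
    c_den = int(len(foc))

    dcg_genes = set(dcgs.loc[dcgs["is_dcg"], "gene"])
    early_hub_dcgs = sorted(set(ok["hub1"]) & dcg_genes)
    retained = []
    for gene in early_hub_dcgs:
        mine = ok[ok["hub1"] == gene]
        if (mine["hub2"] == gene).any():
            retained.append(gene)
    if not early_hub_dcgs:
        logger.debug("no baseline hub is a DCG; retention rate undefined")
    vanishing = [g for g in early_hub_dcgs if g not in retained]
    return HubDynamics(
        constancy_numerator=c_num, constancy_denominator=c_den,
        retention_numerator=len(retained),
        retention_denominator=len(early_hub_dcgs),
        vanishing_hubs=vanishing,
    )


def lower_tail_p(rate_obs: float, null_rates: np.ndarray) -> float:
    """Add-one lower-tail empirical p: (1 + #{null <= obs}) / (1 + n)."""
    null = np.asarray(null_rates, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValueError("no valid null replicates")
    return float((1 + int((null <= rate_obs).sum())) / (1 + null.size))


def _rates_one(hubs: pd.DataFrame, dcgs: pd.DataFrame,
               focused: list[str]) -> tuple[float, float]:
    dyn = hub_rates(hubs, dcgs, focused)
    return dyn.constancy_rate, dyn.retention_rate


def null_by_label_permutation(dataset: ExpressionDataset,
                              compendium: PathwayCompendium,
                              focused: list[str],
                              observed: HubDynamics,
                              cfg: AnalysisConfig | None = None,
                              ) -> HubDynamics:
    """Null hub rates from shuffled sample condition labels.

    Each replicate permutes condition labels (group sizes preserved),
    recomputes every pathway hub and the DCG calls on the relabeled data,
    and records both rates. Lower-tail add-one p-values are attached to a
    copy of ``observed``.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed & 0x7FFFFFFF, 1]))
    samples = list(dataset.matrix.columns)
    labels = [dataset.design[s] for s in samples]
    gene_universe = sorted(compendium.gene_universe()
                           & set(dataset.matrix.index))
    nc, nr = [], []
    for i in range(cfg.n_perm_hub):
        shuffled = rng.permutation(labels)
        design = dict(zip(samples, shuffled))
        permuted = dataset.with_labels(design)
        hubs = compute_hubs(permuted, compendium)
        dcgs = diff_coexpression(permuted, gene_universe, cfg).dcgs
        c, r = _rates_one(hubs, dcgs, focused)
        nc.append(c)
        nr.append(r)
    return _attach_null(observed, np.asarray(nc), np.asarray(nr))


def null_by_annotation_permutation(dataset: ExpressionDataset,
                                   compendium: PathwayCompendium,
                                   focused: list[str],
                                   observed: HubDynamics,
                                   dcgs: pd.DataFrame,
                                   cfg: AnalysisConfig | None = None,
                                   ) -> HubDynamics:
    """Null hub rates from shuffled gene-to-pathway annotation.

    Each replicate redraws every pathway's gene set uniformly (without
    replacement within a pathway) from the measured gene universe,
    preserving the pathway size profile; pseudo-pathways inherit the
    focused status of the real pathway at their position. Hubs are
    recomputed on the real labels; DCG calls are annotation-free and reused.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed & 0x7FFFFFFF, 2]))
    universe = np.asarray(sorted(compendium.gene_universe()
                                 & set(dataset.matrix.index)), dtype=object)
    focused_set = set(focused)
    nc, nr = [], []
    for i in range(cfg.n_perm_hub):
        pseudo, pseudo_focused = [], []
        for pathway in compendium:
            size = min(pathway.size, len(universe))
            genes = rng.choice(universe, size=size, replace=False)
            name = f"pseudo::{pathway.name}"
            pseudo.append(Pathway(name=name, source="shuffled",
                                  genes=frozenset(genes)))
            if pathway.name in focused_set:
                pseudo_focused.append(name)
        hubs = compute_hubs(dataset, PathwayCompendium(pseudo))
        c, r = _rates_one(hubs, dcgs, pseudo_focused)
        nc.append(c)
        nr.append(r)
    return _attach_null(observed, np.asarray(nc), np.asarray(nr))


def _attach_null(observed: HubDynamics, null_constancy: np.ndarray,
                 null_retention: np.ndarray) -> HubDynamics:
    out = HubDynamics(
        constancy_numerator=observed.constancy_numerator,
        constancy_denominator=observed.constancy_denominator,
        retention_numerator=observed.retention_numerator,
        retention_denominator=observed.retention_denominator,
        vanishing_hubs=list(observed.vanishing_hubs),
        null_constancy=null_constancy,
        null_retention=null_retention,
    )
    if observed.constancy_denominator > 0:
        out.p_constancy = lower_tail_p(observed.constancy_rate, null_constancy)
    if observed.retention_denominator > 0:
        valid = null_retention[~np.isnan(null_retention)]
        if valid.size:
            out.p_retention = lower_tail_p(observed.retention_rate, null_retention)
    return out


def plot_null_histogram(null_rates: np.ndarray, rate_obs: float, path,
                        title: str = "") -> None:
    """Observed rate as a vertical line over the permutation-null histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    null = np.asarray(null_rates, dtype=float)
    null = null[~np.isnan(null)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(null, bins=20, color="0.7", edgecolor="0.4")
    ax.axvline(rate_obs, color="red", lw=2, label=f"observed = {rate_obs:.3f}")
    ax.set_xlabel("rate")
    ax.set_ylabel("permutations")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
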