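"""Two-condition synthetic expression data with planted correlation structure.

The generator emulates the statistical regime the analysis assumes:
multivariate-normal expression whose correlation matrix carries
within-pathway blocks that attenuate from the baseline to the perturbed
condition (e.g. rho 0.8 -> 0.1), a designated hub gene per pathway with
elevated within-block correlation, optional cross-pathway couplings that
decohere in condition 2, and uncorrelated background genes. Target
correlation matrices are repaired to the nearest positive-definite matrix
by eigenvalue clipping; generation fails if the repair moves any entry by
more than ``max_repair_dev``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from coexrewire.compendium import Pathway
from coexrewire.datamodel import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class CrosstalkSpec:
    """Planted coupling between ``n_genes_a`` x ``n_genes_b`` non-hub genes."""

    pathway_a: int
    pathway_b: int
    rho_cond1: float
    rho_cond2: float
    n_genes_a: int = 3
    n_genes_b: int = 2


@dataclass
class SynthConfig:
    """Stated world of the synthetic two-condition transcriptome.

    ``rho_within`` maps a pathway class name to its (condition 1,
    condition 2) within-block correlation, e.g. attenuated: (0.8, 0.1) or
    null: (0.8, 0.8); ``pathway_classes`` assigns one class per pathway
    (default: every pathway takes the first declared class). The hub gene
    of each block gets an additive correlation advantage of ``hub_boost``
    in both conditions, capped so the block stays positive definite.
    """

    n_pathways: int = 3
    genes_per_pathway: int = 15
    n_background_genes: int = 30
    samples_per_condition: int = 50
    rho_within: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"attenuated": (0.8, 0.1)})
    pathway_classes: list[str] | None = None
    hub_boost: float = 0.2
    crosstalk: list[CrosstalkSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    rng_seed: int = 0
    max_repair_dev: float = 0.02

    def __post_init__(self) -> None:
        for cls, (r1, r2) in self.rho_within.items():
            for r in (r1, r2):
                if not -1.0 < r < 1.0:
                    raise ValueError(f"rho_within[{cls!r}]={r} outside (-1, 1)")
        for spec in self.crosstalk:
            for r in (spec.rho_cond1, spec.rho_cond2):
                if not -1.0 < r < 1.0:
                    raise ValueError(f"crosstalk rho {r} outside (-1, 1)")
            if not (0 <= spec.pathway_a < self.n_pathways
                    and 0 <= spec.pathway_b < self.n_pathways
                    and spec.pathway_a != spec.pathway_b):
                raise ValueError("crosstalk pathway indices out of range")
        if self.pathway_classes is not None:
            if len(self.pathway_classes) != self.n_pathways:
                raise ValueError("pathway_classes length != n_pathways")
            unknown = set(self.pathway_classes) - set(self.rho_within)
            if unknown:
                raise ValueError(f"unknown pathway classes: {sorted(unknown)}")
        if self.samples_per_condition < 3:
            raise ValueError("need >= 3 samples per condition")

    @property
    def classes(self) -> list[str]:
        if self.pathway_classes is not None:
            return list(self.pathway_classes)
        first = next(iter(self.rho_within))
        return [first] * self.n_pathways


@dataclass
class GroundTruth:
    """Planted structure: per-pathway class, hubs, coupled cross-pathway pairs."""

    pathway_class: dict[str, str]
    hubs: dict[str, str]
    coupled_pairs: dict[str, list[tuple[str, str]]]  # condition -> pairs

    def to_yaml(self, path) -> None:
        payload = {
            "pathway_class": self.pathway_class,
            "hubs": self.hubs,
            "coupled_pairs": {c: [list(p) for p in pairs]
                              for c, pairs in self.coupled_pairs.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _hub_cap(rho: float, p: int) -> float:
    """Largest hub-member correlation keeping the exchangeable block PD.

    For a block of p genes with member-member correlation rho and hub rows
    at h, positive definiteness requires h^2 (p-1) < 1 + (p-2) rho.
    """
    if p < 2 or rho < 0:
        return 0.99
    bound = np.sqrt(max((1.0 + (p - 2) * rho), 0.0) / (p - 1))
    return float(min(bound - 0.005, 0.99))


def _nearest_pd_correlation(target: np.ndarray,
                            eps: float = 1e-7) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped nearest PD correlation and max elementwise shift."""
    vals, vecs = np.linalg.eigh((target + target.T) / 2.0)
    if vals.min() >= eps:
        return target, 0.0
    clipped = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    repaired = clipped / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    dev = float(np.max(np.abs(repaired - target)))
    return repaired, dev


def _target_correlation(cfg: SynthConfig, cond_index: int,
                        gene_names: list[str]) -> np.ndarray:
    n = len(gene_names)
    c = np.eye(n)
    gpp = cfg.genes_per_pathway
    for i, cls in enumerate(cfg.classes):
        rho = cfg.rho_within[cls][cond_index]
        lo, hi = i * gpp, (i + 1) * gpp
        block = np.full((gpp, gpp), rho)
        if cfg.hub_boost > 0 and rho >= 0:
            h = min(rho + cfg.hub_boost, _hub_cap(rho, gpp))
            h = max(h, rho)  # the boost never lowers the hub correlation
            block[0, :] = h
            block[:, 0] = h
        np.fill_diagonal(block, 1.0)
        c[lo:hi, lo:hi] = block
    for spec in cfg.crosstalk:
        rho = (spec.rho_cond1, spec.rho_cond2)[cond_index]
        if rho == 0.0:
            continue
        # couple non-hub genes (offset 1 skips the hub at block position 0)
        rows = [spec.pathway_a * gpp + 1 + k for k in range(spec.n_genes_a)]
        cols = [spec.pathway_b * gpp + 1 + k for k in range(spec.n_genes_b)]
        # Factor-model completion: a cross-group correlation of rho requires
        # the coupled genes to share a latent factor, which also raises their
        # in-group correlation to (block rho + rho). A literal "zeros
        # elsewhere" target with rho >~ 0.35 has no valid correlation matrix.
        for grp, blk in ((rows, spec.pathway_a), (cols, spec.pathway_b)):
            rho_blk = cfg.rho_within[cfg.classes[blk]][cond_index]
            m = min(max(rho_blk, 0.0) + rho, 0.95)
            for u in grp:
                for v in grp:
                    if u != v:
                        c[u, v] = m
                        c[v, u] = m
        for r in rows:
            for col in cols:
                c[r, col] = rho
                c[col, r] = rho
    return c


def _gene_names(cfg: SynthConfig) -> tuple[list[str], list[Pathway]]:
    names: list[str] = []
    pathways: list[Pathway] = []
    for i in range(cfg.n_pathways):
        block = [f"P{i:02d}G{j:02d}" for j in range(cfg.genes_per_pathway)]
        names.extend(block)
        pathways.append(Pathway(name=f"pathway_{i:02d}", source="synthetic",
                                genes=frozenset(block)))
    names.extend(f"BG{j:04d}" for j in range(cfg.n_background_genes))
    return names, pathways


def generate(cfg: SynthConfig,
             ) -> tuple[ExpressionDataset, list[Pathway], GroundTruth]:
    """Draw the synthetic dataset, its pathway GMT content, and the truth.

    A fixed ``cfg.rng_seed`` makes the output byte-identical across runs.
    """
    rng = np.random.default_rng(cfg.rng_seed & 0x7FFFFFFF)
    gene_names, pathways = _gene_names(cfg)
    n_genes = len(gene_names)
    conditions = ("cond1", "cond2")
    blocks, design = [], {}
    coupled: dict[str, list[tuple[str, str]]] = {c: [] for c in conditions}
    for ci, cond in enumerate(conditions):
        target = _target_correlation(cfg, ci, gene_names)
        repaired, dev = _nearest_pd_correlation(target)
        if dev > cfg.max_repair_dev:
            moved = np.unravel_index(np.argmax(np.abs(repaired - target)),
                                     target.shape)
            raise ValueError(
                f"infeasible correlation targets in {cond}: PD repair moved "
                f"({gene_names[moved[0]]}, {gene_names[moved[1]]}) by {dev:.3f}")
        if dev > 0:
            logger.info("%s: PD repair max deviation %.4f", cond, dev)
        chol = np.linalg.cholesky(repaired + 1e-10 * np.eye(n_genes))
        z = rng.standard_normal((n_genes, cfg.samples_per_condition))
        x = cfg.noise_sd * (chol @ z)
        samples = [f"{cond}_s{k:03d}" for k in range(cfg.samples_per_condition)]
        blocks.append(pd.DataFrame(x, index=gene_names, columns=samples))
        design.update({s: cond for s in samples})
        for spec in cfg.crosstalk:
            rho = (spec.rho_cond1, spec.rho_cond2)[ci]
            if rho != 0.0:
                gpp = cfg.genes_per_pathway
                for ka in range(spec.n_genes_a):
                    for kb in range(spec.n_genes_b):
                        pair = (gene_names[spec.pathway_a * gpp + 1 + ka],
                                gene_names[spec.pathway_b * gpp + 1 + kb])
                        coupled[cond].append(tuple(sorted(pair)))

    matrix = pd.concat(blocks, axis=1)
    dataset = ExpressionDataset(matrix=matrix, design=design,
                                conditions=conditions, name="synthetic")
    truth = GroundTruth(
        pathway_class={p.name: cls for p, cls in zip(pathways, cfg.classes)},
        hubs={p.name: f"P{i:02d}G00" for i, p in enumerate(pathways)},
        coupled_pairs=coupled,
    )
    return dataset, pathways, truth


def make_null_copy(dataset: ExpressionDataset,
                   rng_seed: int) -> ExpressionDataset:
    """Label-exchangeable companion: condition labels reshuffled, sizes kept."""
    rng = np.random.default_rng(rng_seed & 0x7FFFFFFF)
    samples = list(dataset.matrix.columns)
    labels = [dataset.design[s] for s in samples]
    shuffled = rng.permutation(labels)
    return dataset.with_labels(dict(zip(samples, shuffled)))
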