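"""Low-redundancy pathway compendium construction from GMT gene sets.

Pathway sets from several curated sources (e.g. PID, PANTHER, INOH) are
merged by name, pruned of near-duplicate pairs, restricted to measured
genes, and bounded in size. The result is the candidate universe for the
rewiring and crosstalk analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from coexrewire.datamodel import DegenerateOutputError

logger = logging.getLogger(__name__)


def _norm_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass
class Pathway:
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class CompendiumConfig:
    """Merge/ablation thresholds and size bounds for the compendium."""

    merge_share_threshold: float = 0.70
    overlap_discard_threshold: float = 0.70
    size_min: int = 5
    size_max: int = 250

    def __post_init__(self) -> None:
        for name in ("merge_share_threshold", "overlap_discard_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not 1 <= self.size_min <= self.size_max:
            raise ValueError("need 1 <= size_min <= size_max")


@dataclass
class PathwayCompendium:
    pathways: list[Pathway]
    n_pathways: int = field(init=False)
    n_genes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_pathways = len(self.pathways)
        self.n_genes = len(self.gene_universe())

    def gene_universe(self) -> set[str]:
        union: set[str] = set()
        for p in self.pathways:
            union |= p.genes
        return union

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": [p.name for p in self.pathways],
             "source": [p.source for p in self.pathways],
             "size": [p.size for p in self.pathways]}
        )


# ---------------------------------------------------------------------------
# GMT I/O

def read_gmt(path, source: str | None = None) -> list[Pathway]:
    """Read a GMT file: name <TAB> description/source <TAB> genes..."""
    pathways: list[Pathway] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            name, desc = parts[0], parts[1]
            genes = [g for g in parts[2:] if g]
            pathways.append(Pathway(name=name, source=source or desc,
                                    genes=frozenset(genes)))
    return pathways


def write_gmt(pathways, path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.name}\t{p.source}\t{genes}\n")


# ---------------------------------------------------------------------------
# Compendium rules

def merge_same_name(pathways: list[Pathway],
                    cfg: CompendiumConfig | None = None) -> list[Pathway]:
    """Integrate identically named pathways from distinct sources.

    Within a name group (case-insensitive, whitespace-normalized) the
    largest set is the base; every other member, visited in decreasing size
    order, contributes its extra genes iff the fraction of its genes already
    shared with the current base exceeds ``merge_share_threshold``; members
    below the threshold are dropped.
    """
    cfg = cfg or CompendiumConfig()
    groups: dict[str, list[Pathway]] = {}
    order: list[str] = []
    for p in pathways:
        key = _norm_name(p.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(p)

    merged: list[Pathway] = []
    for key in order:
        members = sorted(groups[key], key=lambda p: -p.size)
        base = members[0]
        genes = set(base.genes)
        sources = [base.source]
        for other in members[1:]:
            share = len(other.genes & genes) / len(other.genes)
            if share > cfg.merge_share_threshold:
                genes |= other.genes
                sources.append(other.source)
            else:
                logger.info("merge: dropped %r from %s (share %.2f <= %.2f)",
                            other.name, other.source, share,
                            cfg.merge_share_threshold)
        merged.append(Pathway(name=base.name, source="+".join(sources),
                              genes=frozenset(genes)))
    return merged


def ablate_overlaps(pathways: list[Pathway],
                    cfg: CompendiumConfig | None = None) -> list[Pathway]:
    """Discard the smaller of any pathway pair sharing too many genes.

    Pathways are scanned in decreasing size (ties by name, so the result is
    independent of input order); a smaller pathway is discarded when
    ``|intersection| / |smaller|`` strictly exceeds the threshold. Surviving
    pairs all satisfy the bound.
    """
    cfg = cfg or CompendiumConfig()
    ranked = sorted(pathways, key=lambda p: (-p.size, p.name))
    discarded = [False] * len(ranked)
    for i, big in enumerate(ranked):
        if discarded[i]:
            continue
        for j in range(i + 1, len(ranked)):
            if discarded[j]:
                continue
            small = ranked[j]
            frac = len(big.genes & small.genes) / small.size
            if frac > cfg.overlap_discard_threshold:
                discarded[j] = True
                logger.info("ablate: discarded %r (overlap %.2f with %r)",
                            small.name, frac, big.name)
    # returned in ranked order so the output is input-order invariant
    return [p for i, p in enumerate(ranked) if not discarded[i]]


def restrict_and_bound(pathways: list[Pathway], measured_genes: set[str],
                       cfg: CompendiumConfig | None = None) -> PathwayCompendium:
    """Intersect with measured genes and apply the [size_min, size_max] bound."""
    cfg = cfg or CompendiumConfig()
    if not measured_genes:
        raise ValueError("measured_genes is empty")
    kept: list[Pathway] = []
    for p in pathways:
        genes = p.genes & measured_genes
        if cfg.size_min <= len(genes) <= cfg.size_max:
            kept.append(Pathway(name=p.name, source=p.source,
                                genes=frozenset(genes)))
    if not kept:
        raise DegenerateOutputError("no pathways survive restriction/bounds")
    comp = PathwayCompendium(kept)
    logger.info("compendium: %d pathways over %d genes",
                comp.n_pathways, comp.n_genes)
    return comp


def build_compendium(pathways: list[Pathway], measured_genes: set[str],
                     cfg: CompendiumConfig | None = None) -> PathwayCompendium:
    """merge -> ablate -> restrict, the full compendium construction."""
    cfg = cfg or CompendiumConfig()
    return restrict_and_bound(ablate_overlaps(merge_same_name(pathways, cfg), cfg),
                              measured_genes, cfg)
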