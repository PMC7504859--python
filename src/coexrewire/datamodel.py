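"""Expression matrices, sample designs, preprocessing, and configuration.

The expression container is a plain genes-by-samples :class:`pandas.DataFrame`
paired with a two-condition design. Condition 1 is always the declared
baseline so that "decreased" downstream consistently means
baseline -> perturbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (duplicates, missing values, bad layout)."""


class DesignError(ValueError):
    """Sample design violates the two-condition contract."""


class DegenerateOutputError(ValueError):
    """An operation would return an empty or unusable result."""


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with a two-condition design.

    Parameters
    ----------
    matrix
        Real-valued expression, rows indexed by gene identifiers, columns by
        sample identifiers (arbitrary normalized scale, e.g. log FPKM).
    design
        Mapping sample identifier -> condition label; exactly two labels.
    conditions
        Ordered pair ``(baseline, perturbed)``. Condition 1 is the baseline.
    name
        Free-text dataset label.
    """

    matrix: pd.DataFrame
    design: dict[str, str]
    conditions: tuple[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        m = self.matrix
        if m.index.has_duplicates:
            dup = m.index[m.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dup[:5]}")
        if m.columns.has_duplicates:
            dup = m.columns[m.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
        if m.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        missing = [s for s in m.columns if s not in self.design]
        if missing:
            raise DesignError(f"samples absent from design: {missing[:5]}")
        labels = set(self.design[s] for s in m.columns)
        if labels != set(self.conditions):
            raise DesignError(
                f"design labels {sorted(labels)} do not match declared "
                f"conditions {self.conditions}"
            )
        if len(set(self.conditions)) != 2:
            raise DesignError("exactly two distinct condition labels required")
        for c in self.conditions:
            n = sum(1 for s in m.columns if self.design[s] == c)
            if n < 3:
                raise DesignError(f"condition {c!r} has {n} samples (< 3)")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.matrix.columns if self.design[s] == condition]

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        return self.matrix[self.samples_of(condition)]

    def with_labels(self, new_design: dict[str, str]) -> "ExpressionDataset":
        """Same matrix under a different sample-to-condition assignment."""
        return replace(self, design=new_design)


@dataclass
class PreprocessConfig:
    """Gene filtering and transcript-collapsing settings.

    ``median_percentile_cut`` drops genes whose cross-sample median falls
    strictly below that percentile of all gene medians (0.25 typical for
    microarray, 0.50 for RNA-seq). Collapsing keeps, per gene, the transcript
    with the maximum cross-sample median.
    """

    median_percentile_cut: float = 0.5
    collapse_rule: str = "max-median"

    def __post_init__(self) -> None:
        if not 0.0 <= self.median_percentile_cut < 1.0:
            raise ValueError("median_percentile_cut must be in [0, 1)")
        if self.collapse_rule != "max-median":
            raise ValueError("only the max-median collapse rule is supported")


@dataclass
class AnalysisConfig:
    """Global knobs of the differential-coexpression pipeline.

    density
        Coexpression network density rho: fraction of all gene pairs kept
        as links per condition.
    dcl_fraction
        A-priori share q of differentially coexpressed links assumed by the
        limit-fold-change envelope.
    dcg_q_threshold
        BH-adjusted significance cut for differentially coexpressed genes.
    n_perm_gsnca / n_perm_hub
        Label permutations for the pathway rewiring test and the hub-rate
        null distributions, respectively.
    pathway_p_threshold
        Per-dataset cut behind the focused-pathway rule (0.01); the looser
        per-dataset "significant" lists use ``pathway_list_threshold``.
    """

    density: float = 0.1
    dcl_fraction: float = 0.1
    dcg_q_threshold: float = 0.1
    n_perm_gsnca: int = 1000
    n_perm_hub: int = 100
    pathway_p_threshold: float = 0.01
    pathway_list_threshold: float = 0.05
    crosstalk_p_threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("density", "dcg_q_threshold",
                     "pathway_p_threshold", "pathway_list_threshold",
                     "crosstalk_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not 0.0 <= self.dcl_fraction <= 1.0:  # 0 = sign-switch DCLs only
            raise ValueError(f"dcl_fraction={self.dcl_fraction} outside [0, 1]")
        for name in ("n_perm_gsnca", "n_perm_hub"):
            if getattr(self, name) < 10:
                raise ValueError(f"{name} must be >= 10")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# I/O

def read_design(path) -> tuple[dict[str, str], tuple[str, str]]:
    """Read a two-column sample<TAB>condition file.

    A comment line ``#baseline=<label>`` declares condition 1; without it the
    condition of the first listed sample is the baseline.
    """
    design: dict[str, str] = {}
    baseline = None
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("baseline="):
                    baseline = body.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"design line not two-column: {line!r}")
            sample, cond = parts[0].strip(), parts[1].strip()
            if sample in design:
                raise FormatError(f"duplicate sample in design: {sample!r}")
            design[sample] = cond
            if cond not in order:
                order.append(cond)
    if len(order) != 2:
        raise DesignError(f"design declares {len(order)} condition labels, need 2")
    if baseline is None:
        baseline = order[0]
    if baseline not in order:
        raise DesignError(f"declared baseline {baseline!r} not among {order}")
    other = order[0] if order[1] == baseline else order[1]
    return design, (baseline, other)


def read_expression(path, design_path, name: str = "") -> ExpressionDataset:
    """Load a TSV expression matrix (first column ``gene``) plus its design."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = pd.Index(matrix.index.astype(str), name="gene")
    matrix.columns = matrix.columns.astype(str)
    if not all(np.issubdtype(dt, np.number) for dt in matrix.dtypes):
        raise FormatError("non-numeric expression values")
    matrix = matrix.astype(np.float64)
    design, conditions = read_design(design_path)
    return ExpressionDataset(matrix=matrix, design=design,
                             conditions=conditions, name=name or str(path))


def write_expression(dataset: ExpressionDataset, path, design_path=None) -> None:
    out = dataset.matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if design_path is not None:
        write_design(dataset.design, dataset.conditions, design_path)


def write_design(design: dict[str, str], conditions: tuple[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#baseline={conditions[0]}\n")
        for sample, cond in design.items():
            fh.write(f"{sample}\t{cond}\n")


# ---------------------------------------------------------------------------
# Preprocessing

def collapse_to_genes(matrix: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Collapse a transcript-by-sample matrix to one row per gene.

    For each gene the retained row is the transcript with the largest
    cross-sample median; median ties break by first occurrence in file order.
    """
    if not mapping:
        raise ValueError("empty transcript-to-gene mapping")
    missing = [t for t in matrix.index if t not in mapping]
    if missing:
        raise ValueError(f"transcripts without gene mapping: {missing[:5]}")
    medians = matrix.median(axis=1)
    best: dict[str, str] = {}  # gene -> transcript
    for transcript in matrix.index:  # file order makes the tie-break
        gene = mapping[transcript]
        if gene not in best or medians[transcript] > medians[best[gene]]:
            best[gene] = transcript
    collapsed = matrix.loc[[best[g] for g in best]].copy()
    collapsed.index = pd.Index(list(best), name="gene")
    return collapsed


def filter_by_median(dataset: ExpressionDataset,
                     cfg: PreprocessConfig) -> ExpressionDataset:
    """Drop genes whose cross-sample median is strictly below the cut quantile.

    The threshold is the empirical ``median_percentile_cut`` quantile of all
    gene medians (upper interpolation, so a 0.5 cut on distinct medians keeps
    the top half and an all-tied input is kept whole). Like any empirical
    percentile filter the operation is not idempotent on distinct values.
    """
    medians = dataset.matrix.median(axis=1)
    threshold = np.quantile(medians.to_numpy(), cfg.median_percentile_cut,
                            method="higher")
    keep = medians >= threshold
    if not keep.any():
        raise DegenerateOutputError("median filter removed all genes")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("median filter dropped %d/%d genes (cut %.2f)",
                    n_drop, len(medians), cfg.median_percentile_cut)
    return ExpressionDataset(matrix=dataset.matrix.loc[keep],
                             design=dataset.design,
                             conditions=dataset.conditions,
                             name=dataset.name)
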