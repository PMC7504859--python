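"""Pipeline orchestration: preprocess -> compendium -> diffcoexp -> rewiring
-> meta -> hub dynamics -> crosstalk, driven by one YAML config.

Stages communicate exclusively through serialized interface files (TSV /
GMT / JSON), so any stage can be replaced by an external tool. A run
manifest records the config snapshot, input digests, seeds, stage timings,
and the produced file inventory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from coexrewire import __version__
from coexrewire.compendium import (CompendiumConfig, PathwayCompendium,
                                   build_compendium, read_gmt, write_gmt)
from coexrewire.crosstalk import build_scaffold, crosstalk_map
from coexrewire.datamodel import (AnalysisConfig, ExpressionDataset,
                                  PreprocessConfig, filter_by_median,
                                  read_expression, write_expression)
from coexrewire.diffcoexp import diff_coexpression
from coexrewire.hubdyn import (hub_rates, null_by_annotation_permutation,
                               null_by_label_permutation)
from coexrewire.meta import combine_datasets
from coexrewire.rewiring import rewire_all
from coexrewire.synthdata import CrosstalkSpec, SynthConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    version: str
    rng_seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_links(links: pd.DataFrame, path) -> None:
    cols = ["gene_a", "gene_b", "r1", "r2", "is_link", "is_dcl", "category"]
    links[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config_path, out_dir=None) -> RunManifest:
    """Execute the full multi-dataset analysis described by a YAML config.

    Config schema (all analysis keys optional, defaulting to
    :class:`AnalysisConfig`)::

        datasets:
          - {name: ckd, expression: expr.tsv, design: design.tsv}
        pathways: pathways.gmt
        median_percentile_cut: 0.5
        out_dir: results/
        density: 0.1
        ...

    A ``demo: {...}`` block (see :func:`run_demo`) generates synthetic
    inputs instead of reading files.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    acfg = AnalysisConfig(**{k: v for k, v in config.items()
                             if k in AnalysisConfig.__dataclass_fields__})
    out = Path(out_dir or config.get("out_dir", "coexrewire_out"))
    out.mkdir(parents=True, exist_ok=True)

    if "demo" in config:
        demo_dir = out / "synthetic_inputs"
        datasets_spec, gmt_path = _generate_demo_inputs(
            config["demo"], acfg.rng_seed, demo_dir)
    else:
        datasets_spec = config["datasets"]
        gmt_path = Path(config["pathways"])

    digests = {str(gmt_path): _digest(gmt_path)}
    for d in datasets_spec:
        digests[d["expression"]] = _digest(d["expression"])
        digests[d["design"]] = _digest(d["design"])
    manifest = RunManifest(config=config, input_digests=digests,
                           version=__version__, rng_seed=acfg.rng_seed)

    pcfg = PreprocessConfig(
        median_percentile_cut=float(config.get("median_percentile_cut", 0.0)))
    ccfg = CompendiumConfig(**{k: v for k, v in config.items()
                               if k in CompendiumConfig.__dataclass_fields__})

    datasets: dict[str, ExpressionDataset] = {}
    for d in datasets_spec:
        ds = read_expression(d["expression"], d["design"], name=d["name"])
        if pcfg.median_percentile_cut > 0:
            ds = filter_by_median(ds, pcfg)
        datasets[d["name"]] = ds

    # compendium over genes measured in every dataset
    t0 = time.time()
    measured = set.intersection(*[set(ds.matrix.index)
                                  for ds in datasets.values()])
    compendium = build_compendium(read_gmt(gmt_path), measured, ccfg)
    write_gmt(compendium, out / "compendium.gmt")
    compendium.report().to_csv(out / "compendium_report.tsv", sep="\t",
                               index=False)
    manifest.stage_seconds["compendium"] = time.time() - t0

    gene_universe = sorted(compendium.gene_universe())
    per_dataset_p = {}
    diffcoexp_results = {}
    rewiring_tables = {}
    primary = datasets_spec[0]["name"]
    for name, ds in datasets.items():
        t0 = time.time()
        dc = diff_coexpression(ds, gene_universe, acfg)
        diffcoexp_results[name] = dc
        _write_links(dc.links, out / f"{name}_links.tsv")
        dc.dcgs.to_csv(out / f"{name}_dcgs.tsv", sep="\t", index=False,
                       float_format="%.6g")
        manifest.stage_seconds[f"diffcoexp[{name}]"] = time.time() - t0

        t0 = time.time()
        table, _ = rewire_all(ds, compendium, acfg, links=dc.links)
        rewiring_tables[name] = table
        table.to_csv(out / f"{name}_rewiring.tsv", sep="\t", index=False,
                     float_format="%.6g")
        per_dataset_p[name] = table.set_index("pathway")["p"]
        manifest.stage_seconds[f"rewiring[{name}]"] = time.time() - t0

    t0 = time.time()
    p_table = pd.DataFrame(per_dataset_p)
    meta_table = combine_datasets(p_table, acfg.pathway_p_threshold)
    meta_table.to_csv(out / "meta.tsv", sep="\t", float_format="%.6g")
    focused_names = list(meta_table.index[meta_table["focused"]])
    manifest.stage_seconds["meta"] = time.time() - t0

    # hub dynamics on the primary dataset
    t0 = time.time()
    hubs_table = rewiring_tables[primary][["pathway", "hub1", "hub2", "status"]]
    dyn = hub_rates(hubs_table, diffcoexp_results[primary].dcgs, focused_names)
    dyn = null_by_label_permutation(datasets[primary], compendium,
                                    focused_names, dyn, cfg=acfg)
    ann = null_by_annotation_permutation(datasets[primary], compendium,
                                         focused_names, dyn,
                                         diffcoexp_results[primary].dcgs,
                                         cfg=acfg)
    hub_report = {
        "constancy": f"{dyn.constancy_numerator}/{dyn.constancy_denominator}",
        "retention": f"{dyn.retention_numerator}/{dyn.retention_denominator}",
        "vanishing_hubs": dyn.vanishing_hubs,
        "p_constancy_label_perm": dyn.p_constancy,
        "p_retention_label_perm": dyn.p_retention,
        "p_constancy_annotation_perm": ann.p_constancy,
        "p_retention_annotation_perm": ann.p_retention,
    }
    with open(out / "hub_dynamics.json", "w") as fh:
        json.dump(hub_report, fh, indent=2)
    from coexrewire.hubdyn import plot_null_histogram
    if dyn.constancy_denominator > 0:
        plot_null_histogram(dyn.null_constancy, dyn.constancy_rate,
                            out / "hub_constancy_label_null.png",
                            title="hub constancy vs label-permutation null")
        plot_null_histogram(ann.null_constancy, ann.constancy_rate,
                            out / "hub_constancy_annotation_null.png",
                            title="hub constancy vs annotation-shuffle null")
    manifest.stage_seconds["hubdyn"] = time.time() - t0

    # crosstalk on the primary dataset's decreased scaffold
    t0 = time.time()
    primary_dc = diffcoexp_results[primary]
    focused_pathways = [p for p in compendium if p.name in set(focused_names)]
    try:
        scaffold = build_scaffold(primary_dc.links, set(gene_universe))
    except ValueError:
        scaffold = None
        logger.warning("empty decreased scaffold; crosstalk skipped")
    if scaffold is not None and focused_pathways:
        hubs1 = set(hubs_table["hub1"]) | set(hubs_table["hub2"])
        ct_table, ct_genes = crosstalk_map(scaffold, focused_pathways, acfg,
                                           dcgs=primary_dc.dcgs, hubs=hubs1)
        ct_table.to_csv(out / "crosstalk.tsv", sep="\t", index=False,
                        float_format="%.6g")
        ct_genes.to_csv(out / "crosstalk_genes.tsv", sep="\t", index=False)
    manifest.stage_seconds["crosstalk"] = time.time() - t0

    manifest.outputs = sorted({str(p.relative_to(out))
                               for p in out.rglob("*") if p.is_file()}
                              | {"manifest.json"})
    manifest.save(out / "manifest.json")
    logger.info("run complete: %d focused pathways, outputs in %s",
                len(focused_names), out)
    return manifest


def _generate_demo_inputs(demo_cfg: dict, rng_seed: int,
                          out: Path) -> tuple[list[dict], Path]:
    """Synthetic multi-dataset inputs mirroring a primary + auxiliary layout.

    Emits ``n_datasets`` independent draws of the same planted world (shared
    pathway definitions, different sampling seeds) so the meta-aggregation
    and focused-pathway stages are exercised end-to-end.
    """
    out.mkdir(parents=True, exist_ok=True)
    spec = dict(demo_cfg or {})
    n_datasets = int(spec.pop("n_datasets", 3))
    xts = [CrosstalkSpec(**x) for x in spec.pop("crosstalk", [])]
    rho = {k: tuple(v) for k, v in spec.pop(
        "rho_within", {"attenuated": [0.8, 0.1]}).items()}
    datasets_spec = []
    gmt_path = out / "pathways.gmt"
    for i in range(n_datasets):
        cfg = SynthConfig(rho_within=rho, crosstalk=xts,
                          rng_seed=rng_seed + i, **spec)
        dataset, pathways, truth = generate(cfg)
        name = f"synthetic{i + 1}"
        write_expression(dataset, out / f"{name}_expression.tsv",
                         out / f"{name}_design.tsv")
        if i == 0:
            write_gmt(pathways, gmt_path)
            truth.to_yaml(out / "truth.yaml")
        datasets_spec.append({"name": name,
                              "expression": str(out / f"{name}_expression.tsv"),
                              "design": str(out / f"{name}_design.tsv")})
    return datasets_spec, gmt_path
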