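"""End-to-end orchestration: prepare, scan, network, dendrogram, ordination.

``prepare_dataset`` turns raw study tables into the modeling dataset:
dose-response series become baseline/slope features, compositional 16S layers
are closed, reduced to the top taxa and ALR-transformed, and measured groups
pass through normality-driven transforms and PCA proxy selection.
``run_pipeline`` executes every stage and writes plain-text artifacts plus a
machine-readable run log recording the defaults actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import pandas as pd

from . import __version__
from .compositional import prepare_compositional
from .data_model import (
    TMRDataset,
    VariableGroup,
    align_dataset,
    derive_response_group,
)
from .group_structure import euclidean_distances, group_dendrogram
from .io import write_study_tables
from .ordination import classical_mds, permanova
from .tmr_regression import (
    build_network,
    edges_to_frame,
    resolve_bidirectional,
    tmr_scan,
)
from .variable_selection import select_variables, selection_report

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Tunable knobs of a full TMR run (defaults follow the reference analysis)."""

    alpha_report: float = 0.05      # covariate-surfaced edge cutoff in the full table
    alpha_network: float = 0.005    # network significance cutoff
    top_n_taxa: int = 10
    alr_reference: str | None = None
    pseudocount: float = 1e-6
    variance_threshold: float = 0.01
    normality_alpha: float = 0.05
    always_compare: bool = False
    select: bool = True             # PCA proxy selection of measured groups
    standardize_distances: bool = True
    ward_variant: str = "ward.d"
    dose_scale: str = "linear"
    mds_axes: int = 2
    n_perm: int = 999
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def prepare_dataset(
    groups: list[VariableGroup], config: RunConfig | None = None
) -> tuple[TMRDataset, dict]:
    """Build the aligned modeling dataset from raw study groups.

    Returns the dataset and a record dict with, per measured group, the
    transform choices and proxy selections (empty when selection is off).
    """
    config = config or RunConfig()
    records: dict = {"transforms": {}, "selections": {}, "alr": {}}
    prepared = []
    for g in groups:
        if g.role == "response" and (
            g.meta.get("dose_response") or any("@" in v for v in g.variables)
        ):
            g = derive_response_group(g, dose_scale=config.dose_scale)
        if g.role == "measured" and g.meta.get("compositional"):
            g = prepare_compositional(
                g,
                top_n=config.top_n_taxa,
                reference=config.alr_reference,
                pseudocount=config.pseudocount,
            )
            records["alr"][g.name] = {
                "reference": g.meta["alr_reference"],
                "pseudocount": g.meta["pseudocount"],
            }
        if g.role == "measured" and config.select:
            trecs, selections, g = select_variables(
                g,
                variance_threshold=config.variance_threshold,
                normality_alpha=config.normality_alpha,
                always_compare=config.always_compare,
            )
            records["transforms"][g.name] = {r.variable: r.chosen for r in trecs}
            records["selections"][g.name] = selection_report(trecs, selections)
        prepared.append(g)
    return align_dataset(prepared), records


def run_pipeline(
    groups: list[VariableGroup], config: RunConfig | None = None, outdir=None
) -> dict:
    """Execute all stages; returns a result dict and (optionally) writes artifacts.

    Result keys: ``dataset``, ``edges``, ``resolved_edges``, ``network``,
    ``dendrogram``, ``mds`` (per compositional layer), ``permanova`` (per
    compositional layer), ``records`` and ``run_log``.
    """
    config = config or RunConfig()
    dataset, records = prepare_dataset(groups, config)
    dataset.validate_roles()

    edges = tmr_scan(dataset, alpha_report=config.alpha_report)
    resolved = resolve_bidirectional(edges, alpha=config.alpha_network)
    network = build_network(resolved, alpha=config.alpha_network)

    modeled = dataset.by_role("measured") + dataset.by_role("response")
    dendro = group_dendrogram(
        modeled, standardize=config.standardize_distances, variant=config.ward_variant
    )

    treatments = dataset.by_role("treatment")[0]
    mds_results, permanova_results = {}, {}
    for g in dataset.by_role("measured"):
        if g.meta.get("units") != "alr":
            continue
        d = euclidean_distances(g, standardize=config.standardize_distances)
        mds_results[g.name] = classical_mds(d, k=min(config.mds_axes, d.n - 1))
        permanova_results[g.name] = permanova(
            d, treatments.data, n_perm=config.n_perm, seed=config.seed
        )

    run_log = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "n_samples": len(dataset.sample_index),
        "groups": {g.name: g.n_variables for g in dataset.groups},
        "alr": records["alr"],
        "transforms": records["transforms"],
        "ward_variant": config.ward_variant,
        "standardize_distances": config.standardize_distances,
        "n_edges_emitted": len(edges),
        "n_edges_network": len(network.edges),
    }

    result = {
        "dataset": dataset,
        "edges": edges,
        "resolved_edges": resolved,
        "network": network,
        "dendrogram": dendro,
        "mds": mds_results,
        "permanova": permanova_results,
        "records": records,
        "run_log": run_log,
    }
    if outdir is not None:
        _write_artifacts(result, config, outdir)
    return result


def _write_artifacts(result, config: RunConfig, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    tag = f"# config_hash={config.digest()}"

    def _write_frame(frame: pd.DataFrame, name: str, index=False):
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write(tag + "\n")
            frame.to_csv(fh, sep="\t", index=index)

    _write_frame(edges_to_frame(result["edges"]), "edges.tsv")
    _write_frame(edges_to_frame(result["resolved_edges"]), "edges_resolved.tsv")
    _write_frame(edges_to_frame(result["network"].edges), "network_edges.tsv")
    result["network"].write_graphml(os.path.join(outdir, "network.graphml"))

    with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
        fh.write(result["dendrogram"].to_newick() + "\n")
    _write_frame(result["dendrogram"].dissimilarities, "intergroup_dissimilarity.tsv", index=True)

    for name, sel in result["records"]["selections"].items():
        if len(sel):
            _write_frame(sel, f"selection_{name}.tsv")
    for name, mds in result["mds"].items():
        _write_frame(mds.to_frame(), f"mds_{name}.tsv", index=True)
    for name, perm in result["permanova"].items():
        _write_frame(perm.to_frame(), f"permanova_{name}.tsv")

    write_study_tables(result["dataset"].groups, os.path.join(outdir, "aligned"))
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(result["run_log"], fh, indent=2, default=str)
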