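"""Synthetic TMR-shaped multi-omics studies with planted ground truth.

The generator emulates a four-arm murine study of diet-induced obesity and
allergic airway disease: ~40 mice split over Naive / Control / AAD-Vehicle /
AAD-NO2OA arms, two compositional 16S layers (DNA presence, RNA activity),
three metabolite compartments, two host gene-expression compartments, and
flexiVent-style lung-function responses (a baseline and a methacholine
dose-response slope per parameter).

Every variable carries a latent Gaussian *signal*; planted effects add
``beta * source_signal`` to the target's signal before materialization, so
the ledger of true edges is exact on the modeling scale:

* 16S taxa: signals shift per-sample log abundances; counts are drawn from a
  multinomial at the configured depth, so planted effects are linear in the
  additive log-ratio coordinates used downstream (softmax normalization
  cancels in ALR);
* metabolites / expression: values are ``exp(mu + signal)``, i.e. planted
  effects are linear on the log scale;
* responses: baseline and slope features are ``center + signal``; the emitted
  table holds the reconstructed dose series (``<param>@<dose>`` columns) with
  small measurement noise.

Treatment sources are z-scored covariate columns and measured sources are the
latent signals themselves (sd = ``noise_sd`` at the roots), so a configured
``beta`` of 1 is one residual-sd of effect per source-sd: the planted
standardized effect size equals ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import TMRDataset, VariableGroup, align_dataset
from .exceptions import ConfigError

NodeId = tuple[str, str]

ARMS = ("Naive", "Control", "AAD_Vehicle", "AAD_NO2OA")

#: (HDM sensitization, cholera-toxin adjuvant, NO2-OA treatment) per arm
ARM_TREATMENTS = {
    "Naive": (0, 0, 0),
    "Control": (0, 1, 0),
    "AAD_Vehicle": (1, 1, 0),
    "AAD_NO2OA": (1, 1, 1),
}

TREATMENT_GROUP = "treatments"
RESPONSE_GROUP = "lung_function"

#: plausible flexiVent scales: baseline level and per-(mg/mL) slope centers
RESPONSE_CENTERS = {
    "H": (25.0, 0.35),
    "G": (4.0, 0.05),
    "Rn": (0.6, 0.02),
    "Ers": (30.0, 0.4),
    "Rrs": (1.2, 0.03),
}


@dataclass(frozen=True)
class PlantedEffect:
    """One true linear cross-group effect, ``target += beta * source``."""

    source: NodeId
    target: NodeId
    beta: float
    category: int  # 1 treatment->measured, 2 measured->measured, 3 measured->response


@dataclass
class StudyConfig:
    """Shape, noise and ground-truth of one synthetic study."""

    n_per_arm: int = 10
    n_taxa: int = 12
    seq_depth: int = 50_000
    metabolite_groups: dict = field(
        default_factory=lambda: {
            "cecum_metabolites": 4,
            "serum_metabolites": 4,
            "lung_metabolites": 4,
        }
    )
    expression_groups: dict = field(
        default_factory=lambda: {"lung_expression": 3, "colon_expression": 3}
    )
    response_params: tuple = ("H", "G", "Rn", "Ers", "Rrs")
    doses: tuple = (0.0, 3.125, 12.5, 25.0, 50.0)
    noise_sd: float = 0.5
    series_noise_sd: float = 0.05
    effects: tuple = ()
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_per_arm * len(ARMS)


@dataclass
class SyntheticStudy:
    """A generated dataset plus the ledger of its true edges."""

    dataset: TMRDataset
    true_edges: list[PlantedEffect]
    config: StudyConfig


def _taxa_names(n: int) -> list[str]:
    return [f"taxon_{i + 1:02d}" for i in range(n)]


def default_effects(beta: float = 1.3, beta_16s: float = 1.6) -> tuple[PlantedEffect, ...]:
    """The standard planted-effect design: a chain-free DAG of 33 effects.

    18 treatment effects on omics variables, 5 cross-omics effects, and 10
    omics effects on lung-function features, each target with a single
    planted source.  Sources, targets and the effect roles never overlap (a
    chain-free design), so marginal regressions detect no associations other
    than the planted ones.  Edges with a 16S endpoint use ``beta_16s``:
    additive log-ratio coordinates carry the reference bucket's own biological
    variation, which attenuates regression on a 16S source, and the larger
    effect keeps the planted standardized effect on the modeling scale
    comparable across groups.
    """
    b, s = beta, beta_16s
    t = lambda v: (TREATMENT_GROUP, v)
    dna = lambda v: ("16S_DNA", v)
    rna = lambda v: ("16S_RNA", v)
    cec = lambda v: ("cecum_metabolites", v)
    ser = lambda v: ("serum_metabolites", v)
    lme = lambda v: ("lung_metabolites", v)
    lex = lambda v: ("lung_expression", v)
    cex = lambda v: ("colon_expression", v)
    r = lambda v: (RESPONSE_GROUP, v)

    cat1 = [
        PlantedEffect(t("HDM"), dna("taxon_01"), -s, 1),
        PlantedEffect(t("HDM"), rna("taxon_01"), -s, 1),
        PlantedEffect(t("HDM"), lex("gene_1"), b, 1),
        PlantedEffect(t("HDM"), cec("met_1"), b, 1),
        PlantedEffect(t("CT"), rna("taxon_02"), s, 1),
        PlantedEffect(t("CT"), dna("taxon_02"), s, 1),
        PlantedEffect(t("CT"), cex("gene_1"), b, 1),
        PlantedEffect(t("CT"), cec("met_2"), b, 1),
        PlantedEffect(t("NO2OA"), dna("taxon_03"), -s, 1),
        PlantedEffect(t("NO2OA"), rna("taxon_03"), -s, 1),
        PlantedEffect(t("NO2OA"), lme("met_1"), -b, 1),
        PlantedEffect(t("NO2OA"), lex("gene_2"), b, 1),
        PlantedEffect(t("weight_final"), ser("met_1"), b, 1),
        PlantedEffect(t("weight_final"), dna("taxon_04"), s, 1),
        PlantedEffect(t("weight_final"), cex("gene_2"), b, 1),
        PlantedEffect(t("weight_pct"), ser("met_2"), -b, 1),
        PlantedEffect(t("weight_pct"), rna("taxon_04"), -s, 1),
        PlantedEffect(t("weight_pct"), lme("met_2"), b, 1),
    ]
    cat2 = [
        PlantedEffect(rna("taxon_07"), dna("taxon_07"), s, 2),
        PlantedEffect(dna("taxon_08"), rna("taxon_08"), s, 2),
        PlantedEffect(ser("met_4"), dna("taxon_09"), -s, 2),
        PlantedEffect(lme("met_4"), rna("taxon_09"), s, 2),
        PlantedEffect(rna("taxon_10"), dna("taxon_10"), -s, 2),
    ]
    cat3_design = [
        ("H_baseline", cec("met_3"), b),
        ("H_slope", rna("taxon_05"), -s),
        ("G_baseline", dna("taxon_05"), s),
        ("G_slope", cec("met_4"), b),
        ("Rn_baseline", lex("gene_3"), b),
        ("Rn_slope", cex("gene_3"), -b),
        ("Ers_baseline", lme("met_3"), b),
        ("Ers_slope", dna("taxon_06"), s),
        ("Rrs_baseline", ser("met_3"), -b),
        ("Rrs_slope", rna("taxon_06"), -s),
    ]
    cat3 = [PlantedEffect(src, r(target), bb, 3) for target, src, bb in cat3_design]
    return tuple(cat1 + cat2 + cat3)


def default_config(seed: int = 0, effects: tuple | None = None) -> StudyConfig:
    """The standard study conditions with the default planted design."""
    return StudyConfig(effects=default_effects() if effects is None else effects, seed=seed)


def null_config(seed: int = 0) -> StudyConfig:
    """The same study shape with no planted effects (global null)."""
    return StudyConfig(effects=(), seed=seed)


def _response_feature_names(config: StudyConfig) -> list[str]:
    return [f"{p}_{kind}" for p in config.response_params for kind in ("baseline", "slope")]


def _all_variables(config: StudyConfig) -> dict[NodeId, str]:
    """Map every (group, variable) to its role."""
    out: dict[NodeId, str] = {}
    for v in ("HDM", "CT", "NO2OA", "weight_final", "weight_pct"):
        out[(TREATMENT_GROUP, v)] = "treatment"
    for layer in ("16S_DNA", "16S_RNA"):
        for taxon in _taxa_names(config.n_taxa):
            out[(layer, taxon)] = "measured"
    for name, k in config.metabolite_groups.items():
        for i in range(k):
            out[(name, f"met_{i + 1}")] = "measured"
    for name, k in config.expression_groups.items():
        for i in range(k):
            out[(name, f"gene_{i + 1}")] = "measured"
    for feat in _response_feature_names(config):
        out[(RESPONSE_GROUP, feat)] = "response"
    return out


def _validate_effects(config: StudyConfig, roles: dict[NodeId, str]) -> None:
    for e in config.effects:
        if e.source not in roles:
            raise ConfigError(f"effect source {e.source} does not exist")
        if e.target not in roles:
            raise ConfigError(f"effect target {e.target} does not exist")
        if roles[e.source] == "response":
            raise ConfigError(f"effect source {e.source} is a response variable")
        if roles[e.target] == "treatment":
            raise ConfigError(f"effect target {e.target} is a treatment covariate")
        if not np.isfinite(e.beta):
            raise ConfigError(f"effect {e.source} -> {e.target}: beta must be finite")


def _topological_effect_order(effects) -> list[PlantedEffect]:
    """Order effects so every source signal is final before it is used."""
    remaining = list(effects)
    resolved: set[NodeId] = set()
    targets = {e.target for e in remaining}
    ordered = []
    while remaining:
        progress = []
        for e in remaining:
            if e.source not in targets or e.source in resolved:
                progress.append(e)
        if not progress:
            raise ConfigError("effect graph contains a cycle")
        # a target is resolved once ALL of its incoming effects are placed
        ordered.extend(progress)
        placed_targets = {e.target for e in ordered}
        for tgt in placed_targets:
            if all(e in ordered for e in effects if e.target == tgt):
                resolved.add(tgt)
        remaining = [e for e in remaining if e not in ordered]
    return ordered


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Draw one study. Deterministic given ``config`` (including its seed)."""
    roles = _all_variables(config)
    _validate_effects(config, roles)
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"m{i + 1:02d}" for i in range(n)]
    arm_of = np.repeat(ARMS, config.n_per_arm)

    # treatment covariates
    codes = np.array([ARM_TREATMENTS[a] for a in arm_of], dtype=float)
    weight_final = 46.0 + 3.0 * rng.normal(size=n)
    weight_pct = 72.0 + 10.0 * (
        0.6 * (weight_final - 46.0) / 3.0 + 0.8 * rng.normal(size=n)
    )
    treatments = pd.DataFrame(
        {
            "HDM": codes[:, 0],
            "CT": codes[:, 1],
            "NO2OA": codes[:, 2],
            "weight_final": weight_final,
            "weight_pct": weight_pct,
        },
        index=samples,
    )

    # latent signals: root noise for every measured and response variable
    signals: dict[NodeId, np.ndarray] = {}
    for node, role in roles.items():
        if role in ("measured", "response"):
            signals[node] = config.noise_sd * rng.normal(size=n)

    def source_signal(node: NodeId) -> np.ndarray:
        if roles[node] == "treatment":
            col = treatments[node[1]].to_numpy(dtype=float)
            return (col - col.mean()) / col.std(ddof=1)
        return signals[node]

    for e in _topological_effect_order(config.effects):
        signals[e.target] = signals[e.target] + e.beta * source_signal(e.source)

    groups: list[VariableGroup] = [
        VariableGroup(name=TREATMENT_GROUP, role="treatment", data=treatments,
                      meta={"units": "mixed"})
    ]

    # 16S layers: log-abundance baseline + signal -> softmax -> multinomial
    taxa = _taxa_names(config.n_taxa)
    n_major = min(10, config.n_taxa)
    base = np.concatenate(
        [
            np.linspace(3.0, 0.0, n_major),
            np.linspace(-1.5, -2.0, config.n_taxa - n_major),
        ]
    )
    for layer in ("16S_DNA", "16S_RNA"):
        logab = np.column_stack([base[j] + signals[(layer, taxa[j])] for j in range(config.n_taxa)])
        logab -= logab.max(axis=1, keepdims=True)
        probs = np.exp(logab)
        probs /= probs.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(config.seq_depth, probs[i]) for i in range(n)])
        groups.append(
            VariableGroup(
                name=layer, role="measured",
                data=pd.DataFrame(counts, index=samples, columns=taxa),
                meta={"compositional": True, "units": "counts",
                      "layer": "DNA" if layer == "16S_DNA" else "RNA"},
            )
        )

    # metabolite and expression compartments: log-normal around per-variable means
    for name, k in config.metabolite_groups.items():
        mus = 0.5 * rng.normal(size=k)
        cols = {f"met_{i + 1}": np.exp(mus[i] + signals[(name, f"met_{i + 1}")]) for i in range(k)}
        groups.append(
            VariableGroup(name=name, role="measured",
                          data=pd.DataFrame(cols, index=samples),
                          meta={"units": "relative_amount"})
        )
    for name, k in config.expression_groups.items():
        mus = 0.3 * rng.normal(size=k)
        cols = {f"gene_{i + 1}": np.exp(mus[i] + signals[(name, f"gene_{i + 1}")]) for i in range(k)}
        groups.append(
            VariableGroup(name=name, role="measured",
                          data=pd.DataFrame(cols, index=samples),
                          meta={"units": "relative_expression"})
        )

    # responses: reconstruct dose series from baseline/slope features
    series = {}
    for param in config.response_params:
        c_base, c_slope = RESPONSE_CENTERS.get(param, (1.0, 0.1))
        baseline = c_base + signals[(RESPONSE_GROUP, f"{param}_baseline")]
        slope = c_slope + signals[(RESPONSE_GROUP, f"{param}_slope")]
        for dose in config.doses:
            series[f"{param}@{dose:g}"] = (
                baseline + slope * dose + config.series_noise_sd * rng.normal(size=n)
            )
    groups.append(
        VariableGroup(name=RESPONSE_GROUP, role="response",
                      data=pd.DataFrame(series, index=samples),
                      meta={"dose_response": True, "units": "cmH2O_scale"})
    )

    dataset = align_dataset(groups)
    return SyntheticStudy(dataset=dataset, true_edges=list(config.effects), config=config)


def score_recovery(found, truth) -> tuple[float, float]:
    """Precision and recall of recovered edges against the planted ledger.

    Edges are matched on the unordered pair of (group, variable) endpoints —
    the orientation chosen for a bidirectional cross-omics association is a
    heuristic and is not scored.  Duplicate findings of the same pair count
    once.  ``found`` may contain :class:`AssociationEdge` objects or
    (source, target) tuples.
    """
    def pair_of(item):
        if hasattr(item, "predictor"):
            return frozenset((item.predictor, item.response))
        src, tgt = item[0], item[1]
        return frozenset((tuple(src), tuple(tgt)))

    found_pairs = {pair_of(e) for e in found}
    truth_pairs = {frozenset((e.source, e.target)) for e in truth}
    if not found_pairs:
        return 0.0, 0.0
    hits = len(found_pairs & truth_pairs)
    precision = hits / len(found_pairs)
    recall = hits / len(truth_pairs) if truth_pairs else 1.0
    return precision, recall


def truth_frame(study: SyntheticStudy) -> pd.DataFrame:
    """The planted-edge ledger as a table (for ``truth_edges.tsv``)."""
    return pd.DataFrame(
        [
            {
                "source_group": e.source[0], "source": e.source[1],
                "target_group": e.target[0], "target": e.target[1],
                "beta": e.beta, "category": e.category,
            }
            for e in study.true_edges
        ],
        columns=["source_group", "source", "target_group", "target", "beta", "category"],
    )
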