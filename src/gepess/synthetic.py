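"""Desk-scale synthetic datasets with the statistical structure the
method assumes.

The generator emulates the yeast setting at reduced scale: a scale-free
PPI network (preferential attachment), module-structured expression
profiles (complex members co-expressed), subcellular localization enriched
for nucleus/ER among essentials, conservation scores higher for
essentials, and ground-truth labels planted through a known scoring
expression over the *final* feature table.

Circularity (ION consumes orthology, which is keyed to essentiality) is
broken by a two-pass scheme: provisional labels are taken from topology
alone (top NC), the biology tables are sampled against those, the final
features are computed, and the final labels come from the planting
expression plus Gaussian noise. Every stage is deterministic under the
seed, so two runs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as gio
from . import karva
from .features import FeatureConfig, assemble_feature_table, nc_centrality
from .io import DEFAULT_COMPARTMENTS, EssentialityLabels, InteractionNetwork


@dataclass
class SyntheticSpec:
    """Generation parameters.

    Defaults emulate the yeast study conditions at desk scale: ~500
    proteins with a heavy-tailed degree distribution, 36 expression
    samples, and an essential fraction of 0.229 (1167 of 5093).
    """

    n_proteins: int = 500
    edges_per_new_node: int = 3
    n_samples: int = 36
    n_modules: int = 20
    essential_fraction: float = 0.229
    planting_expression: str = "0.6*ION + 0.3*NC + 0.4*nucleus"
    noise_sd: float = 0.2
    rng_seed: int = 42

    def __post_init__(self):
        if not 0.0 < self.essential_fraction < 1.0:
            raise ValueError("essential_fraction must be in (0, 1)")
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be >= 10")

    @property
    def n_essential(self) -> int:
        return round(self.essential_fraction * self.n_proteins)


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


#: Sublinear preferential-attachment exponent. Attachment in real PPI
#: networks is weaker than linear; sublinear growth keeps the degree
#: distribution heavy-tailed without letting a single hub dwarf the rest.
_PA_EXPONENT = 0.75

#: Per-module cohesion (probability that a new member's extra edges stay
#: inside its module), spread so modules range from loose to complex-like.
def _module_cohesion(n_modules: int) -> np.ndarray:
    return np.linspace(0.05, 0.95, n_modules)


def generate_network(spec: SyntheticSpec) -> InteractionNetwork:
    """Modular scale-free network by preferential-attachment growth.

    Starts from a complete seed graph of m = ``edges_per_new_node`` nodes;
    every new node joins a random module and adds exactly m edges — the
    first by (sublinear) preferential attachment over the whole network,
    the rest preferentially inside its module or by triangle closure with
    probability given by the module's cohesion, otherwise globally. The
    result is connected, has exactly (n - m)*m + m*(m-1)/2 edges, a
    heavy-tailed degree distribution, and the triangle-rich modules that
    give the edge clustering coefficient its signal in real PPI networks.
    Node module memberships are stored in the ``module`` node attribute.
    Deterministic under the seed.
    """
    m = spec.edges_per_new_node
    n = spec.n_proteins
    rng = np.random.default_rng(spec.rng_seed)
    cohesion = _module_cohesion(spec.n_modules)
    g = nx.complete_graph(m)
    module = {i: i % spec.n_modules for i in range(m)}
    members: dict[int, list[int]] = {}
    for i in range(m):
        members.setdefault(module[i], []).append(i)

    def pa_choice(pool: list[int], exclude: set[int]) -> int | None:
        pool = [u for u in pool if u not in exclude]
        if not pool:
            return None
        w = np.array([g.degree(u) + 1 for u in pool], dtype=float) ** _PA_EXPONENT
        return pool[rng.choice(len(pool), p=w / w.sum())]

    for v in range(m, n):
        mod = int(rng.integers(0, spec.n_modules))
        module[v] = mod
        q = cohesion[mod]
        targets: set[int] = set()
        first = pa_choice(list(g.nodes), targets)
        targets.add(first)
        while len(targets) < m:
            if rng.random() < q:
                t = pa_choice(members.get(mod, []), targets)
                if t is None:
                    base = list(targets)[int(rng.integers(0, len(targets)))]
                    t = pa_choice(list(g[base]), targets | {v})
                if t is not None:
                    targets.add(t)
                    continue
            t = pa_choice(list(g.nodes), targets)
            if t is not None:
                targets.add(t)
        for t in targets:
            g.add_edge(v, t)
        members.setdefault(mod, []).append(v)

    mapping = dict(zip(sorted(g.nodes), _protein_ids(n)))
    relabeled = nx.relabel_nodes(g, mapping)
    nx.set_node_attributes(relabeled, {mapping[v]: mod for v, mod in module.items()},
                           name="module")
    return InteractionNetwork(relabeled)


def _provisional_essentials(spec: SyntheticSpec, network: InteractionNetwork) -> set[str]:
    # topology-only first pass: top fraction by NC, ties by ID
    nc = nc_centrality(network)
    order = sorted(nc, key=lambda p: (-nc[p], p))
    return set(order[:spec.n_essential])


def generate_expression(spec: SyntheticSpec, network: InteractionNetwork) -> pd.DataFrame:
    """Module-structured expression: proteins in the same module share a
    latent per-sample factor, so within-module correlation far exceeds
    between-module correlation. 5% of proteins are omitted to emulate
    partial expression coverage.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    nodes = sorted(network.graph.nodes)
    attrs = nx.get_node_attributes(network.graph, "module")
    if len(attrs) == len(nodes):
        # co-expression follows the network modules: complex members share
        # a latent factor, mirroring how the composite features expect
        # topology and expression to align
        module = np.array([attrs[p] for p in nodes])
    else:
        module = rng.integers(0, spec.n_modules, len(nodes))
    latent = rng.normal(size=(spec.n_modules, spec.n_samples))
    loading = rng.uniform(0.7, 1.3, len(nodes))
    noise = rng.normal(scale=0.5, size=(len(nodes), spec.n_samples))
    profiles = loading[:, None] * latent[module] + noise
    keep = rng.random(len(nodes)) >= 0.05
    covered = [p for p, k in zip(nodes, keep) if k]
    cols = [f"sample{j:02d}" for j in range(spec.n_samples)]
    return pd.DataFrame(profiles[keep], index=pd.Index(covered, name="protein"),
                        columns=cols)


# per-compartment membership probabilities (essential, nonessential):
# nucleus and ER strongly enriched among essentials, cytoplasm/vacuole
# depleted, the rest neutral background.
_LOC_PROBS: dict[str, tuple[float, float]] = {
    "nucleus": (0.80, 0.08),
    "endoplasmic_reticulum": (0.40, 0.10),
    "cytoplasm": (0.30, 0.50),
    "vacuole": (0.05, 0.20),
}
_LOC_BACKGROUND = (0.08, 0.08)

#: binomial ortholog-count parameters (n trials, p essential, p nonessential):
#: essential proteins have orthologs in nearly every reference organism,
#: nonessential ones in almost none
_ORTH_TRIALS = 20
_ORTH_P = (0.95, 0.03)


def generate_localization_orthology(
        spec: SyntheticSpec, network: InteractionNetwork,
        essentials: set[str] | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Sample the 16-compartment membership table and the per-protein
    conservation (ortholog-count) scores, keyed to the planted labels:
    essentials are likelier nuclear/ER residents and carry higher
    conservation scores."""
    rng = np.random.default_rng(spec.rng_seed + 2)
    if essentials is None:
        essentials = _provisional_essentials(spec, network)
    nodes = sorted(network.graph.nodes)
    is_ess = np.array([p in essentials for p in nodes])
    loc = {}
    for comp in DEFAULT_COMPARTMENTS:
        p_ess, p_non = _LOC_PROBS.get(comp, _LOC_BACKGROUND)
        p = np.where(is_ess, p_ess, p_non)
        loc[comp] = (rng.random(len(nodes)) < p).astype(int)
    loc_df = pd.DataFrame(loc, index=pd.Index(nodes, name="protein"))
    p = np.where(is_ess, _ORTH_P[0], _ORTH_P[1])
    orth = pd.Series(rng.binomial(_ORTH_TRIALS, p).astype(float),
                     index=pd.Index(nodes, name="protein"), name="orthology")
    return loc_df, orth


def plant_labels(spec: SyntheticSpec, features: pd.DataFrame) -> EssentialityLabels:
    """Score every protein with the planting expression plus Gaussian
    noise and label the top ``essential_fraction`` as essential."""
    rng = np.random.default_rng(spec.rng_seed + 3)
    tree = karva.parse_expression(spec.planting_expression, features.columns)
    frame = {c: features[c].to_numpy(dtype=float) for c in features.columns}
    score = np.broadcast_to(np.asarray(karva.evaluate(tree, frame), dtype=float),
                            (len(features),)).copy()
    score = score + rng.normal(scale=spec.noise_sd, size=len(score))
    ids = list(features.index)
    order = sorted(range(len(ids)), key=lambda i: (-score[i], ids[i]))
    essential = {ids[i] for i in order[:spec.n_essential]}
    return EssentialityLabels(essential=essential, universe=set(ids))


def planting_scores(spec: SyntheticSpec, features: pd.DataFrame) -> pd.Series:
    """Noise-free planting-expression scores (the generative signal)."""
    tree = karva.parse_expression(spec.planting_expression, features.columns)
    frame = {c: features[c].to_numpy(dtype=float) for c in features.columns}
    vals = np.broadcast_to(np.asarray(karva.evaluate(tree, frame), dtype=float),
                           (len(features),)).copy()
    return pd.Series(vals, index=features.index)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    network: InteractionNetwork
    expression: pd.DataFrame
    localization: pd.DataFrame
    orthology: pd.Series
    features: pd.DataFrame
    labels: EssentialityLabels


def generate_dataset(spec: SyntheticSpec | None = None,
                     feature_config: FeatureConfig | None = None) -> SyntheticDataset:
    """Run the full two-pass generation and return every artefact,
    including the assembled (normalized) feature table and final labels."""
    spec = spec or SyntheticSpec()
    network = generate_network(spec)
    provisional = _provisional_essentials(spec, network)
    expression = generate_expression(spec, network)
    localization, orthology = generate_localization_orthology(spec, network, provisional)
    features = assemble_feature_table(network, expression, localization, orthology,
                                      config=feature_config)
    labels = plant_labels(spec, features)
    return SyntheticDataset(spec=spec, network=network, expression=expression,
                            localization=localization, orthology=orthology,
                            features=features, labels=labels)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the five input files, the ground-truth essential list, the
    assembled feature table, and the generation parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "essential": outdir / "essential.txt",
        "expression": outdir / "expression.tsv",
        "localization": outdir / "localization.tsv",
        "orthology": outdir / "orthology.tsv",
        "features": outdir / "features.tsv",
        "spec": outdir / "synthetic_spec.yaml",
    }
    gio.write_network(dataset.network, paths["network"])
    gio.write_labels(dataset.labels, paths["essential"])
    dataset.expression.to_csv(paths["expression"], sep="\t", index_label="protein")
    dataset.localization.to_csv(paths["localization"], sep="\t", index_label="protein")
    dataset.orthology.to_frame().to_csv(paths["orthology"], sep="\t", index_label="protein")
    gio.write_feature_table(dataset.features, paths["features"])
    import yaml
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(asdict(dataset.spec), fh, sort_keys=True)
    return paths
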