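"""Bootstrap-validated Spearman co-occurrence networks.

One network is inferred per group/timepoint stratum. Candidate edges are all
species-species pairs plus all species x clinical/metabolite variable pairs;
an edge is kept when both

* the Spearman correlation strictly exceeds its kind's magnitude threshold
  (|rho| > 0.6 for species-species, |rho| > 0.5 for species-variable), and
* a paired bootstrap (default B = 1000 resamples) finds the sign of the
  correlation stable at p <= 0.05.

Positive edges are *synergisms* (co-occurrence), negative ones *exclusions*
(co-exclusion). On the inferred graph the package reports the topology
descriptors used to compare strata (node/edge counts, synergism/exclusion
ratio, mean neighborhood size), positively-connected modules (greedy
modularity maximisation, only clusters of >= 4 nodes reported), hub species
(total degree >= mean + 1 SD of the degree distribution) and shortest-path
betweenness centrality.

The estimation follows a statsmodels-like shape: build a
:class:`CooccurrenceModel` from a stratum's relative abundances (plus
optional variables), call :meth:`~CooccurrenceModel.fit`, and query the
returned :class:`CooccurrenceResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import strata
from .stats import spearman

__all__ = [
    "select_network_species",
    "bootstrap_pvalue",
    "CooccurrenceModel",
    "CooccurrenceResults",
    "CooccurrenceNetwork",
    "TopologySummary",
    "ModulePartition",
    "HubSet",
    "build_network",
    "topology_summary",
    "detect_modules",
    "detect_hubs",
    "betweenness",
    "write_network",
    "read_network",
]

SPECIES = "species"
CLINICAL = "clinical"
METABOLITE = "metabolite"
NODE_KINDS = (SPECIES, CLINICAL, METABOLITE)

#: magnitude thresholds (strict) per edge kind
RHO_SPECIES = 0.6
RHO_VARIABLE = 0.5
ALPHA_BOOT = 0.05
N_BOOT = 1000

_BOOT_RETRY_CAP = 100


def select_network_species(
    rel: pd.DataFrame, meta: pd.DataFrame, threshold: float = 0.001
) -> list[str]:
    """Species whose mean relative abundance reaches ``threshold`` (default
    0.1%) in at least one group/timepoint stratum."""
    keep = []
    means = {
        label: rel.loc[rel.index.intersection(idx)].mean(axis=0)
        for label, idx in strata(meta).items()
    }
    for taxon in rel.columns:
        if any(m[taxon] >= threshold for m in means.values()):
            keep.append(taxon)
    return keep


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=1)


def _row_pearson(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def bootstrap_pvalue(
    x, y, n_boot: int = N_BOOT, seed=None, method: str = "sign"
) -> float:
    """Bootstrap significance of a Spearman correlation.

    ``method="sign"`` (default) is the sign-stability bootstrap: draw
    ``n_boot`` paired resamples with replacement, compute the Spearman
    correlation of each, and report ``p = 2 * min(#{rho* <= 0},
    #{rho* >= 0}) / n_boot`` capped at 1 — small when the resampled
    correlation essentially never changes sign. Resamples with zero rank
    variance are redrawn (up to a retry cap).

    ``method="permutation"`` permutes ``y`` instead and reports
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_boot + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    rng = np.random.default_rng(seed)

    if method == "permutation":
        rho_obs = spearman(x, y)
        if np.isnan(rho_obs):
            return float("nan")
        ys = np.stack([rng.permutation(y) for _ in range(n_boot)])
        rhos = _row_pearson(_rank_rows(np.broadcast_to(x, ys.shape).copy()), _rank_rows(ys))
        return float((1 + np.sum(np.abs(rhos) >= abs(rho_obs))) / (n_boot + 1))
    if method != "sign":
        raise ValueError(f"unknown bootstrap method {method!r}")

    rhos = np.full(n_boot, np.nan)
    todo = np.arange(n_boot)
    for _ in range(_BOOT_RETRY_CAP):
        if not todo.size:
            break
        idx = rng.integers(0, n, size=(todo.size, n))
        rhos[todo] = _row_pearson(_rank_rows(x[idx]), _rank_rows(y[idx]))
        todo = todo[np.isnan(rhos[todo])]
    if todo.size:
        raise RuntimeError(
            "bootstrap retry cap exceeded: resamples are persistently degenerate"
        )
    p = 2.0 * min(np.sum(rhos <= 0), np.sum(rhos >= 0)) / n_boot
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# containers


@dataclass
class CooccurrenceNetwork:
    """A fitted co-occurrence graph for one stratum.

    ``graph`` is an undirected networkx graph whose nodes carry ``kind``
    (species | clinical | metabolite) and whose edges carry ``rho``,
    ``p_boot``, ``sign`` (synergism | exclusion) and ``edge_kind``
    (species-species | species-variable).
    """

    group: str
    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ValueError("self-edges are not allowed")
        for node, data in g.nodes(data=True):
            if data.get("kind") not in NODE_KINDS:
                raise ValueError(f"node {node!r} has invalid kind {data.get('kind')!r}")
        rho_ss = self.provenance.get("rho_species", RHO_SPECIES)
        rho_sv = self.provenance.get("rho_variable", RHO_VARIABLE)
        alpha = self.provenance.get("alpha", ALPHA_BOOT)
        for u, v, data in g.edges(data=True):
            rho = data["rho"]
            thr = rho_ss if data["edge_kind"] == "species-species" else rho_sv
            if not abs(rho) > thr:
                raise ValueError(f"edge ({u}, {v}): |rho|={abs(rho):.3f} <= {thr}")
            if data["p_boot"] > alpha:
                raise ValueError(f"edge ({u}, {v}): p_boot={data['p_boot']} > {alpha}")
            expected = "synergism" if rho > 0 else "exclusion"
            if data["sign"] != expected:
                raise ValueError(f"edge ({u}, {v}): sign does not match rho")

    @property
    def species(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == SPECIES]

    @property
    def variables(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] != SPECIES]

    def species_species_edges(self):
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d["edge_kind"] == "species-species"
        ]


def _round2(x: float) -> float:
    return float(np.round(x, 2)) if np.isfinite(x) else x


@dataclass
class TopologySummary:
    """The per-stratum topology descriptors.

    ``edges``, ``synergisms`` and ``exclusions`` count species-species edges
    only; ``edges_per_node = edges / nodes``; ``avg_neighbors`` is the mean
    total degree including species-variable edges. ``printed()`` rounds to
    the two-decimal precision used in reports.
    """

    nodes: int
    edges: int
    synergisms: int
    exclusions: int
    edges_per_node: float
    syn_excl_ratio: float
    avg_neighbors: float

    def __post_init__(self) -> None:
        if self.edges != self.synergisms + self.exclusions:
            raise ValueError("edges must equal synergisms + exclusions")

    @classmethod
    def from_counts(
        cls, nodes: int, synergisms: int, exclusions: int, avg_neighbors: float = np.nan
    ) -> "TopologySummary":
        edges = synergisms + exclusions
        return cls(
            nodes=nodes,
            edges=edges,
            synergisms=synergisms,
            exclusions=exclusions,
            edges_per_node=edges / nodes if nodes else 0.0,
            syn_excl_ratio=synergisms / exclusions if exclusions else np.inf,
            avg_neighbors=avg_neighbors,
        )

    def printed(self) -> dict:
        return {
            "Nodes": self.nodes,
            "Edges": self.edges,
            "Edges/node ratio": _round2(self.edges_per_node),
            "Synergisms": self.synergisms,
            "Exclusions": self.exclusions,
            "Syn/Escl ratio": _round2(self.syn_excl_ratio),
            "Average number of neighbors": _round2(self.avg_neighbors),
        }


@dataclass
class ModulePartition:
    """Disjoint positively-connected clusters with >= ``min_size`` nodes."""

    modules: dict[str, frozenset]
    min_size: int

    def __post_init__(self) -> None:
        seen: set = set()
        for label, members in self.modules.items():
            if len(members) < self.min_size:
                raise ValueError(f"module {label} smaller than min_size")
            if seen & set(members):
                raise ValueError("modules are not disjoint")
            seen |= set(members)


@dataclass
class HubSet:
    hubs: list[str]
    degrees: pd.Series
    threshold: float


def topology_summary(network: CooccurrenceNetwork) -> TopologySummary:
    """Compute the topology descriptors of a fitted network."""
    g = network.graph
    if g.number_of_nodes() == 0:
        warnings.warn("empty network: all-zero topology summary", stacklevel=2)
        return TopologySummary(0, 0, 0, 0, 0.0, 0.0, 0.0)
    ss = network.species_species_edges()
    syn = sum(1 for *_, d in ss if d["sign"] == "synergism")
    excl = len(ss) - syn
    n_species = len(network.species)
    degrees = [d for _, d in g.degree()]
    return TopologySummary(
        nodes=n_species,
        edges=len(ss),
        synergisms=syn,
        exclusions=excl,
        edges_per_node=len(ss) / n_species if n_species else 0.0,
        syn_excl_ratio=syn / excl if excl else np.inf,
        avg_neighbors=float(np.mean(degrees)) if degrees else 0.0,
    )


def detect_modules(network: CooccurrenceNetwork, min_size: int = 4) -> ModulePartition:
    """Positively-connected clusters by greedy modularity maximisation.

    Community detection runs on the synergism-edge subgraph with |rho| as
    edge weight; communities smaller than ``min_size`` are not reported.
    Node insertion order (lexicographic) makes the result deterministic.
    """
    pos = nx.Graph()
    pos.add_nodes_from(sorted(network.graph.nodes))
    for u, v, d in network.graph.edges(data=True):
        if d["sign"] == "synergism":
            pos.add_edge(*sorted((u, v)), weight=abs(d["rho"]))
    if pos.number_of_edges() == 0:
        return ModulePartition(modules={}, min_size=min_size)
    communities = nx.community.greedy_modularity_communities(pos, weight="weight")
    big = sorted(
        (frozenset(c) for c in communities if len(c) >= min_size),
        key=lambda c: (-len(c), min(c)),
    )
    return ModulePartition(
        modules={f"M{i + 1}": c for i, c in enumerate(big)}, min_size=min_size
    )


def detect_hubs(network: CooccurrenceNetwork) -> HubSet:
    """Highly connected nodes by total degree (species-species plus
    species-variable edges): degree >= mean + 1 SD of the network's degree
    distribution. A degenerate distribution (SD = 0) yields no hubs."""
    deg = pd.Series(dict(network.graph.degree()), dtype=float).sort_index()
    if deg.empty:
        return HubSet(hubs=[], degrees=deg, threshold=np.nan)
    sd = float(deg.std(ddof=0))
    if sd == 0.0:
        if (deg > 0).all() and len(deg) > 1:
            warnings.warn(
                "all degrees equal and positive: no hubs under the mean+SD rule",
                stacklevel=2,
            )
        return HubSet(hubs=[], degrees=deg, threshold=np.inf)
    thr = float(deg.mean() + sd)
    return HubSet(hubs=sorted(deg.index[deg >= thr]), degrees=deg, threshold=thr)


def betweenness(network: CooccurrenceNetwork) -> pd.Series:
    """Shortest-path betweenness centrality on the unweighted skeleton
    (unnormalised pair-dependency sums)."""
    bc = nx.betweenness_centrality(network.graph, normalized=False)
    return pd.Series(bc, dtype=float).sort_index()


# ---------------------------------------------------------------------------
# model / results


class CooccurrenceModel:
    """Co-occurrence network model for one group/timepoint stratum.

    Parameters
    ----------
    rel : DataFrame
        Relative abundances of the stratum's samples (rows) for the species
        retained by the abundance screen (columns).
    variables : DataFrame, optional
        Clinical/metabolite variables for the same samples.
    variable_kinds : mapping, optional
        variable name -> "clinical" or "metabolite" (default clinical).
    group : str
        Stratum label (e.g. "CTRL", "ERA-T0").
    rho_species, rho_variable : float
        Strict magnitude thresholds for the two edge kinds.
    alpha : float
        Bootstrap significance threshold.
    include_isolated_species : bool
        Keep screened species with no edge as isolated nodes (default True);
        variables without edges are always excluded.
    bootstrap : {"sign", "permutation"}
        Bootstrap p-value flavour (see :func:`bootstrap_pvalue`).
    """

    def __init__(
        self,
        rel: pd.DataFrame,
        variables: pd.DataFrame | None = None,
        *,
        variable_kinds: dict[str, str] | None = None,
        group: str = "all",
        rho_species: float = RHO_SPECIES,
        rho_variable: float = RHO_VARIABLE,
        alpha: float = ALPHA_BOOT,
        include_isolated_species: bool = True,
        bootstrap: str = "sign",
    ) -> None:
        if rel.shape[0] < 5:
            raise ValueError("need at least 5 samples in the stratum")
        if variables is not None:
            variables = variables.loc[rel.index]
            overlap = set(variables.columns) & set(rel.columns)
            if overlap:
                raise ValueError(f"variable names collide with species: {sorted(overlap)[:3]}")
        self.rel = rel
        self.variables = variables
        self.variable_kinds = dict(variable_kinds or {})
        self.group = group
        self.rho_species = rho_species
        self.rho_variable = rho_variable
        self.alpha = alpha
        self.include_isolated_species = include_isolated_species
        self.bootstrap = bootstrap

    def _candidate_pairs(self):
        species = list(self.rel.columns)
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                yield a, b, "species-species", self.rho_species
        if self.variables is not None:
            for a in species:
                for v in self.variables.columns:
                    yield a, v, "species-variable", self.rho_variable

    def fit(self, n_boot: int = N_BOOT, seed=None) -> "CooccurrenceResults":
        """Estimate all candidate correlations, bootstrap the threshold
        passers, and assemble the validated network."""
        rng = np.random.default_rng(seed)
        rows = []
        for a, b, kind, thr in self._candidate_pairs():
            x = self.rel[a].to_numpy()
            y = (
                self.rel[b].to_numpy()
                if kind == "species-species"
                else self.variables[b].to_numpy()
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearman(x, y)
            p_boot = np.nan
            if np.isfinite(rho) and abs(rho) > thr:
                p_boot = bootstrap_pvalue(
                    x, y, n_boot=n_boot,
                    seed=rng.integers(0, 2**31 - 1),
                    method=self.bootstrap,
                )
            rows.append(
                {"source": a, "target": b, "edge_kind": kind, "rho": rho, "p_boot": p_boot}
            )
        corr = pd.DataFrame.from_records(rows)

        g = nx.Graph()
        if self.include_isolated_species:
            for sp in self.rel.columns:
                g.add_node(sp, kind=SPECIES)
        kept = corr[
            corr["rho"].abs()
            > np.where(corr["edge_kind"] == "species-species", self.rho_species, self.rho_variable)
        ]
        kept = kept[kept["p_boot"] <= self.alpha]
        for rec in kept.itertuples():
            for node in (rec.source, rec.target):
                if node not in g:
                    if self.variables is not None and node in self.variables.columns:
                        g.add_node(node, kind=self.variable_kinds.get(node, CLINICAL))
                    else:
                        g.add_node(node, kind=SPECIES)
            g.add_edge(
                rec.source,
                rec.target,
                rho=float(rec.rho),
                p_boot=float(rec.p_boot),
                sign="synergism" if rec.rho > 0 else "exclusion",
                edge_kind=rec.edge_kind,
            )
        network = CooccurrenceNetwork(
            group=self.group,
            graph=g,
            provenance={
                "rho_species": self.rho_species,
                "rho_variable": self.rho_variable,
                "alpha": self.alpha,
                "n_boot": n_boot,
                "seed": seed,
                "bootstrap": self.bootstrap,
                "n_samples": int(self.rel.shape[0]),
            },
        )
        return CooccurrenceResults(model=self, network=network, correlations=corr)


@dataclass
class CooccurrenceResults:
    """Fitted network plus the full candidate correlation table.

    ``correlations`` holds every candidate pair's Spearman rho; ``p_boot`` is
    computed only for pairs whose |rho| exceeds the kind threshold (others
    are NaN — they can never become edges).
    """

    model: CooccurrenceModel
    network: CooccurrenceNetwork
    correlations: pd.DataFrame

    def topology(self) -> TopologySummary:
        return topology_summary(self.network)

    def modules(self, min_size: int = 4) -> ModulePartition:
        return detect_modules(self.network, min_size=min_size)

    def hubs(self) -> HubSet:
        return detect_hubs(self.network)

    def betweenness(self) -> pd.Series:
        return betweenness(self.network)

    def summary(self) -> str:
        topo = self.topology().printed()
        lines = [
            f"Co-occurrence network: {self.network.group}",
            f"  samples: {self.model.rel.shape[0]}, species screened: {self.model.rel.shape[1]}",
            f"  thresholds: |rho| > {self.model.rho_species} (species-species), "
            f"> {self.model.rho_variable} (species-variable), "
            f"p_boot <= {self.model.alpha} (B = {self.network.provenance['n_boot']})",
        ]
        for key, val in topo.items():
            lines.append(f"  {key}: {val}")
        mods = self.modules()
        lines.append(f"  modules (>=4 nodes): {len(mods.modules)}")
        hubs = self.hubs()
        lines.append(f"  hubs (degree >= mean+SD): {', '.join(hubs.hubs) or 'none'}")
        return "\n".join(lines)


def build_network(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    variables: pd.DataFrame | None = None,
    *,
    variable_kinds: dict[str, str] | None = None,
    species_threshold: float = 0.001,
    rho_species: float = RHO_SPECIES,
    rho_variable: float = RHO_VARIABLE,
    alpha: float = ALPHA_BOOT,
    n_boot: int = N_BOOT,
    seed=None,
    bootstrap: str = "sign",
) -> CooccurrenceResults:
    """Screen species, subset one stratum, and fit its network.

    ``rel`` spans the whole cohort (the 0.1% abundance screen looks across
    all strata); ``group`` picks the stratum whose samples are modelled.
    """
    groups = strata(meta)
    if group not in groups:
        raise KeyError(f"unknown stratum {group!r}; have {list(groups)}")
    species = select_network_species(rel, meta, threshold=species_threshold)
    idx = rel.index.intersection(groups[group])
    model = CooccurrenceModel(
        rel.loc[idx, species],
        variables.loc[idx] if variables is not None else None,
        variable_kinds=variable_kinds,
        group=group,
        rho_species=rho_species,
        rho_variable=rho_variable,
        alpha=alpha,
        bootstrap=bootstrap,
    )
    return model.fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# export / import


def write_network(network: CooccurrenceNetwork, prefix) -> dict[str, str]:
    """Export a network as Cytoscape-readable files.

    Writes ``<prefix>.sif`` (edges as ``source <sign> target``),
    ``<prefix>.edges.tsv`` (edge attributes), ``<prefix>.nodes.tsv`` (node
    kinds) and ``<prefix>.graphml``. Returns the paths written.
    """
    prefix = str(prefix)
    paths = {
        "sif": prefix + ".sif",
        "edges": prefix + ".edges.tsv",
        "nodes": prefix + ".nodes.tsv",
        "graphml": prefix + ".graphml",
    }
    g = network.graph
    with open(paths["sif"], "w") as fh:
        connected = set()
        for u, v, d in g.edges(data=True):
            fh.write(f"{u}\t{d['sign']}\t{v}\n")
            connected |= {u, v}
        for node in sorted(set(g.nodes) - connected):
            fh.write(f"{node}\n")
    edge_rows = [
        {"source": u, "target": v, **d} for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(
        edge_rows, columns=["source", "target", "rho", "p_boot", "sign", "edge_kind"]
    ).to_csv(paths["edges"], sep="\t", index=False)
    pd.DataFrame(
        [{"id": n, "kind": d["kind"]} for n, d in g.nodes(data=True)]
    ).to_csv(paths["nodes"], sep="\t", index=False)
    gml = g.copy()
    gml.graph["group"] = network.group
    for key, val in network.provenance.items():
        if val is not None:
            gml.graph[f"prov_{key}"] = val
    nx.write_graphml(gml, paths["graphml"])
    return paths


def read_network(graphml_path) -> CooccurrenceNetwork:
    """Re-import a network written by :func:`write_network` (GraphML)."""
    g = nx.read_graphml(graphml_path)
    g = nx.Graph(g)
    group = g.graph.pop("group", "unknown")
    provenance = {
        k[len("prov_") :]: v for k, v in list(g.graph.items()) if k.startswith("prov_")
    }
    for k in list(g.graph):
        del g.graph[k]
    return CooccurrenceNetwork(group=group, graph=g, provenance=provenance)
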