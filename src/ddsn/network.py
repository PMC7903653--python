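"""Shared-phenotype identification, the disease-phenotype bipartite graph,
and the compact weighted disease-disease similarity network (DDSN-C).

Two diseases share a phenotype term under three rules evaluated over every
pair of their direct annotations:

* rule 1 - the two annotations are the identical term (the shared term);
* rule 2 - the two annotations differ but have a common direct parent
  (the shared term is that parent);
* rule 3 - one annotation is a direct parent of the other (the shared term
  is the parent).

"Direct parent" means one is_a hop; more distant common ancestors never
create an edge, so two diseases that only meet at the root stay unlinked.
Per disease pair the multiple shared terms are merged into a single edge
whose weight ``w`` is the mean IC of the distinct shared terms.
"""

from __future__ import annotations

import math
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, NamedTuple, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import DiseaseCorpus
from .errors import ComputationError
from .ontology import ICTable, OntologyDAG

__all__ = [
    "SharedPhenotype",
    "shared_phenotypes_pair",
    "build_bipartite",
    "derive_network",
    "shared_dp_stats",
    "apply_threshold",
    "threshold_sweep",
    "degree_stats",
    "giant_component",
]


class SharedPhenotype(NamedTuple):
    """One route by which a disease pair shares a phenotype term."""

    disease_i: str
    ps_i: str
    term_i: str
    shared_term: str
    rule: int
    disease_j: str
    ps_j: str
    term_j: str


def _routes(
    dag: OntologyDAG, terms_i: Iterable[str], terms_j: Iterable[str]
) -> Iterator[Tuple[str, str, str, int]]:
    """Yield (term_i, term_j, shared_term, rule) for every sharing route."""
    for ti in terms_i:
        parents_i = dag.parents(ti)
        for tj in terms_j:
            if ti == tj:
                yield ti, tj, ti, 1
                continue
            parents_j = dag.parents(tj)
            for p in parents_i & parents_j:
                yield ti, tj, p, 2
            if ti in parents_j:
                yield ti, tj, ti, 3
            if tj in parents_i:
                yield ti, tj, tj, 3



def shared_phenotypes_pair(
    dag: OntologyDAG,
    terms_i: Iterable[str],
    terms_j: Iterable[str],
) -> Dict[str, int]:
    """Shared terms of one disease pair, each with its lowest-numbered rule."""
    shared: Dict[str, int] = {}
    for _, _, s, rule in _routes(dag, terms_i, terms_j):
        if s not in shared or rule < shared[s]:
            shared[s] = rule
    return shared


def build_bipartite(
    corpus: DiseaseCorpus, dag: OntologyDAG
) -> Tuple[List[SharedPhenotype], nx.Graph, Dict[int, float]]:
    """Enumerate all sharing 7-tuples and assemble the bipartite graph.

    Returns the tuple list (sorted, distinct by their full fields), the
    deduplicated disease-phenotype graph (node attribute ``bipartite`` is
    0 for diseases, 1 for phenotype terms), and the rule composition
    fractions over the per-pair distinct shared terms.
    """
    annotations = {d: sorted(ts) for d, ts in corpus.annotations().items()}
    disease_ps = {d: sorted(ps) for d, ps in corpus.disease_ps().items()}
    diseases = sorted(annotations)
    tuples: Set[SharedPhenotype] = set()
    graph = nx.Graph()
    rule_counts = {1: 0, 2: 0, 3: 0}
    for a in range(len(diseases)):
        d_i = diseases[a]
        for b in range(a + 1, len(diseases)):
            d_j = diseases[b]
            pair_shared: Dict[str, int] = {}
            for ti, tj, s, rule in _routes(dag, annotations[d_i], annotations[d_j]):
                if s not in pair_shared or rule < pair_shared[s]:
                    pair_shared[s] = rule
                for ps_i in disease_ps[d_i]:
                    for ps_j in disease_ps[d_j]:
                        tuples.add(
                            SharedPhenotype(d_i, ps_i, ti, s, rule, d_j, ps_j, tj)
                        )
            for s, rule in pair_shared.items():
                rule_counts[rule] += 1
                graph.add_node(d_i, bipartite=0)
                graph.add_node(d_j, bipartite=0)
                graph.add_node(s, bipartite=1)
                graph.add_edge(d_i, s)
                graph.add_edge(d_j, s)
    total = sum(rule_counts.values())
    fractions = {
        r: (c / total if total else float("nan")) for r, c in rule_counts.items()
    }
    return sorted(tuples), graph, fractions


def derive_network(
    tuples: Sequence[SharedPhenotype], ic: ICTable
) -> nx.Graph:
    """Merge per-pair sharing tuples into the compact weighted network.

    Each unordered disease pair gets one edge carrying the distinct shared
    terms (``shared_terms``), their count (``n_shared``) and weight ``w`` =
    mean IC of the shared terms.
    """
    by_pair: Dict[Tuple[str, str], Set[str]] = {}
    for t in tuples:
        key = (
            (t.disease_i, t.disease_j)
            if t.disease_i < t.disease_j
            else (t.disease_j, t.disease_i)
        )
        by_pair.setdefault(key, set()).add(t.shared_term)
    net = nx.Graph()
    for (d_i, d_j), terms in sorted(by_pair.items()):
        for s in terms:
            if s not in ic:
                raise ComputationError(f"shared term {s!r} missing from the IC table")
        # summation in sorted order keeps w bit-identical across processes
        w = sum(ic[s] for s in sorted(terms)) / len(terms)
        net.add_edge(
            d_i,
            d_j,
            w=w,
            n_shared=len(terms),
            shared_terms=tuple(sorted(terms)),
        )
    return net


def _stratum_stats(values: Sequence[float]) -> Dict[str, float]:
    if not values:
        return {
            "mean": float("nan"),
            "sd": float("nan"),
            "median": float("nan"),
            "min": float("nan"),
            "max": float("nan"),
        }
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def shared_dp_stats(
    network: nx.Graph, disease_ps: Mapping[str, Set[str]]
) -> pd.DataFrame:
    """Per-pair shared-term count and weight, stratified by series identity.

    A pair counts as same-series when the two diseases' series membership
    sets intersect. Rows: ``same_ps``, ``diff_ps``, ``all``.
    """
    strata: Dict[str, Dict[str, List[float]]] = {
        s: {"n_shared": [], "w": []} for s in ("same_ps", "diff_ps", "all")
    }
    for d_i, d_j, data in network.edges(data=True):
        same = bool(disease_ps.get(d_i, set()) & disease_ps.get(d_j, set()))
        for key in (("same_ps" if same else "diff_ps"), "all"):
            strata[key]["n_shared"].append(data["n_shared"])
            strata[key]["w"].append(data["w"])
    rows = []
    for name in ("same_ps", "diff_ps", "all"):
        row: Dict[str, float] = {"stratum": name, "n_pairs": len(strata[name]["w"])}
        for prefix, values in (
            ("n_shared", strata[name]["n_shared"]),
            ("ic", strata[name]["w"]),
        ):
            for stat, v in _stratum_stats(values).items():
                row[f"{prefix}_{stat}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def apply_threshold(
    network: nx.Graph, w_star: float
) -> Tuple[nx.Graph, Dict[str, float]]:
    """Keep edges with ``w`` strictly above the threshold, drop isolates.

    The report gives node/edge counts and retention fractions relative to
    the unthresholded network.
    """
    sub = nx.Graph()
    sub.add_nodes_from(network.nodes(data=True))
    for d_i, d_j, data in network.edges(data=True):
        if data["w"] > w_star:
            sub.add_edge(d_i, d_j, **data)
    sub.remove_nodes_from([n for n in sub if sub.degree(n) == 0])
    n0, m0 = network.number_of_nodes(), network.number_of_edges()
    report = {
        "w_star": w_star,
        "nodes_total": n0,
        "edges_total": m0,
        "nodes_kept": sub.number_of_nodes(),
        "edges_kept": sub.number_of_edges(),
        "node_fraction": sub.number_of_nodes() / n0 if n0 else float("nan"),
        "edge_fraction": sub.number_of_edges() / m0 if m0 else float("nan"),
    }
    return sub, report


def threshold_sweep(
    network: nx.Graph, grid: Sequence[float]
) -> pd.DataFrame:
    """Retention curve over a grid of thresholds."""
    rows = [apply_threshold(network, w)[1] for w in grid]
    return pd.DataFrame(rows)


def degree_stats(
    graph: nx.Graph, top_n: int = 10
) -> Dict[str, object]:
    """Per-class degree summary, hubs and the empirical distribution P(k).

    Works on a bipartite graph (using the ``bipartite`` node attribute to
    split classes) or on a plain graph (single class ``all``). The log-log
    least-squares slope of P(k) is exported as a descriptive statistic
    only.
    """
    if graph.number_of_nodes() == 0:
        raise ComputationError("degree statistics on an empty graph")
    bipartite = all("bipartite" in graph.nodes[n] for n in graph.nodes)
    if bipartite and any(graph.nodes[n]["bipartite"] == 1 for n in graph.nodes):
        classes = {
            "disease": [n for n in graph if graph.nodes[n]["bipartite"] == 0],
            "phenotype": [n for n in graph if graph.nodes[n]["bipartite"] == 1],
        }
    else:
        classes = {"all": list(graph.nodes)}
    out: Dict[str, object] = {}
    dist_rows = []
    for cls, nodes in classes.items():
        degrees = np.array([graph.degree(n) for n in nodes], dtype=float)
        hubs = sorted(nodes, key=lambda n: (-graph.degree(n), n))[:top_n]
        ks, counts = np.unique(degrees, return_counts=True)
        pk = counts / counts.sum()
        positive = ks > 0
        if positive.sum() >= 2:
            slope = float(
                np.polyfit(np.log10(ks[positive]), np.log10(pk[positive]), 1)[0]
            )
        else:
            slope = float("nan")
        out[cls] = {
            "n_nodes": len(nodes),
            "degree_mean": float(degrees.mean()),
            "degree_sd": float(degrees.std(ddof=1)) if len(degrees) > 1 else float("nan"),
            "hubs": [(n, graph.degree(n)) for n in hubs],
            "loglog_slope": slope,
        }
        for k, p in zip(ks, pk):
            dist_rows.append({"class": cls, "k": int(k), "p_k": float(p)})
    out["distribution"] = pd.DataFrame(dist_rows)
    return out


def giant_component(network: nx.Graph) -> Dict[str, object]:
    """Connected components by size; the largest with node/edge counts."""
    if network.number_of_nodes() == 0:
        return {"n_components": 0, "sizes": [], "giant_nodes": 0, "giant_edges": 0}
    components = sorted(nx.connected_components(network), key=lambda c: (-len(c), sorted(c)[0]))
    giant = network.subgraph(components[0])
    return {
        "n_components": len(components),
        "sizes": [len(c) for c in components],
        "giant_nodes": giant.number_of_nodes(),
        "giant_edges": giant.number_of_edges(),
        "giant": giant,
    }
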