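"""Dyadicity and heterophilicity of binary node properties on the
disease similarity network.

A *dyad* is an edge plus its two endpoint nodes. For a binary property
(here: membership of one phenotypic series) a dyad is homogeneous when
both endpoints carry the property and heterogeneous when exactly one does.
With ``N`` nodes, ``M`` edges and ``n`` property-carrying nodes, uniform
random placement of the property on the fixed graph gives connectance
``p = 2M / (N(N-1))`` and expected counts

    e11 = C(n, 2) * p          (homogeneous)
    e10 = n * (N - n) * p      (heterogeneous)

Dyadicity D = m11/e11 and heterophilicity H = m10/e10 are the observed-to-
expected ratios; D > 1 marks a dyadic property (its carriers link to each
other more than chance), H > 1 a heterophilic one (its carriers link to
non-carriers more than chance). Zero-expectation ratios are reported as
undefined, never as infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "DyadReport",
    "dyad_counts",
    "expected_dyads",
    "dh_for_property",
    "dh_all",
    "permutation_null",
]

#: equality tolerance when classifying D or H against 1
CLASSIFICATION_TOL = 1e-9


@dataclass
class DyadReport:
    property_id: str
    n_nodes: int
    n_edges: int
    n_property: int
    m11: int
    m10: int
    e11: float
    e10: float
    dyadicity: Optional[float]
    heterophilicity: Optional[float]
    dyadic_class: str
    hetero_class: str
    note: str = ""


def dyad_counts(network: nx.Graph, property_nodes: Set[str]) -> Tuple[int, int]:
    """Observed homogeneous (m11) and heterogeneous (m10) dyad counts."""
    outside = set(property_nodes) - set(network.nodes)
    if outside:
        raise ConfigurationError(
            f"property nodes not in the network: {sorted(outside)[:5]}"
        )
    m11 = m10 = 0
    for u, v in network.edges:
        inside = (u in property_nodes) + (v in property_nodes)
        if inside == 2:
            m11 += 1
        elif inside == 1:
            m10 += 1
    return m11, m10


def expected_dyads(
    n_nodes: int, n_edges: int, n_property: int
) -> Tuple[float, float]:
    """Expected dyad counts under uniform random property placement."""
    if n_nodes < 2:
        raise ConfigurationError(f"need at least 2 nodes, got {n_nodes}")
    if n_property > n_nodes:
        raise ConfigurationError(
            f"property size {n_property} exceeds node count {n_nodes}"
        )
    p = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
    e11 = n_property * (n_property - 1) / 2.0 * p
    e10 = n_property * (n_nodes - n_property) * p
    return e11, e10


def _classify(ratio: Optional[float], above: str, below: str) -> str:
    if ratio is None:
        return "undefined"
    if ratio > 1.0 + CLASSIFICATION_TOL:
        return above
    if ratio < 1.0 - CLASSIFICATION_TOL:
        return below
    return "neutral"


def dh_for_property(
    network: nx.Graph,
    property_nodes: Set[str],
    property_id: str = "property",
) -> DyadReport:
    """Dyadicity and heterophilicity of one binary property."""
    m11, m10 = dyad_counts(network, property_nodes)
    n_nodes = network.number_of_nodes()
    n_edges = network.number_of_edges()
    e11, e10 = expected_dyads(n_nodes, n_edges, len(property_nodes))
    notes = []
    if e11 > 0:
        dyadicity: Optional[float] = m11 / e11
    else:
        dyadicity = None
        notes.append("e11=0")
    if e10 > 0:
        heterophilicity: Optional[float] = m10 / e10
    else:
        heterophilicity = None
        notes.append("e10=0")
    return DyadReport(
        property_id=property_id,
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_property=len(property_nodes),
        m11=m11,
        m10=m10,
        e11=e11,
        e10=e10,
        dyadicity=dyadicity,
        heterophilicity=heterophilicity,
        dyadic_class=_classify(dyadicity, "dyadic", "anti-dyadic"),
        hetero_class=_classify(heterophilicity, "heterophilic", "heterophobic"),
        note="; ".join(notes),
    )


def dh_all(
    network: nx.Graph,
    series_members: Mapping[str, Set[str]],
    ps_classes: Optional[Mapping[str, Iterable[str]]] = None,
    min_members: int = 2,
) -> Tuple[List[DyadReport], pd.DataFrame, pd.DataFrame, List[str]]:
    """One dyad report per series with enough members in the network.

    Series with fewer than ``min_members`` member nodes present in the
    network are skipped (and listed). Returns (reports, per-series table,
    per-class aggregate, skipped series ids). ``ps_classes`` optionally
    maps series -> classification labels for the aggregate.
    """
    reports: List[DyadReport] = []
    skipped: List[str] = []
    for ps_id in sorted(series_members):
        present = set(series_members[ps_id]) & set(network.nodes)
        if len(present) < min_members:
            skipped.append(ps_id)
            continue
        reports.append(dh_for_property(network, present, property_id=ps_id))
    rows = []
    for r in reports:
        rows.append(
            {
                "property_id": r.property_id,
                "n_property": r.n_property,
                "m11": r.m11,
                "m10": r.m10,
                "e11": r.e11,
                "e10": r.e10,
                "dyadicity": r.dyadicity if r.dyadicity is not None else float("nan"),
                "heterophilicity": (
                    r.heterophilicity if r.heterophilicity is not None else float("nan")
                ),
                "dyadic_class": r.dyadic_class,
                "hetero_class": r.hetero_class,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "property_id",
            "n_property",
            "m11",
            "m10",
            "e11",
            "e10",
            "dyadicity",
            "heterophilicity",
            "dyadic_class",
            "hetero_class",
        ],
    )
    agg_rows = []
    if ps_classes is not None and not table.empty:
        by_class: Dict[str, List[DyadReport]] = {}
        for r in reports:
            for cls in sorted(set(ps_classes.get(r.property_id, ()))):
                by_class.setdefault(cls, []).append(r)
        for cls in sorted(by_class):
            group = by_class[cls]
            ds = [r.dyadicity for r in group if r.dyadicity is not None]
            hs = [r.heterophilicity for r in group if r.heterophilicity is not None]
            agg_rows.append(
                {
                    "class": cls,
                    "n_series": len(group),
                    "mean_dyadicity": float(np.mean(ds)) if ds else float("nan"),
                    "mean_heterophilicity": float(np.mean(hs)) if hs else float("nan"),
                }
            )
    aggregate = pd.DataFrame(
        agg_rows,
        columns=["class", "n_series", "mean_dyadicity", "mean_heterophilicity"],
    )
    return reports, table, aggregate, skipped


def permutation_null(
    network: nx.Graph,
    n_property: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> Dict[str, float]:
    """Monte-Carlo check of the closed-form expectations.

    Places the property uniformly at random (fixed size) and returns the
    mean and standard error of D and H over the permutations.
    """
    nodes = sorted(network.nodes)
    e11, e10 = expected_dyads(len(nodes), network.number_of_edges(), n_property)
    ds, hs = [], []
    for _ in range(n_permutations):
        chosen = set(
            nodes[i] for i in rng.choice(len(nodes), size=n_property, replace=False)
        )
        m11, m10 = dyad_counts(network, chosen)
        if e11 > 0:
            ds.append(m11 / e11)
        if e10 > 0:
            hs.append(m10 / e10)
    return {
        "mean_D": float(np.mean(ds)) if ds else float("nan"),
        "se_D": float(np.std(ds, ddof=1) / math.sqrt(len(ds))) if len(ds) > 1 else float("nan"),
        "mean_H": float(np.mean(hs)) if hs else float("nan"),
        "se_H": float(np.std(hs, ddof=1) / math.sqrt(len(hs))) if len(hs) > 1 else float("nan"),
    }
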