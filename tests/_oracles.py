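"""Independent brute-force evaluators used to pin the fast implementations.

Everything here works from a plain ``parents`` dict (term -> set of direct
parents) and never touches the package's cached-closure or rule machinery,
so agreement between the two paths is meaningful.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import numpy as np

from ddsn.corpus import Disease, PhenotypicSeries, build_corpus
from ddsn.ontology import ICTable, OntologyDAG, Term, compute_ic


# ---------------------------------------------------------------------------
# naive graph walks


def naive_ancestors(parents: Mapping[str, Set[str]], t: str, include_self: bool) -> Set[str]:
    """Repeated parent expansion until a fixed point."""
    out = {t}
    changed = True
    while changed:
        changed = False
        for x in list(out):
            for p in parents[x]:
                if p not in out:
                    out.add(p)
                    changed = True
    if not include_self:
        out.discard(t)
    return out


def naive_ic(parents: Mapping[str, Set[str]], annotations: Mapping[str, Set[str]]) -> Dict[str, float]:
    n = len(annotations)
    counts: Dict[str, int] = {}
    for terms in annotations.values():
        reached: Set[str] = set()
        for t in terms:
            reached |= naive_ancestors(parents, t, include_self=True)
        for t in reached:
            counts[t] = counts.get(t, 0) + 1
    return {t: math.log(n / c) / math.log(n) for t, c in counts.items()}


def naive_mica(
    parents: Mapping[str, Set[str]], ic: Mapping[str, float], t1: str, t2: str
) -> Tuple[str, float]:
    """Full common-ancestor enumeration, max IC, smallest-id tie-break.

    Identical terms resolve to the term itself (the IC maximum is attained
    there anyway by monotonicity, but the reported term is pinned).
    """
    if t1 == t2:
        return t1, ic[t1]
    common = naive_ancestors(parents, t1, True) & naive_ancestors(parents, t2, True)
    best = None
    for t in sorted(common):
        if best is None or ic[t] > ic[best]:
            best = t
    return best, ic[best]


def naive_score(
    parents: Mapping[str, Set[str]],
    ic: Mapping[str, float],
    terms_i: Iterable[str],
    terms_j: Iterable[str],
) -> float:
    ti = sorted(set(terms_i))
    tj = sorted(set(terms_j))
    total = 0.0
    for a in ti:
        for b in tj:
            total += naive_mica(parents, ic, a, b)[1]
    return total / (len(ti) * len(tj))


def naive_shared(
    parents: Mapping[str, Set[str]],
    terms_i: Iterable[str],
    terms_j: Iterable[str],
) -> Dict[str, int]:
    """Direct application of the three sharing rules; min rule per term."""
    shared: Dict[str, int] = {}

    def hit(term: str, rule: int) -> None:
        if term not in shared or rule < shared[term]:
            shared[term] = rule

    for a in set(terms_i):
        for b in set(terms_j):
            if a == b:
                hit(a, 1)
            else:
                for p in parents[a] & parents[b]:
                    hit(p, 2)
                if a in parents[b]:
                    hit(a, 3)
                if b in parents[a]:
                    hit(b, 3)
    return shared


def naive_network(
    parents: Mapping[str, Set[str]],
    ic: Mapping[str, float],
    annotations: Mapping[str, Set[str]],
) -> Dict[Tuple[str, str], Tuple[int, float, Tuple[str, ...]]]:
    """All-pairs rule evaluation -> pair -> (n_shared, w, shared terms)."""
    out = {}
    ids = sorted(annotations)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            shared = naive_shared(parents, annotations[ids[i]], annotations[ids[j]])
            if shared:
                terms = tuple(sorted(shared))
                w = sum(ic[t] for t in terms) / len(terms)
                out[(ids[i], ids[j])] = (len(terms), w, terms)
    return out


def naive_dyads(edges: Iterable[Tuple[str, str]], prop: Set[str]) -> Tuple[int, int]:
    m11 = m10 = 0
    for u, v in edges:
        k = (u in prop) + (v in prop)
        if k == 2:
            m11 += 1
        elif k == 1:
            m10 += 1
    return m11, m10


# ---------------------------------------------------------------------------
# random fixtures


def random_parents(rng: np.random.Generator, n_terms: int) -> Dict[str, Set[str]]:
    """Random rooted DAG as a parents dict; term i points at earlier terms."""
    ids = [f"t{i:03d}" for i in range(n_terms)]
    parents: Dict[str, Set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i + 1)))
        picks = rng.choice(i, size=k, replace=False)
        parents[ids[i]] = {ids[int(p)] for p in picks}
    return parents


def dag_from_parents(parents: Mapping[str, Set[str]]) -> OntologyDAG:
    root = min(t for t, ps in parents.items() if not ps)
    terms = {
        t: Term(id=t, name=t, parents=frozenset(ps)) for t, ps in parents.items()
    }
    return OntologyDAG(terms, root)


def random_annotations(
    rng: np.random.Generator,
    parents: Mapping[str, Set[str]],
    n_diseases: int,
    max_terms: int = 5,
) -> Dict[str, Set[str]]:
    ids = sorted(parents)
    out = {}
    for d in range(n_diseases):
        k = int(rng.integers(1, max_terms + 1))
        picks = rng.choice(len(ids), size=k, replace=False)
        out[f"d{d:03d}"] = {ids[int(p)] for p in picks}
    return out


def corpus_from(
    dag: OntologyDAG,
    annotations: Mapping[str, Set[str]],
    ic: ICTable,
    ps_size: int = 4,
):
    """Wrap raw annotations into a corpus, chunking diseases into series."""
    ids = sorted(annotations)
    diseases = {d: Disease(id=d) for d in ids}
    series = {}
    for i in range(0, len(ids), ps_size):
        ps_id = f"PS{i // ps_size:02d}"
        series[ps_id] = PhenotypicSeries(
            id=ps_id, label=ps_id, members=set(ids[i : i + ps_size])
        )
    return build_corpus(diseases, series, annotations, ic)
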