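"""Synthetic ontologies and disease cohorts with planted structure.

The generator stands in for the production database snapshots: it emits a
rooted term DAG, diseases grouped into phenotypic series (PS), per-disease
term annotations, and per-disease classification labels, in exactly the
flat-file formats the corpus parsers read.

Planted structure
-----------------
Every PS owns a *profile*: a set of terms clustered under a random anchor
term (sampled from the anchor's descendant closure), so that sibling and
parent/child sharing - not just identical-term sharing - is exercised.
Each disease draws ``annotations_per_disease`` annotation slots; each slot
comes from its PS profile with probability ``cohesion`` and is otherwise a
uniform background term. An extra ``Binomial(annotations_per_disease,
background_rate)`` uniform noise terms are appended. When ``overlap`` is
positive, the first ``overlap_group_size`` PS form a mutually overlapping
group sharing a common pool of ``round(overlap * profile_size)`` profile
terms (every pair within the group is a planted overlap pair); all other
PS get anchors chosen disjoint from one another whenever the ontology
allows, so they stay clinically isolated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus import Disease, PhenotypicSeries
from .errors import ConfigurationError
from .ontology import OntologyDAG, Term

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_ontology",
    "generate_cohort",
    "fig1_dataset",
    "write_obo",
    "write_annotations",
    "write_ps_table",
    "write_class_table",
    "write_morbidmap",
]

_CLASS_PALETTE = (
    "nervous system disease",
    "metabolic disease",
    "cardiovascular system disease",
    "musculoskeletal system disease",
    "endocrine system disease",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs of the synthetic cohort.

    ``cohesion`` is the per-slot probability that an annotation is drawn
    from the disease's PS profile rather than uniformly from the ontology;
    ``background_rate`` adds extra uniform noise terms on top;
    ``overlap`` is the fraction of the profile shared within the
    overlapping PS group. ``name="fig1"`` is reserved for the hard-coded
    5-term, 3-disease worked example.
    """

    n_terms: int = 200
    max_parents: int = 2
    depth_target: int = 6
    n_ps: int = 10
    diseases_per_ps: int = 8
    profile_size: int = 6
    cohesion: float = 0.8
    overlap: float = 0.0
    overlap_group_size: int = 4
    background_rate: float = 0.05
    annotations_per_disease: int = 6
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        for attr in ("cohesion", "overlap", "background_rate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{attr} must be in [0,1], got {v}")
        for attr in (
            "n_terms",
            "depth_target",
            "n_ps",
            "diseases_per_ps",
            "profile_size",
            "annotations_per_disease",
        ):
            if getattr(self, attr) < 1:
                raise ConfigurationError(f"{attr} must be positive")
        if self.max_parents < 1:
            raise ConfigurationError("max_parents must be at least 1")
        if self.overlap > 0 and self.overlap_group_size > self.n_ps:
            raise ConfigurationError("overlap_group_size cannot exceed n_ps")


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery checks."""

    profiles: Dict[str, FrozenSet[str]]
    shared_pool: FrozenSet[str]
    overlap_pairs: List[Tuple[str, str]]
    overlap_group: List[str]
    seed: int
    config: GeneratorConfig
    notes: List[str] = field(default_factory=list)


def _term_id(i: int) -> str:
    return f"SP:{i:07d}"


def generate_ontology(config: GeneratorConfig) -> OntologyDAG:
    """Rooted random DAG with mean term depth near ``depth_target``.

    Terms are created in id order and may only point at earlier terms, so
    the result is acyclic by construction and deterministic under the
    seed. Each non-root term aims for a normally distributed depth around
    the target and picks its primary parent at that depth (or the nearest
    shallower one); extra parents, up to ``max_parents``, attach at the
    primary parent's depth rank so the term's depth stays well defined.
    """
    if config.n_terms < 2:
        raise ConfigurationError("n_terms must be at least 2")
    rng = np.random.default_rng(config.seed)
    root = _term_id(0)
    depth_of: Dict[str, int] = {root: 0}
    by_depth: Dict[int, List[str]] = {0: [root]}
    terms: Dict[str, Term] = {root: Term(id=root, name="synthetic root")}
    max_depth = config.depth_target + 2
    for i in range(1, config.n_terms):
        tid = _term_id(i)
        want = int(np.clip(round(rng.normal(config.depth_target, 1.2)), 1, max_depth))
        have = max(d for d in by_depth if d < want)
        candidates = by_depth[have]
        primary = candidates[int(rng.integers(len(candidates)))]
        parents = {primary}
        n_extra = int(rng.binomial(config.max_parents - 1, 0.3))
        if n_extra:
            # extra parents share the primary's depth rank so that the
            # shortest-path depth of the new term stays have + 1
            shallow = [t for t in by_depth[have] if t != primary]
            if shallow:
                picks = rng.choice(
                    len(shallow), size=min(n_extra, len(shallow)), replace=False
                )
                parents.update(shallow[j] for j in picks)
        depth = have + 1
        depth_of[tid] = depth
        by_depth.setdefault(depth, []).append(tid)
        terms[tid] = Term(id=tid, name=f"synthetic term {i}", parents=frozenset(parents))
    return OntologyDAG(terms, root)


def _sample(rng: np.random.Generator, population: Sequence[str], k: int) -> List[str]:
    idx = rng.choice(len(population), size=k, replace=False)
    return [population[i] for i in sorted(idx)]


def _pick_anchor(
    rng: np.random.Generator,
    dag: OntologyDAG,
    needed: int,
    used: Set[str],
    notes: List[str],
) -> Tuple[str, List[str]]:
    """An anchor whose descendant closure holds ``needed`` terms, preferring
    closures disjoint from previously used terms."""
    candidates = sorted(t for t in dag.terms if t != dag.root)
    order = rng.permutation(len(candidates))
    fallback: Optional[Tuple[str, List[str]]] = None
    for j in order:
        anchor = candidates[j]
        closure = sorted(dag.descendants(anchor, include_self=True))
        if len(closure) < needed:
            continue
        if not used.intersection(closure):
            return anchor, closure
        if fallback is None:
            fallback = (anchor, closure)
    if fallback is not None:
        notes.append(f"anchor {fallback[0]} overlaps a previously used subtree")
        return fallback
    raise ConfigurationError(
        f"no term has a descendant closure of size >= {needed}; "
        "increase n_terms or lower profile_size"
    )


def generate_cohort(
    dag: OntologyDAG, config: GeneratorConfig
) -> Tuple[
    Dict[str, Set[str]],
    Dict[str, PhenotypicSeries],
    Dict[str, Set[str]],
    SyntheticTruth,
]:
    """Annotations, series, class labels and ground truth for one cohort.

    With ``config.name == "fig1"`` the hard-coded worked example is
    returned instead (the ``dag`` argument is ignored).
    """
    if config.name == "fig1":
        _, annotations, series, classes = fig1_dataset()
        truth = SyntheticTruth(
            profiles={},
            shared_pool=frozenset(),
            overlap_pairs=[],
            overlap_group=[],
            seed=config.seed,
            config=config,
        )
        return annotations, series, classes, truth

    rng = np.random.default_rng(config.seed + 1)
    notes: List[str] = []
    ps_ids = [f"PS{p:03d}" for p in range(config.n_ps)]
    group = ps_ids[: config.overlap_group_size] if config.overlap > 0 else []
    n_shared = round(config.overlap * config.profile_size) if group else 0
    n_own = config.profile_size - n_shared

    used_terms: Set[str] = set()
    shared_pool: List[str] = []
    if group:
        anchor, closure = _pick_anchor(rng, dag, config.profile_size, used_terms, notes)
        shared_pool = _sample(rng, closure, n_shared)
        used_terms.update(shared_pool)

    profiles: Dict[str, FrozenSet[str]] = {}
    for ps_id in ps_ids:
        if ps_id in group:
            anchor, closure = _pick_anchor(
                rng, dag, max(n_own, 1), set(shared_pool), notes
            )
            pool = [t for t in closure if t not in shared_pool]
            own = _sample(rng, pool, min(n_own, len(pool)))
            if len(own) < n_own:
                notes.append(f"{ps_id}: anchor subtree smaller than requested profile")
            profiles[ps_id] = frozenset(shared_pool) | frozenset(own)
        else:
            anchor, closure = _pick_anchor(
                rng, dag, config.profile_size, used_terms, notes
            )
            profile = _sample(rng, closure, config.profile_size)
            used_terms.update(profile)
            profiles[ps_id] = frozenset(profile)

    background = sorted(t for t in dag.terms if t != dag.root)
    annotations: Dict[str, Set[str]] = {}
    series: Dict[str, PhenotypicSeries] = {}
    classes: Dict[str, Set[str]] = {}
    disease_no = 0
    for p, ps_id in enumerate(ps_ids):
        label_kind = "syndrome" if p % 2 else "disorder"
        ps = PhenotypicSeries(id=ps_id, label=f"{ps_id} synthetic {label_kind} series")
        cls = _CLASS_PALETTE[p % len(_CLASS_PALETTE)]
        profile = sorted(profiles[ps_id])
        for _ in range(config.diseases_per_ps):
            disease_no += 1
            did = str(100000 + disease_no)
            terms: Set[str] = set()
            n_profile_draws = int(rng.binomial(config.annotations_per_disease, config.cohesion))
            take = min(n_profile_draws, len(profile))
            terms.update(_sample(rng, profile, take))
            n_background = config.annotations_per_disease - n_profile_draws
            n_background += int(
                rng.binomial(config.annotations_per_disease, config.background_rate)
            )
            for _ in range(n_background):
                terms.add(background[int(rng.integers(len(background)))])
            annotations[did] = terms
            ps.members.add(did)
            classes[did] = {cls}
        series[ps_id] = ps

    truth = SyntheticTruth(
        profiles=profiles,
        shared_pool=frozenset(shared_pool),
        overlap_pairs=[tuple(sorted(pair)) for pair in itertools.combinations(group, 2)],
        overlap_group=list(group),
        seed=config.seed,
        config=config,
        notes=notes,
    )
    return annotations, series, classes, truth


# ---------------------------------------------------------------------------
# The worked example: 5 terms, 3 diseases, 2 series


def fig1_dataset() -> Tuple[
    OntologyDAG,
    Dict[str, Set[str]],
    Dict[str, PhenotypicSeries],
    Dict[str, Set[str]],
]:
    """The hard-coded worked example.

    Terms 0..4 with 1 is_a 0, 4 is_a 0, 2 is_a 4, 3 is_a 4; disease A
    annotated {1, 2}, B {1}, C {3}; series PS1 = {A, B}, PS2 = {C}.
    """
    terms = {
        "0": Term(id="0", name="root"),
        "1": Term(id="1", name="term one", parents=frozenset({"0"})),
        "4": Term(id="4", name="term four", parents=frozenset({"0"})),
        "2": Term(id="2", name="term two", parents=frozenset({"4"})),
        "3": Term(id="3", name="term three", parents=frozenset({"4"})),
    }
    dag = OntologyDAG(terms, "0")
    annotations = {"A": {"1", "2"}, "B": {"1"}, "C": {"3"}}
    series = {
        "PS1": PhenotypicSeries(id="PS1", label="PS1 example series", members={"A", "B"}),
        "PS2": PhenotypicSeries(id="PS2", label="PS2 example series", members={"C"}),
    }
    classes = {
        "A": {"nervous system disease"},
        "B": {"nervous system disease"},
        "C": {"metabolic disease"},
    }
    return dag, annotations, series, classes


# ---------------------------------------------------------------------------
# Flat-file writers (same dialects the corpus module parses)


def write_obo(dag: OntologyDAG, seed: Optional[int] = None) -> str:
    lines = ["format-version: 1.2", "ontology: ddsn-synthetic"]
    if seed is not None:
        lines.append(f"remark: generator seed {seed}")
    for tid in sorted(dag.terms):
        t = dag.terms[tid]
        lines += ["", "[Term]", f"id: {t.id}", f"name: {t.name or t.id}"]
        for p in sorted(t.parents):
            lines.append(f"is_a: {p} ! {dag.terms[p].name or p}")
    return "\n".join(lines) + "\n"


def write_annotations(
    annotations: Dict[str, Set[str]],
    labels: Optional[Dict[str, str]] = None,
    database: str = "OMIM",
) -> str:
    rows = []
    for did in sorted(annotations):
        name = (labels or {}).get(did, f"disease {did}")
        for term in sorted(annotations[did]):
            rows.append(f"{database}\t{did}\t{name}\t\t{term}\tTAS")
    return "\n".join(rows) + "\n"


def write_ps_table(series: Dict[str, PhenotypicSeries]) -> str:
    rows = []
    for ps_id in sorted(series):
        ps = series[ps_id]
        for m in sorted(ps.members):
            rows.append(f"{ps_id}\t{m}\t{ps.label}")
    return "\n".join(rows) + "\n"


def write_class_table(classes: Dict[str, Set[str]]) -> str:
    rows = []
    for did in sorted(classes):
        for cls in sorted(classes[did]):
            rows.append(f"{did}\t{cls}")
    return "\n".join(rows) + "\n"


def write_morbidmap(
    disease_ids: Sequence[str], labels: Optional[Dict[str, str]] = None
) -> str:
    rows = []
    for i, did in enumerate(sorted(disease_ids)):
        name = (labels or {}).get(did, f"Synthetic disease {did}")
        rows.append(f"{name}, {did} (3)\tGENE{i:04d}\t{600000 + i}\t1p36.{i % 9 + 1}")
    return "\n".join(rows) + "\n"
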