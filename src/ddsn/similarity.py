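"""Pairwise clinical similarity and the intra-series / random-baseline /
best-partner analyses.

The similarity of two diseases is the arithmetic mean, over all M x N
ordered pairs of their annotation terms, of the IC of each pair's most
informative common ancestor (the term itself when the two annotations are
identical). The score lives in [0, 1]; two diseases whose annotations only
meet at the root score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus import DiseaseCorpus
from .errors import ConfigurationError
from .ontology import ICTable, OntologyDAG

__all__ = [
    "SimilarityScorer",
    "PartnerRecord",
    "IntraPSProfile",
    "intra_ps_profile",
    "random_baseline",
    "max_partner",
    "partner_summary",
    "partner_crosstab",
]


class SimilarityScorer:
    """All-pairs MICA-IC similarity with per-term-pair caching."""

    def __init__(
        self,
        dag: OntologyDAG,
        ic: ICTable,
        annotations: Mapping[str, Iterable[str]],
    ):
        self.dag = dag
        self.ic = ic
        self.annotations: Dict[str, Tuple[str, ...]] = {
            d: tuple(sorted(set(ts))) for d, ts in annotations.items()
        }
        self._pair_ic: Dict[Tuple[str, str], float] = {}

    def diseases(self) -> List[str]:
        return sorted(self.annotations)

    def term_mica_ic(self, t1: str, t2: str) -> float:
        """IC of the most informative common ancestor of two terms."""
        if t1 == t2:
            return self.ic[t1]
        key = (t1, t2) if t1 < t2 else (t2, t1)
        cached = self._pair_ic.get(key)
        if cached is None:
            common = self.dag._closure(t1) & self.dag._closure(t2)
            cached = max(self.ic[t] for t in common)
            self._pair_ic[key] = cached
        return cached

    def score(self, d_i: str, d_j: str) -> float:
        """Mean MICA IC over all annotation pairs of the two diseases."""
        terms_i = self.annotations.get(d_i)
        terms_j = self.annotations.get(d_j)
        if not terms_i:
            raise ConfigurationError(f"disease {d_i!r} has no annotations")
        if not terms_j:
            raise ConfigurationError(f"disease {d_j!r} has no annotations")
        if terms_j < terms_i:
            # canonical summation order makes the score exactly symmetric
            terms_i, terms_j = terms_j, terms_i
        total = 0.0
        for ti in terms_i:
            for tj in terms_j:
                total += self.term_mica_ic(ti, tj)
        return total / (len(terms_i) * len(terms_j))


@dataclass
class IntraPSProfile:
    ps_id: str
    per_disease: Dict[str, float]
    mean: float
    sd: float


def intra_ps_profile(
    scorer: SimilarityScorer, corpus: DiseaseCorpus, ps_id: str
) -> IntraPSProfile:
    """Per-member mean similarity against the other members of one series."""
    members = sorted(
        m for m in corpus.series[ps_id].members if scorer.annotations.get(m)
    )
    if len(members) < 2:
        raise ConfigurationError(
            f"series {ps_id!r} has fewer than 2 annotated members"
        )
    per: Dict[str, float] = {}
    for m in members:
        others = [scorer.score(m, o) for o in members if o != m]
        per[m] = float(np.mean(others))
    values = np.array([per[m] for m in members])
    sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
    return IntraPSProfile(ps_id=ps_id, per_disease=per, mean=float(values.mean()), sd=sd)


def random_baseline(
    scorer: SimilarityScorer,
    pool: Sequence[str],
    d_i: str,
    k: int,
    rng: np.random.Generator,
) -> float:
    """Mean similarity of ``d_i`` against ``k`` random other diseases.

    Sampling is uniform without replacement from ``pool`` minus ``d_i``;
    when the pool (minus ``d_i``) has exactly ``k`` members the whole pool
    is used and the draw is seed-independent.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    candidates = sorted(set(pool) - {d_i})
    if len(candidates) < k:
        raise ConfigurationError(
            f"pool has {len(candidates)} candidates, cannot draw {k}"
        )
    if len(candidates) == k:
        chosen = candidates
    else:
        chosen = [candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)]
    return float(np.mean([scorer.score(d_i, c) for c in chosen]))


@dataclass
class PartnerRecord:
    disease: str
    partner: str
    score: float
    same_ps: bool
    same_do_class: Optional[bool]
    tie: bool


def _eligible_for_partner(corpus: DiseaseCorpus, scorer: SimilarityScorer) -> List[str]:
    """Single-series diseases whose series has >=2 annotated members."""
    annotated = {d for d in corpus.eligible_diseases if scorer.annotations.get(d)}
    sizes = {
        ps_id: len(ps.members & annotated) for ps_id, ps in corpus.series.items()
    }
    out = []
    for d in sorted(annotated):
        ps_ids = corpus.diseases[d].ps_ids
        if len(ps_ids) != 1:
            continue
        if sizes[next(iter(ps_ids))] < 2:
            continue
        out.append(d)
    return out


def max_partner(
    corpus: DiseaseCorpus, scorer: SimilarityScorer
) -> List[PartnerRecord]:
    """Best-scoring partner per eligible disease.

    Diseases belonging to more than one series, and members of singleton
    series, are excluded. The argmax runs over all other eligible diseases
    (intra- and inter-series alike); ties are flagged and broken by the
    smallest partner identifier.
    """
    eligible = _eligible_for_partner(corpus, scorer)
    if not eligible:
        raise ConfigurationError("no eligible diseases for the partner analysis")
    records: List[PartnerRecord] = []
    for d in eligible:
        best: Optional[str] = None
        best_score = -1.0
        tie = False
        for other in eligible:
            if other == d:
                continue
            s = scorer.score(d, other)
            if s > best_score:
                best, best_score, tie = other, s, False
            elif s == best_score:
                tie = True
                if best is None or other < best:
                    best = other
        assert best is not None
        same_ps = bool(
            corpus.diseases[d].ps_ids & corpus.diseases[best].ps_ids
        )
        ci = corpus.diseases[d].do_classes
        cj = corpus.diseases[best].do_classes
        same_do = (
            (next(iter(ci)) == next(iter(cj)))
            if len(ci) == 1 and len(cj) == 1
            else None
        )
        records.append(
            PartnerRecord(
                disease=d,
                partner=best,
                score=best_score,
                same_ps=same_ps,
                same_do_class=same_do,
                tie=tie,
            )
        )
    return records


def partner_summary(records: Sequence[PartnerRecord]) -> Dict[str, float]:
    n = len(records)
    same = sum(1 for r in records if r.same_ps)
    return {
        "n_diseases": n,
        "n_same_ps": same,
        "n_diff_ps": n - same,
        "frac_same_ps": same / n if n else float("nan"),
        "frac_diff_ps": (n - same) / n if n else float("nan"),
    }


def partner_crosstab(
    records: Sequence[PartnerRecord], corpus: DiseaseCorpus
) -> Dict[str, object]:
    """Same- vs different-class split of the inter-series partner pairs.

    Records whose disease or partner lacks exactly one classification label
    are dropped first; the retained same-series records are reported for
    context, and the inter-series records are partitioned by whether the
    two diseases share their class, with class frequencies and heterologous
    class combinations tabulated.
    """
    def single_class(d: str) -> Optional[str]:
        cs = corpus.diseases[d].do_classes
        return next(iter(cs)) if len(cs) == 1 else None

    kept = []
    dropped = 0
    for r in records:
        ci, cj = single_class(r.disease), single_class(r.partner)
        if ci is None or cj is None:
            dropped += 1
            continue
        kept.append((r, ci, cj))
    inter = [(r, ci, cj) for r, ci, cj in kept if not r.same_ps]
    same_class = [(ci, cj) for r, ci, cj in inter if ci == cj]
    diff_class = [(ci, cj) for r, ci, cj in inter if ci != cj]
    class_freq: Dict[str, int] = {}
    for ci, _ in same_class:
        class_freq[ci] = class_freq.get(ci, 0) + 1
    combo_freq: Dict[Tuple[str, str], int] = {}
    for ci, cj in diff_class:
        key = tuple(sorted((ci, cj)))
        combo_freq[key] = combo_freq.get(key, 0) + 1
    return {
        "n_records": len(records),
        "n_dropped_do": dropped,
        "n_kept": len(kept),
        "n_same_ps": sum(1 for r, _, _ in kept if r.same_ps),
        "n_inter_ps": len(inter),
        "n_same_class": len(same_class),
        "n_diff_class": len(diff_class),
        "same_class_freq": dict(sorted(class_freq.items())),
        "diff_class_combos": {
            " / ".join(k): v for k, v in sorted(combo_freq.items())
        },
    }
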