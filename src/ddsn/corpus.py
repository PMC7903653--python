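"""Disease corpus assembly: catalogue filters, phenotype annotations,
phenotypic-series membership, disease-classification labels, and the
disease-series-term-IC 4-tuple table that the downstream analyses consume.

The catalogue reader speaks the OMIM morbid-map dialect: a phenotype is
retained only when it has a known molecular basis (mapping key "(3)") and
is not a non-disease (label in square brackets), a susceptibility entry
(label in braces) or an unconfirmed entry (label prefixed with "?").
Annotations follow the tab-delimited HPO ``phenotype_annotation`` dialect
(database, disease id, disease name, qualifier, term id, ...), with "NOT"
qualified rows and terms outside the retained ontology subtree dropped.
"""

from __future__ import annotations

import io
import json
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple

import networkx as nx
import obonet

from .errors import ConfigurationError, FormatError
from .ontology import ICTable, OntologyDAG

__all__ = [
    "Disease",
    "PhenotypicSeries",
    "FourTuple",
    "DiseaseCorpus",
    "ExclusionRecord",
    "MorbidmapResult",
    "parse_morbidmap",
    "parse_annotations",
    "parse_ps",
    "parse_class_table",
    "assign_do_classes",
    "build_corpus",
]


@dataclass
class Disease:
    id: str
    label: str = ""
    ps_ids: Set[str] = field(default_factory=set)
    do_classes: Set[str] = field(default_factory=set)
    terms: Set[str] = field(default_factory=set)


@dataclass
class PhenotypicSeries:
    id: str
    label: str = ""
    members: Set[str] = field(default_factory=set)


class FourTuple(NamedTuple):
    disease_id: str
    ps_id: str
    term_id: str
    ic: float


@dataclass
class ExclusionRecord:
    row: int
    entry: str
    reason: str


@dataclass
class MorbidmapResult:
    diseases: Dict[str, Disease]
    exclusions: List[ExclusionRecord]
    n_rows: int
    n_retained_rows: int

    def audit(self) -> Dict[str, int]:
        return {
            "parsed": self.n_rows,
            "retained": self.n_retained_rows,
            "excluded": len(self.exclusions),
        }


_MAPPING_KEY_RE = re.compile(r"\((\d)\)\s*$")
_MIM_RE = re.compile(r",\s*(\d{6})\s*(?:\(\d\)\s*)?$")


def parse_morbidmap(table_text: str, multi_gene: str = "keep") -> MorbidmapResult:
    """Filter a morbid-map table down to confirmed molecular diseases.

    ``multi_gene`` controls rows whose gene-symbol field lists several
    genes: ``"keep"`` retains them (default), ``"exclude"`` drops them with
    reason ``multi-gene``.
    """
    if multi_gene not in ("keep", "exclude"):
        raise ConfigurationError(f"multi_gene must be keep|exclude, got {multi_gene!r}")
    diseases: Dict[str, Disease] = {}
    exclusions: List[ExclusionRecord] = []
    n_rows = 0
    n_retained = 0
    for lineno, line in enumerate(table_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise FormatError(
                f"morbidmap row {lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        n_rows += 1
        phenotype = fields[0].strip()
        genes = [g.strip() for g in fields[1].split(",") if g.strip()]

        if phenotype.startswith("["):
            exclusions.append(ExclusionRecord(lineno, phenotype, "non-disease"))
            continue
        if phenotype.startswith("{"):
            exclusions.append(ExclusionRecord(lineno, phenotype, "susceptibility"))
            continue
        if phenotype.startswith("?"):
            exclusions.append(ExclusionRecord(lineno, phenotype, "unconfirmed"))
            continue
        key_match = _MAPPING_KEY_RE.search(phenotype)
        if key_match is None or key_match.group(1) != "3":
            exclusions.append(ExclusionRecord(lineno, phenotype, "mapping-key"))
            continue
        mim_match = _MIM_RE.search(phenotype)
        if mim_match is None:
            exclusions.append(ExclusionRecord(lineno, phenotype, "no-mim"))
            continue
        if multi_gene == "exclude" and len(genes) > 1:
            exclusions.append(ExclusionRecord(lineno, phenotype, "multi-gene"))
            continue

        mim = mim_match.group(1)
        label = phenotype[: mim_match.start()].strip().rstrip(",")
        n_retained += 1
        if mim not in diseases:
            diseases[mim] = Disease(id=mim, label=label)
    return MorbidmapResult(diseases, exclusions, n_rows, n_retained)


def parse_annotations(
    table_text: str,
    dag: OntologyDAG,
    database: str = "OMIM",
) -> Tuple[Dict[str, Set[str]], List[ExclusionRecord], int]:
    """Disease -> annotated-term sets from a tab-delimited annotation table.

    Keeps rows from ``database`` whose qualifier is not "NOT" and whose term
    lies in the retained subtree; everything else is logged and dropped.
    Returns (annotations, drop log, parsed row count).
    """
    annotations: Dict[str, Set[str]] = {}
    dropped: List[ExclusionRecord] = []
    n_rows = 0
    for lineno, line in enumerate(table_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise FormatError(
                f"annotation row {lineno}: expected >=5 tab-separated fields, got {len(fields)}"
            )
        n_rows += 1
        db, disease_id, _name, qualifier, term = (f.strip() for f in fields[:5])
        if db != database:
            dropped.append(ExclusionRecord(lineno, f"{db}:{disease_id}", "database"))
            continue
        if qualifier.upper() == "NOT":
            dropped.append(ExclusionRecord(lineno, f"{disease_id}/{term}", "negated"))
            continue
        if term not in dag:
            dropped.append(ExclusionRecord(lineno, f"{disease_id}/{term}", "subtree"))
            continue
        annotations.setdefault(disease_id, set()).add(term)
    return annotations, dropped, n_rows


def parse_ps(
    table_text: str,
) -> Tuple[Dict[str, PhenotypicSeries], List[str]]:
    """Phenotypic series from a two-column (ps_id, disease_id[, label]) TSV.

    Duplicated rows collapse; a disease may belong to several series.
    Returns (series, warnings); referential checks against the corpus
    happen at assembly time.
    """
    series: Dict[str, PhenotypicSeries] = {}
    warnings: List[str] = []
    for lineno, line in enumerate(table_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"PS table row {lineno}: need nonempty ps_id and disease_id")
        ps_id, disease_id = fields[0].strip(), fields[1].strip()
        label = fields[2].strip() if len(fields) > 2 and fields[2].strip() else ""
        ps = series.setdefault(ps_id, PhenotypicSeries(id=ps_id, label=label or ps_id))
        if label:
            ps.label = label
        ps.members.add(disease_id)
    return series, warnings


def parse_class_table(table_text: str) -> Dict[str, Set[str]]:
    """Disease -> class-label sets from a plain two-column TSV."""
    classes: Dict[str, Set[str]] = {}
    for lineno, line in enumerate(table_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"class table row {lineno}: need disease_id and class label")
        classes.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return classes


def assign_do_classes(
    diseases: Mapping[str, Disease],
    do_obo_text: str,
    top_classes: Sequence[str],
    xref_prefix: str = "OMIM:",
) -> Dict[str, Disease]:
    """Label diseases with top-level disease-ontology classes.

    Each disease receives every member of ``top_classes`` reachable as an
    ancestor (is_a, including self) of any DO term whose ``xref`` list
    points at the disease. Diseases without cross-references keep an empty
    class set. Labels are the class terms' names when present, else ids.
    """
    graph = obonet.read_obo(io.StringIO(do_obo_text))
    is_a = nx.DiGraph()
    is_a.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            is_a.add_edge(child, parent)
    top = set(top_classes)

    def label(class_id: str) -> str:
        return graph.nodes[class_id].get("name", class_id) if class_id in graph else class_id

    for node, data in graph.nodes(data=True):
        hits = [
            x[len(xref_prefix):]
            for x in data.get("xref", [])
            if x.startswith(xref_prefix)
        ]
        if not hits:
            continue
        reach = ({node} | nx.descendants(is_a, node)) & top
        if not reach:
            continue
        for mim in hits:
            d = diseases.get(mim)
            if d is not None:
                d.do_classes.update(label(c) for c in reach)
    return dict(diseases)


@dataclass
class DiseaseCorpus:
    """The assembled corpus: diseases, series and sorted 4-tuples."""

    diseases: Dict[str, Disease]
    series: Dict[str, PhenotypicSeries]
    four_tuples: List[FourTuple]
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def eligible_diseases(self) -> List[str]:
        """Diseases contributing 4-tuples (annotated and in >=1 series)."""
        return sorted({t.disease_id for t in self.four_tuples})

    def annotations(self) -> Dict[str, Set[str]]:
        return {
            d: set(self.diseases[d].terms) for d in self.eligible_diseases
        }

    def disease_ps(self) -> Dict[str, Set[str]]:
        return {d: set(self.diseases[d].ps_ids) for d in self.eligible_diseases}

    def summary(self) -> Dict[str, object]:
        eligible = self.eligible_diseases
        terms = sorted({t.term_id for t in self.four_tuples})
        ps_ids = sorted({t.ps_id for t in self.four_tuples})
        dp_counts = [len(self.diseases[d].terms) for d in eligible]
        syndromic = [
            p for p in ps_ids if "syndrome" in self.series[p].label.lower()
        ]
        non_syndromic = [p for p in ps_ids if p not in set(syndromic)]

        def _dp_per_d(ps_list: List[str]) -> List[int]:
            ds = sorted(
                {
                    t.disease_id
                    for t in self.four_tuples
                    if t.ps_id in set(ps_list)
                }
            )
            return [len(self.diseases[d].terms) for d in ds]

        return {
            "n_four_tuples": len(self.four_tuples),
            "n_diseases": len(eligible),
            "n_series": len(ps_ids),
            "n_terms": len(terms),
            "dp_per_disease_mean": _mean(dp_counts),
            "dp_per_disease_sd": _sd(dp_counts),
            "syndromic": {
                "n_series": len(syndromic),
                "dp_per_disease_mean": _mean(_dp_per_d(syndromic)),
                "dp_per_disease_sd": _sd(_dp_per_d(syndromic)),
            },
            "non_syndromic": {
                "n_series": len(non_syndromic),
                "dp_per_disease_mean": _mean(_dp_per_d(non_syndromic)),
                "dp_per_disease_sd": _sd(_dp_per_d(non_syndromic)),
            },
            "provenance": self.provenance,
        }

    def four_tuples_tsv(self) -> str:
        lines = ["disease_id\tps_id\tterm_id\tic"]
        for t in self.four_tuples:
            lines.append(f"{t.disease_id}\t{t.ps_id}\t{t.term_id}\t{t.ic:.6f}")
        return "\n".join(lines) + "\n"


def _mean(xs: Sequence[float]) -> float:
    return float(sum(xs) / len(xs)) if xs else float("nan")


def _sd(xs: Sequence[float]) -> float:
    if len(xs) < 2:
        return float("nan")
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def build_corpus(
    diseases: Mapping[str, Disease],
    series: Mapping[str, PhenotypicSeries],
    annotations: Mapping[str, Iterable[str]],
    ic: ICTable,
    provenance: Optional[Dict[str, object]] = None,
) -> DiseaseCorpus:
    """Assemble the 4-tuple table.

    A 4-tuple (disease, series, term, IC) is emitted for every series
    membership x annotation combination of each disease that has at least
    one annotation AND at least one series membership. Output ordering is
    deterministic (disease, series, term).
    """
    diseases = {d: v for d, v in diseases.items()}
    for d in diseases.values():
        d.ps_ids = set()
        d.terms = set(annotations.get(d.id, ()))
    kept_series: Dict[str, PhenotypicSeries] = {}
    for ps in series.values():
        members = {m for m in ps.members if m in diseases}
        if not members:
            continue
        kept_series[ps.id] = PhenotypicSeries(id=ps.id, label=ps.label, members=members)
        for m in members:
            diseases[m].ps_ids.add(ps.id)

    tuples: List[FourTuple] = []
    for d in sorted(diseases):
        dis = diseases[d]
        if not dis.terms or not dis.ps_ids:
            continue
        for ps_id in sorted(dis.ps_ids):
            for term in sorted(dis.terms):
                tuples.append(FourTuple(d, ps_id, term, ic[term]))
    if not tuples:
        raise ConfigurationError(
            "no disease has both annotations and a series membership"
        )
    prov = dict(provenance or {})
    prov.setdefault("n_diseases_in", len(diseases))
    prov.setdefault("n_series_in", len(series))
    return DiseaseCorpus(
        diseases=dict(diseases),
        series=kept_series,
        four_tuples=tuples,
        provenance=prov,
    )
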