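"""End-to-end orchestration: inputs -> corpus -> IC -> similarity ->
bipartite graph -> compact similarity network -> assortativity, with every
table written to disk in a deterministic order and a JSON run summary.

Synthetic runs first write the generated inputs in the same flat-file
dialects the parsers read (OBO ontology, annotation TSV, morbid map, PS
table, class table) and then feed those files through the real parsers, so
a synthetic run exercises the identical code path as a run on database
snapshots. The hard-coded "fig1" worked example is the one exception: its
disease ids are single letters, not catalogue numbers, so it is assembled
in memory.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import assortativity as assort
from . import corpus as corpus_mod
from . import network as network_mod
from . import similarity as sim_mod
from . import synthdata
from .errors import ConfigurationError
from .ontology import ICTable, OntologyDAG, compute_ic, parse_obo

logger = logging.getLogger("ddsn")

__all__ = ["RunConfig", "run_all", "validate_inputs"]

DEFAULT_GRID = tuple(round(0.05 * i, 2) for i in range(20))


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` (a generator configuration) or the five
    input paths must be active. ``baseline_k=None`` uses, for each disease,
    the size of its series minus one.
    """

    outdir: str
    synthetic: Optional[synthdata.GeneratorConfig] = None
    ontology_path: Optional[str] = None
    annotations_path: Optional[str] = None
    morbidmap_path: Optional[str] = None
    ps_path: Optional[str] = None
    classes_path: Optional[str] = None
    root_id: str = "HP:0000118"
    threshold_grid: Sequence[float] = DEFAULT_GRID
    baseline_seed: int = 0
    baseline_k: Optional[int] = None
    multi_gene: str = "keep"
    annotation_database: str = "OMIM"

    def __post_init__(self):
        paths = [self.ontology_path, self.annotations_path, self.ps_path]
        real = all(p is not None for p in paths)
        if (self.synthetic is None) == (not real):
            raise ConfigurationError(
                "exactly one of {synthetic config, real input paths} must be set"
            )
        for w in self.threshold_grid:
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(f"threshold {w} outside [0,1]")


def validate_inputs(config: RunConfig) -> List[str]:
    """Non-mutating sanity checks; returns a list of issue strings."""
    issues: List[str] = []
    if config.synthetic is not None:
        return issues
    for name in ("ontology_path", "annotations_path", "morbidmap_path", "ps_path", "classes_path"):
        p = getattr(config, name)
        if p is None:
            continue
        if not Path(p).is_file():
            issues.append(f"{name}: file not found: {p}")
    if issues:
        return issues
    try:
        obo_text = Path(config.ontology_path).read_text()
        if "[Term]" not in obo_text:
            issues.append("ontology_path: no [Term] stanza found")
            return issues
        dag = parse_obo(obo_text, config.root_id)
    except Exception as exc:
        issues.append(f"ontology_path: {exc}")
        return issues
    try:
        annotations, _, _ = corpus_mod.parse_annotations(
            Path(config.annotations_path).read_text(), dag, config.annotation_database
        )
    except Exception as exc:
        issues.append(f"annotations_path: {exc}")
        return issues
    # referential integrity warnings
    if config.morbidmap_path:
        try:
            mm = corpus_mod.parse_morbidmap(Path(config.morbidmap_path).read_text())
        except Exception as exc:
            issues.append(f"morbidmap_path: {exc}")
            return issues
        if config.ps_path:
            series, _ = corpus_mod.parse_ps(Path(config.ps_path).read_text())
            for ps in series.values():
                for m in sorted(ps.members - set(mm.diseases)):
                    issues.append(
                        f"warning: series {ps.id} references disease {m} absent from the catalogue"
                    )
    return issues


def _load_inputs(
    config: RunConfig, outdir: Path
) -> Tuple[OntologyDAG, corpus_mod.MorbidmapResult, Dict[str, Set[str]], Dict[str, corpus_mod.PhenotypicSeries], Dict[str, Set[str]], Dict[str, object]]:
    """Materialize (or read) the five inputs and push them through the parsers."""
    prov: Dict[str, object] = {}
    if config.synthetic is not None and config.synthetic.name == "fig1":
        dag, annotations, series, classes = synthdata.fig1_dataset()
        diseases = {
            d: corpus_mod.Disease(id=d, label=f"disease {d}") for d in annotations
        }
        mm = corpus_mod.MorbidmapResult(diseases, [], len(diseases), len(diseases))
        for did, cls in classes.items():
            diseases[did].do_classes = set(cls)
        prov["mode"] = "fig1"
        return dag, mm, annotations, series, classes, prov

    if config.synthetic is not None:
        gen = config.synthetic
        dag0 = synthdata.generate_ontology(gen)
        annotations0, series0, classes0, truth = synthdata.generate_cohort(dag0, gen)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        labels = {d: f"Synthetic disease {d}" for d in annotations0}
        (inputs / "ontology.obo").write_text(synthdata.write_obo(dag0, seed=gen.seed))
        (inputs / "annotations.tab").write_text(
            synthdata.write_annotations(annotations0, labels)
        )
        (inputs / "morbidmap.txt").write_text(
            synthdata.write_morbidmap(sorted(annotations0), labels)
        )
        (inputs / "ps.tsv").write_text(synthdata.write_ps_table(series0))
        (inputs / "classes.tsv").write_text(synthdata.write_class_table(classes0))
        config = RunConfig(
            outdir=str(outdir),
            ontology_path=str(inputs / "ontology.obo"),
            annotations_path=str(inputs / "annotations.tab"),
            morbidmap_path=str(inputs / "morbidmap.txt"),
            ps_path=str(inputs / "ps.tsv"),
            classes_path=str(inputs / "classes.tsv"),
            root_id=synthdata._term_id(0),
            threshold_grid=config.threshold_grid,
            baseline_seed=config.baseline_seed,
            baseline_k=config.baseline_k,
        )
        prov["mode"] = "synthetic"
        prov["generator_seed"] = gen.seed
    else:
        prov["mode"] = "files"

    for name in ("ontology_path", "annotations_path", "ps_path"):
        p = getattr(config, name)
        if p is None or not Path(p).is_file():
            raise ConfigurationError(f"{name} missing or not a file: {p}")

    dag = parse_obo(Path(config.ontology_path).read_text(), config.root_id)
    if config.morbidmap_path:
        mm = corpus_mod.parse_morbidmap(
            Path(config.morbidmap_path).read_text(), config.multi_gene
        )
    else:
        mm = None
    annotations, dropped, n_rows = corpus_mod.parse_annotations(
        Path(config.annotations_path).read_text(), dag, config.annotation_database
    )
    prov["annotation_rows"] = n_rows
    prov["annotation_dropped"] = len(dropped)
    if mm is None:
        diseases = {
            d: corpus_mod.Disease(id=d, label=f"disease {d}") for d in annotations
        }
        mm = corpus_mod.MorbidmapResult(diseases, [], len(diseases), len(diseases))
    series, _ = corpus_mod.parse_ps(Path(config.ps_path).read_text())
    classes: Dict[str, Set[str]] = {}
    if config.classes_path and Path(config.classes_path).is_file():
        classes = corpus_mod.parse_class_table(Path(config.classes_path).read_text())
    for did, cls in classes.items():
        if did in mm.diseases:
            mm.diseases[did].do_classes = set(cls)
    prov["morbidmap"] = mm.audit()
    return dag, mm, annotations, series, classes, prov


def _round(x: float, nd: int = 6) -> float:
    if isinstance(x, float) and math.isnan(x):
        return None  # type: ignore[return-value]
    return round(float(x), nd)


def _json_clean(obj):
    if isinstance(obj, dict):
        return {str(k): _json_clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return _round(float(obj))
    return obj


def run_all(config: RunConfig) -> Dict[str, object]:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Deterministic for a fixed configuration and seed: all tables are sorted
    and fixed-point formatted, and the summary JSON has sorted keys.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag, mm, annotations, series, classes, prov = _load_inputs(config, outdir)

    logger.info("corpus: %d diseases annotated, %d series", len(annotations), len(series))
    ic = compute_ic(dag, annotations)
    (outdir / "ic.tsv").write_text(ic.to_tsv())

    corpus = corpus_mod.build_corpus(mm.diseases, series, annotations, ic, prov)
    (outdir / "four_tuples.tsv").write_text(corpus.four_tuples_tsv())
    exclusion_lines = ["row\tentry\treason"] + [
        f"{e.row}\t{e.entry}\t{e.reason}" for e in mm.exclusions
    ]
    (outdir / "exclusions.tsv").write_text("\n".join(exclusion_lines) + "\n")
    corpus_summary = corpus.summary()
    (outdir / "corpus_summary.json").write_text(
        json.dumps(_json_clean(corpus_summary), indent=2, sort_keys=True) + "\n"
    )

    # -- similarity -------------------------------------------------------
    scorer = sim_mod.SimilarityScorer(dag, ic, corpus.annotations())
    pool = corpus.eligible_diseases
    rng = np.random.default_rng(config.baseline_seed)
    sim_rows = []
    intra_means: List[float] = []
    rand_means: List[float] = []
    for ps_id in sorted(corpus.series):
        members = sorted(
            m for m in corpus.series[ps_id].members if scorer.annotations.get(m)
        )
        if len(members) < 2:
            logger.info("series %s skipped (fewer than 2 annotated members)", ps_id)
            continue
        profile = sim_mod.intra_ps_profile(scorer, corpus, ps_id)
        k = config.baseline_k or (len(members) - 1)
        k = min(k, len(pool) - 1)
        for m in members:
            rand = sim_mod.random_baseline(scorer, pool, m, k, rng)
            sim_rows.append(
                {
                    "disease_id": m,
                    "ps_id": ps_id,
                    "intra_ps_mean": profile.per_disease[m],
                    "random_mean": rand,
                    "k": k,
                    "seed": config.baseline_seed,
                }
            )
            intra_means.append(profile.per_disease[m])
            rand_means.append(rand)
    sim_mean = pd.DataFrame(
        sim_rows,
        columns=["disease_id", "ps_id", "intra_ps_mean", "random_mean", "k", "seed"],
    )
    sim_mean.to_csv(outdir / "sim_mean.txt", sep="\t", index=False, float_format="%.6f")

    partner_records = sim_mod.max_partner(corpus, scorer)
    partner_rows = [
        {
            "disease_id": r.disease,
            "best_partner": r.partner,
            "best_score": r.score,
            "same_ps": int(r.same_ps),
            "same_do_class": "" if r.same_do_class is None else int(r.same_do_class),
            "tie": int(r.tie),
        }
        for r in partner_records
    ]
    pd.DataFrame(partner_rows).to_csv(
        outdir / "sim_max.txt", sep="\t", index=False, float_format="%.6f"
    )
    crosstab = sim_mod.partner_crosstab(partner_records, corpus)

    # -- network ----------------------------------------------------------
    tuples, bipartite, rule_fractions = network_mod.build_bipartite(corpus, dag)
    tuple_lines = [
        "disease_i\tps_i\tterm_i\tshared_term\trule\tdisease_j\tps_j\tterm_j"
    ] + [
        f"{t.disease_i}\t{t.ps_i}\t{t.term_i}\t{t.shared_term}\t{t.rule}\t{t.disease_j}\t{t.ps_j}\t{t.term_j}"
        for t in tuples
    ]
    (outdir / "seven_tuples.tsv").write_text("\n".join(tuple_lines) + "\n")
    dp_lines = ["disease_id\tterm_id"] + sorted(
        f"{u}\t{v}" if bipartite.nodes[u]["bipartite"] == 0 else f"{v}\t{u}"
        for u, v in bipartite.edges
    )
    (outdir / "d_dp.txt").write_text("\n".join(dp_lines) + "\n")

    net = network_mod.derive_network(tuples, ic)
    edge_lines = ["disease_i\tdisease_j\tw\tn_shared"] + [
        f"{u}\t{v}\t{d['w']:.6f}\t{d['n_shared']}"
        for u, v, d in sorted(net.edges(data=True))
    ]
    (outdir / "ddsn_c.txt").write_text("\n".join(edge_lines) + "\n")

    strata = network_mod.shared_dp_stats(net, corpus.disease_ps())
    strata.to_csv(outdir / "shared_dp_stats.tsv", sep="\t", float_format="%.6f")
    sweep = network_mod.threshold_sweep(net, config.threshold_grid)
    sweep.to_csv(outdir / "threshold_sweep.csv", index=False, float_format="%.6f")
    degrees = network_mod.degree_stats(bipartite)
    degrees["distribution"].to_csv(
        outdir / "degree_distribution.tsv", sep="\t", index=False, float_format="%.6f"
    )
    giant = network_mod.giant_component(net)

    # -- assortativity ----------------------------------------------------
    ps_classes = {
        ps_id: sorted(
            set().union(
                *(corpus.diseases[m].do_classes for m in corpus.series[ps_id].members)
            )
            if corpus.series[ps_id].members
            else set()
        )
        for ps_id in corpus.series
    }
    reports, dyad_table, class_agg, skipped = assort.dh_all(
        net, {p: s.members for p, s in corpus.series.items()}, ps_classes
    )
    dyad_table.to_csv(outdir / "dyad_report.tsv", sep="\t", index=False, float_format="%.6f")
    class_agg.to_csv(outdir / "dh_by_class.csv", index=False, float_format="%.6f")

    def _msd(xs: Sequence[float]) -> Dict[str, float]:
        return {
            "mean": float(np.mean(xs)) if len(xs) else float("nan"),
            "sd": float(np.std(xs, ddof=1)) if len(xs) > 1 else float("nan"),
        }

    intra = _msd(intra_means)
    rand = _msd(rand_means)
    fold = (
        intra["mean"] / rand["mean"] if rand_means and rand["mean"] > 0 else float("nan")
    )
    summary: Dict[str, object] = {
        "corpus": corpus_summary,
        "similarity": {
            "intra_ps": intra,
            "random": rand,
            "fold_change": fold,
            "n_disease_series_rows": len(sim_rows),
        },
        "max_partner": sim_mod.partner_summary(partner_records),
        "partner_crosstab": crosstab,
        "bipartite": {
            "n_tuples": len(tuples),
            "n_disease_nodes": sum(
                1 for n in bipartite if bipartite.nodes[n]["bipartite"] == 0
            ),
            "n_phenotype_nodes": sum(
                1 for n in bipartite if bipartite.nodes[n]["bipartite"] == 1
            ),
            "n_edges": bipartite.number_of_edges(),
            "rule_fractions": {str(k): v for k, v in rule_fractions.items()},
        },
        "network": {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "giant_nodes": giant["giant_nodes"],
            "giant_edges": giant["giant_edges"],
            "n_components": giant["n_components"],
        },
        "threshold_sweep": sweep.to_dict(orient="records"),
        "table1_strata": strata.reset_index().to_dict(orient="records"),
        "assortativity": {
            "n_series_analyzed": len(reports),
            "n_skipped": len(skipped),
            "n_dyadic": sum(1 for r in reports if r.dyadic_class == "dyadic"),
            "n_anti_dyadic": sum(1 for r in reports if r.dyadic_class == "anti-dyadic"),
            "n_heterophilic": sum(1 for r in reports if r.hetero_class == "heterophilic"),
            "n_heterophobic": sum(1 for r in reports if r.hetero_class == "heterophobic"),
        },
        "provenance": prov,
    }
    summary = _json_clean(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
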