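"""End-to-end analysis of a (synthetic) drought study.

Chains every stage on one :class:`~chromadapt.simulate.SyntheticStudy`:
differential expression and drought-induced calling, recovery and its
2x2 chi-square, homoeolog bias, compartment calling and switch patterns,
TAD calling / dg-dl / fusion-neo events, hotspots, the co-expression
network and the three-evidence target screen — and scores structure
recovery against the generator's truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import compartments as comp_mod
from . import expression as expr_mod
from . import network as net_mod
from . import tads as tad_mod
from .core import Condition, STAGES, TREATMENTS, VARIETIES
from .simulate import SyntheticStudy


@dataclass
class StudyAnalysis:
    study: SyntheticStudy
    de_tables: dict[tuple[str, str], expr_mod.DifferentialTable]
    induced: dict[str, list[expr_mod.DroughtInducedGene]]
    recovery: dict[str, expr_mod.RecoverySummary]
    recovery_chi2: tuple[float, float]
    genome_bias: dict[tuple[str, str], int]
    switch_tables: dict[tuple[str, str], pd.DataFrame]
    compartment_accuracy: float
    called_tads: dict[Condition, dict[str, list[tuple[int, int]]]]
    events: dict[tuple[str, str], list[tad_mod.TADEventCall]]
    event_recovery: dict[str, Any]
    dg_dl: dict[tuple[str, str], tad_mod.DroughtBoundaryComparison]
    network_summary: dict[str, Any] = field(default_factory=dict)
    target_report: net_mod.TargetGeneReport | None = None


# ---------------------------------------------------------------------
# expression side
# ---------------------------------------------------------------------

def run_differential(study: SyntheticStudy, *, alpha: float = 0.05,
                     lfc_threshold: float = 1.0
                     ) -> dict[tuple[str, str], expr_mod.DifferentialTable]:
    meta = study.expression.sample_meta
    out = {}
    for v in VARIETIES:
        for s in STAGES:
            d_ids = meta.query(
                "variety == @v and treatment == 'D' and stage == @s"
            )["sample_id"].tolist()
            c_ids = meta.query(
                "variety == @v and treatment == 'C' and stage == @s"
            )["sample_id"].tolist()
            out[(v, s)] = expr_mod.call_differential(
                study.expression.counts, d_ids, c_ids,
                variety=v, stage=s, alpha=alpha,
                lfc_threshold=lfc_threshold,
            )
    return out


def condition_mean_fpkm(study: SyntheticStudy) -> dict[Condition, pd.Series]:
    """Replicate-averaged FPKM per (variety, treatment, stage)."""
    meta = study.expression.sample_meta
    fpkm = study.expression.fpkm
    out = {}
    for v in VARIETIES:
        for t in TREATMENTS:
            for s in STAGES:
                ids = meta.query(
                    "variety == @v and treatment == @t and stage == @s"
                )["sample_id"].tolist()
                out[Condition(v, t, s)] = fpkm[ids].mean(axis=1)
    return out


def run_bias(study: SyntheticStudy) -> dict[tuple[str, str], int]:
    """Genome-wide bias-change value per (variety, stage)."""
    means = condition_mean_fpkm(study)
    out = {}
    for v in VARIETIES:
        for s in STAGES:
            expr = pd.DataFrame({
                "C": means[Condition(v, "C", s)],
                "D": means[Condition(v, "D", s)],
            })
            table = bias_mod.bias_change_table(study.genome.pairs, expr)
            out[(v, s)] = bias_mod.genome_bias_value(table["index"])
    return out


# ---------------------------------------------------------------------
# chromatin side
# ---------------------------------------------------------------------

def run_compartments(study: SyntheticStudy) -> tuple[
        dict[Condition, dict[str, comp_mod.CompartmentTrack]], float]:
    """Call compartments everywhere; return tracks + truth accuracy."""
    genome = study.genome
    tracks: dict[Condition, dict[str, comp_mod.CompartmentTrack]] = {}
    n_ok = n_tot = 0
    for cond, per_chrom in study.contacts.maps.items():
        tracks[cond] = {}
        for chrom, cm in per_chrom.items():
            et = comp_mod.compute_eigentrack(cm, genome.gene_density(chrom))
            ct = comp_mod.call_compartments(et)
            tracks[cond][chrom] = ct
            truth = study.contacts.truth.compartments[chrom]
            called = ct.labels
            ok = called != "masked"
            n_ok += int((called[ok] == truth[ok]).sum())
            n_tot += int(ok.sum())
    accuracy = n_ok / n_tot if n_tot else float("nan")
    return tracks, accuracy


def run_switches(
    tracks: dict[Condition, dict[str, comp_mod.CompartmentTrack]],
) -> dict[tuple[str, str], pd.DataFrame]:
    """Four-stage switch patterns per (variety, treatment), all chromosomes."""
    out = {}
    for v in VARIETIES:
        for t in TREATMENTS:
            frames = []
            chroms = tracks[Condition(v, t, STAGES[0])].keys()
            for chrom in chroms:
                per_stage = {
                    s: tracks[Condition(v, t, s)][chrom] for s in STAGES
                }
                frames.append(comp_mod.classify_switch_patterns(per_stage))
            df = pd.concat(frames, ignore_index=True)
            span: dict[str, float] = {}
            for f in frames:
                for g, mb in f.attrs["span_mb"].items():
                    span[g] = span.get(g, 0.0) + mb
            df.attrs["span_mb"] = span
            out[(v, t)] = df
    return out


def run_tad_calling(
    study: SyntheticStudy,
) -> dict[Condition, dict[str, list[tuple[int, int]]]]:
    out: dict[Condition, dict[str, list[tuple[int, int]]]] = {}
    for cond, per_chrom in study.contacts.maps.items():
        out[cond] = {}
        for chrom, cm in per_chrom.items():
            track = tad_mod.separation_score(cm)
            out[cond][chrom] = tad_mod.call_tads_from_score(
                track, cm.chrom_length
            )
    return out


def run_events(
    called: dict[Condition, dict[str, list[tuple[int, int]]]],
) -> dict[tuple[str, str], list[tad_mod.TADEventCall]]:
    out = {}
    for v in VARIETIES:
        for s in STAGES:
            out[(v, s)] = tad_mod.detect_tad_events(
                called[Condition(v, "C", s)], called[Condition(v, "D", s)]
            )
    return out


def score_event_recovery(
    study: SyntheticStudy,
    events: dict[tuple[str, str], list[tad_mod.TADEventCall]],
    tolerance: int = tad_mod.DEFAULT_FLANK,
) -> dict[str, Any]:
    """Fraction of planted events detected + false calls on control chroms.

    A planted event counts as detected when a called event of the same
    type, in the same (variety, stage), on the same chromosome has a
    changed boundary within ``tolerance`` bp of the planted one.
    """
    truth = study.contacts.truth
    n_hit = 0
    planted = truth.events
    for ev in planted:
        v, _t, s = ev.condition
        hits = [
            c for c in events.get((v, s), [])
            if c.type == ev.type and c.chrom == ev.chrom
            and any(abs(b - ev.boundary_bp) <= tolerance
                    for b in c.changed_boundaries)
        ]
        n_hit += bool(hits)
    false_on_unperturbed = sum(
        1 for calls in events.values() for c in calls
        if c.chrom in truth.unperturbed_chroms
    )
    return {
        "n_planted": len(planted),
        "n_detected": n_hit,
        "detection_rate": n_hit / len(planted) if planted else float("nan"),
        "false_events_on_unperturbed": false_on_unperturbed,
    }


def run_dg_dl(
    called: dict[Condition, dict[str, list[tuple[int, int]]]],
) -> dict[tuple[str, str], tad_mod.DroughtBoundaryComparison]:
    out = {}
    for v in VARIETIES:
        for s in STAGES:
            cb = tad_mod.boundaries_of_tads(called[Condition(v, "C", s)])
            db = tad_mod.boundaries_of_tads(called[Condition(v, "D", s)])
            out[(v, s)] = tad_mod.classify_drought_boundaries(cb, db)
    return out


# ---------------------------------------------------------------------
# network + target screen
# ---------------------------------------------------------------------

def build_coexpression_edges(
    study: SyntheticStudy, genes: list[str], power: int = 4
) -> pd.DataFrame:
    """Correlation-based edge list over a gene subset (synthetic runs).

    Weight = |Pearson r|^power of log2(FPKM + 1) profiles across all
    samples, a soft-thresholded stand-in for an external co-expression
    weight.  Only the upper triangle is emitted.
    """
    x = np.log2(study.expression.fpkm.loc[genes].to_numpy() + 1.0)
    keep = x.std(axis=1) > 0
    genes = [g for g, k in zip(genes, keep) if k]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x[keep])
    w = np.abs(np.nan_to_num(r)) ** power
    iu, ju = np.triu_indices(len(genes), k=1)
    return pd.DataFrame({
        "gene_a": np.array(genes)[iu],
        "gene_b": np.array(genes)[ju],
        "weight": w[iu, ju],
    })


def run_target_screen(
    study: SyntheticStudy,
    induced: dict[str, list[expr_mod.DroughtInducedGene]],
    dg_dl: dict[tuple[str, str], tad_mod.DroughtBoundaryComparison],
    *,
    boundary_window: int = 20_000,
) -> tuple[dict[str, Any], net_mod.TargetGeneReport]:
    """Edges -> modules -> drought module -> three-evidence screen."""
    deg_union = sorted({ig.gene for v in VARIETIES for ig in induced[v]})
    edges = build_coexpression_edges(study, deg_union)
    graph = net_mod.filter_edges(edges)
    if graph.number_of_nodes() == 0:
        return ({"n_nodes": 0, "n_edges": 0}, net_mod.TargetGeneReport(
            targets={v: set() for v in VARIETIES}, shared=set(),
            specific={v: set() for v in VARIETIES}))
    modules = net_mod.fallback_modules(graph)
    hubs = net_mod.find_hubs(graph, modules)

    # drought-associated module: largest mean |profile| contrast D vs C
    meta = study.expression.sample_meta.set_index("sample_id")
    best_mod, best_delta = None, -np.inf
    for mod in modules.unique():
        members = modules.index[modules == mod]
        prof = net_mod.module_expression_profile(
            list(members), study.expression.fpkm
        )
        d_mean = prof[meta["treatment"] == "D"].mean()
        c_mean = prof[meta["treatment"] == "C"].mean()
        delta = abs(d_mean - c_mean)
        if delta > best_delta:
            best_mod, best_delta = mod, delta
    module_genes = set(modules.index[modules == best_mod])

    evidence = {}
    for v in VARIETIES:
        changed = pd.concat(
            [pd.concat([dg_dl[(v, s)].dg, dg_dl[(v, s)].dl])
             for s in STAGES], ignore_index=True,
        )
        near = tad_mod.genes_near_boundaries(
            changed, study.genome.genes, window=boundary_window
        )
        evidence[v] = {
            "induced": {ig.gene for ig in induced[v]},
            "module": module_genes,
            "tad_change": near,
        }
    report = net_mod.screen_target_genes(evidence)
    summary = {
        "n_nodes": graph.graph["n_nodes"],
        "n_edges": graph.graph["n_edges"],
        "n_modules": int(modules.nunique()),
        "drought_module": best_mod,
        "drought_module_size": len(module_genes),
        "hubs": hubs,
    }
    return summary, report


# ---------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------

def analyze_study(study: SyntheticStudy) -> StudyAnalysis:
    de = run_differential(study)
    induced = {
        v: expr_mod.call_drought_induced(
            {s: de[(v, s)] for s in ("ID", "MD", "SD")}
        )
        for v in VARIETIES
    }
    recovery = {
        v: expr_mod.classify_recovery(induced[v], de[(v, "RW")])
        for v in VARIETIES
    }
    chi2 = expr_mod.chi_square_2x2(expr_mod.recovery_table(
        recovery["sensitive"], recovery["tolerant"]
    ))

    genome_bias = run_bias(study)
    tracks, comp_acc = run_compartments(study)
    switches = run_switches(tracks)
    called = run_tad_calling(study)
    events = run_events(called)
    ev_recovery = score_event_recovery(study, events)
    dg_dl = run_dg_dl(called)
    net_summary, report = run_target_screen(study, induced, dg_dl)

    return StudyAnalysis(
        study=study, de_tables=de, induced=induced, recovery=recovery,
        recovery_chi2=chi2, genome_bias=genome_bias,
        switch_tables=switches, compartment_accuracy=comp_acc,
        called_tads=called, events=events, event_recovery=ev_recovery,
        dg_dl=dg_dl, network_summary=net_summary, target_report=report,
    )
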