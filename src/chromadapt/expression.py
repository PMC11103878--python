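"""Drought-induced gene calling and post-rewatering recovery.

A *drought-induced gene* is one that is differentially expressed
(drought vs control) in at least one of the drought stages (ID, MD, SD)
with every differential stage agreeing in direction.  The RW stage is
reserved for the recovery analysis: an induced gene that is no longer
differential after re-watering has *recovered*, otherwise it is *still
differential*.  Comparing the recovered / still-differential counts of
two varieties in a 2x2 chi-square test asks whether one variety
recovers its transcriptome faster.

The internal differential caller is a moderated t-test on log2(x + 1):
per-gene pooled variances are shrunk toward the across-gene median
(an empirical-Bayes moderation in the limma tradition) so that the
two-replicate design of the study retains power, with
Benjamini-Hochberg correction across genes.  Tables produced by an
external DE tool can be loaded in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DegenerateInputError, DROUGHT_STAGES, InputError

DIRECTIONS = ("up", "down", "ns")


@dataclass
class DifferentialTable:
    """Per-gene calls for one (variety, stage) drought-vs-control contrast."""

    variety: str
    stage: str
    #: columns: gene, lfc (log2 drought/control), padj, direction
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"gene", "lfc", "padj", "direction"}
        if not req <= set(self.calls.columns):
            raise InputError(f"DE table needs columns {sorted(req)}")
        bad = ~self.calls["direction"].isin(DIRECTIONS)
        if bad.any():
            raise InputError(
                f"unknown direction {self.calls['direction'][bad].iloc[0]!r}"
            )

    def direction_of(self) -> pd.Series:
        return self.calls.set_index("gene")["direction"]


def call_differential(
    abundance: pd.DataFrame,
    drought_samples: list[str],
    control_samples: list[str],
    *,
    variety: str = "",
    stage: str = "",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    prior_df: float = 10.0,
) -> DifferentialTable:
    """Moderated t-test on log2(x + 1) per gene, BH-corrected.

    ``abundance`` is genes x samples (counts or FPKM-like).  Per-gene
    pooled variances are shrunk toward the across-gene median with
    ``prior_df`` pseudo-degrees of freedom, which keeps the test usable
    at two replicates per arm.  A gene is called ``up``/``down`` when
    padj <= alpha, |lfc| >= lfc_threshold and the fold change is
    non-zero; otherwise ``ns``.  Degenerate variances are explicit:
    identical arms are ``ns`` (p = 1), exactly separated constant arms
    get p = 0.
    """
    if not 0 < alpha <= 1:
        raise InputError("alpha must lie in (0, 1]")
    if prior_df < 0:
        raise InputError("prior_df must be non-negative")
    if not drought_samples or not control_samples:
        raise InputError("each contrast arm needs at least one sample")
    for s in (*drought_samples, *control_samples):
        if s not in abundance.columns:
            raise InputError(f"sample {s!r} not in abundance matrix")

    x = np.log2(abundance[drought_samples].to_numpy(dtype=float) + 1.0)
    y = np.log2(abundance[control_samples].to_numpy(dtype=float) + 1.0)
    n1, n2 = x.shape[1], y.shape[1]
    lfc = x.mean(axis=1) - y.mean(axis=1)

    df = n1 + n2 - 2
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df if df > 0 else np.zeros_like(ss)
    pos = s2[s2 > 0]
    s0 = float(np.median(pos)) if pos.size else 0.0
    denom_df = df + prior_df
    s2_mod = ((prior_df * s0 + df * s2) / denom_df if denom_df > 0
              else np.zeros_like(s2))
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = lfc / se
        p = 2.0 * stats.t.sf(np.abs(t), max(denom_df, 1.0))
    p[(se == 0) & (lfc == 0)] = 1.0
    p[(se == 0) & (lfc != 0)] = 0.0
    p[np.isnan(p)] = 1.0

    padj = multipletests(p, method="fdr_bh")[1]
    sig = (padj <= alpha) & (np.abs(lfc) >= lfc_threshold) & (lfc != 0)
    direction = np.where(sig & (lfc > 0), "up",
                         np.where(sig & (lfc < 0), "down", "ns"))
    calls = pd.DataFrame({
        "gene": abundance.index.to_numpy(), "lfc": lfc, "padj": padj,
        "direction": direction,
    })
    return DifferentialTable(variety=variety, stage=stage, calls=calls)


@dataclass(frozen=True)
class DroughtInducedGene:
    gene: str
    direction: str  # up or down
    supporting_stages: tuple[str, ...]


def call_drought_induced(
    tables: dict[str, DifferentialTable],
) -> list[DroughtInducedGene]:
    """Induced genes from the ID/MD/SD tables of one variety.

    A gene qualifies iff it is non-ns in >= 1 drought stage and all its
    non-ns stages share one direction; RW never contributes.
    """
    missing = [s for s in DROUGHT_STAGES if s not in tables]
    if missing:
        raise InputError(f"missing DE table(s) for stage(s): {missing}")
    per_stage = {s: tables[s].direction_of() for s in DROUGHT_STAGES}
    genes = per_stage[DROUGHT_STAGES[0]].index
    out: list[DroughtInducedGene] = []
    for g in genes:
        dirs = {s: per_stage[s].get(g, "ns") for s in DROUGHT_STAGES}
        active = {s: d for s, d in dirs.items() if d != "ns"}
        if not active:
            continue
        uniq = set(active.values())
        if len(uniq) > 1:
            continue  # conflicting directions across stages
        out.append(DroughtInducedGene(
            gene=g, direction=uniq.pop(),
            supporting_stages=tuple(s for s in DROUGHT_STAGES if s in active),
        ))
    return out


@dataclass
class RecoverySummary:
    variety: str
    recovered: int
    still_differential: int
    missing: int
    recovered_genes: list[str] = field(default_factory=list)
    still_genes: list[str] = field(default_factory=list)
    missing_genes: list[str] = field(default_factory=list)

    @property
    def n_induced(self) -> int:
        return self.recovered + self.still_differential + self.missing


def classify_recovery(
    induced: list[DroughtInducedGene],
    rw_table: DifferentialTable,
) -> RecoverySummary:
    """Partition induced genes into recovered / still-differential at RW.

    Induced genes absent from the RW table are counted and reported as
    missing, never silently dropped.
    """
    rw = rw_table.direction_of()
    summary = RecoverySummary(variety=rw_table.variety, recovered=0,
                              still_differential=0, missing=0)
    for ig in induced:
        if ig.gene not in rw.index:
            summary.missing += 1
            summary.missing_genes.append(ig.gene)
        elif rw[ig.gene] == "ns":
            summary.recovered += 1
            summary.recovered_genes.append(ig.gene)
        else:
            summary.still_differential += 1
            summary.still_genes.append(ig.gene)
    return summary


def recovery_table(a: RecoverySummary, b: RecoverySummary) -> np.ndarray:
    """2x2 table [[rec_a, still_a], [rec_b, still_b]] for the chi-square."""
    return np.array([[a.recovered, a.still_differential],
                     [b.recovered, b.still_differential]], dtype=np.int64)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 contingency table.

    ``correction`` enables the Yates continuity correction.  Returns
    (statistic, p).  A zero row or column marginal makes the test
    undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("chi_square_2x2 expects a 2x2 table")
    if np.any(t < 0):
        raise InputError("cell counts must be non-negative")
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateInputError(
            "a zero marginal leaves the chi-square test undefined"
        )
    stat, p, _dof, _exp = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def count_expressed(fpkm: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Descriptive per-sample count of genes at or above an FPKM floor."""
    return (fpkm >= threshold).sum(axis=0)
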