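"""Homoeolog expression bias between the A_t and D_t subgenomes.

Three complementary analyses of homoeologous gene pairs in an
allotetraploid:

1. *Direction categories* per stage: each pair is ``common`` (neither
   homoeolog differential, or both differential in the same direction),
   ``single`` (exactly one differential) or ``opposite`` (both
   differential, opposing directions).
2. *Bias dynamics* across the four stages of one (variety, treatment)
   context: ``stableAtbias`` if the A_t copy is strictly higher at every
   stage, ``stableDtbias`` if the D_t copy is, otherwise ``dynamic``.
   Exact ties count as "not higher", so an all-tie pair is dynamic.
3. *Bias-change index*: per condition a pair is coded +1 (A_t-biased),
   0 (unbiased) or -1 (D_t-biased); the index is the drought state minus
   the control state (range -2..+2), and the genome-wide bias value is
   the sum over pairs — positive means drought shifts expression toward
   the A_t subgenome.

The bias state itself uses a log-ratio rule: state = +1 when
``log2((At + eps) / (Dt + eps)) >= lfc_cut``, -1 when ``<= -lfc_cut``,
else 0; pairs with both homoeologs below ``min_expr`` are called 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InputError, STAGES, subgenome_of

#: default pseudocount, expression floor and log2-ratio cutoff of the
#: bias criterion; recorded in output metadata by the writers
DEFAULT_EPS = 0.1
DEFAULT_MIN_EXPR = 1.0
DEFAULT_LFC_CUT = 1.0

ATBIAS, NOBIAS, DTBIAS = 1, 0, -1


@dataclass(frozen=True)
class HomoeologPair:
    pair_id: str
    gene_At: str
    gene_Dt: str


def validate_pair_map(pairs: pd.DataFrame, gene_chrom: pd.Series) -> None:
    """Check subgenome placement and uniqueness of a pair map.

    ``pairs`` has columns pair_id / gene_At / gene_Dt; ``gene_chrom``
    maps gene id to chromosome name.
    """
    for col, sub in (("gene_At", "A"), ("gene_Dt", "D")):
        chroms = gene_chrom.reindex(pairs[col])
        if chroms.isna().any():
            missing = pairs[col][chroms.isna().to_numpy()].iloc[0]
            raise InputError(f"pair gene {missing!r} not in annotation")
        bad = [c for c in chroms if subgenome_of(c) != sub]
        if bad:
            raise InputError(
                f"{col} genes must lie on the {sub} subgenome; found {bad[0]}"
            )
    members = pd.concat([pairs["gene_At"], pairs["gene_Dt"]])
    if members.duplicated().any():
        raise InputError("a gene may belong to at most one homoeolog pair")


# ---------------------------------------------------------------------
# 1. direction categories
# ---------------------------------------------------------------------

def classify_pair_direction(call_At: str, call_Dt: str) -> str:
    """Category of one pair at one stage from the two DE directions.

    Directions are ``up`` / ``down`` / ``ns``.
    """
    for c in (call_At, call_Dt):
        if c not in ("up", "down", "ns"):
            raise InputError(f"unknown DE direction {c!r}")
    if call_At == "ns" and call_Dt == "ns":
        return "common"
    if call_At == "ns" or call_Dt == "ns":
        return "single"
    return "common" if call_At == call_Dt else "opposite"


def classify_pair_directions(
    pairs: pd.DataFrame, calls: pd.DataFrame
) -> pd.DataFrame:
    """Direction category for every pair at every stage present in ``calls``.

    ``calls`` has columns gene / stage / direction (one row per gene and
    stage).  Returns columns pair_id / stage / category.
    """
    d = calls.set_index(["gene", "stage"])["direction"]
    rows = []
    for stage in calls["stage"].unique():
        for rec in pairs.itertuples(index=False):
            try:
                a = d[(rec.gene_At, stage)]
                b = d[(rec.gene_Dt, stage)]
            except KeyError as exc:
                raise InputError(
                    f"missing DE call for homoeolog {exc.args[0]}"
                ) from None
            rows.append((rec.pair_id, stage, classify_pair_direction(a, b)))
    return pd.DataFrame(rows, columns=["pair_id", "stage", "category"])


# ---------------------------------------------------------------------
# 2. bias state and dynamics
# ---------------------------------------------------------------------

def call_bias_state(
    expr_At,
    expr_Dt,
    *,
    min_expr: float = DEFAULT_MIN_EXPR,
    lfc_cut: float = DEFAULT_LFC_CUT,
    eps: float = DEFAULT_EPS,
):
    """Bias state (+1 / 0 / -1) from paired expression values.

    Vectorized: accepts scalars or equal-length arrays.
    """
    a = np.asarray(expr_At, dtype=float)
    b = np.asarray(expr_Dt, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise InputError("expression values must be non-negative")
    ratio = np.log2((a + eps) / (b + eps))
    state = np.where(ratio >= lfc_cut, ATBIAS,
                     np.where(ratio <= -lfc_cut, DTBIAS, NOBIAS))
    state = np.where((a < min_expr) & (b < min_expr), NOBIAS, state)
    return int(state) if state.ndim == 0 else state.astype(int)


def classify_bias_dynamics(expr_At_by_stage, expr_Dt_by_stage) -> str:
    """Stability class of one pair over the four stages of one context.

    Arguments map stage -> expression of the A_t / D_t homoeolog.  The
    class is ``stableAtbias`` / ``stableDtbias`` only under a strict
    inequality at *all four* stages; anything else — including exact
    ties — is ``dynamic``.
    """
    missing = [s for s in STAGES if s not in expr_At_by_stage
               or s not in expr_Dt_by_stage]
    if missing:
        raise InputError(f"missing stages for bias dynamics: {missing}")
    a = np.array([float(expr_At_by_stage[s]) for s in STAGES])
    d = np.array([float(expr_Dt_by_stage[s]) for s in STAGES])
    if np.all(a > d):
        return "stableAtbias"
    if np.all(d > a):
        return "stableDtbias"
    return "dynamic"


# ---------------------------------------------------------------------
# 3. bias-change index
# ---------------------------------------------------------------------

def bias_change_index(control_state: int, drought_state: int) -> int:
    """Drought bias state minus control bias state, in {-2..+2}."""
    for s in (control_state, drought_state):
        if s not in (ATBIAS, NOBIAS, DTBIAS):
            raise InputError(f"bias state must be in {{-1, 0, 1}}, got {s}")
    return int(drought_state) - int(control_state)


def genome_bias_value(indices) -> int:
    """Sum of per-pair bias-change indices; positive = A_t-ward shift."""
    arr = np.asarray(list(indices), dtype=int)
    if arr.size and (arr.max() > 2 or arr.min() < -2):
        raise InputError("bias-change indices must lie in [-2, 2]")
    return int(arr.sum())


def bias_change_table(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    *,
    min_expr: float = DEFAULT_MIN_EXPR,
    lfc_cut: float = DEFAULT_LFC_CUT,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Per-pair bias states and change indices for one (variety, stage).

    ``expr`` is indexed by gene id with columns ``C`` and ``D`` holding
    the expression under control and drought.  Returns one row per pair
    with state_C / state_D / index; pairs with a missing homoeolog
    measurement are excluded (reported via the ``n_excluded`` attr).
    """
    present = expr.index
    ok = pairs["gene_At"].isin(present) & pairs["gene_Dt"].isin(present)
    kept = pairs[ok]
    out = pd.DataFrame({"pair_id": kept["pair_id"].to_numpy()})
    for treat in ("C", "D"):
        a = expr.loc[kept["gene_At"], treat].to_numpy()
        d = expr.loc[kept["gene_Dt"], treat].to_numpy()
        out[f"state_{treat}"] = call_bias_state(
            a, d, min_expr=min_expr, lfc_cut=lfc_cut, eps=eps
        )
    out["index"] = out["state_D"] - out["state_C"]
    out.attrs["n_excluded"] = int((~ok).sum())
    out.attrs["params"] = {"min_expr": min_expr, "lfc_cut": lfc_cut,
                           "eps": eps}
    return out
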