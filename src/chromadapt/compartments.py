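"""A/B compartment calling and four-stage switch-pattern taxonomy.

Compartments are called per chromosome from the binned contact matrix:
observed/expected normalization by per-distance mean, Pearson
correlation matrix, first principal component; the eigenvector sign is
oriented so that gene-rich bins (above-median density on an orientation
track) carry positive values, since the A compartment is the active,
gene-rich state.  A bin is A where the oriented value is > 0, B where
< 0; an exact 0 is masked (the sign rule is strict on both sides).

Across the four stages a bin traces a four-letter string over {A, B}
(stage order ID, MD, SD, RW) that falls into one of five groups:

========  ==============================  =======================
group     meaning                         members
========  ==============================  =======================
stable    no switch                       AAAA BBBB
AB        ends A -> B                     AAAB ABAB AABB ABBB
BA        ends B -> A                     BAAA BABA BBAA BBBA
ABA       away from A and back            ABBA ABAA AABA
BAB       away from B and back            BAAB BABB BBAB
========  ==============================  =======================

The group is a pure function of the first and last letters (equal and
constant = stable; equal but non-constant = ABA/BAB; unequal = AB/BA),
which reproduces the enumerated memberships above exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core import DegenerateInputError, InputError, STAGES
from .expression import chi_square_2x2
from .hic import ContactMatrix

SWITCH_GROUPS = ("stable", "AB", "BA", "ABA", "BAB")


@dataclass
class EigenTrack:
    chrom: str
    bin_size: int
    #: oriented first-PC value per bin; NaN where masked
    values: np.ndarray
    valid: np.ndarray
    #: fraction of correlation-matrix variance carried by the first PC
    explained: float
    low_signal: bool


@dataclass
class CompartmentTrack:
    chrom: str
    bin_size: int
    labels: np.ndarray  # 'A' / 'B' / 'masked' per bin

    @property
    def n_bins(self) -> int:
        return len(self.labels)


def observed_over_expected(matrix: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean contact (distance normalization)."""
    n = matrix.shape[0]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    expected = np.array([
        matrix[d == k].mean() if np.any(matrix[d == k]) else np.nan
        for k in range(n)
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = matrix / expected[d]
    return oe


def compute_eigentrack(
    cm: ContactMatrix,
    orientation_track: np.ndarray,
    *,
    low_signal_threshold: float = 0.1,
) -> EigenTrack:
    """First principal component of the O/E correlation matrix, oriented.

    ``orientation_track`` is a per-bin reference (typically gene
    density); the sign is chosen so the eigenvector covaries positively
    with it — gene-rich bins carry positive values, and negating the
    track flips every sign.  Bins with all-zero rows are masked.
    The track is flagged ``low_signal`` when the first PC explains less
    than ``low_signal_threshold`` of the correlation variance (no plaid /
    checkerboard structure to speak of).
    """
    m = cm.matrix
    orientation_track = np.asarray(orientation_track, dtype=float)
    if orientation_track.shape != (cm.n_bins,):
        raise InputError("orientation track length must equal bin count")
    valid = ~cm.masked_bins()
    if not valid.any():
        raise DegenerateInputError(f"contact matrix for {cm.chrom} is all zero")
    if valid.sum() < 10:
        raise DegenerateInputError("fewer than 10 unmasked bins")

    sub = m[np.ix_(valid, valid)]
    oe = observed_over_expected(sub)
    oe[~np.isfinite(oe)] = 0.0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    # bins with zero O/E variance produce NaN correlation rows: mask them
    bad = np.all(~np.isfinite(corr) | (corr == 0), axis=1) | np.isnan(
        np.diag(corr))
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)

    evals, evecs = np.linalg.eigh(corr)
    pc1 = evecs[:, -1]
    explained = float(max(evals[-1], 0.0) / corr.shape[0])
    pc1 = np.where(bad, np.nan, pc1)

    values = np.full(cm.n_bins, np.nan)
    values[valid] = pc1
    valid_out = valid.copy()
    valid_out[valid] = ~bad

    # orient by the covariance of the eigenvector with the demeaned
    # reference track: positive values end up in gene-rich bins, and
    # negating the track flips every sign exactly
    ref = orientation_track[valid_out]
    cov = float(np.nansum(values[valid_out] * (ref - ref.mean())))
    if cov < 0:
        values = -values

    return EigenTrack(
        chrom=cm.chrom, bin_size=cm.bin_size, values=values,
        valid=valid_out, explained=explained,
        low_signal=explained < low_signal_threshold,
    )


def call_compartments(track: EigenTrack) -> CompartmentTrack:
    """Sign rule: > 0 is A, < 0 is B, exactly 0 (or masked) is masked."""
    v = track.values
    labels = np.where(~track.valid | np.isnan(v), "masked",
                      np.where(v > 0, "A", np.where(v < 0, "B", "masked")))
    return CompartmentTrack(chrom=track.chrom, bin_size=track.bin_size,
                            labels=labels)


# ---------------------------------------------------------------------
# switch patterns
# ---------------------------------------------------------------------

def switch_group(pattern: str) -> str:
    """Group of one four-letter A/B string (see module docstring)."""
    if len(pattern) != 4 or set(pattern) - {"A", "B"}:
        raise InputError(f"pattern must be 4 letters over A/B, got {pattern!r}")
    first, last = pattern[0], pattern[-1]
    if first == last:
        if pattern == first * 4:
            return "stable"
        return "ABA" if first == "A" else "BAB"
    return "AB" if first == "A" else "BA"


def enumerate_switch_partition() -> dict[str, list[str]]:
    """All 16 strings grouped; sizes are stable 2, AB 4, BA 4, ABA 3, BAB 3."""
    out: dict[str, list[str]] = {g: [] for g in SWITCH_GROUPS}
    for letters in product("AB", repeat=4):
        s = "".join(letters)
        out[switch_group(s)].append(s)
    return out


def classify_switch_patterns(
    tracks: dict[str, CompartmentTrack],
) -> pd.DataFrame:
    """Per-bin switch pattern and group for one chromosome.

    ``tracks`` maps each stage (ID, MD, SD, RW) to its compartment track
    on identical binning.  Bins masked in any stage are excluded.  The
    result carries per-group span totals in Mb in ``.attrs['span_mb']``.
    """
    missing = [s for s in STAGES if s not in tracks]
    if missing:
        raise InputError(f"missing stage track(s): {missing}")
    first = tracks[STAGES[0]]
    for s in STAGES:
        t = tracks[s]
        if t.n_bins != first.n_bins or t.bin_size != first.bin_size:
            raise InputError("stage tracks must share one binning")

    labels = np.stack([tracks[s].labels for s in STAGES])  # 4 x n
    ok = ~(labels == "masked").any(axis=0)
    bins = np.nonzero(ok)[0]
    patterns = ["".join(labels[:, b]) for b in bins]
    groups = [switch_group(p) for p in patterns]
    df = pd.DataFrame({
        "chrom": first.chrom,
        "bin": bins,
        "start": bins * first.bin_size,
        "end": (bins + 1) * first.bin_size,
        "pattern": patterns,
        "group": groups,
    })
    span = {g: 0.0 for g in SWITCH_GROUPS}
    for g, cnt in df["group"].value_counts().items():
        span[g] = cnt * first.bin_size / 1e6
    df.attrs["span_mb"] = span
    return df


def associate_switches_with_genes(
    switches: pd.DataFrame,
    genes: pd.DataFrame,
    de_direction: pd.Series,
    *,
    correction: bool = False,
) -> dict:
    """Assign genes to switch groups and test DE enrichment in switch bins.

    A gene belongs to a switch region iff its interval overlaps a
    switching (non-stable) bin by >= 1 bp.  The 2x2 table crosses
    in/out-switch-region membership with DE (non-ns) status over all
    genes; it is passed to the chi-square test.
    """
    if genes.empty:
        raise InputError("empty gene set")
    req = {"chrom", "start", "end", "group"}
    if not req <= set(switches.columns):
        raise InputError(f"switch table needs columns {sorted(req)}")

    per_group: dict[str, list[str]] = {g: [] for g in SWITCH_GROUPS
                                       if g != "stable"}
    in_switch = np.zeros(len(genes), dtype=bool)
    for chrom, sw in switches[switches["group"] != "stable"].groupby("chrom"):
        sel = (genes["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        gs = genes.loc[sel, "start"].to_numpy()[:, None]
        ge = genes.loc[sel, "end"].to_numpy()[:, None]
        bs = sw["start"].to_numpy()[None, :]
        be = sw["end"].to_numpy()[None, :]
        hit = (gs < be) & (ge > bs)
        in_switch[sel] |= hit.any(axis=1)
        gids = genes.loc[sel, "gene_id"].to_numpy()
        grp = sw["group"].to_numpy()
        for g in set(grp):
            members = hit[:, grp == g].any(axis=1)
            per_group.setdefault(g, []).extend(gids[members])

    de = de_direction.reindex(genes["gene_id"]).fillna("ns").to_numpy()
    is_de = de != "ns"
    table = np.array([
        [int((in_switch & is_de).sum()), int((in_switch & ~is_de).sum())],
        [int((~in_switch & is_de).sum()), int((~in_switch & ~is_de).sum())],
    ])
    stat, p = chi_square_2x2(table, correction=correction)
    return {
        "genes_by_group": {g: sorted(set(v)) for g, v in per_group.items()},
        "in_switch": pd.Series(in_switch, index=genes["gene_id"].to_numpy()),
        "table": table,
        "statistic": stat,
        "p_value": p,
    }
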