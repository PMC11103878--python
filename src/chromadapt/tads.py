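"""TAD boundary comparison algebra.

All coordinates are 0-based half-open, bp.  A TAD boundary at position
``p`` is compared through its flanked region ``[p - flank, p + flank)``
(default flank 40 kb, i.e. an 80-kb region); two boundaries are
*conserved* iff their regions intersect by at least 1 bp.  On top of
that rule this module builds:

* insulation-style TAD-separation scores and a minimal score-based
  TAD caller (lower score = stronger insulation);
* reciprocal-best boundary matching between two samples;
* the iterative four-stage pan-boundary map (ID -> MD -> SD -> RW
  accretion, then re-mapping every stage onto the final set);
* drought gain / loss (dg / dl) classification of boundaries;
* fusion (>= 2 control TADs merge into one drought TAD) and neo-TAD
  (one control TAD splits into >= 2 drought TADs) event detection;
* hotspot calling: non-overlapping 10-Mb genome tiles holding more than
  8 changed boundaries of one type, consecutive qualifying tiles merged;
* gene-to-boundary assignment within a per-side window;
* the 16-sample cross-variety pan-boundary set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import InputError, STAGES
from .hic import ContactMatrix

DEFAULT_FLANK = 40_000
HOTSPOT_WINDOW = 10_000_000
HOTSPOT_MIN_COUNT = 8  # a window qualifies strictly above this count


# ---------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------

def boundary_frame(records) -> pd.DataFrame:
    """Normalize (chrom, pos) records into a sorted boundary table."""
    df = pd.DataFrame(records, columns=["chrom", "pos"])
    df["pos"] = df["pos"].astype(np.int64)
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def boundaries_of_tads(tads: dict[str, list[tuple[int, int]]]) -> pd.DataFrame:
    """Unique start/end positions of per-chromosome TAD interval lists."""
    recs = []
    for chrom, ivs in tads.items():
        validate_tads(ivs, chrom)
        pos = sorted({p for s, e in ivs for p in (s, e)})
        recs.extend((chrom, p) for p in pos)
    return boundary_frame(recs)


def validate_tads(tads: list[tuple[int, int]], chrom: str = "?") -> None:
    prev_end = -1
    for s, e in sorted(tads):
        if e <= s:
            raise InputError(f"TAD on {chrom} has end <= start: ({s}, {e})")
        if s < prev_end:
            raise InputError(f"overlapping TADs within one sample on {chrom}")
        prev_end = e


# ---------------------------------------------------------------------
# separation score and a minimal score-based caller
# ---------------------------------------------------------------------

@dataclass
class SeparationScoreTrack:
    chrom: str
    bin_size: int
    #: per-bin averaged z score; NaN where no window fits
    score: np.ndarray
    window_sizes: tuple[int, ...]


def separation_score(
    cm: ContactMatrix,
    window_sizes: tuple[int, ...] = (100_000, 200_000),
) -> SeparationScoreTrack:
    """Insulation-style TAD-separation score per bin.

    For each bin edge ``i`` and window of ``w`` bins, the raw score is
    the mean contact between the ``w`` bins upstream and the ``w`` bins
    downstream of the edge (the contacts a boundary at ``i * bin_size``
    would insulate).  Raw tracks are z-normalized per chromosome and
    averaged over window sizes; lower means stronger insulation.
    """
    n = cm.n_bins
    m = cm.matrix
    tracks = []
    for wbp in window_sizes:
        if wbp % cm.bin_size:
            raise InputError("window size must be a multiple of bin_size")
        w = wbp // cm.bin_size
        if 2 * w > n:
            raise InputError(
                f"window {wbp} bp does not fit a {cm.chrom_length} bp chromosome"
            )
        raw = np.full(n, np.nan)
        for i in range(w, n - w + 1):
            raw[min(i, n - 1)] = m[i - w:i, i:i + w].mean()
        mu = np.nanmean(raw)
        sd = np.nanstd(raw)
        tracks.append((raw - mu) / sd if sd > 0 else raw - mu)
    stacked = np.stack(tracks)
    counts = np.isfinite(stacked).sum(axis=0)
    score = np.full(n, np.nan)
    has = counts > 0
    score[has] = np.nansum(np.where(np.isfinite(stacked), stacked, 0.0),
                           axis=0)[has] / counts[has]
    return SeparationScoreTrack(chrom=cm.chrom, bin_size=cm.bin_size,
                                score=score,
                                window_sizes=tuple(window_sizes))


def call_tads_from_score(
    track: SeparationScoreTrack,
    chrom_length: int,
    *,
    z_cut: float = -0.8,
    min_spacing_bins: int = 3,
) -> list[tuple[int, int]]:
    """Segment a chromosome into TADs at separation-score minima.

    A boundary is a local minimum of the score below ``z_cut``; minima
    closer than ``min_spacing_bins`` keep only the deepest.  TADs are the
    intervals between consecutive boundaries, closed by the chromosome
    ends.
    """
    s = track.score
    n = len(s)
    cand = []
    for i in range(1, n - 1):
        if not np.isfinite(s[i]) or s[i] >= z_cut:
            continue
        left = s[i - 1] if np.isfinite(s[i - 1]) else np.inf
        right = s[i + 1] if np.isfinite(s[i + 1]) else np.inf
        if s[i] <= left and s[i] <= right:
            cand.append(i)
    # enforce spacing, deepest wins, deterministic left-to-right sweep
    kept: list[int] = []
    for i in sorted(cand, key=lambda j: (s[j], j)):
        if all(abs(i - k) >= min_spacing_bins for k in kept):
            kept.append(i)
    kept.sort()
    cuts = [0] + [i * track.bin_size for i in kept] + [chrom_length]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


# ---------------------------------------------------------------------
# boundary matching
# ---------------------------------------------------------------------

@dataclass
class MatchResult:
    #: matched (index_a, index_b) pairs into the input frames
    pairs: list[tuple[int, int]]
    a_specific: list[int]
    b_specific: list[int]
    flank: int

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _flanked(pos: np.ndarray, flank: int,
             chrom_length: int | None) -> tuple[np.ndarray, np.ndarray]:
    start = np.maximum(pos - flank, 0)
    end = pos + flank
    if chrom_length is not None:
        end = np.minimum(end, chrom_length)
    return start, end


def match_boundaries(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    chrom_lengths: dict[str, int] | None = None,
) -> MatchResult:
    """Reciprocal-best-overlap matching of two boundary sets.

    Two boundaries can match iff their flanked regions intersect by at
    least 1 bp.  One-to-many cases are resolved by largest overlap, ties
    by smallest position distance, then by leftmost partner; a pair is
    kept only when each member is the other's best.  Every boundary ends
    up matched or specific.
    """
    if flank <= 0:
        raise InputError("flank must be positive")
    if chrom_lengths is not None:
        for df in (set_a, set_b):
            unknown = set(df["chrom"]) - set(chrom_lengths)
            if unknown:
                raise InputError(f"boundaries on unknown chromosome(s): "
                                 f"{sorted(unknown)}")
    pairs: list[tuple[int, int]] = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    chroms = sorted(set(set_a["chrom"]) | set(set_b["chrom"]))
    for chrom in chroms:
        ia = np.nonzero((set_a["chrom"] == chrom).to_numpy())[0]
        ib = np.nonzero((set_b["chrom"] == chrom).to_numpy())[0]
        if not len(ia) or not len(ib):
            continue
        pa = set_a["pos"].to_numpy()[ia]
        pb = set_b["pos"].to_numpy()[ib]
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        as_, ae = _flanked(pa, flank, clen)
        bs, be = _flanked(pb, flank, clen)
        ov = (np.minimum(ae[:, None], be[None, :])
              - np.maximum(as_[:, None], bs[None, :]))
        dist = np.abs(pa[:, None] - pb[None, :])
        ov = np.where(ov > 0, ov, -1)

        def best(axis_ov, axis_dist, other_pos):
            # rank: overlap desc, distance asc, position asc
            order = np.lexsort((other_pos, axis_dist, -axis_ov))
            return order[0]

        best_b_for_a = np.array([
            best(ov[i], dist[i], pb) if (ov[i] > 0).any() else -1
            for i in range(len(pa))
        ])
        best_a_for_b = np.array([
            best(ov[:, j], dist[:, j], pa) if (ov[:, j] > 0).any() else -1
            for j in range(len(pb))
        ])
        for i in range(len(pa)):
            j = best_b_for_a[i]
            if j >= 0 and ov[i, j] > 0 and best_a_for_b[j] == i:
                pairs.append((int(ia[i]), int(ib[j])))
                matched_a.add(int(ia[i]))
                matched_b.add(int(ib[j]))
    return MatchResult(
        pairs=pairs,
        a_specific=sorted(set(range(len(set_a))) - matched_a),
        b_specific=sorted(set(range(len(set_b))) - matched_b),
        flank=flank,
    )


def assign_to_reference(
    queries: pd.DataFrame,
    reference: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
) -> np.ndarray:
    """One-sided best-overlap assignment of each query boundary.

    Returns, per query row, the index of the reference boundary whose
    flanked region overlaps it most (ties: nearest, then leftmost), or
    -1 when no reference region intersects at all.
    """
    out = np.full(len(queries), -1, dtype=int)
    for chrom in sorted(set(queries["chrom"])):
        iq = np.nonzero((queries["chrom"] == chrom).to_numpy())[0]
        ir = np.nonzero((reference["chrom"] == chrom).to_numpy())[0]
        if not len(iq) or not len(ir):
            continue
        pq = queries["pos"].to_numpy()[iq]
        pr = reference["pos"].to_numpy()[ir]
        qs, qe = _flanked(pq, flank, None)
        rs, re_ = _flanked(pr, flank, None)
        ov = (np.minimum(qe[:, None], re_[None, :])
              - np.maximum(qs[:, None], rs[None, :]))
        dist = np.abs(pq[:, None] - pr[None, :])
        for k in range(len(pq)):
            if (ov[k] > 0).any():
                order = np.lexsort((pr, dist[k], -ov[k]))
                out[iq[k]] = int(ir[order[0]])
    return out


# ---------------------------------------------------------------------
# pan-boundary construction (four stages, one sample context)
# ---------------------------------------------------------------------

CONSERVATION_CLASSES = {1: "stage-specific", 2: "conserved-2",
                        3: "conserved-3", 4: "conserved-4"}


@dataclass
class PanBoundarySet:
    #: columns: chrom, pos (representative, from the earliest contributing
    #: stage), origin_stage, present_<stage> flags, n_stages, conservation
    entries: pd.DataFrame
    flank: int
    #: per input stage, the pan-entry index of each of its boundaries
    assignments: dict[str, np.ndarray] = field(default_factory=dict)


def build_pan_boundaries(
    stage_sets: dict[str, pd.DataFrame],
    flank: int = DEFAULT_FLANK,
    order: tuple[str, ...] = STAGES,
) -> PanBoundarySet:
    """Iterative pan-boundary map over the four stages.

    Accretion starts from the first stage of ``order`` (ID by default);
    each later stage contributes only boundaries unmatched against the
    current pan set.  Every stage is then re-mapped onto the final set by
    one-sided best overlap to fill the presence vector, and entries are
    classified by the number of stages present.
    """
    missing = [s for s in order if s not in stage_sets]
    if missing:
        raise InputError(f"missing stage boundary set(s): {missing}")
    pan = stage_sets[order[0]][["chrom", "pos"]].copy()
    pan["origin_stage"] = order[0]
    for stage in order[1:]:
        cur = stage_sets[stage][["chrom", "pos"]]
        if cur.empty:
            continue
        res = match_boundaries(cur, pan[["chrom", "pos"]], flank=flank)
        add = cur.iloc[res.a_specific].copy()
        add["origin_stage"] = stage
        pan = pd.concat([pan, add], ignore_index=True)
    pan = pan.sort_values(["chrom", "pos"], ignore_index=True)

    assignments: dict[str, np.ndarray] = {}
    for stage in order:
        cur = stage_sets[stage][["chrom", "pos"]]
        idx = assign_to_reference(cur, pan[["chrom", "pos"]], flank=flank)
        assignments[stage] = idx
        present = np.zeros(len(pan), dtype=bool)
        present[idx[idx >= 0]] = True
        pan[f"present_{stage}"] = present
    pan["n_stages"] = sum(pan[f"present_{s}"].astype(int) for s in order)
    pan["conservation"] = pan["n_stages"].map(CONSERVATION_CLASSES)
    return PanBoundarySet(entries=pan, flank=flank, assignments=assignments)


# ---------------------------------------------------------------------
# drought gain / loss
# ---------------------------------------------------------------------

@dataclass
class DroughtBoundaryComparison:
    conserved: pd.DataFrame  # control boundaries matched in drought
    dg: pd.DataFrame         # drought-specific (gained)
    dl: pd.DataFrame         # control-specific (lost)
    conserved_fraction: float


def classify_drought_boundaries(
    control: pd.DataFrame,
    drought: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    chrom_lengths: dict[str, int] | None = None,
) -> DroughtBoundaryComparison:
    """Label boundaries conserved / dg (drought gain) / dl (drought loss).

    The conserved fraction is reported relative to the pooled pan set of
    the two samples (conserved pairs + dg + dl).
    """
    res = match_boundaries(control, drought, flank=flank,
                           chrom_lengths=chrom_lengths)
    conserved = control.iloc[[i for i, _ in res.pairs]].reset_index(drop=True)
    dl = control.iloc[res.a_specific].reset_index(drop=True)
    dg = drought.iloc[res.b_specific].reset_index(drop=True)
    total = len(conserved) + len(dg) + len(dl)
    frac = len(conserved) / total if total else float("nan")
    return DroughtBoundaryComparison(conserved=conserved, dg=dg, dl=dl,
                                     conserved_fraction=frac)


# ---------------------------------------------------------------------
# fusion / neo-TAD events
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TADEventCall:
    type: str  # "fusion" or "neo"
    chrom: str
    control_tads: tuple[tuple[int, int], ...]
    drought_tads: tuple[tuple[int, int], ...]
    #: internal boundaries lost (fusion) or gained (neo) under drought
    changed_boundaries: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.type == "fusion":
            if len(self.control_tads) < 2 or len(self.drought_tads) != 1:
                raise InputError("fusion needs >=2 control TADs and 1 drought TAD")
        elif self.type == "neo":
            if len(self.control_tads) != 1 or len(self.drought_tads) < 2:
                raise InputError("neo needs 1 control TAD and >=2 drought TADs")
        else:
            raise InputError(f"unknown event type {self.type!r}")


def _mergers(
    parts: list[tuple[int, int]],
    whole: list[tuple[int, int]],
    chrom: str,
    flank: int,
) -> list[tuple[tuple[int, int], tuple[tuple[int, int], ...], tuple[int, ...]]]:
    """Whole-side TADs that absorb >= 2 contiguous part-side TADs.

    A whole TAD qualifies when both of its outer boundaries are matched
    (flank rule) to the outer boundaries of a contiguous chain of >= 2
    part TADs and at least one internal chain boundary is unmatched on
    the whole side.  Returns (whole_tad, chain, changed_boundaries).
    """
    validate_tads(parts, chrom)
    validate_tads(whole, chrom)
    parts = sorted(parts)
    pb = boundary_frame([(chrom, p) for t in parts for p in t]
                        ).drop_duplicates(ignore_index=True)
    wb = boundary_frame([(chrom, p) for t in whole for p in t]
                        ).drop_duplicates(ignore_index=True)
    res = match_boundaries(pb, wb, flank=flank)
    part_to_whole = {pb["pos"].iloc[i]: wb["pos"].iloc[j]
                     for i, j in res.pairs}
    whole_to_part = {w: p for p, w in part_to_whole.items()}

    out = []
    for ws, we in sorted(whole):
        ps = whole_to_part.get(ws)
        pe = whole_to_part.get(we)
        if ps is None or pe is None or pe <= ps:
            continue
        chain = [t for t in parts if t[0] >= ps and t[1] <= pe]
        if len(chain) < 2:
            continue
        if chain[0][0] != ps or chain[-1][1] != pe:
            continue
        if any(chain[i][1] != chain[i + 1][0] for i in range(len(chain) - 1)):
            continue  # the chain must tile the whole TAD without gaps
        internal = [chain[i][1] for i in range(len(chain) - 1)]
        lost = tuple(p for p in internal if p not in part_to_whole)
        if not lost:
            continue
        out.append(((ws, we), tuple(chain), lost))
    return out


def detect_tad_events(
    control: dict[str, list[tuple[int, int]]],
    drought: dict[str, list[tuple[int, int]]],
    flank: int = DEFAULT_FLANK,
) -> list[TADEventCall]:
    """Fusion and neo-TAD events between a control and a drought TAD set.

    Fusion: >= 2 contiguous control TADs merge into one drought TAD
    (their shared internal boundaries disappear).  Neo: one control TAD
    splits into >= 2 contiguous drought TADs (new internal boundaries
    appear).  Outer boundaries must be conserved under the flanked
    >= 1 bp overlap rule; events are maximal by construction because the
    absorbing TAD fixes the chain.
    """
    events: list[TADEventCall] = []
    for chrom in sorted(set(control) | set(drought)):
        c = control.get(chrom, [])
        d = drought.get(chrom, [])
        for whole, chain, lost in _mergers(c, d, chrom, flank):
            events.append(TADEventCall(
                type="fusion", chrom=chrom, control_tads=chain,
                drought_tads=(whole,), changed_boundaries=lost,
            ))
        for whole, chain, gained in _mergers(d, c, chrom, flank):
            events.append(TADEventCall(
                type="neo", chrom=chrom, control_tads=(whole,),
                drought_tads=chain, changed_boundaries=gained,
            ))
    return events


# ---------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Hotspot:
    chrom: str
    start: int
    end: int
    type: str  # "dg" or "dl"
    count: int


def call_hotspots(
    boundaries: pd.DataFrame,
    kind: str,
    chrom_lengths: dict[str, int],
    window: int = HOTSPOT_WINDOW,
    min_count: int = HOTSPOT_MIN_COUNT,
) -> list[Hotspot]:
    """Regions with more than ``min_count`` changed boundaries per window.

    The genome is tiled into non-overlapping ``window``-bp tiles; a tile
    qualifies iff it holds strictly more than ``min_count`` boundaries of
    the given type, and consecutive qualifying tiles merge into one
    hotspot whose count is the total number of boundaries inside.
    """
    if kind not in ("dg", "dl"):
        raise InputError("hotspot kind must be 'dg' or 'dl'")
    out: list[Hotspot] = []
    for chrom, sub in boundaries.groupby("chrom"):
        if chrom not in chrom_lengths:
            raise InputError(f"boundaries on unknown chromosome {chrom!r}")
        clen = chrom_lengths[chrom]
        pos = np.sort(sub["pos"].to_numpy())
        n_tiles = int(np.ceil(clen / window)) or 1
        counts = np.bincount(np.minimum(pos // window, n_tiles - 1),
                             minlength=n_tiles)
        qual = counts > min_count
        k = 0
        while k < n_tiles:
            if not qual[k]:
                k += 1
                continue
            j = k
            while j + 1 < n_tiles and qual[j + 1]:
                j += 1
            start, end = k * window, min((j + 1) * window, clen)
            inside = int(((pos >= start) & (pos < end)).sum())
            out.append(Hotspot(chrom=chrom, start=start, end=end,
                               type=kind, count=inside))
            k = j + 1
    return out


def shared_hotspots(
    a: list[Hotspot], b: list[Hotspot]
) -> list[tuple[Hotspot, Hotspot]]:
    """Hotspot pairs from two samples whose intervals overlap >= 1 bp."""
    pairs = []
    for ha in a:
        for hb in b:
            if (ha.chrom == hb.chrom and ha.start < hb.end
                    and hb.start < ha.end):
                pairs.append((ha, hb))
    return pairs


def shared_percentage(shared: int, total: int) -> float:
    """Shared hotspots as a percentage, rounded to one decimal."""
    if total <= 0:
        raise InputError("total hotspot count must be positive")
    return round(100.0 * shared / total, 1)


# ---------------------------------------------------------------------
# genes near boundaries
# ---------------------------------------------------------------------

def genes_near_boundaries(
    boundaries: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 20_000,
) -> set[str]:
    """Genes overlapping ``[pos - window, pos + window)`` of any boundary.

    The default 20-kb per-side window follows the target-screen
    convention; 10 kb reproduces the narrower boundary-region convention
    used for DEG counting.
    """
    hits: set[str] = set()
    for chrom, sub in boundaries.groupby("chrom"):
        sel = genes["chrom"] == chrom
        if not sel.any():
            continue
        gs = genes.loc[sel, "start"].to_numpy()[:, None]
        ge = genes.loc[sel, "end"].to_numpy()[:, None]
        pos = sub["pos"].to_numpy()[None, :]
        hit = (gs < pos + window) & (ge > pos - window)
        hits |= set(genes.loc[sel, "gene_id"].to_numpy()[hit.any(axis=1)])
    return hits


# ---------------------------------------------------------------------
# 16-sample cross-variety pan set
# ---------------------------------------------------------------------

def build_cross_sample_pan(
    sample_sets: list[tuple[str, pd.DataFrame]],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Unified pan-boundary set over many samples (canonically 16).

    Reciprocal-best matching is run between every pair of sample sets;
    the connected components of the resulting match graph are the pan
    entries.  Each entry reports a representative position (leftmost
    member) and a presence flag per sample.  The construction is
    symmetric in the inputs, so the result is invariant to the order in
    which the sets are supplied.
    """
    keys = [k for k, _ in sample_sets]
    if len(set(keys)) != len(keys):
        raise InputError("duplicate sample keys in cross-sample pan input")
    g = nx.Graph()
    for k, df in sample_sets:
        for i in range(len(df)):
            g.add_node((k, i))
    for x in range(len(sample_sets)):
        for y in range(x + 1, len(sample_sets)):
            ka, da = sample_sets[x]
            kb, db = sample_sets[y]
            res = match_boundaries(da, db, flank=flank)
            for i, j in res.pairs:
                g.add_edge((ka, i), (kb, j))

    frames = dict(sample_sets)
    rows = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        positions = [(frames[k]["chrom"].iloc[i], frames[k]["pos"].iloc[i])
                     for k, i in members]
        chrom, pos = min(positions, key=lambda t: (t[0], t[1]))
        present = {f"present_{k}": any(m[0] == k for m in members)
                   for k in keys}
        rows.append({"chrom": chrom, "pos": pos,
                     "n_samples": sum(present.values()), **present})
    return (pd.DataFrame(rows)
            .sort_values(["chrom", "pos"], ignore_index=True))
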