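"""Synthetic allotetraploid drought study with ground truth.

Generates a miniature version of the study design — an A_t/D_t
allotetraploid genome with homoeolog pairs, an RNA-seq-like count matrix
with planted drought effects, and per-sample Hi-C contact matrices with
planted TADs, checkerboard A/B compartments and drought-induced TAD
fusion / neo-TAD events — together with truth labels for every
downstream stage of the analysis.

Randomness is split into one child stream per output family (genome,
expression, contacts), all derived from the master seed, so regenerating
one family never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bias as _bias
from .config import SimConfig
from .core import (
    CapacityError,
    Condition,
    DROUGHT_STAGES,
    ParameterError,
    STAGES,
    VARIETIES,
    subgenome_of,
)
from .hic import ContactMatrix

_STREAMS = ("genome", "expression", "contacts")


def _rng_for(config: SimConfig, family: str) -> np.random.Generator:
    idx = _STREAMS.index(family)
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


# =====================================================================
# genome
# =====================================================================

@dataclass
class Genome:
    """Chromosomes, gene intervals, homoeolog pairs, planted structure."""

    config: SimConfig
    chrom_lengths: dict[str, int]
    #: gene table: gene_id, chrom, start, end (0-based half-open), bin,
    #: phase (planted compartment of the containing bin), near_boundary
    genes: pd.DataFrame
    #: pair map: pair_id, gene_At, gene_Dt
    pairs: pd.DataFrame
    #: per chromosome, sorted *internal* TAD boundary bin indices of the
    #: baseline (control) partition; chromosome ends are implicit
    tad_boundaries: dict[str, list[int]] = field(default_factory=dict)
    #: per chromosome, the subset of internal boundaries (bin indices)
    #: where the compartment phase switches; these edges coincide with
    #: TAD boundaries, as compartment transitions do in real genomes
    phase_switches: dict[str, list[int]] = field(default_factory=dict)

    @property
    def bin_size(self) -> int:
        return self.config.bin_size

    def compartment_phase(self, chrom: str) -> np.ndarray:
        """Planted A/B label per bin (blocks of roughly one period, A first)."""
        return _phase_from_switches(
            self.phase_switches[chrom], self.config.n_bins
        )

    def gene_density(self, chrom: str) -> np.ndarray:
        """Genes per bin, used to orient compartment eigenvectors."""
        counts = np.zeros(self.config.n_bins)
        sub = self.genes[self.genes["chrom"] == chrom]
        np.add.at(counts, sub["bin"].to_numpy(), 1.0)
        return counts

    def control_tads(self, chrom: str) -> list[tuple[int, int]]:
        return _tads_from_boundaries(
            self.tad_boundaries[chrom], self.config.n_bins, self.bin_size
        )


def _tads_from_boundaries(
    internal: list[int], n_bins: int, bin_size: int
) -> list[tuple[int, int]]:
    cuts = [0, *internal, n_bins]
    return [(cuts[i] * bin_size, cuts[i + 1] * bin_size)
            for i in range(len(cuts) - 1)]


def min_tad_width_bins(config: SimConfig) -> int:
    return max(3, config.n_bins // (3 * config.tads_per_chrom))


def _phase_from_switches(switches: list[int], n_bins: int) -> np.ndarray:
    phase = np.zeros(n_bins, dtype=int)
    for b in switches:
        phase[b:] += 1
    return np.where(phase % 2 == 0, "A", "B")


def _pick_phase_switches(internal: list[int], period_bins: int,
                         n_bins: int) -> list[int]:
    """TAD boundaries nearest to each multiple of the compartment period."""
    switches: list[int] = []
    arr = np.asarray(internal)
    if not len(arr):
        return switches
    for target in range(period_bins, n_bins, period_bins):
        b = int(arr[np.argmin(np.abs(arr - target))])
        if b not in switches:
            switches.append(b)
    return sorted(switches)


def generate_genome(config: SimConfig) -> Genome:
    """Build the genome model: chromosomes, genes, pairs, TAD partition.

    Homoeologs are placed syntenically: the D-subgenome mirror of an
    A-subgenome chromosome carries its genes in the same bins, and the
    first ``round(homoeolog_fraction * n_genes / 2)`` positional matches
    form the pair map.  Gene-bearing bins are drawn with a 3:1 preference
    for planted A-compartment bins, so the A compartment is gene-rich.
    """
    rng = _rng_for(config, "genome")
    n_half = config.n_genes // 2
    n_pairs = round(config.homoeolog_fraction * config.n_genes / 2)
    if n_pairs > n_half:
        raise CapacityError(
            f"cannot form {n_pairs} pairs from {n_half} genes per subgenome"
        )

    chroms = config.chrom_names
    chrom_lengths = {c: config.chrom_length for c in chroms}

    # per-chromosome gene counts within a subgenome (even split)
    n_chrom = config.n_chrom_per_subgenome
    per_chrom = [n_half // n_chrom + (1 if i < n_half % n_chrom else 0)
                 for i in range(n_chrom)]
    if max(per_chrom, default=0) > config.n_bins:
        raise CapacityError(
            f"{max(per_chrom)} genes requested on a chromosome with only "
            f"{config.n_bins} placeable bins"
        )

    # TAD partition: drawn per A chromosome; the homoeologous D
    # chromosome shares it (synteny).  Compartment phase switches snap
    # to TAD boundaries nearest each multiple of the period.
    w_min = min_tad_width_bins(config)
    if config.tads_per_chrom * w_min > config.n_bins:
        raise CapacityError("tads_per_chrom exceeds what the binning allows")
    tad_boundaries: dict[str, list[int]] = {}
    phase_switches: dict[str, list[int]] = {}
    for ci in range(n_chrom):
        extra = rng.multinomial(
            config.n_bins - config.tads_per_chrom * w_min,
            np.full(config.tads_per_chrom, 1.0 / config.tads_per_chrom),
        )
        widths = w_min + extra
        internal = list(np.cumsum(widths)[:-1])
        switches = _pick_phase_switches(internal, config.period_bins,
                                        config.n_bins)
        for chrom in (chroms[ci], chroms[n_chrom + ci]):
            tad_boundaries[chrom] = list(internal)
            phase_switches[chrom] = list(switches)

    rows = []
    for ci in range(n_chrom):
        phase_ci = _phase_from_switches(phase_switches[chroms[ci]],
                                        config.n_bins)
        weights = np.where(phase_ci == "A", 3.0, 1.0)
        weights /= weights.sum()
        bins = np.sort(rng.choice(config.n_bins, size=per_chrom[ci],
                                  replace=False, p=weights))
        lengths = rng.integers(1000, 5001, size=per_chrom[ci])
        for sub_idx, sub in enumerate("AD"):
            chrom = chroms[ci] if sub == "A" else chroms[n_chrom + ci]
            for j, (b, ln) in enumerate(zip(bins, lengths)):
                start = int(b) * config.bin_size
                glen = int(min(ln, config.bin_size))
                rows.append((f"{chrom}G{j + 1:04d}", chrom, start,
                             start + glen, int(b)))
    extra_odd = config.n_genes - 2 * n_half
    if extra_odd:  # odd n_genes: one unpaired extra gene on the first A chrom
        chrom = chroms[0]
        used = {r[4] for r in rows if r[1] == chrom}
        free = [b for b in range(config.n_bins) if b not in used]
        if not free:
            raise CapacityError("no free bin left for the odd gene")
        b = free[0]
        rows.append((f"{chrom}GX{1:04d}", chrom, b * config.bin_size,
                     b * config.bin_size + 2000, b))

    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "bin"]
    ).sort_values(["chrom", "start"], ignore_index=True)
    phase_by_chrom = {
        c: _phase_from_switches(phase_switches[c], config.n_bins)
        for c in chroms
    }
    genes["phase"] = [
        phase_by_chrom[c][b] for c, b in zip(genes["chrom"], genes["bin"])
    ]

    # near-boundary flag: gene overlaps [b - 20 kb, b + 20 kb) of any
    # planted internal boundary of its chromosome
    flank = 20_000
    near = np.zeros(len(genes), dtype=bool)
    for chrom, bs in tad_boundaries.items():
        positions = np.array(bs) * config.bin_size
        sel = genes["chrom"] == chrom
        if not len(positions) or not sel.any():
            continue
        gs = genes.loc[sel, "start"].to_numpy()[:, None]
        ge = genes.loc[sel, "end"].to_numpy()[:, None]
        hit = ((gs < positions[None, :] + flank)
               & (ge > positions[None, :] - flank)).any(axis=1)
        near[sel.to_numpy()] = hit
    genes["near_boundary"] = near

    a_genes = genes[genes["chrom"].str.startswith("A")
                    & ~genes["gene_id"].str.contains("GX")]
    a_genes = a_genes.sort_values(["chrom", "bin"], ignore_index=True)
    pair_rows = []
    for k in range(n_pairs):
        ga = a_genes.iloc[k]
        gd = "D" + ga["gene_id"][1:]
        pair_rows.append((f"P{k + 1:05d}", ga["gene_id"], gd))
    pairs = pd.DataFrame(pair_rows,
                         columns=["pair_id", "gene_At", "gene_Dt"])
    if len(pairs):
        _bias.validate_pair_map(pairs,
                                genes.set_index("gene_id")["chrom"])

    return Genome(config=config, chrom_lengths=chrom_lengths, genes=genes,
                  pairs=pairs, tad_boundaries=tad_boundaries,
                  phase_switches=phase_switches)


# =====================================================================
# expression
# =====================================================================

@dataclass
class ExpressionTruth:
    #: per (gene, variety, stage): planted direction up / down / ns
    de: pd.DataFrame
    #: per (pair, variety, treatment, stage): planted bias state
    bias: pd.DataFrame
    #: per-gene response sign (+1 up, -1 down, 0 ns), for diagnostics
    response: pd.Series


@dataclass
class ExpressionResult:
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    sample_meta: pd.DataFrame
    truth: ExpressionTruth


def _planted_log2_effect(
    config: SimConfig,
    direction: np.ndarray,
    on_dt: np.ndarray,
    recovered: np.ndarray,
    stage: str,
) -> np.ndarray:
    """Drought-vs-control log2 shift per gene for one variety and stage."""
    supp = config.drought_suppression
    if stage in DROUGHT_STAGES:
        mag = float(supp.get(stage, 0.0))
        active = (direction != 0) & (mag > 0)
    else:  # RW: unrecovered genes retain the SD-level effect
        mag = float(supp.get("SD", 0.0))
        active = (direction != 0) & (mag > 0) & ~recovered
    eff = np.where(active, direction * mag, 0.0)
    eff = eff - np.where(active & on_dt, config.dt_extra_suppression, 0.0)
    return eff


def simulate_expression(genome: Genome, config: SimConfig) -> ExpressionResult:
    """Negative-binomial counts with planted drought effects + truth.

    log2 mean = gene baseline (log-normal, boosted for A-compartment and
    boundary-proximal genes) + treatment effect.  Under drought the
    planted effect is ``direction x suppression[stage]`` with an extra
    downward shift for responsive D_t genes; at RW it persists only for
    genes that did not recover.  An FPKM-like matrix
    (counts / (gene kb x library millions)) is emitted alongside counts.
    """
    if config.dispersion <= 0:
        raise ParameterError("dispersion must be positive")
    rng = _rng_for(config, "expression")
    genes = genome.genes
    n = len(genes)

    baseline = rng.normal(config.baseline_log2_mean,
                          config.baseline_log2_sd, n)
    # homoeologs diverge from a shared ancestral level rather than
    # being independent draws
    if len(genome.pairs):
        gidx_b = pd.Index(genes["gene_id"])
        ia_b = gidx_b.get_indexer(genome.pairs["gene_At"])
        id_b = gidx_b.get_indexer(genome.pairs["gene_Dt"])
        baseline[id_b] = baseline[ia_b] + rng.normal(
            0.0, config.pair_baseline_divergence_sd, len(genome.pairs))
    baseline += np.where(genes["phase"] == "A",
                         config.a_compartment_boost, 0.0)
    baseline += np.where(genes["near_boundary"],
                         config.boundary_expression_boost, 0.0)

    u = rng.random(n)
    direction = np.where(u < config.frac_down, -1,
                         np.where(u < config.frac_down + config.frac_up,
                                  1, 0))
    # homoeolog pairs respond concordantly: the D_t member inherits its
    # partner's class with probability pair_response_concordance
    if len(genome.pairs):
        gidx0 = pd.Index(genes["gene_id"])
        ia0 = gidx0.get_indexer(genome.pairs["gene_At"])
        id0 = gidx0.get_indexer(genome.pairs["gene_Dt"])
        inherit = rng.random(len(genome.pairs)) < (
            config.pair_response_concordance)
        direction[id0[inherit]] = direction[ia0[inherit]]
    on_dt = genes["chrom"].map(subgenome_of).to_numpy() == "D"
    recovered = {
        v: rng.random(n) < config.recovery_fraction[v] for v in VARIETIES
    }

    # true log2 means per (variety, treatment, stage)
    log2_mean: dict[Condition, np.ndarray] = {}
    for v in VARIETIES:
        for s in STAGES:
            log2_mean[Condition(v, "C", s)] = baseline.copy()
            log2_mean[Condition(v, "D", s)] = baseline + _planted_log2_effect(
                config, direction, on_dt, recovered[v], s
            )

    sample_ids, meta_rows, cols = [], [], []
    for v, t, s, r in config.design:
        sid = f"{v}_{t}_{s}_r{r}"
        sample_ids.append(sid)
        meta_rows.append((sid, v, t, s, r))
        mu = log2_mean[Condition(v, t, s)]
        noise = (rng.normal(0.0, config.expression_noise_sd, n)
                 if config.expression_noise_sd > 0 else 0.0)
        lam = 2.0 ** (mu + noise)
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, lam * config.dispersion)
        cols.append(rng.poisson(lam))
    counts = pd.DataFrame(np.column_stack(cols),
                          index=genes["gene_id"], columns=sample_ids)
    sample_meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "variety", "treatment", "stage", "replicate"],
    )

    glen_kb = (genes["end"] - genes["start"]).to_numpy() / 1000.0
    libsize_m = counts.sum(axis=0).to_numpy() / 1e6
    libsize_m[libsize_m == 0] = 1.0  # degenerate all-zero library
    fpkm = counts / glen_kb[:, None] / libsize_m[None, :]

    # --- truth labels -------------------------------------------------
    de_rows = []
    for v in VARIETIES:
        for s in STAGES:
            eff = log2_mean[Condition(v, "D", s)] - log2_mean[
                Condition(v, "C", s)]
            lab = np.where(eff > 0, "up", np.where(eff < 0, "down", "ns"))
            de_rows.append(pd.DataFrame({
                "gene": genes["gene_id"], "variety": v, "stage": s,
                "direction": lab,
            }))
    truth_de = pd.concat(de_rows, ignore_index=True)

    bias_rows = []
    if len(genome.pairs):
        gidx = pd.Index(genes["gene_id"])
        ia = gidx.get_indexer(genome.pairs["gene_At"])
        idp = gidx.get_indexer(genome.pairs["gene_Dt"])
        for cond, mu in log2_mean.items():
            fa = 2.0 ** mu[ia] / glen_kb[ia]
            fd = 2.0 ** mu[idp] / glen_kb[idp]
            state = _bias.call_bias_state(fa, fd)
            bias_rows.append(pd.DataFrame({
                "pair_id": genome.pairs["pair_id"],
                "variety": cond.variety, "treatment": cond.treatment,
                "stage": cond.stage, "state": state,
            }))
    truth_bias = (pd.concat(bias_rows, ignore_index=True) if bias_rows
                  else pd.DataFrame(columns=["pair_id", "variety",
                                             "treatment", "stage", "state"]))

    truth = ExpressionTruth(
        de=truth_de, bias=truth_bias,
        response=pd.Series(direction, index=genes["gene_id"],
                           name="response"),
    )
    return ExpressionResult(counts=counts, fpkm=fpkm,
                            sample_meta=sample_meta, truth=truth)


# =====================================================================
# contact maps
# =====================================================================

@dataclass(frozen=True)
class PlantedEvent:
    condition: Condition
    chrom: str
    type: str  # "fusion" (boundary removed) or "neo" (boundary added)
    boundary_bp: int
    control_tads: tuple[tuple[int, int], ...]
    drought_tads: tuple[tuple[int, int], ...]


@dataclass
class ContactTruth:
    #: per condition, per chromosome: TAD intervals (bp, half-open)
    tads: dict[Condition, dict[str, list[tuple[int, int]]]]
    #: per chromosome: planted A/B label per bin
    compartments: dict[str, np.ndarray]
    events: list[PlantedEvent]
    #: chromosomes never perturbed by planted events
    unperturbed_chroms: list[str]


@dataclass
class ContactMapsResult:
    maps: dict[Condition, dict[str, ContactMatrix]]
    truth: ContactTruth


def _plant_events(
    rng: np.random.Generator,
    genome: Genome,
    config: SimConfig,
    cond: Condition,
    eligible: list[str],
) -> tuple[dict[str, list[int]], list[PlantedEvent]]:
    """Pick fusion (remove) and neo (add) boundaries for one drought sample.

    Candidates are enumerated leftmost-first per chromosome; the stream
    draws a permutation and candidates are accepted greedily under the
    non-interference constraints (no two removed boundaries adjacent, neo
    splits only TADs untouched by a fusion and wide enough to host two
    sub-TADs).
    """
    w_min = min_tad_width_bins(config)
    bsz = config.bin_size
    boundaries = {c: list(genome.tad_boundaries[c]) for c in eligible}

    # compartment switch points stay put under drought: fusing across a
    # compartment transition would leave a residual insulation edge
    fusion_cands = [
        (c, i) for c in eligible for i in range(len(boundaries[c]))
        if boundaries[c][i] not in genome.phase_switches[c]
    ]
    order = rng.permutation(len(fusion_cands))
    removed: dict[str, set[int]] = {c: set() for c in eligible}
    n_removed = 0
    for k in order:
        c, i = fusion_cands[k]
        if n_removed == config.n_fusion:
            break
        if {i - 1, i + 1} & removed[c]:
            continue  # adjacent removals would merge >2 TADs into one event
        removed[c].add(i)
        n_removed += 1
    if n_removed < config.n_fusion:
        raise CapacityError(
            f"cannot plant {config.n_fusion} fusion events: only "
            f"{n_removed} non-adjacent internal boundaries available"
        )

    events: list[PlantedEvent] = []
    new_bounds: dict[str, list[int]] = {}
    fused_tads: dict[str, set[int]] = {c: set() for c in eligible}
    for c in eligible:
        internal = boundaries[c]
        cuts = [0, *internal, config.n_bins]
        for i in sorted(removed[c]):
            left = (cuts[i] * bsz, cuts[i + 1] * bsz)
            right = (cuts[i + 1] * bsz, cuts[i + 2] * bsz)
            events.append(PlantedEvent(
                condition=cond, chrom=c, type="fusion",
                boundary_bp=internal[i] * bsz,
                control_tads=(left, right),
                drought_tads=((left[0], right[1]),),
            ))
            fused_tads[c] |= {i, i + 1}
        new_bounds[c] = [b for j, b in enumerate(internal)
                         if j not in removed[c]]

    neo_cands = []
    for c in eligible:
        cuts = [0, *boundaries[c], config.n_bins]
        for t in range(len(cuts) - 1):
            if t in fused_tads[c]:
                continue
            if cuts[t + 1] - cuts[t] >= 2 * w_min:
                neo_cands.append((c, t))
    order = rng.permutation(len(neo_cands))
    chosen = [neo_cands[k] for k in order[: config.n_neo]]
    if len(chosen) < config.n_neo:
        raise CapacityError(
            f"cannot plant {config.n_neo} neo events: only "
            f"{len(neo_cands)} splittable TADs available"
        )
    for c, t in sorted(chosen):
        cuts = [0, *boundaries[c], config.n_bins]
        s, e = cuts[t], cuts[t + 1]
        mid = s + (e - s) // 2
        new_bounds[c] = sorted(new_bounds[c] + [mid])
        events.append(PlantedEvent(
            condition=cond, chrom=c, type="neo", boundary_bp=mid * bsz,
            control_tads=((s * bsz, e * bsz),),
            drought_tads=((s * bsz, mid * bsz), (mid * bsz, e * bsz)),
        ))
    return new_bounds, events


def _build_matrix(
    rng: np.random.Generator,
    config: SimConfig,
    phase: np.ndarray,
    internal_boundaries: list[int],
) -> np.ndarray:
    n = config.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = config.contact_depth * (1.0 + d) ** (-config.decay_exponent)
    s = np.where(phase == "A", 1.0, -1.0)
    comp = 1.0 + config.checkerboard_amplitude * np.outer(s, s)
    tad_id = np.searchsorted(internal_boundaries, np.arange(n), side="right")
    tad = np.where(np.equal.outer(tad_id, tad_id),
                   config.tad_enrichment, 1.0)
    m = base * comp * tad
    if config.contact_noise_sd > 0:
        z = rng.normal(0.0, config.contact_noise_sd, (n, n))
        z = np.triu(z) + np.triu(z, 1).T  # symmetric noise field
        m = m * np.exp(z)
    return m


def simulate_contact_maps(
    genome: Genome, config: SimConfig
) -> ContactMapsResult:
    """Per-condition contact matrices with planted structures + truth.

    Control samples share the baseline TAD partition; each drought sample
    carries ``n_fusion`` planted fusions (internal boundary removed) and
    ``n_neo`` planted neo-TAD splits (internal boundary added), never on
    the last D-subgenome chromosome, which serves as an unperturbed
    negative control.
    """
    rng = _rng_for(config, "contacts")
    chroms = config.chrom_names
    unperturbed = [chroms[-1]]
    eligible = [c for c in chroms if c not in unperturbed]

    phase = {c: genome.compartment_phase(c) for c in chroms}
    truth_tads: dict[Condition, dict[str, list[tuple[int, int]]]] = {}
    events: list[PlantedEvent] = []
    maps: dict[Condition, dict[str, ContactMatrix]] = {}

    for v in VARIETIES:
        for t in ("C", "D"):
            for s in STAGES:
                cond = Condition(v, t, s)
                bounds = {c: list(genome.tad_boundaries[c]) for c in chroms}
                if t == "D":
                    new_bounds, evs = _plant_events(
                        rng, genome, config, cond, eligible
                    )
                    bounds.update(new_bounds)
                    events.extend(evs)
                truth_tads[cond] = {
                    c: _tads_from_boundaries(bounds[c], config.n_bins,
                                             config.bin_size)
                    for c in chroms
                }
                maps[cond] = {
                    c: ContactMatrix(
                        chrom=c, bin_size=config.bin_size,
                        matrix=_build_matrix(rng, config, phase[c],
                                             bounds[c]),
                    )
                    for c in chroms
                }

    truth = ContactTruth(tads=truth_tads, compartments=phase,
                         events=events, unperturbed_chroms=unperturbed)
    return ContactMapsResult(maps=maps, truth=truth)


# =====================================================================
# bundle
# =====================================================================

@dataclass
class SyntheticStudy:
    config: SimConfig
    genome: Genome
    expression: ExpressionResult
    contacts: ContactMapsResult


def simulate_study(config: SimConfig) -> SyntheticStudy:
    genome = generate_genome(config)
    return SyntheticStudy(
        config=config,
        genome=genome,
        expression=simulate_expression(genome, config),
        contacts=simulate_contact_maps(genome, config),
    )
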