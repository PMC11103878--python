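"""Simulation configuration.

:class:`SimConfig` holds every knob of the synthetic study generator.  The
defaults describe a miniature but complete version of the study design:
two varieties x two treatments x four stages x two replicates, two
chromosomes per subgenome, drought suppression that deepens with stage and
hits the D_t subgenome harder, and contact maps with planted topologically
associating domains (TADs), checkerboard A/B compartments, and planted
fusion / neo-TAD events on drought samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import (
    Condition,
    ParameterError,
    STAGES,
    TREATMENTS,
    VARIETIES,
)


def full_factorial_design(n_replicates: int = 2) -> list[tuple[str, str, str, int]]:
    """Every (variety, treatment, stage, replicate) cell of the study."""
    return [
        (v, t, s, r)
        for v in VARIETIES
        for t in TREATMENTS
        for s in STAGES
        for r in range(1, n_replicates + 1)
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic allotetraploid drought study.

    Genome geometry
    ---------------
    ``n_chrom_per_subgenome`` chromosomes per subgenome, each of
    ``chrom_length`` bp, binned at ``bin_size`` bp for contact maps.

    Expression model
    ----------------
    Counts are negative binomial with a log-normal gene baseline
    (``baseline_log2_mean`` / ``baseline_log2_sd`` on the log2 scale) and
    gene-level dispersion ``dispersion``.  A fraction of genes respond to
    drought (``frac_down`` down, ``frac_up`` up) with a stage-dependent
    log2 magnitude ``drought_suppression``; responsive D_t genes receive an
    extra downward shift ``dt_extra_suppression`` (the subgenome asymmetry).
    At RW each responsive gene has recovered (back to control mean) with
    variety-specific probability ``recovery_fraction``.

    Contact model
    -------------
    matrix = depth x (1+d)^-decay_exponent x compartment checkerboard
    (amplitude ``checkerboard_amplitude``, block period
    ``compartment_period``) x intra-TAD enrichment ``tad_enrichment``
    x multiplicative log-normal noise (``contact_noise_sd``).  Drought
    samples carry ``n_fusion`` removed and ``n_neo`` added internal TAD
    boundaries per sample; the last D-subgenome chromosome is left
    unperturbed as a negative control.
    """

    seed: int = 0

    # genome geometry
    n_chrom_per_subgenome: int = 2
    chrom_length: int = 6_000_000
    bin_size: int = 20_000
    n_genes: int = 800
    homoeolog_fraction: float = 0.8

    # design
    design: list[tuple[str, str, str, int]] = field(
        default_factory=full_factorial_design
    )

    # expression effect parameters (log2 scale unless noted)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.1
    drought_suppression: dict[str, float] = field(
        default_factory=lambda: {"ID": 1.0, "MD": 1.8, "SD": 2.5}
    )
    dt_extra_suppression: float = 0.5
    recovery_fraction: dict[str, float] = field(
        default_factory=lambda: {"sensitive": 0.3, "tolerant": 0.85}
    )
    frac_down: float = 0.30
    frac_up: float = 0.15
    #: probability that the D_t member of a homoeolog pair inherits its
    #: partner's drought-response class; high concordance mirrors the
    #: predominance of same-direction ("common") pair responses
    pair_response_concordance: float = 0.9
    #: log2 SD of the baseline divergence between homoeolog partners;
    #: homoeologs share an ancestral expression level, so their baseline
    #: ratio is much tighter than two random genes'
    pair_baseline_divergence_sd: float = 1.0
    expression_noise_sd: float = 0.25
    a_compartment_boost: float = 1.0
    boundary_expression_boost: float = 0.75

    # contact structure parameters
    tads_per_chrom: int = 12
    tad_enrichment: float = 2.0
    decay_exponent: float = 1.0
    compartment_period: int = 600_000
    checkerboard_amplitude: float = 0.3
    contact_depth: float = 100.0
    contact_noise_sd: float = 0.1
    n_fusion: int = 2
    n_neo: int = 2

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")
        for name in (
            "n_chrom_per_subgenome",
            "chrom_length",
            "bin_size",
            "n_genes",
            "compartment_period",
            "tads_per_chrom",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 <= self.homoeolog_fraction <= 1.0:
            raise ParameterError("homoeolog_fraction must lie in [0, 1]")
        for name in ("frac_down", "frac_up", "pair_response_concordance"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.frac_down + self.frac_up > 1.0:
            raise ParameterError("frac_down + frac_up must not exceed 1")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        if self.tad_enrichment <= 1.0:
            raise ParameterError("tad_enrichment must exceed 1")
        if self.chrom_length % self.bin_size:
            raise ParameterError("bin_size must divide chrom_length")
        if self.compartment_period % self.bin_size:
            raise ParameterError("bin_size must divide compartment_period")
        for v, f in self.recovery_fraction.items():
            if v not in VARIETIES or not 0.0 <= f <= 1.0:
                raise ParameterError(
                    "recovery_fraction maps each variety to a value in [0, 1]"
                )
        supp = self.drought_suppression
        if set(supp) - set(STAGES):
            raise ParameterError("drought_suppression keys must be stages")
        if any(s < 0 for s in supp.values()):
            raise ParameterError(
                "drought_suppression magnitudes are non-negative"
            )
        positive = [s for s in supp.values() if s > 0]
        if positive and self.dt_extra_suppression >= min(positive):
            # otherwise the extra D_t shift could flip a planted direction
            # and the truth labels would no longer match the model means
            raise ParameterError(
                "dt_extra_suppression must be smaller than every non-zero "
                "per-stage drought suppression magnitude"
            )
        if self.dt_extra_suppression < 0:
            raise ParameterError("dt_extra_suppression must be >= 0")
        cells = {(v, t, s) for (v, t, s, _r) in self.design}
        required = {
            (v, t, s) for v in VARIETIES for t in TREATMENTS for s in STAGES
        }
        missing = required - cells
        if missing:
            raise ParameterError(
                f"design is missing {len(missing)} (variety, treatment, stage)"
                f" cells, e.g. {sorted(missing)[0]}"
            )
        for v, t, s, r in self.design:
            Condition(v, t, s).validate()
            if r < 1:
                raise ParameterError("replicate indices start at 1")

    # -- derived geometry ------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.chrom_length // self.bin_size

    @property
    def period_bins(self) -> int:
        return self.compartment_period // self.bin_size

    @property
    def chrom_names(self) -> list[str]:
        n = self.n_chrom_per_subgenome
        return [f"A{i:02d}" for i in range(1, n + 1)] + [
            f"D{i:02d}" for i in range(1, n + 1)
        ]

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["design"] = [list(cell) for cell in self.design]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "design" in data:
            data["design"] = [tuple(cell) for cell in data["design"]]
        return cls(**data)
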