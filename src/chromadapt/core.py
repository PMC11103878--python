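"""Shared vocabularies, keys and error types.

The study design is a 2 x 2 x 4 factorial: two varieties of an
allotetraploid (one drought-sensitive, one drought-tolerant), two water
regimes (C = well-watered control, D = drought), and four sampling stages
(ID = initial drought, MD = mild drought, SD = severe drought, RW =
re-watered). Chromosomes belong to one of two subgenomes, named with an
``A``/``D`` prefix (A_t and D_t).
"""

from __future__ import annotations

from typing import NamedTuple

VARIETIES: tuple[str, str] = ("sensitive", "tolerant")
TREATMENTS: tuple[str, str] = ("C", "D")
STAGES: tuple[str, str, str, str] = ("ID", "MD", "SD", "RW")
#: Stages during which drought stress is applied; RW is reserved for the
#: recovery analysis and never contributes to drought-induced calling.
DROUGHT_STAGES: tuple[str, str, str] = ("ID", "MD", "SD")

SUBGENOMES: tuple[str, str] = ("A", "D")


class Condition(NamedTuple):
    """One cell of the factorial design (replicates merged)."""

    variety: str
    treatment: str
    stage: str

    def validate(self) -> "Condition":
        if self.variety not in VARIETIES:
            raise InputError(f"unknown variety {self.variety!r}")
        if self.treatment not in TREATMENTS:
            raise InputError(f"unknown treatment {self.treatment!r}")
        if self.stage not in STAGES:
            raise InputError(f"unknown stage {self.stage!r}")
        return self

    @property
    def label(self) -> str:
        return f"{self.variety}_{self.treatment}_{self.stage}"


def all_conditions() -> list[Condition]:
    """The 16 merged samples in canonical (variety, treatment, stage) order."""
    return [
        Condition(v, t, s)
        for v in VARIETIES
        for t in TREATMENTS
        for s in STAGES
    ]


def subgenome_of(chrom: str) -> str:
    """Subgenome of a chromosome from its naming prefix (``A01`` -> ``A``)."""
    if not chrom or chrom[0] not in SUBGENOMES:
        raise InputError(
            f"chromosome {chrom!r} carries no A/D subgenome prefix"
        )
    return chrom[0]


class ChromadaptError(Exception):
    """Base class for package errors."""


class InputError(ChromadaptError, ValueError):
    """Malformed or inconsistent user input."""


class ParameterError(ChromadaptError, ValueError):
    """Invalid configuration or operation parameter."""


class CapacityError(ChromadaptError, ValueError):
    """A request exceeds what the simulated genome can accommodate."""


class DegenerateInputError(ChromadaptError, ValueError):
    """Input is formally valid but carries no usable signal."""
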