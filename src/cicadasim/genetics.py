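"""One-locus diploid genetics of emergence strategies.

A single locus carries either a *size-based* emergence allele (emerge the
summer after reaching a threshold body size) or an *age-based* allele with a
fixed cycle length in years.  Size-based emergence is dominant; two age-based
alleles produce an age-based phenotype whose cycle length is the average of
the two allele cycle lengths, rounded up or down at random (probability 1/2
each) when the average is not an integer.  This averaging is what makes
between-cycle matings produce hybrid offspring with an intermediate cycle --
the phenomenon the rest of the package is built to study.

Alleles are represented compactly as non-negative integers throughout the
simulation engines: ``0`` encodes the size-based allele, ``c >= 1`` encodes an
age-based allele with cycle length ``c``.  The dataclasses below are the
user-facing forms; :func:`allele_code` / :func:`allele_from_code` convert.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "EmergenceKind",
    "Allele",
    "Genotype",
    "Phenotype",
    "SIZE_CODE",
    "MAX_MUTANT_CYCLE",
    "allele_code",
    "allele_from_code",
    "resolve_phenotype",
    "resolve_phenotype_code",
    "mutate_allele",
    "mutate_allele_code",
    "make_offspring_genotype",
]

#: Integer code of the size-based allele.
SIZE_CODE = 0

#: Upper bound of the cycle length drawn when a size-based allele mutates
#: into an age-based one (uniform on 1..30).
MAX_MUTANT_CYCLE = 30


class EmergenceKind(str, Enum):
    SIZE = "SIZE"
    AGE = "AGE"


@dataclass(frozen=True)
class Allele:
    """An emergence allele: size-based, or age-based with a cycle length."""

    kind: EmergenceKind
    cycle_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind is EmergenceKind.AGE:
            if self.cycle_length is None or self.cycle_length < 1:
                raise ValueError("AGE allele requires cycle_length >= 1")
        elif self.cycle_length is not None:
            raise ValueError("SIZE allele carries no cycle length")

    def __str__(self) -> str:
        if self.kind is EmergenceKind.SIZE:
            return "SIZE"
        return f"AGE:{self.cycle_length}"


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of alleles; parental origin is not tracked."""

    allele_a: Allele
    allele_b: Allele

    @property
    def heterozygous(self) -> bool:
        return self.allele_a != self.allele_b

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"


@dataclass(frozen=True)
class Phenotype:
    kind: EmergenceKind
    emergence_age: int | None = None

    def __post_init__(self) -> None:
        if self.kind is EmergenceKind.AGE:
            if self.emergence_age is None or self.emergence_age < 1:
                raise ValueError("AGE phenotype requires emergence_age >= 1")
        elif self.emergence_age is not None:
            raise ValueError("SIZE phenotype carries no emergence age")


def allele_code(allele: Allele) -> int:
    """Integer code of an allele (0 = SIZE, c = AGE with cycle length c)."""
    return SIZE_CODE if allele.kind is EmergenceKind.SIZE else int(allele.cycle_length)


def allele_from_code(code: int) -> Allele:
    if code == SIZE_CODE:
        return Allele(EmergenceKind.SIZE)
    return Allele(EmergenceKind.AGE, int(code))


def resolve_phenotype_code(code_a: int, code_b: int, rng: np.random.Generator) -> int:
    """Phenotype code from two allele codes.

    Size-based emergence is dominant: if either allele is size-based the
    phenotype is size-based (code 0).  Two age-based alleles average; a
    half-integer average is rounded up or down with probability 1/2 each.
    """
    if code_a == SIZE_CODE or code_b == SIZE_CODE:
        return SIZE_CODE
    total = code_a + code_b
    if total % 2 == 0:
        return total // 2
    return total // 2 + (1 if rng.random() < 0.5 else 0)


def resolve_phenotype(genotype: Genotype, rng: np.random.Generator) -> Phenotype:
    code = resolve_phenotype_code(
        allele_code(genotype.allele_a), allele_code(genotype.allele_b), rng
    )
    if code == SIZE_CODE:
        return Phenotype(EmergenceKind.SIZE)
    return Phenotype(EmergenceKind.AGE, code)


def mutate_allele_code(code: int, rng: np.random.Generator) -> int:
    """Mutated allele code.

    An age-based allele mutates to size-based with probability 1/2, otherwise
    its cycle length changes by one year (longer or shorter with equal
    probability; a one-year cycle cannot shrink and stays at one).  A
    size-based allele mutates to an age-based allele with a cycle length
    drawn uniformly from 1..30.  The +/-1 step of an age-based allele is not
    capped at 30; the 1..30 range applies only to the size-to-age mutation.
    """
    if code == SIZE_CODE:
        return int(rng.integers(1, MAX_MUTANT_CYCLE + 1))
    if rng.random() < 0.5:
        return SIZE_CODE
    if rng.random() < 0.5:
        return max(1, code - 1)
    return code + 1


def mutate_allele(allele: Allele, rng: np.random.Generator) -> Allele:
    return allele_from_code(mutate_allele_code(allele_code(allele), rng))


def make_offspring_genotype(
    mother: Genotype,
    father: Genotype,
    mutation_prob: float,
    rng: np.random.Generator,
) -> Genotype:
    """Offspring genotype: one allele drawn uniformly from each parent,
    each transmitted allele independently mutated with ``mutation_prob``."""
    if not 0.0 <= mutation_prob <= 1.0:
        raise ValueError("mutation_prob must be a probability")
    codes = []
    for parent in (mother, father):
        pair = (allele_code(parent.allele_a), allele_code(parent.allele_b))
        code = pair[0] if rng.random() < 0.5 else pair[1]
        if mutation_prob > 0.0 and rng.random() < mutation_prob:
            code = mutate_allele_code(code, rng)
        codes.append(code)
    return Genotype(allele_from_code(codes[0]), allele_from_code(codes[1]))
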