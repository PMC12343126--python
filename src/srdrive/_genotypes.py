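"""Genotype classes shared across the package.

An X-linked locus with a driving allele ``SR`` and a standard allele ``ST``
yields exactly five genotype classes: hemizygous males (one X) and the three
female diplotypes.
"""

from __future__ import annotations

import enum


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Genotype(enum.Enum):
    """The five genotype classes of an X-linked two-allele drive system."""

    SR = ("SR", Sex.MALE, ("SR",))
    ST = ("ST", Sex.MALE, ("ST",))
    SRSR = ("SRSR", Sex.FEMALE, ("SR", "SR"))
    SRST = ("SRST", Sex.FEMALE, ("SR", "ST"))
    STST = ("STST", Sex.FEMALE, ("ST", "ST"))

    def __init__(self, token: str, sex: Sex, alleles: tuple[str, ...]):
        self.token = token
        self.sex = sex
        self.alleles = alleles

    @property
    def carries_drive(self) -> bool:
        return "SR" in self.alleles

    @classmethod
    def from_token(cls, token: str) -> "Genotype":
        try:
            return _TOKEN_MAP[token]
        except KeyError:
            raise ValueError(
                f"unknown genotype token {token!r}; expected one of "
                f"{sorted(_TOKEN_MAP)}"
            ) from None


_TOKEN_MAP = {g.token: g for g in Genotype}

#: Canonical ordering used for abundance vectors: males first, then females.
GENOTYPE_ORDER: tuple[Genotype, ...] = (
    Genotype.SR,
    Genotype.ST,
    Genotype.SRSR,
    Genotype.SRST,
    Genotype.STST,
)
GENOTYPE_INDEX = {g: i for i, g in enumerate(GENOTYPE_ORDER)}
GENOTYPE_TOKENS = tuple(g.token for g in GENOTYPE_ORDER)

MALE_GENOTYPES: tuple[Genotype, ...] = (Genotype.SR, Genotype.ST)
FEMALE_GENOTYPES: tuple[Genotype, ...] = (
    Genotype.SRSR,
    Genotype.SRST,
    Genotype.STST,
)
FEMALE_TOKENS = tuple(g.token for g in FEMALE_GENOTYPES)
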