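"""Exact analytics of the segregational model of karyotype sorting.

A hybrid heterozygous at ``n`` fusion sites forms ``n`` trivalents, each of
which segregates into one of two balanced configurations independently.
The hybrid therefore produces ``2^n`` balanced gamete types, each with
frequency ``1/2^n``.  Crossing two such gamete pools gives a Punnett square
whose homozygous zygotes lie on a diagonal with as many cells as there are
gamete types; only the first and last diagonal cells reconstitute the
parental karyotypes, so the fraction of homozygous *classes* carrying a
novel karyotype is

    r = 1 - 2 / 2^n

which rises from 0 at n = 1 to 0.99999988 at n = 24.  Novel homozygotes
carry intermediate diploid chromosome numbers, the seed of a homoploid
hybrid species.

All probabilities are exact rationals; floats appear only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Sequence

from .architecture import (
    FUSED,
    UNFUSED,
    ArchitectureMismatchError,
    DiploidGenotype,
    FusionArchitecture,
    GameteHaplotype,
    meiotic_figure,
)

__all__ = [
    "EnumerationSizeError",
    "GameteEnumeration",
    "ZygoteClass",
    "PunnettResult",
    "enumerate_balanced_gametes",
    "punnett_square",
    "novel_homozygote_fraction",
    "PARENTAL_P1",
    "PARENTAL_P2",
    "NOVEL_HOMOZYGOTE",
    "HETEROZYGOTE",
]

PARENTAL_P1 = "parental_P1"
PARENTAL_P2 = "parental_P2"
NOVEL_HOMOZYGOTE = "novel_homozygote"
HETEROZYGOTE = "heterozygote"

#: Above this many gamete types, enumerations stay analytic (no list).
DEFAULT_MATERIALIZE_LIMIT = 2**16


class EnumerationSizeError(ValueError):
    """An operation needed a materialized enumeration that is analytic-only."""


@dataclass(frozen=True)
class GameteEnumeration:
    """Balanced gametes of one genotype: ``2^h`` types of frequency ``1/2^h``.

    ``gametes`` is ``None`` when the enumeration exceeded the materialize
    limit; counts and frequencies remain exact either way.
    """

    genotype: DiploidGenotype
    total_count: int
    frequency: Fraction
    gametes: tuple[GameteHaplotype, ...] | None

    @property
    def materialized(self) -> bool:
        return self.gametes is not None

    @property
    def architecture(self) -> FusionArchitecture:
        return self.genotype.architecture


def enumerate_balanced_gametes(
    genotype: DiploidGenotype,
    materialize_limit: int = DEFAULT_MATERIALIZE_LIMIT,
) -> GameteEnumeration:
    """All balanced gametes of a genotype.

    Each heterozygous site transmits either allele; homozygous sites
    transmit their allele unchanged.  The list of gamete objects is built
    only when ``2^h <= materialize_limit``; otherwise the enumeration is
    analytic (``total_count`` and ``frequency`` only), so a fully
    heterozygous 24-site hybrid (2^24 = 16,777,216 types) costs nothing.
    """
    het = genotype.heterozygous_sites
    total = 2 ** len(het)
    freq = Fraction(1, total)
    gametes: tuple[GameteHaplotype, ...] | None = None
    if total <= materialize_limit:
        base = [pair[0] for pair in genotype.alleles]  # homozygous: either copy
        out = []
        for combo in product((UNFUSED, FUSED), repeat=len(het)):
            alleles = list(base)
            for site, allele in zip(het, combo):
                alleles[site] = allele
            out.append(GameteHaplotype(genotype.architecture, tuple(alleles)))
        gametes = tuple(out)
    return GameteEnumeration(genotype, total, freq, gametes)


@dataclass(frozen=True)
class ZygoteClass:
    """One distinct zygote genotype of a Punnett square."""

    genotype: DiploidGenotype
    probability: Fraction
    classification: str
    m: int  # diploid chromosome number of the class's meiotic figure

    @property
    def h(self) -> int:
        return self.genotype.h


@dataclass(frozen=True)
class PunnettResult:
    """Zygote classes of a cross between two balanced-gamete pools."""

    classes: tuple[ZygoteClass, ...]
    cell_count: int  # full ordered square, (2^h_a) * (2^h_b)
    homozygous_class_count: int
    r: Fraction  # novel fraction among homozygous classes
    parent_p1: DiploidGenotype
    parent_p2: DiploidGenotype

    @property
    def novel_classes(self) -> tuple[ZygoteClass, ...]:
        return tuple(c for c in self.classes if c.classification == NOVEL_HOMOZYGOTE)

    def by_classification(self) -> dict[str, list[ZygoteClass]]:
        out: dict[str, list[ZygoteClass]] = {}
        for c in self.classes:
            out.setdefault(c.classification, []).append(c)
        return out


def _encode(gamete: GameteHaplotype) -> int:
    bits = 0
    for i, a in enumerate(gamete.alleles):
        if a == FUSED:
            bits |= 1 << i
    return bits


def _decode_pairs(lo: int, hi: int, n_sites: int) -> tuple[tuple[int, int], ...]:
    return tuple(((lo >> i) & 1, (hi >> i) & 1) for i in range(n_sites))


def _default_parents(
    genotype_a: DiploidGenotype, genotype_b: DiploidGenotype
) -> tuple[DiploidGenotype, DiploidGenotype]:
    """Infer parental homozygotes: all-unfused (P1) vs all-fused (P2) over
    the variable sites.

    Exact for the canonical case — an F1 (or its selfing) of two homozygous
    races that differ only in fusion state.  Pass explicit parents for
    anything more exotic.
    """
    arch = genotype_a.architecture
    p1, p2 = [], []
    for (a1, b1), (a2, b2) in zip(genotype_a.alleles, genotype_b.alleles):
        options = {a1, b1, a2, b2}
        p1.append((min(options),) * 2)
        p2.append((max(options),) * 2)
    return DiploidGenotype(arch, tuple(p1)), DiploidGenotype(arch, tuple(p2))


def punnett_square(
    enum_a: GameteEnumeration,
    enum_b: GameteEnumeration,
    parents: tuple[DiploidGenotype, DiploidGenotype] | None = None,
) -> PunnettResult:
    """Cross two materialized gamete enumerations into zygote classes.

    All ordered gamete pairs are formed; zygotes identical as unordered
    per-site allele pairs are merged into classes with summed exact
    probabilities.  Each homozygous class is classified against the two
    parental karyotypes (inferred via :func:`_default_parents` when not
    given); everything off the diagonal is a heterozygote.
    """
    if enum_a.architecture != enum_b.architecture:
        raise ArchitectureMismatchError("enumerations use different architectures")
    if not (enum_a.materialized and enum_b.materialized):
        raise EnumerationSizeError(
            "punnett_square needs materialized enumerations; "
            f"got {enum_a.total_count} x {enum_b.total_count} gamete types — "
            "raise materialize_limit or use the analytic summaries"
        )
    arch = enum_a.architecture
    p1, p2 = parents if parents is not None else _default_parents(
        enum_a.genotype, enum_b.genotype
    )
    p1_key = tuple(p1.alleles)
    p2_key = tuple(p2.alleles)

    ints_a = [_encode(g) for g in enum_a.gametes]
    ints_b = [_encode(g) for g in enum_b.gametes]
    counts: dict[tuple[int, int], int] = {}
    for a in ints_a:
        for b in ints_b:
            key = (a & b, a | b)
            counts[key] = counts.get(key, 0) + 1

    cell_count = enum_a.total_count * enum_b.total_count
    classes = []
    hom = novel = 0
    for (lo, hi), cnt in sorted(counts.items()):
        pairs = _decode_pairs(lo, hi, arch.n_sites)
        genotype = DiploidGenotype(arch, pairs)
        if lo == hi:  # homozygous at every site
            hom += 1
            if pairs == p1_key:
                label = PARENTAL_P1
            elif pairs == p2_key:
                label = PARENTAL_P2
            else:
                label = NOVEL_HOMOZYGOTE
                novel += 1
        else:
            label = HETEROZYGOTE
        classes.append(
            ZygoteClass(
                genotype=genotype,
                probability=Fraction(cnt, cell_count),
                classification=label,
                m=meiotic_figure(genotype).m,
            )
        )
    return PunnettResult(
        classes=tuple(classes),
        cell_count=cell_count,
        homozygous_class_count=hom,
        r=Fraction(novel, hom) if hom else Fraction(0),
        parent_p1=p1,
        parent_p2=p2,
    )


def novel_homozygote_fraction(n_het: int) -> Fraction:
    """Exact r = 1 - 2/2^n: novel fraction of the homozygous diagonal.

    ``n_het`` is the number of fusion/fission differences between the
    hybridizing races.  r(1) = 0 (pure reversion), r(3) = 3/4, r(24) =
    0.99999988 to eight decimals — reversion to a parental karyotype
    becomes vanishingly rare as the races diverge.
    """
    if n_het < 1:
        raise ValueError("n_het must be >= 1")
    return Fraction(2**n_het - 2, 2**n_het)
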