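"""Chromosomal fusion/fission architectures, races, genotypes and gametes.

Two chromosomal races of a species with holocentric chromosomes can share a
common set of ancestral chromosome *units* while differing in which pairs of
units are joined by chromosomal fusions (equivalently, split by fissions —
the same site seen from opposite directions).  This module represents that
shared frame as a :class:`FusionArchitecture`: ``U`` ancestral haploid units
plus an ordered list of pairwise-disjoint candidate fusion *sites*, each an
unordered pair of unit indices.  A race fixes a subset of sites in the fused
state; a diploid genotype carries an unordered allele pair (fused/unfused)
at every site; a gamete carries one allele per site.

From a genotype the expected meiotic metaphase-I figure follows directly:

* a heterozygous site pairs one fused chromosome with its two unfused
  homologs and appears as one **trivalent** (3 chromosomes);
* a fused/fused site appears as one **bivalent** of fused chromosomes
  (2 chromosomes);
* an unfused/unfused site appears as two bivalents (4 chromosomes);
* every unit belonging to no site appears as one bivalent.

The default architecture models the Wood White butterfly *Leptidea
sinapis*: 53 ancestral units and 25 candidate fusion sites, with a
high-chromosome-number "spanish" race (no fusions, 2n = 106) and a
low-number "swedish" race (24 fusions fixed, 2n = 58; the 25th site is
polymorphic in the wild population).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "UNFUSED",
    "FUSED",
    "ArchitectureMismatchError",
    "FusionArchitecture",
    "RaceKaryotype",
    "DiploidGenotype",
    "GameteHaplotype",
    "MeioticFigureCounts",
    "haploid_number",
    "meiotic_figure",
    "cross",
    "f1_hybrid",
    "DEFAULT_ARCHITECTURE",
    "default_races",
    "spanish_race",
    "swedish_race",
    "to_document",
    "from_document",
    "load_architecture",
    "dump_architecture",
]

#: Allele states of a fusion site.
UNFUSED = 0
FUSED = 1


class ArchitectureMismatchError(ValueError):
    """Raised when objects built on different architectures are combined."""


def _default_sites() -> tuple[tuple[int, int], ...]:
    # 25 disjoint sites pairing units (1,2), (3,4), ..., (49,50);
    # units 51-53 remain invariant.
    return tuple((2 * i + 1, 2 * i + 2) for i in range(25))


@dataclass(frozen=True)
class FusionArchitecture:
    """Shared set of ancestral chromosome units and candidate fusion sites.

    Parameters
    ----------
    n_units
        Count ``U`` of ancestral haploid chromosome units (default 53).
    sites
        Ordered list of unordered, pairwise-disjoint pairs of 1-based unit
        indices.  Sites are identified by their 0-based list position in
        code and reported 1-based in output.
    """

    n_units: int = 53
    sites: tuple[tuple[int, int], ...] = field(default_factory=_default_sites)

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("architecture needs at least one unit")
        norm = []
        seen: set[int] = set()
        for pair in self.sites:
            a, b = (int(u) for u in pair)
            if a == b:
                raise ValueError(f"fusion site ({a},{b}) joins a unit with itself")
            a, b = (a, b) if a < b else (b, a)
            for u in (a, b):
                if not 1 <= u <= self.n_units:
                    raise ValueError(f"unit {u} outside 1..{self.n_units}")
                if u in seen:
                    raise ValueError(f"unit {u} appears in more than one fusion site")
                seen.add(u)
            norm.append((a, b))
        object.__setattr__(self, "sites", tuple(norm))

    @property
    def n_sites(self) -> int:
        """Number of candidate fusion sites ``F``."""
        return len(self.sites)

    @property
    def invariant_unit_count(self) -> int:
        """Units participating in no fusion site (``U - 2F``)."""
        return self.n_units - 2 * self.n_sites


@dataclass(frozen=True)
class RaceKaryotype:
    """A chromosomal race: a subset of sites fixed in the fused state."""

    architecture: FusionArchitecture
    fused_sites: frozenset[int] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        fused = frozenset(int(i) for i in self.fused_sites)
        for i in fused:
            if not 0 <= i < self.architecture.n_sites:
                raise ValueError(f"site index {i} outside 0..{self.architecture.n_sites - 1}")
        object.__setattr__(self, "fused_sites", fused)

    @property
    def haploid_number(self) -> int:
        return self.architecture.n_units - len(self.fused_sites)

    @property
    def diploid_number(self) -> int:
        return 2 * self.haploid_number

    def gamete(self) -> "GameteHaplotype":
        """The unique gamete of this (homozygous) race."""
        alleles = tuple(
            FUSED if i in self.fused_sites else UNFUSED
            for i in range(self.architecture.n_sites)
        )
        return GameteHaplotype(self.architecture, alleles)

    def genotype(self) -> "DiploidGenotype":
        """The homozygous diploid genotype of this race."""
        return cross(self.gamete(), self.gamete())


@dataclass(frozen=True)
class GameteHaplotype:
    """One allele (fused/unfused) per fusion site of a balanced gamete."""

    architecture: FusionArchitecture
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        alleles = tuple(int(a) for a in self.alleles)
        if len(alleles) != self.architecture.n_sites:
            raise ValueError("one allele required per fusion site")
        if any(a not in (UNFUSED, FUSED) for a in alleles):
            raise ValueError("alleles must be UNFUSED (0) or FUSED (1)")
        object.__setattr__(self, "alleles", alleles)

    @property
    def chromosome_count(self) -> int:
        """Haploid chromosome number carried by this gamete.

        Every invariant unit is one chromosome; a fused site contributes one
        chromosome, an unfused site two.
        """
        arch = self.architecture
        return arch.invariant_unit_count + sum(
            1 if a == FUSED else 2 for a in self.alleles
        )


@dataclass(frozen=True)
class DiploidGenotype:
    """Unordered fused/unfused allele pair at every fusion site."""

    architecture: FusionArchitecture
    alleles: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != self.architecture.n_sites:
            raise ValueError("one allele pair required per fusion site")
        norm = []
        for pair in self.alleles:
            a, b = (int(x) for x in pair)
            if a not in (UNFUSED, FUSED) or b not in (UNFUSED, FUSED):
                raise ValueError("alleles must be UNFUSED (0) or FUSED (1)")
            norm.append((a, b) if a <= b else (b, a))
        object.__setattr__(self, "alleles", tuple(norm))

    @property
    def heterozygous_sites(self) -> tuple[int, ...]:
        return tuple(i for i, (a, b) in enumerate(self.alleles) if a != b)

    @property
    def h(self) -> int:
        """Number of heterozygous fusion sites (the model's *n*)."""
        return len(self.heterozygous_sites)

    def meiotic_figure(self) -> "MeioticFigureCounts":
        return meiotic_figure(self)


@dataclass(frozen=True)
class MeioticFigureCounts:
    """Observable layer of a meiotic metaphase-I karyotype.

    ``x`` bivalents and ``y`` trivalents make ``n = x + y`` countable
    elements holding ``m = 2x + 3y`` chromosomes.  Small dot-like
    univalents ``s`` are imperfect-pairing noise and excluded from both
    ``n`` and ``m`` by convention.
    """

    x: int
    y: int
    s: int = 0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.s < 0:
            raise ValueError("element counts must be non-negative")

    @property
    def n(self) -> int:
        return self.x + self.y

    @property
    def m(self) -> int:
        return 2 * self.x + 3 * self.y


def haploid_number(race: RaceKaryotype) -> int:
    """Haploid chromosome number of a race: ``U`` minus its fixed fusions."""
    return race.haploid_number


def meiotic_figure(genotype: DiploidGenotype) -> MeioticFigureCounts:
    """Predict the metaphase-I figure (bivalents/trivalents) of a genotype.

    Each heterozygous site yields one trivalent; each fused/fused site one
    bivalent; each unfused/unfused site two bivalents; each invariant unit
    one bivalent.  Univalents are never predicted (``s = 0``): they belong
    to the observation layer only.
    """
    x = genotype.architecture.invariant_unit_count
    y = 0
    for a, b in genotype.alleles:
        if a != b:
            y += 1
        elif a == FUSED:
            x += 1
        else:
            x += 2
    return MeioticFigureCounts(x=x, y=y)


def cross(gamete_a: GameteHaplotype, gamete_b: GameteHaplotype) -> DiploidGenotype:
    """Fuse two gametes into a diploid genotype (same architecture required)."""
    if gamete_a.architecture != gamete_b.architecture:
        raise ArchitectureMismatchError("gametes come from different architectures")
    pairs = tuple(zip(gamete_a.alleles, gamete_b.alleles))
    return DiploidGenotype(gamete_a.architecture, pairs)


def f1_hybrid(race_a: RaceKaryotype, race_b: RaceKaryotype) -> DiploidGenotype:
    """F1 of two homozygous races: heterozygous exactly where they differ."""
    return cross(race_a.gamete(), race_b.gamete())


# ---------------------------------------------------------------------------
# Presets and JSON serialization
# ---------------------------------------------------------------------------

DEFAULT_ARCHITECTURE = FusionArchitecture()


def spanish_race(architecture: FusionArchitecture | None = None) -> RaceKaryotype:
    """High-chromosome-number race: no fusion fixed (2n = 106 by default)."""
    arch = architecture or DEFAULT_ARCHITECTURE
    return RaceKaryotype(arch, frozenset(), name="spanish")


def swedish_race(
    architecture: FusionArchitecture | None = None, n_fused: int = 24
) -> RaceKaryotype:
    """Low-chromosome-number race: first ``n_fused`` sites fixed fused.

    With the default architecture and ``n_fused=24`` this is the Swedish
    karyotype (2n = 58); the 25th site is left unfused, mirroring its
    polymorphism in the wild population.
    """
    arch = architecture or DEFAULT_ARCHITECTURE
    if n_fused > arch.n_sites:
        raise ValueError("more fused sites requested than the architecture has")
    return RaceKaryotype(arch, frozenset(range(n_fused)), name="swedish")


def default_races() -> dict[str, RaceKaryotype]:
    return {"spanish": spanish_race(), "swedish": swedish_race()}


def to_document(
    architecture: FusionArchitecture,
    races: Mapping[str, RaceKaryotype] | None = None,
) -> dict:
    """Serialize an architecture (+ optional race presets) to a JSON document.

    Site indices inside ``races`` are written 1-based, matching reports.
    """
    doc: dict = {
        "U": architecture.n_units,
        "sites": [list(s) for s in architecture.sites],
    }
    if races is not None:
        doc["races"] = {
            name: sorted(i + 1 for i in race.fused_sites)
            for name, race in races.items()
        }
    return doc


def from_document(doc: Mapping) -> tuple[FusionArchitecture, dict[str, RaceKaryotype]]:
    """Inverse of :func:`to_document`; unknown keys are ignored."""
    try:
        arch = FusionArchitecture(int(doc["U"]), tuple(tuple(s) for s in doc["sites"]))
    except KeyError as exc:
        raise ValueError(f"architecture document missing key {exc}") from exc
    races = {
        str(name): RaceKaryotype(
            arch, frozenset(int(i) - 1 for i in idx), name=str(name)
        )
        for name, idx in dict(doc.get("races", {})).items()
    }
    return arch, races


def load_architecture(path: Union[str, Path]) -> tuple[FusionArchitecture, dict[str, RaceKaryotype]]:
    with open(path, encoding="utf-8") as fh:
        return from_document(json.load(fh))


def dump_architecture(
    path: Union[str, Path],
    architecture: FusionArchitecture,
    races: Mapping[str, RaceKaryotype] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_document(architecture, races), fh, indent=2)
        fh.write("\n")
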