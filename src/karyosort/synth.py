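"""Synthetic cytogenetic observation tables, plus the published fixture.

Real count tables have a characteristic texture: per-specimen metaphase-I
counts that may repeat across cells and carry sporadic small dot-like
univalents (``29 + 2s``), asynaptic diploid counts flagged approximate
(``ca82``) or missing, and a handful of specimens per hybrid generation.
This module renders simulated genotypes into that texture so the whole
parse → decompose → summarize pipeline is testable end-to-end with known
ground truth, and packages the published 63-specimen count table as a
checksummed fixture.

Univalent noise is additive annotation: it populates ``s`` without
altering the recorded element count ``n`` or diploid count ``m``, matching
the convention that decomposition ignores univalents.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .architecture import DiploidGenotype, meiotic_figure
from .counts import CountNotation, ObservedCountRecord
from .simulate import SimulationResult
from . import tableio

__all__ = [
    "NoiseModel",
    "SyntheticTable",
    "FixtureError",
    "observe_individual",
    "generate_observed_table",
    "table_from_simulation",
    "load_table1_fixture",
]


@dataclass(frozen=True)
class NoiseModel:
    """Observation-layer noise.

    ``p_univalent`` is the per-trivalent, per-cell probability of showing
    up as a detached univalent annotation (the published table gives no
    rate; 0.1 is a placeholder default, not a measured value).  ``p_ca``
    flags the diploid count approximate, ``p_missing_m`` drops it, and
    ``cells_per_sample`` sets how many MI cells are recorded per specimen.
    """

    p_univalent: float = 0.1
    p_ca: float = 0.8
    p_missing_m: float = 0.1
    cells_per_sample: int = 1

    def __post_init__(self) -> None:
        for name in ("p_univalent", "p_ca", "p_missing_m"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(p_univalent=0.0, p_ca=0.0, p_missing_m=0.0, cells_per_sample=1)


@dataclass(frozen=True)
class SyntheticTable:
    """Generated records plus the per-sample generating truth (x, y, m)."""

    records: tuple[ObservedCountRecord, ...]
    truth: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def write(self, target) -> None:
        tableio.write_count_table(self.records, target)


def observe_individual(
    genotype: DiploidGenotype,
    noise: NoiseModel,
    rng: np.random.Generator,
    sample_id: str = "S0",
    line: str = "F1",
) -> ObservedCountRecord:
    """Render one genotype as a specimen record under the noise model.

    Each MI cell independently draws univalent noise over the genotype's
    trivalents; the diploid count is flagged ``ca`` or dropped at the
    configured rates.  With zero noise the record decomposes back to the
    genotype's true figure exactly.
    """
    fig = meiotic_figure(genotype)
    mi = tuple(
        CountNotation(
            value=fig.n,
            s_count=int(rng.binomial(fig.y, noise.p_univalent)) if fig.y else 0,
        )
        for _ in range(noise.cells_per_sample)
    )
    m_obs: CountNotation | None = CountNotation(
        value=fig.m, approximate=bool(rng.random() < noise.p_ca)
    )
    if rng.random() < noise.p_missing_m:
        m_obs = None
    return ObservedCountRecord(
        sample_id=sample_id, line=line, mi_observations=mi, m_observation=m_obs
    )


def generate_observed_table(
    genotypes_by_generation: Mapping[str, Sequence[DiploidGenotype]],
    per_generation_samples: int,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> SyntheticTable:
    """Sample specimens per generation and render them as a count table.

    Sampling is without replacement; asking for more specimens than a
    generation holds is an error.
    """
    records: list[ObservedCountRecord] = []
    truth: dict[str, tuple[int, int, int]] = {}
    for label, genotypes in genotypes_by_generation.items():
        if per_generation_samples > len(genotypes):
            raise ValueError(
                f"{label}: requested {per_generation_samples} samples from "
                f"{len(genotypes)} individuals"
            )
        picks = rng.choice(len(genotypes), size=per_generation_samples, replace=False)
        for j, idx in enumerate(sorted(int(i) for i in picks)):
            sid = f"{label}-{j:03d}"
            g = genotypes[idx]
            fig = meiotic_figure(g)
            records.append(observe_individual(g, noise, rng, sample_id=sid, line=label))
            truth[sid] = (fig.x, fig.y, fig.m)
    return SyntheticTable(records=tuple(records), truth=truth)


def table_from_simulation(
    result: SimulationResult,
    replicate: int,
    per_generation_samples: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    labels: Sequence[str] = ("F1", "F2", "F3", "F4"),
) -> SyntheticTable:
    """Emulate the breeding experiment's sampling from a kept simulation.

    Generation ``t`` of the replicate is labeled ``labels[t]``; the run
    must have been executed with ``keep_populations=True`` and a horizon of
    at least ``len(labels) - 1``.
    """
    by_gen = {
        label: result.genotypes_at(replicate, t) for t, label in enumerate(labels)
    }
    return generate_observed_table(by_gen, per_generation_samples, noise, rng)


# ---------------------------------------------------------------------------
# published fixture
# ---------------------------------------------------------------------------


class FixtureError(RuntimeError):
    """The packaged fixture failed its checksum."""


def load_table1_fixture(validate: bool = True) -> list[ObservedCountRecord]:
    """The published 63-specimen count table, checksum-verified.

    With ``validate=True`` every row is also decomposed where possible so
    that printed-estimate inconsistencies surface as
    :class:`~karyosort.counts.CountInconsistencyWarning` (one row, 12Z051,
    prints a trivalent count that violates 2x + 3y = m; it is kept verbatim
    and flagged, never corrected).
    """
    data = resources.files("karyosort.data")
    raw = (data / "table1.tsv").read_bytes()
    expected = (data / "table1.sha256").read_text().strip()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise FixtureError(
            f"table1.tsv checksum mismatch: {digest} != {expected}"
        )
    import io

    records = tableio.read_count_table(io.StringIO(raw.decode("utf-8")))
    if validate:
        from .counts import decompose_record

        for rec in records:
            decompose_record(rec, warn=True)
    return records
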