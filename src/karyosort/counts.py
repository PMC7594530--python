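"""Parsing and decomposition of observed cytogenetic counts.

A metaphase-I (MI) spread of a fusion heterozygote shows ``n`` countable
elements — ``x`` bivalents plus ``y`` trivalents — while asynaptic meiosis
of the same male shows the diploid chromosome number ``m``.  Because a
bivalent holds two chromosomes and a trivalent three,

    2x + 3y = m        x + y = n

and therefore  ``y = m - 2n``,  ``x = n - y``.  The proportion of
chromosomes in the homozygous state (part of bivalents, not trivalents) is
``100 * 2x / m``.

This module parses the count notation used in cytogenetic tables
(``ca82``, ``29 + 2s``, ``ca106–108``), performs the decomposition,
summarizes each hybrid generation (range, mean, sample SD of the
homozygosity proportion), and tests the generation effect with a one-way
ANOVA whose p-value — and Tukey–Kramer pairwise comparisons — come from a
label-permutation null.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CountParseError",
    "InfeasibleCountsError",
    "CountInconsistencyWarning",
    "CountNotation",
    "ObservedCountRecord",
    "DecompositionResult",
    "GenerationSummary",
    "GenerationTestResult",
    "parse_count_notation",
    "decompose",
    "decompose_record",
    "homozygosity_proportion",
    "round_half_up",
    "summarize_generation",
    "summarize_table",
    "generation_effect_test",
    "GENERATION_LABELS",
]

GENERATION_LABELS = ("F1", "F2", "F3", "F4")
LINE_LABELS = ("Spain", "Sweden") + GENERATION_LABELS


class CountParseError(ValueError):
    """A count token does not match the notation grammar."""


class InfeasibleCountsError(ValueError):
    """(n, m) outside the feasible band 2n <= m <= 3n."""

    def __init__(self, message: str, bound: str):
        super().__init__(message)
        self.bound = bound  # "m<2n" or "m>3n"


class CountInconsistencyWarning(UserWarning):
    """Printed estimates of a record disagree with their recomputation."""


@dataclass(frozen=True)
class CountNotation:
    """One token of the cytogenetic count notation.

    ``ca82`` is an approximate count; ``29 + 2s`` is an exact element count
    of 29 with two small dot-like univalents (excluded from the value);
    ``ca106–108`` is an approximate range.  A trailing parenthetical
    annotation (e.g. ``53 (at MII)``) is preserved as ``note``.
    """

    value: int
    approximate: bool = False
    range_high: int | None = None
    s_count: int = 0
    note: str | None = None

    def __post_init__(self) -> None:
        if self.value < 0 or self.s_count < 0:
            raise ValueError("counts must be non-negative")
        if self.range_high is not None and self.range_high < self.value:
            raise ValueError("range high end below its low end")

    def render(self) -> str:
        """Back to token text (canonical spacing, en-dash ranges)."""
        out = ("ca" if self.approximate else "") + str(self.value)
        if self.range_high is not None:
            out += f"–{self.range_high}"
        if self.s_count == 1:
            out += " + s"
        elif self.s_count > 1:
            out += f" + {self.s_count}s"
        if self.note:
            out += f" ({self.note})"
        return out


_TOKEN_RE = re.compile(r"^(ca)?(\d+)(?:[–-](\d+))?(?:\+(?:(\d+))?s)?$")
_NOTE_RE = re.compile(r"\(([^()]*)\)\s*$")


def parse_count_notation(text: str) -> CountNotation:
    """Parse one count token; raises :class:`CountParseError` otherwise.

    Whitespace-tolerant: ``29+2s`` and ``29 + 2s`` are equivalent; both
    the en-dash and the ASCII hyphen delimit ranges.
    """
    raw = text.strip()
    note = None
    m_note = _NOTE_RE.search(raw)
    if m_note:
        note = m_note.group(1).strip()
        raw = raw[: m_note.start()].strip()
    compact = re.sub(r"\s+", "", raw)
    m = _TOKEN_RE.match(compact)
    if not m or not compact:
        raise CountParseError(f"unparseable count token: {text!r}")
    ca, value, high, s_digits = m.groups()
    s_count = 0
    if compact.endswith("s"):
        s_count = int(s_digits) if s_digits else 1
    return CountNotation(
        value=int(value),
        approximate=ca is not None,
        range_high=int(high) if high is not None else None,
        s_count=s_count,
        note=note,
    )


@dataclass(frozen=True)
class ObservedCountRecord:
    """One specimen's observations: MI element counts and/or a diploid count.

    ``printed_x``/``printed_y`` hold verbatim estimate-column tokens when the
    record comes from a published table; they are provenance, never inputs
    to recomputation.
    """

    sample_id: str
    line: str
    mi_observations: tuple[CountNotation, ...] = ()
    m_observation: CountNotation | None = None
    printed_x: str | None = None
    printed_y: str | None = None

    def __post_init__(self) -> None:
        if not self.mi_observations and self.m_observation is None:
            raise ValueError(
                f"record {self.sample_id}: needs an MI or a diploid observation"
            )
        if self.line not in LINE_LABELS:
            raise ValueError(f"record {self.sample_id}: unknown line {self.line!r}")

    @property
    def modal_n(self) -> int | None:
        """Modal MI element count ignoring univalents; ties break low."""
        if not self.mi_observations:
            return None
        counts = Counter(obs.value for obs in self.mi_observations)
        top = max(counts.values())
        return min(v for v, c in counts.items() if c == top)

    @property
    def m_value(self) -> int | None:
        """Diploid count used for decomposition (low endpoint of a range)."""
        return None if self.m_observation is None else self.m_observation.value


def round_half_up(value, ndigits: int = 0) -> float:
    """Decimal round-half-up (2.345 -> 2.35 at 2 digits), exact for Fractions."""
    scaled = Fraction(value) * 10**ndigits
    return float(math.floor(scaled + Fraction(1, 2))) / 10**ndigits


@dataclass(frozen=True)
class DecompositionResult:
    """Bivalent/trivalent decomposition of one (n, m) observation pair."""

    x: int
    y: int
    proportion: Fraction  # exact homozygosity percentage, 100*2x/m
    approximate: bool = False

    @property
    def proportion_hom(self) -> float:
        """Homozygosity percentage rounded half-up to 1 decimal place."""
        return round_half_up(self.proportion, 1)


def decompose(n: int, m: int, approximate: bool = False) -> DecompositionResult:
    """Solve 2x + 3y = m, x + y = n for the bivalent/trivalent counts.

    Feasible iff ``2n <= m <= 3n``; outside that band the observation pair
    cannot come from bivalents and trivalents alone.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m < 2:
        raise ValueError("m must be >= 2")
    y = m - 2 * n
    x = n - y
    if y < 0:
        raise InfeasibleCountsError(
            f"(n={n}, m={m}): m < 2n implies a negative trivalent count", "m<2n"
        )
    if x < 0:
        raise InfeasibleCountsError(
            f"(n={n}, m={m}): m > 3n implies a negative bivalent count", "m>3n"
        )
    return DecompositionResult(
        x=x, y=y, proportion=Fraction(200 * x, m), approximate=approximate
    )


def homozygosity_proportion(x: int, m: int) -> float:
    """Percentage of chromosomes in bivalents, 100*2x/m, to 1 decimal."""
    if m <= 0:
        raise ValueError("m must be positive")
    if x < 0 or 2 * x > m:
        raise ValueError(f"2x = {2 * x} outside 0..m = {m}")
    return round_half_up(Fraction(200 * x, m), 1)


def _printed_int(token: str | None) -> int | None:
    if token is None:
        return None
    try:
        return int(token.strip())
    except ValueError:
        return None


def decompose_record(
    record: ObservedCountRecord, warn: bool = True
) -> DecompositionResult | None:
    """Decompose one record, or ``None`` when n or m is unavailable.

    When the record carries printed estimate columns that disagree with the
    recomputation, a :class:`CountInconsistencyWarning` is emitted — the
    printed values are provenance and are never silently corrected.
    """
    n = record.modal_n
    m_obs = record.m_observation
    if n is None or m_obs is None:
        return None
    approx = (
        m_obs.approximate
        or m_obs.range_high is not None
        or any(o.approximate for o in record.mi_observations)
    )
    result = decompose(n, m_obs.value, approximate=approx)
    if warn:
        px, py = _printed_int(record.printed_x), _printed_int(record.printed_y)
        if (px is not None and px != result.x) or (py is not None and py != result.y):
            warnings.warn(
                f"sample {record.sample_id}: printed estimates "
                f"(x={record.printed_x}, y={record.printed_y}) are inconsistent "
                f"with the decomposition of (n={n}, m={m_obs.value}) -> "
                f"(x={result.x}, y={result.y})",
                CountInconsistencyWarning,
                stacklevel=2,
            )
    return result


@dataclass(frozen=True)
class GenerationSummary:
    """Per-generation summary of decomposable records (a Table-2-style row)."""

    generation: str
    k: int
    x_range: tuple[int, int]
    y_range: tuple[int, int]
    prop_range: tuple[float, float]
    prop_mean: float
    prop_sd: float | None  # sample SD (n-1); None for a single record


def _eligible(records: Iterable[ObservedCountRecord], generation: str):
    out = []
    for rec in records:
        if rec.line != generation:
            continue
        res = decompose_record(rec, warn=False)
        if res is not None:
            out.append((rec, res))
    return out


def summarize_generation(
    records: Iterable[ObservedCountRecord], generation: str
) -> GenerationSummary:
    """Ranges, mean and sample SD of the homozygosity proportion.

    Only records with both a resolvable MI count and a diploid count enter.
    The mean is reported to 1 decimal and the SD (n-1 denominator) to 2,
    both rounded half-up; statistics are computed on unrounded proportions.
    """
    eligible = _eligible(records, generation)
    if not eligible:
        raise ValueError(f"no decomposable records for generation {generation!r}")
    results = [res for _, res in eligible]
    props = [float(res.proportion) for res in results]
    k = len(results)
    mean = sum(props) / k
    sd = math.sqrt(sum((p - mean) ** 2 for p in props) / (k - 1)) if k >= 2 else None
    return GenerationSummary(
        generation=generation,
        k=k,
        x_range=(min(r.x for r in results), max(r.x for r in results)),
        y_range=(min(r.y for r in results), max(r.y for r in results)),
        prop_range=(
            min(r.proportion_hom for r in results),
            max(r.proportion_hom for r in results),
        ),
        prop_mean=round_half_up(mean, 1),
        prop_sd=None if sd is None else round_half_up(sd, 2),
    )


def summarize_table(
    records: Iterable[ObservedCountRecord],
    generations: Sequence[str] = GENERATION_LABELS,
) -> list[GenerationSummary]:
    """Summaries for every requested generation that has eligible records."""
    records = list(records)
    out = []
    for gen in generations:
        if _eligible(records, gen):
            out.append(summarize_generation(records, gen))
    return out


# ---------------------------------------------------------------------------
# Generation-effect test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenerationTestResult:
    """One-way ANOVA with a permutation p-value and pairwise comparisons.

    ``pairwise`` maps each generation pair to its Holm-adjusted permutation
    p-value of the Tukey–Kramer statistic
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))``.
    """

    F_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float]
    n_perm: int
    group_sizes: dict[str, int] = field(default_factory=dict)


def _f_from_sums(S, counts, total_sum, total_sq, n, k):
    """Vectorized one-way ANOVA F from per-group sums S (rows = datasets)."""
    between = (S**2 / counts).sum(axis=-1) - total_sum**2 / n
    within = total_sq - (S**2 / counts).sum(axis=-1)
    msb = between / (k - 1)
    msw = within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(within > 1e-12, msb / np.maximum(msw, 1e-300), np.where(between > 1e-12, np.inf, 0.0))
    return F, msw


def generation_effect_test(
    records: Iterable[ObservedCountRecord],
    n_perm: int = 10_000,
    seed: int = 0,
    generations: Sequence[str] = GENERATION_LABELS,
) -> GenerationTestResult:
    """Test the effect of hybrid generation on the homozygosity proportion.

    The F statistic is the classical between/within mean-square ratio; its
    p-value is obtained by permuting generation labels (``(1 + #{F* >= F})
    / (1 + n_perm)``), which is robust to the small, unequal group sizes.
    Pairwise differences use the Tukey–Kramer q statistic against the same
    permutation null, Holm-adjusted across pairs.
    """
    groups: dict[str, list[float]] = {}
    for rec in records:
        if rec.line not in generations:
            continue
        res = decompose_record(rec, warn=False)
        if res is not None:
            groups.setdefault(rec.line, []).append(float(res.proportion))
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two generations with >= 2 records each")
    labels = sorted(groups, key=lambda g: (generations.index(g) if g in generations else 99))
    v = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    counts = np.array([len(groups[g]) for g in labels], dtype=float)
    n, k = len(v), len(labels)
    onehot = np.zeros((n, k))
    start = 0
    for j, g in enumerate(labels):
        onehot[start : start + len(groups[g]), j] = 1.0
        start += len(groups[g])

    total_sum, total_sq = v.sum(), (v**2).sum()
    S_obs = v @ onehot
    F_obs, msw_obs = _f_from_sums(S_obs[None, :], counts, total_sum, total_sq, n, k)
    F_obs, msw_obs = float(F_obs[0]), float(msw_obs[0])

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    V = v[idx]
    S = V @ onehot  # (n_perm, k); row sums/squares are permutation-invariant
    F_perm, msw_perm = _f_from_sums(S, counts, total_sum, total_sq, n, k)
    p_value = (1 + int((F_perm >= F_obs - 1e-12).sum())) / (1 + n_perm)

    pairs = list(combinations(range(k), 2))
    means_obs = S_obs / counts
    means_perm = S / counts
    raw_p = {}
    for i, j in pairs:
        scale = np.sqrt(0.5 * (1.0 / counts[i] + 1.0 / counts[j]))
        q_obs = abs(means_obs[i] - means_obs[j]) / (math.sqrt(max(msw_obs, 1e-300)) * scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            q_perm = np.abs(means_perm[:, i] - means_perm[:, j]) / (
                np.sqrt(np.maximum(msw_perm, 1e-300)) * scale
            )
        raw_p[(labels[i], labels[j])] = (1 + int((q_perm >= q_obs - 1e-12).sum())) / (
            1 + n_perm
        )

    # Holm step-down adjustment
    items = sorted(raw_p.items(), key=lambda kv: kv[1])
    adjusted, running = {}, 0.0
    m_tests = len(items)
    for rank, (pair, p) in enumerate(items):
        running = max(running, (m_tests - rank) * p)
        adjusted[pair] = min(1.0, running)

    return GenerationTestResult(
        F_statistic=F_obs,
        p_value=p_value,
        pairwise=adjusted,
        n_perm=n_perm,
        group_sizes={g: len(groups[g]) for g in labels},
    )
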