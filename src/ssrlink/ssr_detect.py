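"""Perfect and compound microsatellite (SSR) detection and motif statistics.

A microsatellite is a tandem repetition of a 1-6 bp DNA motif.  This module
finds all *maximal perfect* repeat tracts in assembled scaffolds using
per-unit-length minimum repeat counts (defaults: mono-10, di-6, tri-5,
tetra-5, penta-5, hexa-5), merges neighbouring tracts separated by at most a
fixed interval (default 100 bp) into *compound* loci, canonicalises motifs
into rotation/reverse-complement equivalence classes (e.g. ``AAG/CTT``), and
produces per-pool summary statistics: totals, frequencies, densities,
per-type and per-class tables, and motif repeat-number histograms.

Coordinates are 1-based inclusive throughout, the de facto convention of
microsatellite survey tables.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ratio_pct, round_half_up

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRSearchParams",
    "SSRLocus",
    "MotifClass",
    "SexStats",
    "SSRSummary",
    "reverse_complement",
    "is_primitive",
    "find_perfect_ssrs",
    "merge_compound",
    "canonical_motif_class",
    "summarize_ssrs",
    "repeat_number_distribution",
]

#: minimum repeat counts per unit length (mono through hexa)
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

_INVALID_BASE = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter string.

    ``AC`` is primitive; ``ACAC`` (= 2 x ``AC``) and ``AAA`` are not.
    """
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


@dataclass(frozen=True)
class SSRSearchParams:
    """Search thresholds for perfect/compound SSR detection.

    ``min_repeats`` maps unit length (1..6) to the minimum number of tandem
    copies required to call a tract.  ``max_compound_interval`` is the
    largest gap in bp between two tracts that are still merged into one
    compound locus.
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_compound_interval: int = 100

    def __post_init__(self) -> None:
        for u in range(1, 7):
            if u not in self.min_repeats:
                raise ValueError(f"min_repeats missing unit length {u}")
            if self.min_repeats[u] < 2:
                raise ValueError(
                    f"min_repeats[{u}] must be >= 2, got {self.min_repeats[u]}"
                )
        if self.max_compound_interval < 0:
            raise ValueError("max_compound_interval must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """One detected microsatellite tract (1-based inclusive coordinates).

    Perfect loci satisfy ``tract_length == unit_length * repeat_count`` and
    carry a primitive motif.  Compound loci span two or more perfect tracts
    (stored in ``components``) plus the interruptions between them; their
    ``motif`` is the '+'-joined constituent motifs and ``unit_length`` /
    ``repeat_count`` are 0.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    unit_length: int
    is_compound: bool = False
    components: tuple["SSRLocus", ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad locus coordinates {self.start}-{self.end}")
        if not self.is_compound:
            if not 1 <= self.unit_length <= 6:
                raise ValueError(f"unit_length {self.unit_length} out of range")
            if self.tract_length != self.unit_length * self.repeat_count:
                raise ValueError(
                    "tract_length must equal unit_length * repeat_count"
                )
            if not is_primitive(self.motif):
                raise ValueError(f"motif {self.motif!r} is not primitive")

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "SSRLocus") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of motifs under rotation and reverse complement.

    The label is ``X/Y`` where ``X`` is the lexicographically smallest string
    among all rotations of the motif and of its reverse complement, and
    ``Y`` is the smallest rotation of ``reverse_complement(X)``
    (e.g. ``AC/GT``, ``AAG/CTT``, ``AGC/CTG``).
    """

    label: str

    @property
    def canonical(self) -> str:
        return self.label.split("/", 1)[0]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def find_perfect_ssrs(
    seq: str, seq_id: str, params: SSRSearchParams | None = None
) -> list[SSRLocus]:
    """Find all maximal perfect SSR tracts in an uppercase A/C/G/T/N string.

    A tract is reported when its (primitive) motif of unit length *u* is
    tandem-repeated at least ``params.min_repeats[u]`` times.  N bases never
    participate in a tract.  When maximal tracts of different unit lengths
    overlap, the longer tract wins (ties: smaller unit length, then leftmost
    start), so each genomic interval yields a single call.  Loci are returned
    sorted by start position.
    """
    params = params or SSRSearchParams()
    m = _INVALID_BASE.search(seq)
    if m:
        raise ValueError(
            f"invalid base {seq[m.start()]!r} at position {m.start() + 1}"
            f" in sequence {seq_id!r}"
        )
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    candidates: list[SSRLocus] = []
    for u in range(1, 7):
        min_rep = params.min_repeats[u]
        if n < u * min_rep:
            continue
        # eq[j] is True when position j matches position j+u and neither is N;
        # a maximal run of length L starting at s certifies that seq[s:s+L+u]
        # has period u.
        eq = (arr[:-u] == arr[u:]) & not_n[:-u] & not_n[u:]
        padded = np.zeros(eq.size + 2, dtype=np.int8)
        padded[1:-1] = eq
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        for s, e in zip(starts.tolist(), stops.tolist()):
            count = (e - s + u) // u
            if count < min_rep:
                continue
            motif = seq[s : s + u]
            if not is_primitive(motif):
                continue  # already reported under its primitive unit
            candidates.append(
                SSRLocus(seq_id, s + 1, s + count * u, motif, count, u)
            )
    return _resolve_overlaps(candidates)


def _resolve_overlaps(candidates: list[SSRLocus]) -> list[SSRLocus]:
    """Keep one call per genomic interval: longer tract wins, then smaller
    unit length, then leftmost start."""
    order = sorted(
        candidates, key=lambda l: (-l.tract_length, l.unit_length, l.start)
    )
    accepted: list[SSRLocus] = []
    for cand in order:
        if all(not cand.overlaps(a) for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda l: (l.start, l.unit_length))


def merge_compound(
    loci: Sequence[SSRLocus], max_interval: int = 100
) -> list[SSRLocus]:
    """Merge consecutive perfect loci separated by <= ``max_interval`` bp.

    Input loci must come from a single sequence, be sorted by start and
    non-overlapping.  Merging is transitive: a chain of loci with pairwise
    gaps within the interval collapses into one compound locus spanning from
    the first tract's start to the last tract's end.
    """
    loci = list(loci)
    if not loci:
        return []
    if len({l.seq_id for l in loci}) > 1:
        raise ValueError("merge_compound expects loci from a single sequence")
    groups: list[list[SSRLocus]] = [[loci[0]]]
    for prev, nxt in zip(loci, loci[1:]):
        if nxt.start <= prev.end:
            raise ValueError(
                f"overlapping input loci {prev.start}-{prev.end} and"
                f" {nxt.start}-{nxt.end}"
            )
        gap = nxt.start - prev.end - 1
        if gap <= max_interval:
            groups[-1].append(nxt)
        else:
            groups.append([nxt])
    merged: list[SSRLocus] = []
    for group in groups:
        if len(group) == 1:
            merged.append(group[0])
        else:
            merged.append(
                SSRLocus(
                    seq_id=group[0].seq_id,
                    start=group[0].start,
                    end=group[-1].end,
                    motif="+".join(g.motif for g in group),
                    repeat_count=0,
                    unit_length=0,
                    is_compound=True,
                    components=tuple(group),
                )
            )
    return merged


def canonical_motif_class(motif: str) -> MotifClass:
    """Canonical rotation/reverse-complement class of a primitive motif.

    Invariant under any rotation of the input and under reverse complement;
    e.g. ``GT``, ``TG``, ``CA`` and ``AC`` all map to ``AC/GT``.
    """
    motif = motif.upper()
    if not motif or len(motif) > 6:
        raise ValueError("motif must have length 1..6")
    if _INVALID_BASE.search(motif) or "N" in motif:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = reverse_complement(motif)
    rc_rotations = {rc[i:] + rc[:i] for i in range(len(rc))}
    canon = min(rotations | rc_rotations)
    # the partner label is the smallest rotation of the canonical strand's
    # reverse complement (survey-table convention: AGC/CTG, ATC/ATG)
    canon_rc = reverse_complement(canon)
    partner = min(canon_rc[i:] + canon_rc[:i] for i in range(len(canon_rc)))
    return MotifClass(f"{canon}/{partner}")


@dataclass(frozen=True)
class SexStats:
    """Per-pool headline statistics (the survey-table shape)."""

    total_sequences: int
    total_length_bp: int
    n_ssrs: int
    n_sequences_with_ssr: int
    n_sequences_with_multiple_ssr: int
    n_compound_ssrs: int
    frequency_pct: float
    density_bp_per_ssr: int | None


@dataclass(frozen=True)
class SSRSummary:
    """Full summary: headline stats plus per-type / per-class tables and
    repeat-number histograms, one column group per pool."""

    per_sex: dict[str, SexStats]
    type_table: pd.DataFrame
    class_table: pd.DataFrame
    repeat_histograms: dict[str, pd.DataFrame]


def summarize_ssrs(
    loci_by_sex: Mapping[str, Sequence[SSRLocus]],
    seq_lengths_by_sex: Mapping[str, Mapping[str, int]],
    params: SSRSearchParams | None = None,
) -> SSRSummary:
    """Summarise detected perfect loci per pool.

    ``loci_by_sex`` holds the *perfect* loci (pre compound merging); compound
    formation is recomputed here to count tracts in compound formation.
    Percentages are rounded half-up to two decimals; density (bp per SSR) to
    the nearest integer, absent when a pool has no SSRs.  Compound loci are
    counted via their constituent perfect tracts in the per-type and
    per-class tables.
    """
    params = params or SSRSearchParams()
    per_sex: dict[str, SexStats] = {}
    type_cols: dict[str, pd.Series] = {}
    class_counts: dict[str, Counter] = {}
    histograms: dict[str, pd.DataFrame] = {}
    for sex, loci in loci_by_sex.items():
        lengths = seq_lengths_by_sex.get(sex)
        if not lengths:
            raise ValueError(f"no sequences provided for pool {sex!r}")
        total_sequences = len(lengths)
        total_length = int(sum(lengths.values()))
        n_ssrs = len(loci)
        per_seq = Counter(l.seq_id for l in loci)
        with_ssr = len(per_seq)
        multi = sum(1 for c in per_seq.values() if c > 1)
        n_compound_tracts = 0
        by_seq: dict[str, list[SSRLocus]] = {}
        for l in sorted(loci, key=lambda x: (x.seq_id, x.start)):
            by_seq.setdefault(l.seq_id, []).append(l)
        for seq_loci in by_seq.values():
            for m in merge_compound(seq_loci, params.max_compound_interval):
                if m.is_compound:
                    n_compound_tracts += len(m.components)
        freq = ratio_pct(with_ssr, total_sequences)
        density = (
            int(round_half_up(Fraction(total_length, n_ssrs), 0))
            if n_ssrs
            else None
        )
        per_sex[sex] = SexStats(
            total_sequences=total_sequences,
            total_length_bp=total_length,
            n_ssrs=n_ssrs,
            n_sequences_with_ssr=with_ssr,
            n_sequences_with_multiple_ssr=multi,
            n_compound_ssrs=n_compound_tracts,
            frequency_pct=freq,
            density_bp_per_ssr=density,
        )
        unit_counts = Counter(l.unit_length for l in loci)
        counts = pd.Series(
            [unit_counts.get(u, 0) for u in range(1, 7)],
            index=[UNIT_NAMES[u] for u in range(1, 7)],
            dtype=int,
        )
        type_cols[f"{sex}_count"] = counts
        if n_ssrs:
            type_cols[f"{sex}_pct"] = counts.map(
                lambda c: ratio_pct(int(c), n_ssrs)
            )
        else:
            type_cols[f"{sex}_pct"] = counts.map(lambda c: 0.0)
        cc: Counter = Counter()
        for l in loci:
            cc[
                (l.unit_length, canonical_motif_class(l.motif).label)
            ] += 1
        class_counts[sex] = cc
        histograms[sex] = repeat_number_distribution(loci)

    type_table = pd.DataFrame(type_cols)
    type_table.loc["total"] = [
        type_table[c].sum() if c.endswith("_count") else round_half_up(
            sum(type_table[c].iloc[:6]), 2
        )
        for c in type_table.columns
    ]

    all_keys = sorted({k for cc in class_counts.values() for k in cc})
    class_table = pd.DataFrame(
        {
            f"{sex}_count": [class_counts[sex].get(k, 0) for k in all_keys]
            for sex in loci_by_sex
        },
        index=pd.MultiIndex.from_tuples(
            all_keys, names=["unit_length", "motif_class"]
        )
        if all_keys
        else None,
    )
    return SSRSummary(
        per_sex=per_sex,
        type_table=type_table,
        class_table=class_table,
        repeat_histograms=histograms,
    )


#: repeat-number histogram bins: exact counts 5..19 plus an overflow bin
HISTOGRAM_BINS = [str(k) for k in range(5, 20)] + [">19"]


def repeat_number_distribution(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """Histogram of motif repeat numbers (bins 5..19 and >19) per unit length.

    Compound loci are not accepted: pass perfect tracts (use the components
    of compound loci if needed).  Bin totals per unit length equal the locus
    counts for that unit length.
    """
    table = pd.DataFrame(
        0,
        index=HISTOGRAM_BINS,
        columns=[UNIT_NAMES[u] for u in range(1, 7)],
        dtype=int,
    )
    for l in loci:
        if l.is_compound:
            raise ValueError("repeat_number_distribution expects perfect loci")
        if l.repeat_count < 5:
            raise ValueError(
                f"repeat count {l.repeat_count} below the histogram range"
            )
        bin_label = str(l.repeat_count) if l.repeat_count <= 19 else ">19"
        table.loc[bin_label, UNIT_NAMES[l.unit_length]] += 1
    return table
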