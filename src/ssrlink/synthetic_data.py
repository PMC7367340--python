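"""Synthetic male/female scaffold pools with planted SSR loci and ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes: two pools of assembled scaffolds, each scaffold carrying at most
one planted SSR locus embedded in locus-specific flanking sequence, plus
SSR-free background scaffolds.  Planted loci come in three kinds: *shared*
loci present in both pools (with optional allele-length polymorphism
between copies), and strictly *female-specific* / *male-specific* loci
present in one pool only.  Each locus appears as several copies per pool
(mimicking allelic variants assembling separately); the first copy carries
the unmutated flank template, later copies receive substitution noise in
the flanks at a configured rate, and the repeat tracts themselves are
always exact.  Flank length straddles the 20 bp filter for a configured
fraction of shared loci, exercising the flank-length filter without
touching the sex-specific recovery benchmark.

Background sequence and flanks are rejection-sampled against the SSR
detector so that essentially no incidental repeat above the detection
thresholds exists outside the planted tracts, and the bases adjacent to a
tract are constrained so the tract cannot be extended by the detector.
Everything is driven by one seeded generator: identical seeds give
byte-identical pools and truth tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flank_cluster import Cluster
from .ssr_detect import (
    SSRSearchParams,
    find_perfect_ssrs,
    is_primitive,
)

__all__ = [
    "GeneratorConfig",
    "Placement",
    "TruthLocus",
    "TruthTable",
    "generate_pools",
    "truth_evaluate",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic pools.

    Defaults plant 200 shared plus 20 female-specific and 20 male-specific
    loci, two copies per pool per locus, 1% substitution noise in flank
    copies, an A/T-rich dinucleotide-dominated motif spectrum, and repeat
    counts at or above the detection minima.
    """

    seed: int = 0
    n_shared_loci: int = 200
    n_female_specific_loci: int = 20
    n_male_specific_loci: int = 20
    copies_per_pool: int = 2
    scaffold_length_range: tuple[int, int] = (600, 900)
    flank_length_range: tuple[int, int] = (160, 220)
    short_flank_fraction: float = 0.10
    flank_mutation_rate: float = 0.01
    allele_length_polymorphism_prob: float = 0.6
    unit_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.55, 3: 0.25, 4: 0.03, 5: 0.01, 6: 0.01}
    )
    at_richness: float = 0.70
    repeat_count_range: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: {
            1: (10, 16),
            2: (6, 14),
            3: (5, 10),
            4: (5, 8),
            5: (5, 7),
            6: (5, 6),
        }
    )
    gc_content: float = 0.35
    n_background_scaffolds: int = 50
    n_scaffolds_per_sex: int | None = None
    search_params: SSRSearchParams = field(default_factory=SSRSearchParams)

    def __post_init__(self) -> None:
        for name in (
            "n_shared_loci",
            "n_female_specific_loci",
            "n_male_specific_loci",
            "n_background_scaffolds",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.copies_per_pool < 1:
            raise ValueError("copies_per_pool must be >= 1")
        for name in (
            "short_flank_fraction",
            "flank_mutation_rate",
            "allele_length_polymorphism_prob",
            "gc_content",
            "at_richness",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for u, (lo, hi) in self.repeat_count_range.items():
            if lo > hi:
                raise ValueError(f"empty repeat count range for unit {u}")
            if lo < self.search_params.min_repeats[u]:
                raise ValueError(
                    f"repeat counts for unit {u} must respect the detection"
                    f" minimum {self.search_params.min_repeats[u]}"
                )

    @property
    def n_loci(self) -> int:
        return (
            self.n_shared_loci
            + self.n_female_specific_loci
            + self.n_male_specific_loci
        )


@dataclass(frozen=True)
class Placement:
    sex: str
    scaffold_id: str
    start: int  # 1-based inclusive tract coordinates on the scaffold
    end: int
    tract_length: int


@dataclass(frozen=True)
class TruthLocus:
    locus_id: str
    specificity: str  # shared | female | male
    motif: str
    unit_length: int
    base_repeat_count: int
    left_flank_len: int
    right_flank_len: int
    placements: tuple[Placement, ...]


@dataclass(frozen=True)
class TruthTable:
    """Ground truth mapping planted loci to placements and specificity."""

    loci: tuple[TruthLocus, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            for p in l.placements:
                rows.append(
                    {
                        "locus_id": l.locus_id,
                        "specificity": l.specificity,
                        "motif": l.motif,
                        "unit_length": l.unit_length,
                        "base_repeat_count": l.base_repeat_count,
                        "left_flank_len": l.left_flank_len,
                        "right_flank_len": l.right_flank_len,
                        "sex": p.sex,
                        "scaffold_id": p.scaffold_id,
                        "start": p.start,
                        "end": p.end,
                        "tract_length": p.tract_length,
                    }
                )
        return pd.DataFrame(rows)

    def ids_by_specificity(self, specificity: str) -> set[str]:
        return {l.locus_id for l in self.loci if l.specificity == specificity}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _ssr_free_seq(
    rng: np.random.Generator,
    length: int,
    config: GeneratorConfig,
    forbid_last: str | None = None,
    forbid_first: str | None = None,
    max_tries: int = 200,
) -> str:
    """Background/flank sequence with no detectable SSR and constrained
    boundary bases (so a planted tract cannot extend into it)."""
    if length == 0:
        return ""
    for _ in range(max_tries):
        seq = _random_seq(rng, length, config.gc_content)
        if forbid_last is not None and seq[-1] == forbid_last:
            allowed = [b for b in "ACGT" if b != forbid_last]
            seq = seq[:-1] + str(rng.choice(allowed))
        if forbid_first is not None and seq[0] == forbid_first:
            allowed = [b for b in "ACGT" if b != forbid_first]
            seq = str(rng.choice(allowed)) + seq[1:]
        if not find_perfect_ssrs(seq, "tmp", config.search_params):
            return seq
    raise RuntimeError("could not sample an SSR-free sequence")


def _draw_motif(rng: np.random.Generator, config: GeneratorConfig) -> str:
    units = sorted(config.unit_length_weights)
    weights = np.array([config.unit_length_weights[u] for u in units], float)
    weights /= weights.sum()
    at = config.at_richness
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    while True:
        u = int(rng.choice(units, p=weights))
        motif = "".join(rng.choice(_BASES, size=u, p=probs))
        if is_primitive(motif):
            return motif


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protect: set[int]
) -> str:
    """Substitution noise at ``rate`` per base, sparing ``protect`` positions."""
    if rate <= 0 or not seq:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if int(i) in protect:
            continue
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = str(rng.choice(alternatives))
    return "".join(chars)


def generate_pools(
    config: GeneratorConfig,
) -> tuple[dict[str, str], dict[str, str], TruthTable]:
    """Generate (male scaffolds, female scaffolds, truth) deterministically.

    Scaffolds are returned as insertion-ordered ``{scaffold_id: sequence}``
    maps.  Raises a config error when a planted core (flanks plus tract)
    cannot fit the maximum scaffold length.
    """
    rng = np.random.default_rng(config.seed)
    s_lo, s_hi = config.scaffold_length_range
    f_lo, f_hi = config.flank_length_range
    pools: dict[str, dict[str, str]] = {"male": {}, "female": {}}
    counters = {"male": 0, "female": 0}
    truth_loci: list[TruthLocus] = []

    kinds = (
        [("shared", i) for i in range(config.n_shared_loci)]
        + [("female", i) for i in range(config.n_female_specific_loci)]
        + [("male", i) for i in range(config.n_male_specific_loci)]
    )
    for kind, idx in kinds:
        motif = _draw_motif(rng, config)
        u = len(motif)
        c_lo, c_hi = config.repeat_count_range[u]
        base_count = int(rng.integers(c_lo, c_hi + 1))
        sexes = ["male", "female"] if kind == "shared" else [kind]
        # allele repeat counts: copy 0 of each pool carries the base allele
        counts_by_sex: dict[str, list[int]] = {}
        for sex in sexes:
            counts = [base_count]
            for _ in range(config.copies_per_pool - 1):
                if rng.random() < config.allele_length_polymorphism_prob:
                    delta = int(rng.choice([-2, -1, 1, 2]))
                    counts.append(max(c_lo, base_count + delta))
                else:
                    counts.append(base_count)
            counts_by_sex[sex] = counts
        # boundary constraints: every allele is a whole number of units, so
        # the detector would extend the tract only through motif[-1] on the
        # left or motif[0] on the right; forbid those bases at the junctions
        llen = int(rng.integers(f_lo, f_hi + 1))
        rlen = int(rng.integers(f_lo, f_hi + 1))
        # a fraction of shared loci sit at a scaffold edge with a genuinely
        # short flank on that side, exercising the 20 bp filter; no padding
        # is added on the short side, otherwise scaffold background would
        # silently restore the flank
        short_side = None
        if kind == "shared" and rng.random() < config.short_flank_fraction:
            short_side = "left" if rng.random() < 0.5 else "right"
            if short_side == "left":
                llen = int(rng.integers(5, 20))
            else:
                rlen = int(rng.integers(5, 20))
        left_template = _ssr_free_seq(
            rng, llen, config, forbid_last=motif[-1]
        )
        right_template = _ssr_free_seq(
            rng, rlen, config, forbid_first=motif[0]
        )
        max_tract = max(c for v in counts_by_sex.values() for c in v) * u
        if llen + rlen + max_tract > s_hi:
            raise ValueError(
                f"locus {kind}_{idx} core ({llen + rlen + max_tract} bp) does"
                f" not fit the maximum scaffold length {s_hi}"
            )
        placements: list[Placement] = []
        protect_left = {llen - 1} if llen else set()
        protect_right = {0} if rlen else set()
        for sex in sexes:
            for copy_idx, count in enumerate(counts_by_sex[sex]):
                if copy_idx == 0:
                    lf, rf = left_template, right_template
                else:
                    lf = _mutate(
                        rng, left_template, config.flank_mutation_rate, protect_left
                    )
                    rf = _mutate(
                        rng, right_template, config.flank_mutation_rate, protect_right
                    )
                tract = (motif * count)[: count * u]
                core = lf + tract + rf
                slen = int(rng.integers(s_lo, s_hi + 1))
                slen = max(slen, len(core))
                pad_total = slen - len(core)
                if short_side == "left":
                    pad_left = 0
                elif short_side == "right":
                    pad_left = pad_total
                else:
                    pad_left = int(rng.integers(0, pad_total + 1))
                scaffold = (
                    _ssr_free_seq(rng, pad_left, config)
                    + core
                    + _ssr_free_seq(rng, pad_total - pad_left, config)
                )
                sid = f"{'M' if sex == 'male' else 'F'}_scaf_{counters[sex]:05d}"
                counters[sex] += 1
                pools[sex][sid] = scaffold
                start = pad_left + len(lf) + 1
                placements.append(
                    Placement(
                        sex=sex,
                        scaffold_id=sid,
                        start=start,
                        end=start + count * u - 1,
                        tract_length=count * u,
                    )
                )
        truth_loci.append(
            TruthLocus(
                locus_id=f"{kind}_{idx:04d}",
                specificity=kind,
                motif=motif,
                unit_length=u,
                base_repeat_count=base_count,
                left_flank_len=llen,
                right_flank_len=rlen,
                placements=tuple(placements),
            )
        )
    for sex in ("male", "female"):
        for _ in range(config.n_background_scaffolds):
            slen = int(rng.integers(s_lo, s_hi + 1))
            sid = f"{'M' if sex == 'male' else 'F'}_scaf_{counters[sex]:05d}"
            counters[sex] += 1
            pools[sex][sid] = _ssr_free_seq(rng, slen, config)
    if config.n_scaffolds_per_sex is not None:
        for sex in ("male", "female"):
            if len(pools[sex]) > config.n_scaffolds_per_sex:
                raise ValueError(
                    "n_scaffolds_per_sex smaller than the number of planted"
                    " placements"
                )
            while len(pools[sex]) < config.n_scaffolds_per_sex:
                slen = int(rng.integers(s_lo, s_hi + 1))
                sid = f"{'M' if sex == 'male' else 'F'}_scaf_{counters[sex]:05d}"
                counters[sex] += 1
                pools[sex][sid] = _ssr_free_seq(rng, slen, config)
    return pools["male"], pools["female"], TruthTable(tuple(truth_loci))


def _attribute_record(
    record_id: str, placement_map: Mapping[str, list[tuple[int, int, str]]]
) -> str | None:
    """Map a masked-record id ``scaffold|start-end`` to a planted locus id by
    coordinate overlap with the truth placements."""
    scaffold, _, span = record_id.partition("|")
    try:
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError:
        return None
    for p_start, p_end, locus_id in placement_map.get(scaffold, []):
        if start <= p_end and p_start <= end:
            return locus_id
    return None


def truth_evaluate(
    predicted_clusters: Sequence[Cluster], truth: TruthTable
) -> tuple[float, float, pd.DataFrame]:
    """Precision/recall of female-specific cluster calling against truth.

    A predicted cluster is attributed to the unique planted locus its
    members overlap; clusters spanning several loci or none are counted as
    false positives and logged.  Precision is the fraction of predicted
    clusters attributed to truly female-specific loci; recall is the
    fraction of planted female-specific loci recovered by at least one
    predicted cluster.  With no predictions, precision is vacuously 1.0.
    """
    placement_map: dict[str, list[tuple[int, int, str]]] = {}
    specificity: dict[str, str] = {}
    for locus in truth.loci:
        specificity[locus.locus_id] = locus.specificity
        for p in locus.placements:
            placement_map.setdefault(p.scaffold_id, []).append(
                (p.start, p.end, locus.locus_id)
            )
    counts = {"female": 0, "male": 0, "shared": 0, "unattributed": 0}
    recovered: set[str] = set()
    for cluster in predicted_clusters:
        attributed = {
            _attribute_record(m.record_id, placement_map)
            for m in cluster.members
        }
        if len(attributed) != 1 or None in attributed:
            logger.warning(
                "cluster %s is not attributable to a unique planted locus",
                cluster.cluster_id,
            )
            counts["unattributed"] += 1
            continue
        locus_id = attributed.pop()
        kind = specificity[locus_id]
        counts[kind] += 1
        if kind == "female":
            recovered.add(locus_id)
    n_pred = len(predicted_clusters)
    tp = counts["female"]
    precision = tp / n_pred if n_pred else 1.0
    planted = truth.ids_by_specificity("female")
    recall = len(recovered) / len(planted) if planted else 1.0
    confusion = pd.DataFrame(
        {"n_predicted_clusters": pd.Series(counts)},
    )
    return precision, recall, confusion
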