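"""SSR masking, flank filtering and identity/coverage clustering.

The homology signal for a microsatellite locus lives in its flanking
sequence, not in the repeat tract itself (tract length varies between
alleles).  Each SSR-containing sequence is therefore converted to a
*masked record*: the repeat tract is replaced by a single mask token ``R``
so that alleles of different tract length have identical masked sequences,
while the original tract length is kept as metadata for length-polymorphism
scoring.  Records whose flanks are shorter than 20 bp on either side are
discarded (too short for a reliable similarity comparison), and the
remainder are clustered greedily by local-alignment identity and coverage:
95%/70% for the within-pool passes, 80%/70% for the pooled cross-sex pass
whose female-only clusters are the sex-linked candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._align import encode, sw_traceback_counts
from .ssr_detect import SSRLocus

__all__ = [
    "MASK_TOKEN",
    "MaskedRecord",
    "ClusterParams",
    "Cluster",
    "mask_record",
    "mask_records",
    "filter_flanks",
    "align_identity",
    "greedy_cluster",
    "classify_sex_specific",
]

logger = logging.getLogger(__name__)

MASK_TOKEN = "R"


@dataclass(frozen=True)
class MaskedRecord:
    """A sequence with its SSR tract replaced by one mask token.

    ``masked_seq`` is ``left_flank + 'R' + right_flank``; flank lengths are
    stored explicitly (they drive the 20 bp filter) and the original tract
    length is preserved for SSLP scoring.  A source sequence with several
    SSRs yields one MaskedRecord per locus.
    """

    record_id: str
    sex: str
    masked_seq: str
    left_flank_len: int
    right_flank_len: int
    locus: SSRLocus
    original_tract_length: int

    def __post_init__(self) -> None:
        if self.masked_seq.count(MASK_TOKEN) != 1:
            raise ValueError("masked_seq must contain exactly one mask token")


@dataclass(frozen=True)
class ClusterParams:
    """Identity/coverage thresholds and alignment penalties.

    Identity is ``matches / alignment columns`` of the best local alignment;
    coverage is the fraction of the shorter sequence inside that alignment.
    Defaults follow the two published threshold sets: 0.95/0.70 within a
    pool, 0.80/0.70 across pools (pass ``identity_threshold=0.80``).
    """

    identity_threshold: float = 0.95
    coverage_threshold: float = 0.70
    gap_open_penalty: float = 1.0
    gap_extend_penalty: float = 0.0
    match_score: float = 1.0
    mismatch_penalty: float = 1.0

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class Cluster:
    """A group of masked records deemed homologous.

    The representative is the founding (longest) member; every other member
    passed the identity/coverage thresholds against it.
    """

    cluster_id: int
    members: list[MaskedRecord] = field(default_factory=list)

    @property
    def representative(self) -> MaskedRecord:
        return self.members[0]

    @property
    def sexes_present(self) -> frozenset[str]:
        return frozenset(m.sex for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


def mask_record(
    seq: str,
    seq_id: str,
    sex: str,
    locus: SSRLocus,
    max_flank: int | None = None,
) -> MaskedRecord:
    """Replace the tract of ``locus`` by the mask token.

    ``max_flank`` optionally truncates each flank to at most that many bases
    nearest the tract (keeps alignment cost bounded on long scaffolds while
    retaining far more context than the 20 bp filter needs).
    """
    if not 1 <= locus.start <= locus.end <= len(seq):
        raise ValueError(
            f"locus {locus.start}-{locus.end} out of bounds for sequence"
            f" {seq_id!r} of length {len(seq)}"
        )
    left = seq[: locus.start - 1]
    right = seq[locus.end :]
    if max_flank is not None:
        left = left[-max_flank:] if max_flank else ""
        right = right[:max_flank]
    return MaskedRecord(
        record_id=f"{seq_id}|{locus.start}-{locus.end}",
        sex=sex,
        masked_seq=left + MASK_TOKEN + right,
        left_flank_len=len(left),
        right_flank_len=len(right),
        locus=locus,
        original_tract_length=locus.tract_length,
    )


def mask_records(
    seq: str,
    seq_id: str,
    sex: str,
    loci: Sequence[SSRLocus],
    max_flank: int | None = None,
) -> list[MaskedRecord]:
    """One MaskedRecord per locus (multi-SSR sequences are split)."""
    return [mask_record(seq, seq_id, sex, l, max_flank) for l in loci]


def filter_flanks(
    records: Iterable[MaskedRecord], min_flank: int = 20
) -> list[MaskedRecord]:
    """Keep records whose flanks are both >= ``min_flank`` bp (inclusive)."""
    return [
        r
        for r in records
        if r.left_flank_len >= min_flank and r.right_flank_len >= min_flank
    ]


def align_identity(
    a: str, b: str, params: ClusterParams | None = None
) -> tuple[float, float]:
    """Identity and coverage of the best local alignment of ``a`` vs ``b``.

    identity = matches / alignment columns (gap columns included);
    coverage = residues of the *shorter* sequence inside the alignment,
    divided by its full length.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    params = params or ClusterParams()
    # canonical argument order guarantees symmetry despite traceback tie-breaks
    if (len(a), a) <= (len(b), b):
        short, long_ = a, b
    else:
        short, long_ = b, a
    _, matches, columns, short_used, _ = sw_traceback_counts(
        encode(short),
        encode(long_),
        params.match_score,
        -params.mismatch_penalty,
        params.gap_open_penalty,
        params.gap_extend_penalty,
    )
    if columns == 0:
        return 0.0, 0.0
    return matches / columns, short_used / len(short)


def greedy_cluster(
    records: Sequence[MaskedRecord],
    params: ClusterParams | None = None,
    prefilter_k: int | None = 16,
) -> list[Cluster]:
    """Greedy incremental (CD-HIT style) clustering of masked records.

    Records are sorted by length descending (ties by record id) and each is
    compared against existing cluster representatives in creation order,
    joining the first whose identity and coverage both meet the thresholds,
    or founding a new cluster.  Deterministic given the input set.

    ``prefilter_k`` enables a k-mer screen: a representative is aligned only
    when it shares at least one ``prefilter_k``-mer with the query (records
    shorter than the k value are always aligned).  At the published
    thresholds a passing pair shares many such words, so the screen prunes
    unrelated pairs without affecting the partition; pass ``None`` to
    disable it.
    """
    params = params or ClusterParams()
    order = sorted(records, key=lambda r: (-len(r.masked_seq), r.record_id))
    clusters: list[Cluster] = []
    rep_kmers: list[set[str] | None] = []
    seen_seq: dict[str, Cluster] = {}

    def kmers(seq: str) -> set[str] | None:
        if prefilter_k is None or len(seq) < prefilter_k:
            return None
        return {seq[i : i + prefilter_k] for i in range(len(seq) - prefilter_k + 1)}

    for rec in order:
        # identical masked sequences always co-cluster (and this shortcut
        # returns exactly what a full scan would: alignment outcomes depend
        # only on the sequence)
        hit = seen_seq.get(rec.masked_seq)
        if hit is not None:
            hit.members.append(rec)
            continue
        q_kmers = kmers(rec.masked_seq)
        target = None
        for cluster, r_kmers in zip(clusters, rep_kmers):
            if (
                q_kmers is not None
                and r_kmers is not None
                and q_kmers.isdisjoint(r_kmers)
            ):
                continue
            identity, coverage = align_identity(
                rec.masked_seq, cluster.representative.masked_seq, params
            )
            if (
                identity >= params.identity_threshold
                and coverage >= params.coverage_threshold
            ):
                target = cluster
                break
        if target is None:
            target = Cluster(cluster_id=len(clusters))
            clusters.append(target)
            rep_kmers.append(kmers(rec.masked_seq))
        target.members.append(rec)
        seen_seq[rec.masked_seq] = target
    return clusters


def classify_sex_specific(
    clusters: Sequence[Cluster],
) -> dict[str, list[Cluster]]:
    """Partition clusters by sex of origin of their members.

    ``female_specific`` clusters contain only female-pool records,
    ``male_specific`` only male-pool records, ``shared`` both.  The three
    lists are disjoint and exhaustive.
    """
    partition: dict[str, list[Cluster]] = {
        "female_specific": [],
        "male_specific": [],
        "shared": [],
    }
    for cluster in clusters:
        sexes = cluster.sexes_present
        if not sexes or not sexes <= {"male", "female"}:
            bad = sorted(sexes - {"male", "female"})
            raise ValueError(
                f"cluster {cluster.cluster_id} has unlabeled members: {bad}"
            )
        if sexes == {"female"}:
            partition["female_specific"].append(cluster)
        elif sexes == {"male"}:
            partition["male_specific"].append(cluster)
        else:
            partition["shared"].append(cluster)
    return partition
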