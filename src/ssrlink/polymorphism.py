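"""SSR length polymorphism (SSLP) scoring per cluster.

Within a cluster of homologous masked records, allelic variation shows up
as distinct original repeat-tract lengths.  The SSLP score of a cluster is
the number of distinct tract lengths among its members: 1 when all lengths
agree, 2 for two lengths, and so on.  The distribution is binned as
SSLP = 1..9 plus SSLP >= 10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from ._util import ratio_pct
from .flank_cluster import Cluster

__all__ = ["SSLPScore", "sslp_score", "sslp_distribution", "SSLP_BINS"]


@dataclass(frozen=True)
class SSLPScore:
    cluster_id: int
    score: int
    distinct_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.score != len(self.distinct_lengths) or self.score < 1:
            raise ValueError("score must equal the number of distinct lengths")


def sslp_score(cluster: Cluster) -> SSLPScore:
    """Score = number of distinct repeat-tract lengths (bp) in the cluster."""
    if not cluster.members:
        raise ValueError(f"cluster {cluster.cluster_id} is empty")
    lengths = tuple(
        sorted({m.original_tract_length for m in cluster.members})
    )
    return SSLPScore(
        cluster_id=cluster.cluster_id,
        score=len(lengths),
        distinct_lengths=lengths,
    )


SSLP_BINS = [f"SSLP = {k}" for k in range(1, 10)] + ["SSLP >= 10"]


def sslp_distribution(scores: Iterable[SSLPScore]) -> pd.DataFrame:
    """Binned SSLP counts and percentages (two decimals, half-up).

    Bin counts sum to the number of clusters scored; the returned frame has
    one row per bin plus a ``Total`` row.
    """
    scores = list(scores)
    counts: Counter = Counter()
    for s in scores:
        counts[s.score if s.score <= 9 else 10] += 1
    total = len(scores)
    rows = []
    for k, label in zip(list(range(1, 10)) + [10], SSLP_BINS):
        c = counts.get(k, 0)
        rows.append((label, c, ratio_pct(c, total) if total else 0.0))
    rows.append(("Total", total, 100.0 if total else 0.0))
    return pd.DataFrame(rows, columns=["bin", "count", "pct"]).set_index("bin")
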