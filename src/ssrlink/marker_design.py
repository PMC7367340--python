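"""Primer design and screening for sex-linked SSR marker candidates.

Female-specific clusters with a length polymorphism (SSLP >= 2) are turned
into PCR markers: a mask-anchored consensus of the cluster flanks is built,
primer pairs are enumerated in the two flanks under standard constraints
(length 18-27 nt, Tm 57-63 C, GC 0.30-0.70, no homopolymer run > 4,
product 100-400 bp spanning the whole repeat tract), and survivors are
screened with five rules: no mononucleotide or compound repeats, exactly
one SSR type inside the amplicon, primers inside the cluster consensus with
SSLP >= 2, both binding sites exactly conserved in at least two cluster
members, and exact duplicate pairs removed.  Candidates are finally
validated by in-silico PCR against the original (unmasked) male and female
pools: a usable sex marker amplifies from female templates only.

Melting temperatures come from a nearest-neighbour thermodynamic model
(unified dimer parameters, two-decade standard set) at fixed, documented
conditions: 250 nM primer, 50 mM monovalent salt, entropic salt correction
0.368 * (N-1) * ln[Na+].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .flank_cluster import MASK_TOKEN, Cluster
from .polymorphism import SSLPScore
from .ssr_detect import (
    SSRSearchParams,
    canonical_motif_class,
    find_perfect_ssrs,
    merge_compound,
    reverse_complement,
)

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "MarkerCandidate",
    "melting_temp",
    "cluster_consensus",
    "select_candidate_clusters",
    "design_primers",
    "screen_primers",
    "dedupe_candidates",
    "insilico_pcr",
]

# Unified nearest-neighbour dimer parameters: dH kcal/mol, dS cal/(mol K),
# keyed by the top-strand 5'->3' dimer; a dimer and its reverse complement
# share one duplex and therefore one entry value.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation terms per terminal base
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
_R_GAS = 1.987  # cal/(mol K)


def melting_temp(
    primer: str, primer_nM: float = 250.0, na_mM: float = 50.0
) -> float:
    """Nearest-neighbour duplex melting temperature in degrees Celsius.

    Deterministic; a primer and its reverse complement have equal Tm, and
    substituting A/T content for G/C raises it.  Ambiguous bases raise.
    """
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError("primer too short for a nearest-neighbor estimate")
    if any(b not in "ACGT" for b in primer):
        bad = next(b for b in primer if b not in "ACGT")
        raise ValueError(f"ambiguous base {bad!r} in primer")
    dh = _INIT[primer[0]][0] + _INIT[primer[-1]][0]
    ds = _INIT[primer[0]][1] + _INIT[primer[-1]][1]
    for i in range(len(primer) - 1):
        h, s = _NN[primer[i : i + 2]]
        dh += h
        ds += s
    if primer == reverse_complement(primer):
        ds += -1.4  # symmetry correction for self-complementary duplexes
    ds += 0.368 * (len(primer) - 1) * math.log(na_mM / 1000.0)
    ct = primer_nM * 1e-9
    return 1000.0 * dh / (ds + _R_GAS * math.log(ct)) - 273.15


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraints; defaults follow common SSR-genotyping practice."""

    product_range: tuple[int, int] = (100, 400)
    primer_length: tuple[int, int] = (18, 27)
    tm_range: tuple[float, float] = (57.0, 63.0)
    gc_range: tuple[float, float] = (0.30, 0.70)
    max_homopolymer: int = 4
    max_candidates_per_flank: int = 40
    max_pairs: int = 10


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on a masked consensus.

    The reverse primer is stored 5'->3' on the reverse strand.
    ``product_size`` is computed with the longest allele of the cluster;
    ``forward_start`` and ``reverse_site_start`` are 0-based offsets of the
    forward primer in the left flank and of the reverse-primer binding site
    in the right flank of the consensus.
    """

    forward_seq: str
    reverse_seq: str
    forward_tm: float
    reverse_tm: float
    product_size: int
    forward_start: int
    reverse_site_start: int


@dataclass(frozen=True)
class MarkerCandidate:
    """A screened sex-linked marker: cluster, primer pair, expected products."""

    cluster_id: int
    primer_pair: PrimerPair
    motif_class: str
    sslp_score: int
    expected_products_by_sex: Mapping[str, tuple[int, ...]] = field(
        default_factory=dict
    )


def cluster_consensus(cluster: Cluster) -> str:
    """Mask-anchored majority consensus of a cluster's masked sequences.

    Flank columns are indexed outward from the mask token (members differ
    only by substitutions and by how far their flanks extend, so the mask is
    the natural anchor).  A column is kept while it is present in at least
    half of the members; the majority base wins, ties broken alphabetically.
    """
    if not cluster.members:
        raise ValueError("cannot build a consensus for an empty cluster")
    lefts = []
    rights = []
    for m in cluster.members:
        left, right = m.masked_seq.split(MASK_TOKEN)
        lefts.append(left)
        rights.append(right)
    n = len(cluster.members)

    def majority(column: list[str]) -> str:
        counts = Counter(column)
        top = max(counts.values())
        return min(b for b, c in counts.items() if c == top)

    left_cols = []
    for k in range(1, max(len(l) for l in lefts) + 1):
        col = [l[-k] for l in lefts if len(l) >= k]
        if 2 * len(col) < n:
            break
        left_cols.append(majority(col))
    right_cols = []
    for k in range(max(len(r) for r in rights)):
        col = [r[k] for r in rights if len(r) > k]
        if 2 * len(col) < n:
            break
        right_cols.append(majority(col))
    return "".join(reversed(left_cols)) + MASK_TOKEN + "".join(right_cols)


def select_candidate_clusters(
    clusters: Sequence[Cluster], scores: Mapping[int, SSLPScore]
) -> list[int]:
    """Cluster ids eligible for primer design.

    Requires SSLP >= 2 (a monomorphic locus cannot give a length marker),
    a non-mononucleotide primitive motif, no compound loci, and a single
    motif class across members (one SSR type per marker).
    """
    keep: list[int] = []
    for cluster in clusters:
        score = scores.get(cluster.cluster_id)
        if score is None or score.score < 2:
            continue
        loci = [m.locus for m in cluster.members]
        if any(l.is_compound for l in loci):
            continue
        if any(l.unit_length < 2 for l in loci):
            continue
        classes = {canonical_motif_class(l.motif).label for l in loci}
        if len(classes) != 1:
            continue
        keep.append(cluster.cluster_id)
    return keep


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _flank_candidates(
    flank: str, constraints: PrimerConstraints
) -> list[tuple[int, str, float]]:
    """All (start, sequence, Tm) windows in a flank passing the per-primer
    constraints, capped to the windows with Tm nearest the range midpoint."""
    lo, hi = constraints.primer_length
    tlo, thi = constraints.tm_range
    glo, ghi = constraints.gc_range
    mid = (tlo + thi) / 2
    out = []
    for length in range(lo, hi + 1):
        for start in range(len(flank) - length + 1):
            sub = flank[start : start + length]
            if not glo <= _gc_fraction(sub) <= ghi:
                continue
            if _max_run(sub) > constraints.max_homopolymer:
                continue
            tm = melting_temp(sub)
            if not tlo <= tm <= thi:
                continue
            out.append((start, sub, tm))
    out.sort(key=lambda c: (abs(c[2] - mid), c[0], len(c[1])))
    return out[: constraints.max_candidates_per_flank]


def design_primers(
    consensus: str,
    member_tract_lengths: Sequence[int],
    constraints: PrimerConstraints | None = None,
) -> list[PrimerPair]:
    """Enumerate primer pairs on a masked consensus.

    The amplicon always spans the entire repeat tract.  The reported product
    size uses the longest member allele; feasibility additionally requires
    the *shortest* allele's product to stay at or above the lower bound, so
    every allele of the series remains inside the scorable size window.
    Pairs are ranked by ``|Tm_f - Tm_r|`` (then product size, then position)
    and at most ``constraints.max_pairs`` are returned; an empty list means
    no feasible pair, which is not an error.
    """
    constraints = constraints or PrimerConstraints()
    if consensus.count(MASK_TOKEN) != 1:
        raise ValueError("consensus must contain exactly one mask token")
    if not member_tract_lengths:
        raise ValueError("member tract lengths required for product sizing")
    left, right = consensus.split(MASK_TOKEN)
    t_long = max(member_tract_lengths)
    t_short = min(member_tract_lengths)
    p_lo, p_hi = constraints.product_range
    fwd_cands = _flank_candidates(left, constraints)
    rev_sites = _flank_candidates(right, constraints)
    pairs = []
    for fi, fseq, ftm in fwd_cands:
        left_arm = len(left) - fi
        for rj, site, stm in rev_sites:
            right_arm = rj + len(site)
            if left_arm + t_long + right_arm > p_hi:
                continue
            if left_arm + t_short + right_arm < p_lo:
                continue
            pairs.append(
                PrimerPair(
                    forward_seq=fseq,
                    reverse_seq=reverse_complement(site),
                    forward_tm=round(ftm, 2),
                    reverse_tm=round(stm, 2),
                    product_size=left_arm + t_long + right_arm,
                    forward_start=fi,
                    reverse_site_start=rj,
                )
            )
    pairs.sort(
        key=lambda p: (
            abs(p.forward_tm - p.reverse_tm),
            p.product_size,
            p.forward_start,
            p.reverse_site_start,
        )
    )
    return pairs[: constraints.max_pairs]


def _amplicon_template(cluster: Cluster, consensus: str) -> tuple[str, int]:
    """Consensus with the mask expanded to the longest member allele tract."""
    rep_locus = cluster.representative.locus
    t_long = max(m.original_tract_length for m in cluster.members)
    motif = rep_locus.motif
    tract = (motif * (t_long // len(motif) + 1))[:t_long]
    left, right = consensus.split(MASK_TOKEN)
    return left + tract + right, t_long


def screen_primers(
    pairs: Sequence[PrimerPair],
    cluster: Cluster,
    consensus: str,
    score: SSLPScore,
    search_params: SSRSearchParams | None = None,
    min_member_support: int = 2,
) -> list[MarkerCandidate]:
    """Apply the five marker screening rules to designed pairs.

    (1) mono/compound motifs are excluded (checked on the members' loci);
    (2) the amplicon contains exactly one SSR of the cluster's motif class;
    (3) primers lie in the cluster consensus and the cluster has SSLP >= 2;
    (4) both primer binding sites are exactly conserved in at least
    ``min_member_support`` members; (5) duplicate pairs are dropped.
    """
    search_params = search_params or SSRSearchParams()
    loci = [m.locus for m in cluster.members]
    if any(l.is_compound or l.unit_length < 2 for l in loci):
        return []
    classes = {canonical_motif_class(l.motif).label for l in loci}
    if len(classes) != 1 or score.score < 2:
        return []
    motif_class = classes.pop()
    template, t_long = _amplicon_template(cluster, consensus)
    left, _ = consensus.split(MASK_TOKEN)
    out: list[MarkerCandidate] = []
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        key = (pair.forward_seq, pair.reverse_seq)
        if key in seen:
            continue
        site = reverse_complement(pair.reverse_seq)
        amp_start = pair.forward_start
        amp_end = len(left) + t_long + pair.reverse_site_start + len(site)
        amplicon = template[amp_start:amp_end]
        if not amplicon.startswith(pair.forward_seq) or not amplicon.endswith(
            site
        ):
            continue
        amp_loci = merge_compound(
            find_perfect_ssrs(amplicon, "amplicon", search_params),
            search_params.max_compound_interval,
        )
        if len(amp_loci) != 1 or amp_loci[0].is_compound:
            continue
        if canonical_motif_class(amp_loci[0].motif).label != motif_class:
            continue
        fwd_support = sum(
            1 for m in cluster.members if pair.forward_seq in m.masked_seq
        )
        rev_support = sum(1 for m in cluster.members if site in m.masked_seq)
        if fwd_support < min_member_support or rev_support < min_member_support:
            continue
        seen.add(key)
        out.append(
            MarkerCandidate(
                cluster_id=cluster.cluster_id,
                primer_pair=pair,
                motif_class=motif_class,
                sslp_score=score.score,
            )
        )
    return out


def dedupe_candidates(
    candidates: Iterable[MarkerCandidate],
) -> list[MarkerCandidate]:
    """Drop candidates whose exact primer pair already appeared (rule 5
    applied across clusters)."""
    out = []
    seen: set[tuple[str, str]] = set()
    for c in candidates:
        key = (c.primer_pair.forward_seq, c.primer_pair.reverse_seq)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


def _exact_sites(template: str, word: str) -> list[int]:
    sites = []
    pos = template.find(word)
    while pos != -1:
        sites.append(pos)
        pos = template.find(word, pos + 1)
    return sites


def _approx_sites(
    template: str, word: str, max_mismatch: int, seed_len: int, seed_at_end: bool
) -> list[int]:
    """Start positions where ``word`` matches with <= max_mismatch mismatches
    and an exact seed at its 3'-proximal end (right end when ``seed_at_end``)."""
    if max_mismatch <= 0:
        return _exact_sites(template, word)
    n = len(word)
    seed = word[-seed_len:] if seed_at_end else word[:seed_len]
    offset = n - seed_len if seed_at_end else 0
    sites = []
    pos = template.find(seed)
    while pos != -1:
        start = pos - offset
        if 0 <= start <= len(template) - n:
            mism = sum(
                1 for a, b in zip(word, template[start : start + n]) if a != b
            )
            if mism <= max_mismatch:
                sites.append(start)
        pos = template.find(seed, pos + 1)
    return sorted(set(sites))


def insilico_pcr(
    pair: PrimerPair,
    templates: Mapping[str, str] | Iterable[tuple[str, str]],
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    max_product: int = 2000,
) -> list[tuple[str, int]]:
    """Predict PCR products of a primer pair on unmasked templates.

    A product is reported wherever the two primers bind convergently within
    ``max_product`` bp, each with at most ``max_mismatch`` mismatches and an
    exact ``three_prime_exact``-base 3' seed.  Both template orientations
    are scanned.  Product size includes both primers.
    """
    if isinstance(templates, Mapping):
        items: Iterable[tuple[str, str]] = templates.items()
    else:
        items = templates
    fwd = pair.forward_seq.upper()
    rev = pair.reverse_seq.upper()
    products: list[tuple[str, int]] = []
    for tid, seq in items:
        seq = seq.upper()
        for upstream, downstream in ((fwd, rev), (rev, fwd)):
            # upstream primer on the plus strand (3' end at its right edge),
            # downstream primer on the minus strand: its plus-strand binding
            # site is the reverse complement, 3' end at the site's left edge.
            up_sites = _approx_sites(
                seq, upstream, max_mismatch, three_prime_exact, True
            )
            if not up_sites:
                continue
            down_site = reverse_complement(downstream)
            down_sites = _approx_sites(
                seq, down_site, max_mismatch, three_prime_exact, False
            )
            for u in up_sites:
                for d in down_sites:
                    end = d + len(down_site)
                    size = end - u
                    if d < u + len(upstream) or end < u:
                        continue
                    if size > max_product:
                        continue
                    products.append((tid, size))
    return sorted(set(products))
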