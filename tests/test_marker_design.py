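"""Melting temperature, consensus, primer design/screening, in-silico PCR."""

import numpy as np
import pytest

from ssrlink.flank_cluster import Cluster, MaskedRecord
from ssrlink.marker_design import (
    PrimerConstraints,
    PrimerPair,
    cluster_consensus,
    dedupe_candidates,
    design_primers,
    insilico_pcr,
    melting_temp,
    screen_primers,
    select_candidate_clusters,
)
from ssrlink.polymorphism import sslp_score
from ssrlink.ssr_detect import SSRLocus, reverse_complement


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _member(cid, i, left, right, motif, reps):
    tract = len(motif) * reps
    locus = SSRLocus(
        f"scaf_c{cid}_{i}", len(left) + 1, len(left) + tract, motif, reps,
        len(motif),
    )
    return MaskedRecord(
        record_id=f"c{cid}m{i}",
        sex="female",
        masked_seq=left + "R" + right,
        left_flank_len=len(left),
        right_flank_len=len(right),
        locus=locus,
        original_tract_length=tract,
    )


class TestMeltingTemp:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temp("A" * 18) < melting_temp("GC" * 9)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            primer = _rand(rng, 20)
            assert melting_temp(primer) == pytest.approx(
                melting_temp(reverse_complement(primer))
            )

    def test_agreement_with_published_nearest_neighbor_calculator(self):
        from Bio.SeqUtils import MeltingTemp as mt

        rng = np.random.default_rng(1)
        for _ in range(10):
            primer = _rand(rng, 20)
            reference = mt.Tm_NN(
                primer, nn_table=mt.DNA_NN3, dnac1=250, dnac2=0,
                Na=50, saltcorr=5,
            )
            assert melting_temp(primer) == pytest.approx(reference, abs=1.5)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            melting_temp("ACGTACGTNACGTACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            melting_temp("ACGTACG")


class TestClusterConsensus:
    def test_majority_vote_restores_template(self):
        rng = np.random.default_rng(2)
        left, right = _rand(rng, 60), _rand(rng, 60)
        members = []
        for i in range(3):
            l = list(left)
            if i == 2:
                l[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[l[10]]
            members.append(_member(0, i, "".join(l), right, "AG", 8 + i))
        consensus = cluster_consensus(Cluster(0, members))
        assert consensus == left + "R" + right

    def test_sparse_columns_dropped(self):
        rng = np.random.default_rng(3)
        left, right = _rand(rng, 50), _rand(rng, 50)
        members = [
            _member(0, 0, left, right, "AG", 8),
            _member(0, 1, left[30:], right, "AG", 8),
            _member(0, 2, left[30:], right, "AG", 8),
        ]
        consensus = cluster_consensus(Cluster(0, members))
        # only the last 20 left-flank columns are present in >= half
        assert consensus == left[30:] + "R" + right


class TestSelectCandidateClusters:
    def _scored(self, cluster):
        return {cluster.cluster_id: sslp_score(cluster)}

    def test_polymorphic_dinucleotide_kept(self):
        rng = np.random.default_rng(4)
        left, right = _rand(rng, 40), _rand(rng, 40)
        c = Cluster(0, [_member(0, i, left, right, "AG", 8 + i) for i in range(3)])
        assert select_candidate_clusters([c], self._scored(c)) == [0]

    def test_mononucleotide_excluded(self):
        rng = np.random.default_rng(5)
        left, right = _rand(rng, 40), _rand(rng, 40)
        c = Cluster(0, [_member(0, i, left, right, "A", 12 + i) for i in range(3)])
        assert select_candidate_clusters([c], self._scored(c)) == []

    def test_monomorphic_excluded(self):
        rng = np.random.default_rng(6)
        left, right = _rand(rng, 40), _rand(rng, 40)
        c = Cluster(0, [_member(0, i, left, right, "AG", 8) for i in range(3)])
        assert select_candidate_clusters([c], self._scored(c)) == []

    def test_compound_excluded(self):
        rng = np.random.default_rng(7)
        left, right = _rand(rng, 40), _rand(rng, 40)
        base = [_member(0, i, left, right, "AG", 8 + i) for i in range(2)]
        perfect = [
            SSRLocus("s", 41, 56, "AG", 8, 2),
            SSRLocus("s", 60, 71, "TC", 6, 2),
        ]
        compound_locus = SSRLocus(
            "s", 41, 71, "AG+TC", 0, 0, is_compound=True,
            components=tuple(perfect),
        )
        comp = MaskedRecord(
            record_id="c0m9", sex="female",
            masked_seq=left + "R" + right,
            left_flank_len=40, right_flank_len=40,
            locus=compound_locus, original_tract_length=31,
        )
        c = Cluster(0, base + [comp])
        assert select_candidate_clusters([c], self._scored(c)) == []


class TestDesignPrimers:
    def test_feasible_cluster_yields_spanning_pairs(self):
        rng = np.random.default_rng(8)
        left, right = _rand(rng, 150), _rand(rng, 150)
        consensus = left + "R" + right
        pairs = design_primers(consensus, [20, 24])
        assert pairs
        for p in pairs:
            assert 100 <= p.product_size <= 400
            assert left[p.forward_start :].startswith(p.forward_seq)
            site = reverse_complement(p.reverse_seq)
            assert right[p.reverse_site_start :].startswith(site)
            # product spans the whole tract: forward in left flank, site in
            # right flank, longest allele counted between them
            left_arm = len(left) - p.forward_start
            right_arm = p.reverse_site_start + len(site)
            assert p.product_size == left_arm + 24 + right_arm

    def test_short_flanks_are_infeasible(self):
        rng = np.random.default_rng(9)
        consensus = _rand(rng, 30) + "R" + _rand(rng, 30)
        assert design_primers(consensus, [20]) == []

    def test_all_alleles_stay_in_product_window(self):
        rng = np.random.default_rng(10)
        consensus = _rand(rng, 150) + "R" + _rand(rng, 150)
        lengths = [12, 36]
        for p in design_primers(consensus, lengths):
            left_arm = 150 - p.forward_start
            right_arm = p.reverse_site_start + len(p.reverse_seq)
            assert left_arm + max(lengths) + right_arm <= 400
            assert left_arm + min(lengths) + right_arm >= 100

    def test_pairs_ranked_by_tm_difference(self):
        rng = np.random.default_rng(11)
        consensus = _rand(rng, 150) + "R" + _rand(rng, 150)
        pairs = design_primers(consensus, [20, 24])
        diffs = [abs(p.forward_tm - p.reverse_tm) for p in pairs]
        assert diffs == sorted(diffs)


def _pair(fwd, site, fwd_start, site_start, product):
    return PrimerPair(
        forward_seq=fwd,
        reverse_seq=reverse_complement(site),
        forward_tm=round(melting_temp(fwd), 2),
        reverse_tm=round(melting_temp(site), 2),
        product_size=product,
        forward_start=fwd_start,
        reverse_site_start=site_start,
    )


class TestScreenPrimers:
    def _cluster(self, rng, left, right, motif="AG", reps=(8, 10)):
        members = [
            _member(0, i, left, right, motif, r) for i, r in enumerate(reps)
        ]
        return Cluster(0, members)

    def test_second_repeat_inside_amplicon_rejected(self):
        rng = np.random.default_rng(12)
        left = _rand(rng, 120)
        # a second tract 30 bp after the target: any amplicon reaching past
        # it contains two repeats (reported as one compound span)
        right = _rand(rng, 30) + "CT" * 8 + _rand(rng, 60)
        cluster = self._cluster(rng, left, right)
        consensus = cluster_consensus(cluster)
        score = sslp_score(cluster)
        beyond = _pair(left[80:100], right[60:80], 80, 60, 40 + 20 + 80)
        within = _pair(left[80:100], right[5:25], 80, 5, 40 + 20 + 25)
        kept = screen_primers([beyond, within], cluster, consensus, score)
        assert [c.primer_pair for c in kept] == [within]

    def test_duplicate_pairs_removed(self):
        rng = np.random.default_rng(13)
        left, right = _rand(rng, 120), _rand(rng, 120)
        cluster = self._cluster(rng, left, right)
        consensus = cluster_consensus(cluster)
        score = sslp_score(cluster)
        pair = _pair(left[80:100], right[40:60], 80, 40, 40 + 20 + 60)
        kept = screen_primers([pair, pair], cluster, consensus, score)
        assert len(kept) == 1

    def test_site_mutated_in_all_but_one_member_rejected(self):
        rng = np.random.default_rng(14)
        left, right = _rand(rng, 120), _rand(rng, 120)
        members = [_member(0, 0, left, right, "AG", 8)]
        mutated = list(left)
        mutated[90] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[90]]
        members.append(_member(0, 1, "".join(mutated), right, "AG", 10))
        cluster = Cluster(0, members)
        score = sslp_score(cluster)
        consensus = left + "R" + right  # majority resolves to member 0's flank
        pair = _pair(left[80:100], right[40:60], 80, 40, 40 + 20 + 60)
        assert screen_primers([pair], cluster, consensus, score) == []

    def test_cross_cluster_duplicates_deduplicated(self):
        rng = np.random.default_rng(15)
        left, right = _rand(rng, 120), _rand(rng, 120)
        cluster = self._cluster(rng, left, right)
        consensus = cluster_consensus(cluster)
        score = sslp_score(cluster)
        pair = _pair(left[80:100], right[40:60], 80, 40, 40 + 20 + 60)
        (cand,) = screen_primers([pair], cluster, consensus, score)
        other = type(cand)(
            cluster_id=99,
            primer_pair=cand.primer_pair,
            motif_class=cand.motif_class,
            sslp_score=cand.sslp_score,
        )
        assert len(dedupe_candidates([cand, other])) == 1


class TestInsilicoPCR:
    def test_constructed_template_single_product(self):
        rng = np.random.default_rng(16)
        fwd = _rand(rng, 20)
        rev = _rand(rng, 20)
        insert = _rand(rng, 100)
        template = fwd + insert + reverse_complement(rev)
        pair = _pair(fwd, reverse_complement(rev), 0, 0, 140)
        products = insilico_pcr(pair, {"t": template})
        assert products == [("t", 140)]

    def test_missing_reverse_site_gives_no_product(self):
        rng = np.random.default_rng(17)
        fwd = _rand(rng, 20)
        rev = _rand(rng, 20)
        template = fwd + _rand(rng, 100)
        pair = _pair(fwd, reverse_complement(rev), 0, 0, 140)
        assert insilico_pcr(pair, {"t": template}) == []

    def test_opposite_orientation_detected(self):
        rng = np.random.default_rng(18)
        fwd = _rand(rng, 20)
        rev = _rand(rng, 20)
        template = fwd + _rand(rng, 100) + reverse_complement(rev)
        flipped = reverse_complement(template)
        pair = _pair(fwd, reverse_complement(rev), 0, 0, 140)
        assert insilico_pcr(pair, {"t": flipped}) == [("t", 140)]

    def test_mismatch_allowed_outside_three_prime_seed(self):
        rng = np.random.default_rng(19)
        fwd = _rand(rng, 20)
        rev = _rand(rng, 20)
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        fwd_mut = list(fwd)
        fwd_mut[5] = swap[fwd_mut[5]]
        template = "".join(fwd_mut) + _rand(rng, 80) + reverse_complement(rev)
        pair = _pair(fwd, reverse_complement(rev), 0, 0, 120)
        assert insilico_pcr(pair, {"t": template}) == []
        assert insilico_pcr(pair, {"t": template}, max_mismatch=1) == [
            ("t", 120)
        ]
        # a mismatch in the exact 3' seed blocks annealing even at the
        # relaxed mismatch budget
        fwd_3p = list(fwd)
        fwd_3p[-1] = swap[fwd_3p[-1]]
        template2 = "".join(fwd_3p) + _rand(rng, 80) + reverse_complement(rev)
        assert insilico_pcr(pair, {"t": template2}, max_mismatch=1) == []

    def test_distant_sites_beyond_limit_ignored(self):
        rng = np.random.default_rng(20)
        fwd = _rand(rng, 20)
        rev = _rand(rng, 20)
        template = fwd + _rand(rng, 2500) + reverse_complement(rev)
        pair = _pair(fwd, reverse_complement(rev), 0, 0, 2540)
        assert insilico_pcr(pair, {"t": template}) == []
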