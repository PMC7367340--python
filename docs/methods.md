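# Methods

## Problem setting and model

In a dioecious species, pooling DNA of several same-sex individuals and
sequencing the two pools separately (bulked-segregant analysis) turns a
sex-linked locus into a presence/absence contrast between assemblies. For
microsatellites the contrast is detected not on the repeat tract itself —
its length varies between alleles — but on the *flanking* sequence, which
is treated as a locally unique, slowly mutating identifier of the locus.
The pipeline therefore (i) finds repeat tracts, (ii) replaces each tract
with one mask token so homologous loci become comparable regardless of
allele length, (iii) groups masked records by flank homology, and (iv)
reads sex linkage and length polymorphism off the groups.

## SSR detection

A perfect SSR is a maximal tandem run of a primitive 1–6 bp motif meeting
per-unit minimum repeat counts (defaults mono-10, di-6, tri-5, tetra-5,
penta-5, hexa-5). Detection scans a period-u equality mask
(`seq[i] == seq[i+u]`), so each maximal run is found once, at its leftmost
phase; partial trailing units are truncated (tract length is always
`unit_length × repeat_count`). `N` never participates in a tract.
Non-primitive motifs (AA, ACAC, …) are reported under their primitive unit.
When maximal tracts of different unit lengths overlap (poly-A running out
of an (TA)n tract), one call per interval is kept: longest tract first,
ties to the smaller unit, then leftmost start. Perfect tracts separated by
≤ 100 bp merge transitively into one compound locus; compound loci are
counted via their constituent tracts in the per-type/per-class tables and
are excluded from marker design.

Motif classes are equivalence classes under cyclic rotation and reverse
complement. The label is `X/Y` with `X` the smallest string over all
rotations of both strands and `Y` the smallest rotation of the reverse
complement of `X` (hence `AGC/CTG`, `ATC/ATG`); there are exactly 4
dinucleotide and 10 trinucleotide classes. Percentages in every report
table are computed with exact rational arithmetic and rounded half-up to
two decimals; densities (bp per SSR) round to the nearest integer.

## Masking, filtering, clustering

Each detected locus yields one masked record: `left flank + R + right
flank` (a multi-SSR sequence yields one record per locus). Using a *single*
mask token, rather than one per masked base, makes alleles of different
tract length byte-identical after masking — the property that lets
clustering assemble allelic series, without which length polymorphism could
never exceed 1. The original tract length is kept as metadata. Flanks are
truncated to at most 150 bp per side (`max_flank`), bounding alignment cost
while keeping far more context than the filter needs; records with either
flank below 20 bp are removed as unalignable.

Identity and coverage come from the best local (Smith–Waterman/Gotoh)
alignment: identity = matches / alignment columns (gap columns included),
coverage = residues of the shorter sequence inside the alignment / its
length. Scoring is match +1, mismatch −1, and affine gaps priced as
gap-open 1 with free extension, mirroring the `-gap 1 -gep-ext 0`
convention of the clustering tools this stage emulates; all four penalties
are configuration, not constants. The mask token matches only itself.
Argument order is canonicalised before aligning so the function is exactly
symmetric despite traceback tie-breaks. The kernel is numba-compiled; a
plain-Python dynamic-programming implementation of the same contract lives
in the test suite as an independent oracle.

Clustering is greedy incremental first-fit: records sorted by length
descending (ties by id), each compared against existing cluster
representatives in creation order and joined to the first whose identity
*and* coverage meet the thresholds (0.95/0.70 within a pool, 0.80/0.70 for
the pooled cross-sex pass), else founding a new cluster. The representative
is the founding, longest member. Two accelerations preserve the partition:
identical masked sequences short-circuit to the cluster of their first
occurrence (alignment outcomes depend only on the sequence), and a
16-mer-sharing prefilter skips representatives with no word in common with
the query — at ≥ 80 % identity over ≥ 70 % of a ≥ 40 bp record, shared
16-mers are expected in the hundreds, while unrelated 300 bp records share
one with probability ~2 × 10⁻⁵. The prefilter can be disabled
(`prefilter_k=None`).

The two within-pool passes produce the clustering survey tables; the
independent cross-pool pass produces the sex partition: clusters with only
female members are female-specific, only male members male-specific,
otherwise shared.

## SSLP and marker design

A cluster's SSLP score is the number of distinct member tract lengths in
bp (for a fixed motif this is repeat count up to the unit factor).
Female-specific clusters with SSLP ≥ 2, a primitive non-mononucleotide
motif, no compound loci and a single motif class enter marker design.

The design template is a mask-anchored consensus: flank columns are indexed
outward from the mask token, kept while present in at least half of the
members, majority base per column (ties alphabetically). Primer windows of
18–27 nt are accepted with Tm 57–63 °C, GC fraction 0.30–0.70 and no
homopolymer run above 4; candidate pairs must span the entire tract with a
product of 100–400 bp. The upper bound is enforced with the *longest*
member allele and the lower bound with the *shortest*, so every allele of
the series stays inside the scorable window no matter which cluster member
a product derives from. Pairs are ranked by |Tm_f − Tm_r|, then product
size, then position.

Melting temperatures use a nearest-neighbour thermodynamic model with the
published unified dimer parameters, duplex initiation terms per terminal
base, a symmetry correction for self-complementary primers, the entropic
salt correction 0.368·(N−1)·ln[Na⁺], and fixed documented conditions of
250 nM primer and 50 mM monovalent salt. The test suite cross-checks the
implementation against Biopython's independent Tm_NN calculator to within
±1.5 °C.

Screening re-applies the five marker rules: no mono/compound repeats; the
amplicon (consensus with the mask expanded to the longest allele) must
contain exactly one perfect SSR of the cluster's class; the cluster must be
polymorphic and the primers must lie in its consensus; both binding sites
must be *exactly* conserved in at least two members (the operational
reading of the "support two primers in clusters" rule — a site mutated in
all but one member cannot genotype the series); exact duplicate pairs,
within and across clusters, are dropped.

In-silico PCR scans each unmasked template in both orientations for
convergent binding sites within 2 kb, requiring at most `max_mismatch`
mismatches (default 0) and an exact 3-base 3' seed per primer; product size
includes both primers. A marker is sex-discriminating when it yields at
least one 100–400 bp product on female scaffolds and none on male
scaffolds.

## Synthetic data generator

The generator emulates what the analysis stage of a BSA survey actually
consumes: two pools of assembled scaffolds. Defaults (the package's study
conditions): 200 shared, 20 female-specific and 20 male-specific loci; two
copies per pool per locus; scaffolds 600–900 bp with one planted locus
each plus 50 SSR-free background scaffolds per pool; locus flank templates
160–220 bp; 1 % substitution noise in the flanks of non-reference copies;
allele-length polymorphism with probability 0.6 (repeat count shifted by
±1–2 units, floored at the detection minimum); an A/T-rich,
dinucleotide-dominated motif spectrum (unit-length weights
0.15/0.55/0.25/0.03/0.01/0.01, A/T base weight 0.70, GC content 0.35)
qualitatively matching published plant genome surveys; repeat counts at or
above the detection minima. Copy 0 of each locus carries the unmutated
flank template — the analogue of the locus's assembly consensus — so
member-to-representative divergence equals the configured mutation rate.

Repeat tracts are planted exactly (no noise), background and flanks are
rejection-sampled against the detector itself so no incidental SSR above
threshold appears, and the bases adjacent to each tract are constrained so
the detector cannot extend it; planted loci are therefore recovered at
exactly their planted coordinates. A configurable fraction (10 %) of
*shared* loci is placed at a scaffold edge with a 5–19 bp flank on that
side; restricting the short-flank exercise to shared loci keeps the
flank-filter test independent of the sex-linked recovery benchmark (and
the edge placement matters: padding the short side with background would
silently restore the flank window and the filter would never fire).

What the generator does **not** emulate: read-level error models, assembly
artefacts and collapsed repeats, enrichment-probe bias, paralogous flank
families, indel mutations, or realistic genome-scale SSR densities
(~10³ loci per pool, not ~10⁶). Passing tests therefore demonstrate the
correctness of the algorithms under the stated homology model, not
robustness to assembly pathology. All randomness flows from one seed;
identical seeds give byte-identical pools, truth tables and report files
(outputs contain no timestamps).

## Evaluation and numerical choices

Female-specific calling is scored against the truth table by coordinate
overlap: a predicted cluster is attributed to the unique planted locus its
members overlap (clusters spanning several loci, or none, count as false
positives); precision is over predicted clusters, recall over planted
female-specific loci, with vacuous conventions of 1.0 when the respective
denominator is empty. Problem sizes used by the automated checks — 1,000
sequences ≤ 300 bp for the detector-vs-brute-force comparison, 500 records
in 100 families at 2 % mutation for clustering recovery, the default
conditions above for the end-to-end run — keep the whole suite and the
acceptance script within tens of seconds on one core while leaving each
property's failure modes reachable.

Degenerate inputs are contracts, not silent defaults: empty sequences,
unlabeled sexes, empty clusters, zero totals and out-of-bounds loci raise;
an infeasible primer design returns an empty list (a locus may genuinely
admit no primer pair); a run with no female-specific clusters completes
with an empty marker table and a warning.

## Known limitations

- Greedy first-fit clustering is order-dependent by design (deterministic,
  CD-HIT semantics) and is not guaranteed to maximise any global objective;
  threshold monotonicity holds empirically, not provably.
- The primer designer is deliberately simple: no hairpin/dimer
  thermodynamics, no positional weighting, no thermodynamic penalty model
  for mismatched annealing. It implements the screening logic the marker
  discovery depends on, not a general oligo design engine.
- The SSLP score conflates tract-length classes when different motifs would
  give the same bp length; within single-class clusters (enforced for
  markers) this cannot occur.
- At very high mutation rates the mask-anchored consensus (no indel
  handling) would drift from members; with substitution-only noise, as
  generated, it is exact.
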