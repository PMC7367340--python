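"""End-to-end orchestration: search -> mask/filter -> cluster -> sex-linked
-> SSLP -> primers, with survey-style report tables.

``run_pipeline`` executes the stages in order on either a pair of input
FASTA pools or on synthetic pools from :mod:`ssrlink.synthetic_data`,
logging input/output cardinalities at every stage so the funnel from raw
scaffolds to validated markers is auditable, and returns a
:class:`ReportBundle` whose percentage columns are re-derivable from the
counts in the same table (checked automatically on emission).  All outputs
are deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ssrio
from ._util import ratio_pct
from .flank_cluster import (
    Cluster,
    ClusterParams,
    MaskedRecord,
    classify_sex_specific,
    filter_flanks,
    greedy_cluster,
    mask_records,
)
from .marker_design import (
    MarkerCandidate,
    PrimerConstraints,
    cluster_consensus,
    dedupe_candidates,
    design_primers,
    insilico_pcr,
    screen_primers,
    select_candidate_clusters,
)
from .polymorphism import sslp_distribution, sslp_score
from .ssr_detect import (
    SSRSearchParams,
    SSRSummary,
    find_perfect_ssrs,
    merge_compound,
    summarize_ssrs,
)
from .synthetic_data import GeneratorConfig, TruthTable, generate_pools, truth_evaluate

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "compute_summary_percentages",
]

logger = logging.getLogger(__name__)

VERSION = "1.0.0"


def compute_summary_percentages(counts: pd.Series, total: int) -> pd.Series:
    """Percentage column for a labeled count table.

    ``100 * count / total`` rounded half-up to two decimals, computed with
    exact rational arithmetic so printed tables reproduce bit-for-bit.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return counts.map(lambda c: ratio_pct(int(c), total))


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run.

    Provide either both pool FASTA paths or a generator config (the seed is
    injected into the generator so one ``--seed`` controls the whole run).
    """

    male_fasta: str | Path | None = None
    female_fasta: str | Path | None = None
    generator: GeneratorConfig | None = None
    search: SSRSearchParams = field(default_factory=SSRSearchParams)
    within_params: ClusterParams = field(
        default_factory=lambda: ClusterParams(0.95, 0.70)
    )
    cross_params: ClusterParams = field(
        default_factory=lambda: ClusterParams(0.80, 0.70)
    )
    min_flank: int = 20
    max_flank: int = 150
    primer_constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    outdir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.male_fasta is not None and self.female_fasta is not None
        if not has_files and self.generator is None:
            raise ValueError(
                "provide male_fasta+female_fasta or a generator config"
            )
        if self.min_flank < 0 or self.max_flank < self.min_flank:
            raise ValueError("need 0 <= min_flank <= max_flank")


@dataclass
class ReportBundle:
    """Every report table of one run plus run metadata."""

    summary: SSRSummary
    headline_table: pd.DataFrame
    flank_filter_table: pd.DataFrame
    within_cluster_table: pd.DataFrame
    partition_table: pd.DataFrame
    sslp_scores: pd.DataFrame
    sslp_table: pd.DataFrame
    marker_table: pd.DataFrame
    markers: list[MarkerCandidate]
    female_specific_clusters: list[Cluster]
    evaluation: pd.DataFrame | None
    metadata: dict

    def validate_percentages(self) -> None:
        """Every percentage column must recompute from the counts next to it."""
        checks = [
            (self.flank_filter_table, "n_retained", "n_records", "retained_pct"),
            (self.within_cluster_table, "n_clusters", "n_records", "cluster_pct"),
        ]
        for table, num, den, pct in checks:
            for _, row in table.iterrows():
                if row[den]:
                    expect = ratio_pct(int(row[num]), int(row[den]))
                    if expect != row[pct]:
                        raise AssertionError(
                            f"inconsistent percentage in report: {row[pct]} !="
                            f" {expect}"
                        )
        total = int(self.partition_table.loc["total", "n_clusters"])
        if total:
            for label in ("female_specific", "male_specific", "shared"):
                expect = ratio_pct(
                    int(self.partition_table.loc[label, "n_clusters"]), total
                )
                if expect != self.partition_table.loc[label, "pct"]:
                    raise AssertionError("inconsistent partition percentage")


def _detect_pool(
    pool: dict[str, str], search: SSRSearchParams
) -> tuple[dict[str, list], dict[str, list]]:
    perfect: dict[str, list] = {}
    merged: dict[str, list] = {}
    for seq_id, seq in pool.items():
        loci = find_perfect_ssrs(seq, seq_id, search)
        if loci:
            perfect[seq_id] = loci
            merged[seq_id] = merge_compound(loci, search.max_compound_interval)
    return perfect, merged


def _masked_for_pool(
    pool: dict[str, str],
    merged: dict[str, list],
    sex: str,
    max_flank: int,
) -> list[MaskedRecord]:
    out: list[MaskedRecord] = []
    for seq_id, loci in merged.items():
        out.extend(mask_records(pool[seq_id], seq_id, sex, loci, max_flank))
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run all stages and return the report bundle (writing files when
    ``config.outdir`` is set)."""
    logging.basicConfig(level=config.log_level)
    generated = False
    truth: TruthTable | None = None
    if config.generator is not None:
        gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
        male_pool, female_pool, truth = generate_pools(gen_cfg)
        generated = True
        logger.info(
            "simulated pools: %d male / %d female scaffolds",
            len(male_pool),
            len(female_pool),
        )
    else:
        male_pool = ssrio.read_fasta(config.male_fasta)
        female_pool = ssrio.read_fasta(config.female_fasta)
        logger.info(
            "loaded pools: %d male / %d female scaffolds",
            len(male_pool),
            len(female_pool),
        )
    pools = {"male": male_pool, "female": female_pool}

    # stage 1: SSR search and statistics
    perfect: dict[str, dict[str, list]] = {}
    merged: dict[str, dict[str, list]] = {}
    for sex, pool in pools.items():
        perfect[sex], merged[sex] = _detect_pool(pool, config.search)
        logger.info(
            "%s: %d perfect SSRs on %d scaffolds",
            sex,
            sum(len(v) for v in perfect[sex].values()),
            len(perfect[sex]),
        )
    summary = summarize_ssrs(
        {sex: [l for v in perfect[sex].values() for l in v] for sex in pools},
        {sex: {k: len(s) for k, s in pools[sex].items()} for sex in pools},
        config.search,
    )
    headline = pd.DataFrame(
        {
            sex: {
                "total_sequences": st.total_sequences,
                "total_length_bp": st.total_length_bp,
                "n_ssrs": st.n_ssrs,
                "n_sequences_with_ssr": st.n_sequences_with_ssr,
                "n_sequences_with_multiple_ssr": st.n_sequences_with_multiple_ssr,
                "n_compound_ssrs": st.n_compound_ssrs,
                "frequency_pct": st.frequency_pct,
                "density_bp_per_ssr": st.density_bp_per_ssr,
            }
            for sex, st in summary.per_sex.items()
        }
    )

    # stage 2: mask and flank-filter
    masked: dict[str, list[MaskedRecord]] = {}
    filtered: dict[str, list[MaskedRecord]] = {}
    filter_rows = []
    for sex in pools:
        masked[sex] = _masked_for_pool(
            pools[sex], merged[sex], sex, config.max_flank
        )
        filtered[sex] = filter_flanks(masked[sex], config.min_flank)
        n_rec, n_keep = len(masked[sex]), len(filtered[sex])
        filter_rows.append(
            {
                "sex": sex,
                "n_records": n_rec,
                "n_retained": n_keep,
                "retained_pct": ratio_pct(n_keep, n_rec) if n_rec else 0.0,
            }
        )
        logger.info("%s: %d masked records, %d pass flank filter", sex, n_rec, n_keep)
    flank_filter_table = pd.DataFrame(filter_rows).set_index("sex")

    # stage 3: within-pool clustering (95%/70%)
    within_rows = []
    for sex in pools:
        clusters = greedy_cluster(filtered[sex], config.within_params)
        within_rows.append(
            {
                "sex": sex,
                "n_records": len(filtered[sex]),
                "n_clusters": len(clusters),
                "cluster_pct": ratio_pct(len(clusters), len(filtered[sex]))
                if filtered[sex]
                else 0.0,
            }
        )
        logger.info("%s: %d within-pool clusters", sex, len(clusters))
    within_cluster_table = pd.DataFrame(within_rows).set_index("sex")

    # stage 4: cross-sex clustering (80%/70%) and sex partition
    pooled = filtered["male"] + filtered["female"]
    cross_clusters = greedy_cluster(pooled, config.cross_params)
    partition = classify_sex_specific(cross_clusters)
    female_specific = partition["female_specific"]
    n_total = len(cross_clusters)
    partition_rows = {
        label: {
            "n_clusters": len(partition[label]),
            "pct": ratio_pct(len(partition[label]), n_total) if n_total else 0.0,
        }
        for label in ("female_specific", "male_specific", "shared")
    }
    partition_rows["total"] = {"n_clusters": n_total, "pct": 100.0 if n_total else 0.0}
    partition_table = pd.DataFrame(partition_rows).T
    partition_table["n_clusters"] = partition_table["n_clusters"].astype(int)
    logger.info(
        "cross-pool: %d clusters (%d female-specific, %d male-specific, %d shared)",
        n_total,
        len(female_specific),
        len(partition["male_specific"]),
        len(partition["shared"]),
    )
    if not female_specific:
        logger.warning("no female-specific clusters: marker table will be empty")

    # stage 5: SSLP scoring of female-specific clusters
    scores = {c.cluster_id: sslp_score(c) for c in female_specific}
    sslp_scores_table = pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "score": s.score,
                "distinct_lengths": ",".join(map(str, s.distinct_lengths)),
            }
            for s in scores.values()
        ],
        columns=["cluster_id", "score", "distinct_lengths"],
    )
    sslp_table = sslp_distribution(scores.values())

    # stage 6: marker/primer design, screening, in-silico PCR validation
    candidate_ids = select_candidate_clusters(female_specific, scores)
    by_id = {c.cluster_id: c for c in female_specific}
    raw_candidates: list[MarkerCandidate] = []
    for cid in candidate_ids:
        cluster = by_id[cid]
        consensus = cluster_consensus(cluster)
        pairs = design_primers(
            consensus,
            [m.original_tract_length for m in cluster.members],
            config.primer_constraints,
        )
        screened = screen_primers(
            pairs, cluster, consensus, scores[cid], config.search
        )
        if screened:
            raw_candidates.append(screened[0])  # best-ranked pair per cluster
    candidates = dedupe_candidates(raw_candidates)
    logger.info(
        "markers: %d candidate clusters, %d screened primer pairs",
        len(candidate_ids),
        len(candidates),
    )
    p_lo, p_hi = config.primer_constraints.product_range
    markers: list[MarkerCandidate] = []
    marker_rows = []
    for i, cand in enumerate(candidates, start=1):
        products = {
            sex: tuple(
                size for _, size in insilico_pcr(cand.primer_pair, pools[sex])
            )
            for sex in ("male", "female")
        }
        cand = dataclasses.replace(cand, expected_products_by_sex=products)
        markers.append(cand)
        validated = (
            any(p_lo <= s <= p_hi for s in products["female"])
            and not products["male"]
        )
        pp = cand.primer_pair
        marker_rows.append(
            {
                "Primer": f"Primer{i}",
                "Upstream sequence": pp.forward_seq,
                "Downstream sequence": pp.reverse_seq,
                "Tm (C) up": pp.forward_tm,
                "Tm (C) down": pp.reverse_tm,
                "Size (bp)": pp.product_size,
                "cluster_id": cand.cluster_id,
                "motif_class": cand.motif_class,
                "sslp_score": cand.sslp_score,
                "female_products": ",".join(map(str, products["female"])),
                "male_products": ",".join(map(str, products["male"])),
                "sex_discriminating": validated,
            }
        )
    marker_table = pd.DataFrame(
        marker_rows,
        columns=[
            "Primer",
            "Upstream sequence",
            "Downstream sequence",
            "Tm (C) up",
            "Tm (C) down",
            "Size (bp)",
            "cluster_id",
            "motif_class",
            "sslp_score",
            "female_products",
            "male_products",
            "sex_discriminating",
        ],
    )

    evaluation = None
    if truth is not None:
        precision, recall, confusion = truth_evaluate(female_specific, truth)
        evaluation = confusion.copy()
        evaluation.loc["precision"] = precision
        evaluation.loc["recall"] = recall
        logger.info(
            "female-specific calling: precision %.3f recall %.3f", precision, recall
        )

    metadata = {
        "version": VERSION,
        "seed": config.seed,
        "generated_pools": generated,
        "search_min_repeats": dict(config.search.min_repeats),
        "max_compound_interval": config.search.max_compound_interval,
        "within_identity": config.within_params.identity_threshold,
        "cross_identity": config.cross_params.identity_threshold,
        "coverage": config.within_params.coverage_threshold,
        "min_flank": config.min_flank,
        "max_flank": config.max_flank,
        "product_range": list(config.primer_constraints.product_range),
    }

    bundle = ReportBundle(
        summary=summary,
        headline_table=headline,
        flank_filter_table=flank_filter_table,
        within_cluster_table=within_cluster_table,
        partition_table=partition_table,
        sslp_scores=sslp_scores_table,
        sslp_table=sslp_table,
        marker_table=marker_table,
        markers=markers,
        female_specific_clusters=female_specific,
        evaluation=evaluation,
        metadata=metadata,
    )
    bundle.validate_percentages()

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if generated:
            ssrio.write_fasta(male_pool, outdir / "male_pool.fasta")
            ssrio.write_fasta(female_pool, outdir / "female_pool.fasta")
            truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for sex in pools:
            ssrio.write_misa_tsv(merged[sex], outdir / f"ssr_{sex}.tsv")
        headline.to_csv(outdir / "summary_headline.tsv", sep="\t")
        summary.type_table.to_csv(outdir / "summary_motif_types.tsv", sep="\t")
        summary.class_table.to_csv(outdir / "summary_motif_classes.tsv", sep="\t")
        for sex, hist in summary.repeat_histograms.items():
            hist.to_csv(outdir / f"repeat_histogram_{sex}.tsv", sep="\t")
        ssrio.write_masked_records(
            filtered["male"] + filtered["female"],
            outdir / "masked.fasta",
            outdir / "masked_records.tsv",
        )
        flank_filter_table.to_csv(outdir / "flank_filter.tsv", sep="\t")
        within_cluster_table.to_csv(outdir / "clusters_within.tsv", sep="\t")
        ssrio.write_clusters_tsv(cross_clusters, outdir / "clusters_cross.tsv")
        partition_table.to_csv(outdir / "sex_partition.tsv", sep="\t")
        sslp_scores_table.to_csv(outdir / "sslp_scores.tsv", sep="\t", index=False)
        sslp_table.to_csv(outdir / "sslp_distribution.tsv", sep="\t")
        marker_table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        if evaluation is not None:
            evaluation.to_csv(outdir / "evaluation.tsv", sep="\t")
        with open(outdir / "run_meta.yaml", "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=True)
        logger.info("report written to %s", outdir)
    return bundle
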