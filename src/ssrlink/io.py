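"""FASTA and TSV input/output for the pipeline's external formats.

FASTA reading/writing goes through Biopython; loci are exported in a
MISA-style tab-separated dialect (ID, SSR nr., SSR type p1..p6/c, motif,
size, start, end with 1-based inclusive coordinates), masked records as a
mask-token FASTA plus a sidecar TSV carrying the per-record metadata needed
to rebuild them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .flank_cluster import Cluster, MaskedRecord
from .ssr_detect import SSRLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "misa_motif_label",
    "write_misa_tsv",
    "write_masked_records",
    "read_masked_records",
    "write_clusters_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (wrapped or unwrapped, case-insensitive) multi-FASTA into an
    insertion-ordered id -> uppercase sequence map."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()),
        str(path),
        "fasta",
    )


def misa_motif_label(locus: SSRLocus) -> str:
    """``(AC)6`` for perfect loci; compound loci join their constituents."""
    if locus.is_compound:
        return "+".join(misa_motif_label(c) for c in locus.components)
    return f"({locus.motif}){locus.repeat_count}"


def write_misa_tsv(
    loci_by_seq: Mapping[str, Sequence[SSRLocus]], path: str | Path
) -> None:
    rows = []
    for seq_id, loci in loci_by_seq.items():
        for nr, locus in enumerate(sorted(loci, key=lambda l: l.start), start=1):
            ssr_type = "c" if locus.is_compound else f"p{locus.unit_length}"
            rows.append(
                {
                    "ID": seq_id,
                    "SSR nr.": nr,
                    "SSR type": ssr_type,
                    "SSR motif": misa_motif_label(locus),
                    "size": locus.tract_length,
                    "start": locus.start,
                    "end": locus.end,
                }
            )
    pd.DataFrame(
        rows,
        columns=["ID", "SSR nr.", "SSR type", "SSR motif", "size", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


_SIDECAR_COLUMNS = [
    "record_id",
    "sex",
    "seq_id",
    "start",
    "end",
    "motif",
    "unit_length",
    "repeat_count",
    "is_compound",
    "tract_length",
    "left_flank_len",
    "right_flank_len",
]


def write_masked_records(
    records: Iterable[MaskedRecord],
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    records = list(records)
    write_fasta({r.record_id: r.masked_seq for r in records}, fasta_path)
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "sex": r.sex,
                "seq_id": r.locus.seq_id,
                "start": r.locus.start,
                "end": r.locus.end,
                "motif": r.locus.motif,
                "unit_length": r.locus.unit_length,
                "repeat_count": r.locus.repeat_count,
                "is_compound": r.locus.is_compound,
                "tract_length": r.original_tract_length,
                "left_flank_len": r.left_flank_len,
                "right_flank_len": r.right_flank_len,
            }
        )
    pd.DataFrame(rows, columns=_SIDECAR_COLUMNS).to_csv(
        sidecar_path, sep="\t", index=False
    )


def read_masked_records(
    fasta_path: str | Path, sidecar_path: str | Path
) -> list[MaskedRecord]:
    """Rebuild MaskedRecords from a mask FASTA plus its sidecar TSV.

    Compound loci are reconstructed without their component tracts (the
    sidecar stores the span and joined motif only), which is sufficient for
    clustering and SSLP scoring.
    """
    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq)  # keep case: mask token must survive
    table = pd.read_csv(sidecar_path, sep="\t")
    out: list[MaskedRecord] = []
    for row in table.itertuples(index=False):
        if row.record_id not in seqs:
            raise ValueError(f"record {row.record_id!r} missing from FASTA")
        locus = SSRLocus(
            seq_id=row.seq_id,
            start=int(row.start),
            end=int(row.end),
            motif=row.motif,
            repeat_count=int(row.repeat_count),
            unit_length=int(row.unit_length),
            is_compound=bool(row.is_compound),
        )
        out.append(
            MaskedRecord(
                record_id=row.record_id,
                sex=row.sex,
                masked_seq=seqs[row.record_id],
                left_flank_len=int(row.left_flank_len),
                right_flank_len=int(row.right_flank_len),
                locus=locus,
                original_tract_length=int(row.tract_length),
            )
        )
    return out


def write_clusters_tsv(clusters: Sequence[Cluster], path: str | Path) -> None:
    rows = []
    for cluster in clusters:
        rep_id = cluster.representative.record_id
        for member in cluster.members:
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "record_id": member.record_id,
                    "sex": member.sex,
                    "is_representative": member.record_id == rep_id,
                }
            )
    pd.DataFrame(
        rows, columns=["cluster_id", "record_id", "sex", "is_representative"]
    ).to_csv(path, sep="\t", index=False)
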