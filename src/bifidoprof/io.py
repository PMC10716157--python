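"""Readers and writers for the plain-text formats the pipeline consumes.

Dialects:

* FASTA — standard; reference records carry ``taxonomy=`` and
  ``outgroup=`` key-value tags in the description.
* Hit tables — BLAST tabular (outfmt-6-like) with two extension columns:
  ``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore qcovhsp slineage``.
* Count/metadata/feature tables — TSV with samples as rows; missing
  metadata cells are empty or ``NA``.
* Distance matrices — square TSV with a header row and an id column.
* Trees — Newick.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from .classify import HitRecord, ZotuAssignment
from .refdb import ReferenceDB, ReferenceSequence
from .taxonomy import TaxonomyPath

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qcovhsp", "slineage",
]


class ParseError(ValueError):
    """A file violated its documented dialect; carries the line number."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[tuple[str, str, str]]:
    """(id, description, sequence) triples; wrapped lines and CRLF are fine."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, str(rec.seq).upper()))
    return out


def write_fasta(path: PathLike, records: Iterable[tuple[str, str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_refdb_fasta(path: PathLike, db: ReferenceDB) -> None:
    write_fasta(
        path,
        (
            (r.id, f"{r.id} taxonomy={r.taxonomy.to_string()} outgroup={int(r.is_outgroup)}", r.sequence)
            for r in db.records
        ),
    )


def read_refdb_fasta(path: PathLike) -> ReferenceDB:
    records = []
    for rid, desc, seq in read_fasta(path):
        # species names contain spaces, so the lineage is everything
        # between the taxonomy= tag and the trailing outgroup= tag
        m = re.search(r"taxonomy=(?P<tax>.+?)\s+outgroup=(?P<out>[01])\s*$", desc)
        if m is None:
            raise ParseError(f"record {rid} lacks taxonomy=/outgroup= tags")
        records.append(
            ReferenceSequence(
                id=rid,
                sequence=seq,
                taxonomy=TaxonomyPath.from_string(m.group("tax")),
                is_outgroup=bool(int(m.group("out"))),
            )
        )
    return ReferenceDB(records=records, dedup_map={r.id: r.id for r in records})


def write_dedup_map(path: PathLike, db: ReferenceDB) -> None:
    with open(path, "w") as fh:
        fh.write("original_id\trepresentative_id\n")
        for orig, rep in sorted(db.dedup_map.items()):
            fh.write(f"{orig}\t{rep}\n")


# ---------------------------------------------------------------------------
# taxonomy sidecar
# ---------------------------------------------------------------------------

def read_taxonomy_tsv(path: PathLike) -> dict[str, TaxonomyPath]:
    """``genome_id<TAB>lineage`` with ``rank__Name`` levels joined by ';'."""
    out: dict[str, TaxonomyPath] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                out[parts[0]] = TaxonomyPath.from_string(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# BLAST tabular hit tables
# ---------------------------------------------------------------------------

def read_blast_tab(path: PathLike, max_rows_per_query: int = 2000) -> list[HitRecord]:
    """Parse a 14-column hit table; per-query rows beyond the cap are
    dropped (a parser cap distinct from the hit-retention thresholds)."""
    hits: list[HitRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(BLAST_COLUMNS)} columns, got {len(parts)}"
                )
            qseqid = parts[0]
            seen[qseqid] = seen.get(qseqid, 0) + 1
            if seen[qseqid] > max_rows_per_query:
                continue
            try:
                hits.append(
                    HitRecord(
                        zotu_id=qseqid,
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        bit_score=float(parts[11]),
                        evalue=float(parts[10]),
                        query_coverage=float(parts[12]),
                        subject_taxonomy=TaxonomyPath.from_string(parts[13]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(path: PathLike, hits: pd.DataFrame) -> None:
    """Serialize a simulated hit frame (zotu_id, subject_id,
    percent_identity, bit_score, evalue, query_coverage, lineage) as
    14-column BLAST tabular, filling alignment bookkeeping columns."""
    with open(path, "w") as fh:
        for _, h in hits.iterrows():
            row = [
                h["zotu_id"], h["subject_id"], f"{h['percent_identity']:.2f}",
                "460", "5", "0", "1", "460", "1", "460",
                f"{h['evalue']:.2e}", f"{h['bit_score']:.1f}",
                f"{h['query_coverage']:.1f}", h["lineage"],
            ]
            fh.write("\t".join(map(str, row)) + "\n")


def hits_from_frame(frame: pd.DataFrame) -> list[HitRecord]:
    """HitRecords from an in-memory simulated hit frame."""
    return [
        HitRecord(
            zotu_id=h["zotu_id"],
            subject_id=h["subject_id"],
            percent_identity=float(h["percent_identity"]),
            bit_score=float(h["bit_score"]),
            evalue=float(h["evalue"]),
            query_coverage=float(h["query_coverage"]),
            subject_taxonomy=TaxonomyPath.from_string(h["lineage"]),
        )
        for _, h in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# assignments
# ---------------------------------------------------------------------------

def write_assignments(path: PathLike, assignments: Sequence[ZotuAssignment]) -> None:
    with open(path, "w") as fh:
        fh.write("zotu_id\tstatus\tsource\trule\ttaxonomy\tmax_bit_nt\tmax_bit_bif\n")
        for a in assignments:
            fh.write(
                "\t".join(
                    [
                        a.zotu_id, a.status, a.source or "NA", a.rule_fired,
                        a.taxonomy.to_string() if a.taxonomy else "NA",
                        "NA" if a.max_bit_nt is None else f"{a.max_bit_nt:g}",
                        "NA" if a.max_bit_bif is None else f"{a.max_bit_bif:g}",
                    ]
                )
                + "\n"
            )


def read_assignments(path: PathLike) -> list[ZotuAssignment]:
    out: list[ZotuAssignment] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("zotu_id\t"):
            raise ParseError(f"{path}:1: unexpected header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            out.append(
                ZotuAssignment(
                    zotu_id=parts[0],
                    status=parts[1],
                    source=None if parts[2] == "NA" else parts[2],
                    rule_fired=parts[3],
                    taxonomy=None if parts[4] == "NA" else TaxonomyPath.from_string(parts[4]),
                    max_bit_nt=None if parts[5] == "NA" else float(parts[5]),
                    max_bit_bif=None if parts[6] == "NA" else float(parts[6]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_count_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: count table has missing cells")
    return df.astype(int)


def write_table(path: PathLike, df: pd.DataFrame, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_bif16s(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float).rename("bif16s")


def read_metadata(path: PathLike) -> pd.DataFrame:
    """Metadata TSV; empty cells and ``NA`` become missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=True)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("metadata: %d missing cells across %d columns", n_missing, df.shape[1])
    return df


def read_distance_matrix(path: PathLike) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(path: PathLike, dm: DistanceMatrix) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path: PathLike) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ParseError(f"{path}: duplicate tip labels")
    return tree
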