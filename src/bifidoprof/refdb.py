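"""Reference-database construction for groEL amplicon profiling.

The reference database is built from assembled genomes by in-silico PCR:
the amplified region between a forward primer site and the nearest
downstream reverse primer site (on either strand) is excised, the primer
bases are removed, exact duplicate amplicons are collapsed, and each
retained record carries the ranked taxonomy of its source genome.
A pairwise-identity summary provides the database-level QC: within-genus
amplicons should be far more similar to one another than to the outgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .taxonomy import TaxonomyPath

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes -> set of concrete bases.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class AlphabetError(ValueError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


def _validate(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise AlphabetError(f"{what} contains non-IUPAC characters: {sorted(bad)!r}")
    return seq


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement()).upper()


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair.

    ``reverse`` is given 5'->3' on the opposite strand, as primers are
    ordered; the amplicon on the forward strand therefore reads
    ``forward + insert + revcomp(reverse)``.
    """

    forward: str
    reverse: str
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _validate(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _validate(self.reverse, "reverse primer"))
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class ReferenceSequence:
    id: str
    sequence: str
    taxonomy: TaxonomyPath
    source_genome: str = ""
    is_outgroup: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate(self.sequence, f"record {self.id}"))


@dataclass
class ReferenceDB:
    records: list[ReferenceSequence]
    dedup_map: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def _site_matches(seq: str, pos: int, primer: str, max_mm: int) -> bool:
    """Degeneracy-aware primer match at *pos* with <= *max_mm* mismatches."""
    mm = 0
    for k, p in enumerate(primer):
        if not (IUPAC[seq[pos + k]] & IUPAC[p]):
            mm += 1
            if mm > max_mm:
                return False
    return True


def _scan_strand(
    seq: str,
    fwd: str,
    rev_rc: str,
    max_mm: int,
    lo: int,
    hi: int,
) -> list[str]:
    """Left-to-right scan of one strand for primer-flanked inserts.

    The leftmost forward site with the nearest downstream reverse site
    whose insert falls in the length window wins; once an amplicon is
    emitted scanning resumes after its reverse primer.
    """
    out: list[str] = []
    n = len(seq)
    i = 0
    while i <= n - len(fwd):
        if _site_matches(seq, i, fwd, max_mm):
            start = i + len(fwd)
            j = start
            hit = None
            while j <= n - len(rev_rc):
                insert_len = j - start
                if insert_len > hi:
                    break
                if _site_matches(seq, j, rev_rc, max_mm):
                    if insert_len >= lo:
                        hit = j
                        break
                    logger.debug(
                        "reverse site at %d gives insert of %d nt (below window); continuing",
                        j, insert_len,
                    )
                j += 1
            if hit is not None:
                out.append(seq[start:hit])
                i = hit + len(rev_rc)
                continue
        i += 1
    return out


def extract_amplicon(
    genome: str,
    primers: PrimerPair,
    amplicon_min: int = 350,
    amplicon_max: int = 600,
) -> list[str]:
    """In-silico PCR: every primer-flanked insert on either strand.

    Returns inserts in forward-primer orientation with the primer bases
    removed, restricted to the [amplicon_min, amplicon_max] insert-length
    window (the expected product is ~460 nt).
    """
    genome = _validate(genome, "genome")
    if not genome:
        raise AlphabetError("genome is empty")
    rev_rc = revcomp(primers.reverse)
    hits = _scan_strand(genome, primers.forward, rev_rc, primers.max_mismatches,
                        amplicon_min, amplicon_max)
    hits += _scan_strand(revcomp(genome), primers.forward, rev_rc,
                         primers.max_mismatches, amplicon_min, amplicon_max)
    return hits


def dedupe(records: Iterable[ReferenceSequence]) -> ReferenceDB:
    """Collapse exact-string duplicates, keeping the first-seen record.

    In-group and outgroup records are deduplicated independently so that
    an outgroup amplicon never absorbs an in-group one.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to deduplicate")
    kept: list[ReferenceSequence] = []
    rep_by_seq: dict[tuple[bool, str], str] = {}
    dedup_map: dict[str, str] = {}
    for rec in records:
        key = (rec.is_outgroup, rec.sequence)
        rep = rep_by_seq.get(key)
        if rep is None:
            rep_by_seq[key] = rec.id
            kept.append(rec)
            dedup_map[rec.id] = rec.id
        else:
            dedup_map[rec.id] = rep
            logger.debug("collapsing %s into %s", rec.id, rep)
    return ReferenceDB(records=kept, dedup_map=dedup_map)


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Optional[PairwiseAligner] = None) -> float:
    """Fraction of matching columns over the global-alignment length."""
    if aligner is None:
        aligner = _aligner()
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def identity_summary(db: ReferenceDB, threshold: float = 0.75) -> dict:
    """Pairwise-identity QC of the reference database.

    Returns the fraction of in-group pairs with identity above *threshold*
    and the maximum identity between any in-group and outgroup record.
    """
    ingroup = [r for r in db.records if not r.is_outgroup]
    outgroup = [r for r in db.records if r.is_outgroup]
    if len(db.records) < 2 or len(ingroup) < 2:
        raise ValueError("need at least two in-group records for an identity summary")
    aligner = _aligner()
    in_idents: list[float] = []
    for i in range(len(ingroup)):
        for j in range(i + 1, len(ingroup)):
            in_idents.append(pairwise_identity(ingroup[i].sequence, ingroup[j].sequence, aligner))
    out_max = None
    if outgroup:
        out_max = max(
            pairwise_identity(r.sequence, o.sequence, aligner)
            for r in ingroup
            for o in outgroup
        )
    n_above = sum(1 for x in in_idents if x > threshold)
    return {
        "n_ingroup_pairs": len(in_idents),
        "frac_ingroup_above_threshold": n_above / len(in_idents),
        "threshold": threshold,
        "min_ingroup_identity": min(in_idents),
        "mean_ingroup_identity": sum(in_idents) / len(in_idents),
        "max_ingroup_outgroup_identity": out_max,
    }


def build_refdb(
    genomes: Iterable[tuple[str, str]],
    taxonomy: dict[str, TaxonomyPath],
    primers: PrimerPair,
    outgroup_ids: Optional[set[str]] = None,
    amplicon_min: int = 350,
    amplicon_max: int = 600,
) -> ReferenceDB:
    """Extract, trim and deduplicate amplicons from (genome_id, sequence) pairs.

    Genomes without a taxonomy entry or without a primer-flanked amplicon
    are skipped with a log message.
    """
    outgroup_ids = outgroup_ids or set()
    records: list[ReferenceSequence] = []
    for genome_id, seq in genomes:
        tax = taxonomy.get(genome_id)
        if tax is None:
            logger.warning("genome %s has no taxonomy entry; skipped", genome_id)
            continue
        amplicons = extract_amplicon(seq, primers, amplicon_min, amplicon_max)
        if not amplicons:
            logger.info("genome %s yielded no amplicon", genome_id)
        for k, amp in enumerate(amplicons):
            rec_id = genome_id if len(amplicons) == 1 else f"{genome_id}.{k + 1}"
            records.append(
                ReferenceSequence(
                    id=rec_id,
                    sequence=amp,
                    taxonomy=tax,
                    source_genome=genome_id,
                    is_outgroup=genome_id in outgroup_ids,
                )
            )
    if not records:
        raise ValueError("no amplicons extracted from any genome")
    return dedupe(records)
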