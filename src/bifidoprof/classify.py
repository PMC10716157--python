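"""ZOTU taxonomy assignment from dual-database alignment hits.

Each ZOTU (zero-radius OTU: an exact denoised amplicon variant) is aligned
against two databases: a general nucleotide database ("NT") and the
purpose-built groEL amplicon database ("BIF").  Per database, hits are
filtered on e-value / coverage / identity, and a conservative taxonomy is
derived by the top-percent LCA rule: among hits scoring at least
``min_score``, keep those within ``top_percent`` of the best bit score and
take the longest common lineage prefix.

The two per-database taxonomies are then reconciled by a bit-score
arbitration decision tree:

1. no hits in either database            -> discarded (no hits);
2. NT taxonomy outside genus Bifidobacterium and NT bit score dominant
                                         -> discarded (non-bifidobacterial);
3. identical taxonomies                  -> assigned (agree);
4. equal best bit scores, or BIF ahead by less than a factor of 1/0.9
                                         -> the finer-rank taxonomy of the two;
5. BIF ahead by a factor of 1/0.9 or more -> BIF taxonomy;
6. otherwise (NT ahead, NT within genus)  -> NT taxonomy, with a warning.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .taxonomy import TaxonomyPath, lca

logger = logging.getLogger(__name__)

TARGET_GENUS = "Bifidobacterium"


@dataclass(frozen=True)
class HitRecord:
    """One filtered-alignment hit in BLAST-tabular style."""

    zotu_id: str
    subject_id: str
    percent_identity: float
    bit_score: float
    evalue: float
    query_coverage: float
    subject_taxonomy: TaxonomyPath

    def __post_init__(self) -> None:
        for name in ("percent_identity", "bit_score", "evalue", "query_coverage"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class Thresholds:
    """Hit-retention thresholds (defaults follow the Megablast run settings)."""

    max_evalue: float = 1e-10
    min_query_coverage: float = 60.0
    min_percent_identity: float = 75.0
    max_target_seqs: int = 1000


@dataclass(frozen=True)
class ZotuAssignment:
    zotu_id: str
    status: str  # discarded_no_hits | discarded_nonbif_nt_dominant | assigned
    taxonomy: Optional[TaxonomyPath]
    source: Optional[str]  # NT | BIF | agree | merged_finer
    max_bit_nt: Optional[float]
    max_bit_bif: Optional[float]
    rule_fired: str

    def __post_init__(self) -> None:
        if (self.status == "assigned") != (self.taxonomy is not None):
            raise ValueError("taxonomy must be present iff status is 'assigned'")


def filter_hits(hits: Iterable[HitRecord], thresholds: Thresholds = Thresholds()) -> list[HitRecord]:
    """Apply the retention thresholds; cap each ZOTU's hits by bit score.

    Bounds are inclusive: a hit exactly at the coverage or identity
    threshold is retained.
    """
    passing = [
        h
        for h in hits
        if h.evalue <= thresholds.max_evalue
        and h.query_coverage >= thresholds.min_query_coverage
        and h.percent_identity >= thresholds.min_percent_identity
    ]
    by_zotu: dict[str, list[HitRecord]] = {}
    for h in passing:
        by_zotu.setdefault(h.zotu_id, []).append(h)
    out: list[HitRecord] = []
    for zotu_id, zhits in by_zotu.items():
        if len(zhits) > thresholds.max_target_seqs:
            zhits = sorted(zhits, key=lambda h: -h.bit_score)[: thresholds.max_target_seqs]
            logger.debug("ZOTU %s capped at %d hits", zotu_id, thresholds.max_target_seqs)
        out.extend(zhits)
    return out


def lca_top_percent(
    hits: Sequence[HitRecord],
    min_score: float = 100.0,
    top_percent: float = 10.0,
) -> tuple[Optional[TaxonomyPath], Optional[float]]:
    """Top-percent LCA of one ZOTU's hits.

    Hits below *min_score* bits are dropped first; among the survivors,
    hits within *top_percent* percent of the best bit score are retained
    and their longest common lineage prefix is returned, together with the
    best bit score.  Returns ``(None, None)`` if no hit survives.
    """
    zotus = {h.zotu_id for h in hits}
    if len(zotus) > 1:
        raise ValueError(f"hits span multiple ZOTUs: {sorted(zotus)}")
    scored = [h for h in hits if h.bit_score >= min_score]
    if not scored:
        return None, None
    best = max(h.bit_score for h in scored)
    cutoff = (1.0 - top_percent / 100.0) * best
    retained = [h for h in scored if h.bit_score >= cutoff]
    return lca(h.subject_taxonomy for h in retained), best


def arbitrate(
    zotu_id: str,
    nt_taxonomy: Optional[TaxonomyPath],
    max_bit_nt: Optional[float],
    bif_taxonomy: Optional[TaxonomyPath],
    max_bit_bif: Optional[float],
    bif_factor: float = 0.9,
) -> ZotuAssignment:
    """Reconcile the NT and BIF taxonomies of one ZOTU (total function)."""
    # Rule 1: nothing to work with.
    if nt_taxonomy is None and bif_taxonomy is None:
        return ZotuAssignment(zotu_id, "discarded_no_hits", None, None,
                              max_bit_nt, max_bit_bif, "rule1_no_hits")

    bit_nt = max_bit_nt if max_bit_nt is not None else 0.0
    bit_bif = max_bit_bif if max_bit_bif is not None else 0.0

    # Rule 2: the general database says this is not Bifidobacterium, and
    # its evidence dominates.
    if (
        nt_taxonomy is not None
        and not nt_taxonomy.has_genus(TARGET_GENUS)
        and bit_nt > bit_bif
    ):
        return ZotuAssignment(zotu_id, "discarded_nonbif_nt_dominant", None, None,
                              max_bit_nt, max_bit_bif, "rule2_nonbif_nt_dominant")

    # Rule 3: the two databases agree outright.
    if nt_taxonomy is not None and bif_taxonomy is not None and nt_taxonomy == bif_taxonomy:
        return ZotuAssignment(zotu_id, "assigned", nt_taxonomy, "agree",
                              max_bit_nt, max_bit_bif, "rule3_agree")

    # Rule 4: scores tied, or BIF ahead but by less than a factor of 1/0.9:
    # neither database clearly wins, take the finer-rank path (BIF on ties).
    if bit_bif == bit_nt or (bit_bif > bit_nt and bif_factor * bit_bif <= bit_nt):
        if bif_taxonomy is None:
            chosen = nt_taxonomy
        elif nt_taxonomy is None:
            chosen = bif_taxonomy
        elif nt_taxonomy.finer_than(bif_taxonomy):
            chosen = nt_taxonomy
        else:
            chosen = bif_taxonomy
        return ZotuAssignment(zotu_id, "assigned", chosen, "merged_finer",
                              max_bit_nt, max_bit_bif, "rule4_merged_finer")

    # Rule 5: BIF clearly dominant.
    if bit_bif > bit_nt and bif_factor * bit_bif > bit_nt:
        return ZotuAssignment(zotu_id, "assigned", bif_taxonomy, "BIF",
                              max_bit_nt, max_bit_bif, "rule5_bif_dominant")

    # Rule 6: NT dominant with an in-genus NT lineage (or absent BIF).
    logger.warning("ZOTU %s: NT bit score dominates an in-genus NT lineage; "
                   "assigning NT taxonomy", zotu_id)
    return ZotuAssignment(zotu_id, "assigned", nt_taxonomy, "NT",
                          max_bit_nt, max_bit_bif, "rule6_nt_dominant")


def classify_table(
    zotu_ids: Sequence[str],
    nt_hits: Iterable[HitRecord],
    bif_hits: Iterable[HitRecord],
    thresholds: Thresholds = Thresholds(),
    min_score: float = 100.0,
    top_percent: float = 10.0,
    bif_factor: float = 0.9,
) -> list[ZotuAssignment]:
    """Classify every ZOTU: filter -> per-database top-percent LCA -> arbitrate."""
    known = set(zotu_ids)

    def group(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
        by: dict[str, list[HitRecord]] = {}
        for h in hits:
            if h.zotu_id not in known:
                logger.warning("hit for unknown ZOTU %s skipped", h.zotu_id)
                continue
            by.setdefault(h.zotu_id, []).append(h)
        return by

    nt_by = group(filter_hits(nt_hits, thresholds))
    bif_by = group(filter_hits(bif_hits, thresholds))

    out: list[ZotuAssignment] = []
    for zotu_id in zotu_ids:
        nt_tax, nt_bit = lca_top_percent(nt_by.get(zotu_id, []), min_score, top_percent)
        bif_tax, bif_bit = lca_top_percent(bif_by.get(zotu_id, []), min_score, top_percent)
        out.append(arbitrate(zotu_id, nt_tax, nt_bit, bif_tax, bif_bit, bif_factor))

    counts = Counter(a.rule_fired for a in out)
    logger.info("classification rule counts: %s", dict(sorted(counts.items())))
    return out
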