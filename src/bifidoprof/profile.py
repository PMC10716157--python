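"""Composite species abundances and rarefaction.

A ZOTU count table (samples x ZOTUs, non-negative integers) is combined
with per-ZOTU taxonomy assignments and a per-sample genus-level fraction
from whole-community 16S profiling.  A species' composite relative
abundance is its share of the bifidobacterial reads rescaled by the
genus's share of the whole community:

    abundance(s) = reads(s) / reads(genus) * bif16s

ZOTUs resolved only to the genus pool into a "Bifidobacterium
(unclassified)" bucket; discarded and non-bifidobacterial ZOTUs enter
neither numerator nor denominator.  Rarefaction (used for diversity
analyses only) subsamples each sample to a fixed depth without
replacement; composite abundances are computed from unrarefied counts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .classify import TARGET_GENUS, ZotuAssignment

logger = logging.getLogger(__name__)

UNCLASSIFIED = "Bifidobacterium (unclassified)"


def _check_counts(table: pd.DataFrame) -> pd.DataFrame:
    if (table.values < 0).any():
        raise ValueError("count table contains negative entries")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("sample or ZOTU ids are not unique")
    return table


def rarefy(table: pd.DataFrame, depth: int = 2000, seed: Optional[int] = None) -> pd.DataFrame:
    """Subsample each sample to *depth* reads without replacement.

    Samples with fewer than *depth* reads are dropped (logged).  The draw
    is multivariate hypergeometric, so no ZOTU can exceed its original
    count and totals equal *depth* exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    _check_counts(table)
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.index[~keep])
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:10])
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    sub = table.loc[keep]
    counts = sub.to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return pd.DataFrame(out, index=sub.index, columns=sub.columns)


def species_map(assignments: Iterable[ZotuAssignment]) -> dict[str, Optional[str]]:
    """ZOTU id -> feature name (species, the unclassified bucket, or None).

    ZOTUs assigned a species within the target genus map to that species;
    ZOTUs resolved within the genus but not to species map to the
    unclassified bucket; everything else (discarded, or assigned outside
    the genus) maps to None and is excluded from profiling.
    """
    out: dict[str, Optional[str]] = {}
    for a in assignments:
        if a.status != "assigned" or a.taxonomy is None:
            out[a.zotu_id] = None
        elif a.taxonomy.genus == TARGET_GENUS:
            out[a.zotu_id] = a.taxonomy.species or UNCLASSIFIED
        else:
            out[a.zotu_id] = None
    return out


def composite_abundance(
    table: pd.DataFrame,
    assignments: Iterable[ZotuAssignment],
    bif16s: pd.Series,
) -> pd.DataFrame:
    """Per-sample composite species abundances on the whole-community scale.

    Row sums equal the sample's 16S bifidobacterial fraction exactly
    (conservation), except for samples without any bifidobacterial read,
    which get a zero row and a warning.
    """
    _check_counts(table)
    missing = set(table.index) - set(bif16s.index)
    if missing:
        raise ValueError(f"samples without a 16S genus fraction: {sorted(missing)[:10]}")
    fractions = bif16s.loc[table.index].astype(float)
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("bif16s fractions must lie in [0, 1]")

    smap = species_map(assignments)
    unknown = set(table.columns) - set(smap)
    if unknown:
        raise ValueError(f"assignments missing for ZOTUs: {sorted(unknown)[:10]}")

    features = sorted({f for f in smap.values() if f is not None})
    if UNCLASSIFIED in features:  # keep the bucket last for readability
        features.remove(UNCLASSIFIED)
        features.append(UNCLASSIFIED)

    reads = pd.DataFrame(0.0, index=table.index, columns=features)
    for zotu in table.columns:
        feat = smap[zotu]
        if feat is not None:
            reads[feat] += table[zotu].astype(float)
    denom = reads.sum(axis=1)
    zero = denom == 0
    if zero.any():
        logger.warning("%d samples have zero bifidobacterial reads; zero rows emitted",
                       int(zero.sum()))
    denom_safe = denom.replace(0, np.nan)
    profile = reads.div(denom_safe, axis=0).mul(fractions, axis=0).fillna(0.0)
    return profile


def aggregate_by(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    group_var: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Group means of each feature plus group sizes.

    Samples with a missing group value are excluded; empty groups cannot
    arise after that exclusion.
    """
    if group_var not in metadata.columns:
        raise KeyError(f"{group_var!r} not in metadata")
    groups = metadata.loc[profile.index, group_var]
    valid = groups.notna()
    if not valid.all():
        logger.warning("aggregate_by: %d samples missing %r excluded",
                       int((~valid).sum()), group_var)
    sub = profile.loc[valid]
    g = groups.loc[valid]
    means = sub.groupby(g, observed=True).mean()
    sizes = sub.groupby(g, observed=True).size()
    return means, sizes
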