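"""End-to-end orchestration: classify -> profile -> diversity -> associate.

The pipeline consumes a ZOTU count table, two hit tables, a per-sample
16S genus fraction and a metadata table, and writes per-stage outputs
plus a manifest recording seeds, input checksums and the per-stage
accounting (ZOTUs discarded per rule, samples dropped at rarefaction).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, assoc, diversity, io, profile
from .classify import Thresholds, classify_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str = ""
    nt_hits: str = ""
    bif_hits: str = ""
    bif16s: str = ""
    metadata: str = ""
    tree: Optional[str] = None
    out_dir: str = "results"
    # thresholds
    max_evalue: float = 1e-10
    min_query_coverage: float = 60.0
    min_percent_identity: float = 75.0
    max_target_seqs: int = 1000
    min_score: float = 100.0
    top_percent: float = 10.0
    bif_factor: float = 0.9
    rarefy_depth: int = 2000
    n_perm: int = 999
    alpha_raw: float = assoc.ALPHA_RAW
    alpha_adj: float = assoc.ALPHA_ADJ
    covariates: list[str] = field(default_factory=lambda: [
        "latitude", "longitude", "altitude", "age", "sex", "ethnicity",
        "staple_food", "residence", "sampling_month",
    ])
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(assoc.DEFAULT_REFERENCE_LEVELS))
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.bif_factor <= 1):
            raise ValueError("bif_factor must lie in (0, 1]")
        if self.rarefy_depth < 1 or self.n_perm < 1:
            raise ValueError("rarefy_depth and n_perm must be positive")
        for name in ("counts", "nt_hits", "bif_hits", "bif16s", "metadata"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name} input missing: {path!r}")
        if self.tree and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree input missing: {self.tree!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in ("counts", "nt_hits", "bif_hits", "bif16s", "metadata")
        },
        "stages": {},
    }

    # ---- classify ----
    table = io.read_count_table(config.counts)
    thresholds = Thresholds(
        max_evalue=config.max_evalue,
        min_query_coverage=config.min_query_coverage,
        min_percent_identity=config.min_percent_identity,
        max_target_seqs=config.max_target_seqs,
    )
    assignments = classify_table(
        list(table.columns),
        io.read_blast_tab(config.nt_hits),
        io.read_blast_tab(config.bif_hits),
        thresholds=thresholds,
        min_score=config.min_score,
        top_percent=config.top_percent,
        bif_factor=config.bif_factor,
    )
    io.write_assignments(out / "assignments.tsv", assignments)
    manifest["stages"]["classify"] = {
        "n_zotus": len(assignments),
        "by_rule": dict(sorted(Counter(a.rule_fired for a in assignments).items())),
        "by_status": dict(sorted(Counter(a.status for a in assignments).items())),
    }

    # ---- profile ----
    bif16s = io.read_bif16s(config.bif16s)
    species_profile = profile.composite_abundance(table, assignments, bif16s)
    io.write_table(out / "species_profile.tsv", species_profile)
    manifest["stages"]["profile"] = {
        "n_samples": int(species_profile.shape[0]),
        "n_features": int(species_profile.shape[1]),
    }

    # ---- diversity ----
    rarefied = profile.rarefy(table, depth=config.rarefy_depth, seed=config.seed)
    tree = io.read_newick(config.tree) if config.tree else None
    alpha = diversity.alpha_diversity(rarefied, tree)
    io.write_table(out / "alpha_diversity.tsv", alpha)
    bc = diversity.beta_diversity(rarefied, "bray_curtis")
    io.write_distance_matrix(out / "bray_curtis.tsv", bc)
    jsd_dm = diversity.beta_diversity(rarefied, "jsd")
    io.write_distance_matrix(out / "jsd.tsv", jsd_dm)
    manifest["stages"]["diversity"] = {
        "rarefy_depth": config.rarefy_depth,
        "n_samples_rarefied": int(rarefied.shape[0]),
        "n_samples_dropped": int(table.shape[0] - rarefied.shape[0]),
    }

    # ---- associate ----
    metadata = io.read_metadata(config.metadata)
    covars = [c for c in config.covariates if c in metadata.columns]
    bc_species = diversity.beta_diversity(species_profile.loc[species_profile.sum(axis=1) > 0],
                                          "bray_curtis")
    rows = []
    for i, cov in enumerate(covars):
        series = metadata.loc[[str(s) for s in bc_species.ids], cov]
        keep = series.notna().to_numpy()
        if keep.sum() < 10 or series[keep].nunique() < 2:
            logger.warning("covariate %r skipped (too few complete cases)", cov)
            continue
        sub_ids = [sid for sid, k in zip(bc_species.ids, keep) if k]
        res = assoc.dbrda_univariate(
            bc_species.filter(sub_ids), series[keep],
            n_perm=config.n_perm, seed=config.seed + i + 1,
            reference_levels=config.reference_levels,
        )
        rows.append({"analysis": "dbrda", "term": res.term, "estimate": res.estimate,
                     "se": "", "p": res.p, "n": res.n})
    import pandas as pd

    dbrda_df = pd.DataFrame(rows)
    if len(dbrda_df):
        dbrda_df["p_adj"] = assoc.bh_adjust(dbrda_df["p"].to_numpy())
    io.write_table(out / "dbrda_univariate.tsv", dbrda_df.set_index("term")
                   if len(dbrda_df) else dbrda_df)

    ridge_covars = metadata[covars].dropna()
    ridge_df = pd.DataFrame()
    if len(ridge_covars) >= 30:
        feats = species_profile.loc[species_profile.index.intersection(ridge_covars.index)]
        ridge_df = assoc.ridge_associate_table(
            feats, ridge_covars.loc[feats.index],
            reference_levels=config.reference_levels,
        )
        io.write_table(out / "ridge_associations.tsv", ridge_df.set_index("feature"))
    manifest["stages"]["associate"] = {
        "n_dbrda_terms": int(len(dbrda_df)),
        "n_ridge_rows": int(len(ridge_df)),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
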