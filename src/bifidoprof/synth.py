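"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the pipeline end to end without any download:

* ``simulate_refset`` — groEL-bearing genomes with primer sites, feeding
  reference-database construction;
* ``simulate_hit_tables`` — NT/BIF hit tables whose bit scores and
  lineages force named branches of the arbitration decision tree;
* ``simulate_cohort`` — a cohort of samples with planted covariate
  effects: piecewise-linear age trajectories with change points at 16
  and 30 years, latitude/longitude/altitude gradients, ethnicity
  offsets, wheat-responder species, and an urbanization diversity shift.

Species compositions use logistic-normal noise (additive effects on the
log scale, softmax to a composition), read depths are negative binomial,
and ZOTU counts multinomial, so every association operation has a
well-defined recovery target recorded in the returned truth tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .refdb import PrimerPair, revcomp
from .taxonomy import TaxonomyPath

logger = logging.getLogger(__name__)

GENUS_PREFIX = "d__Bacteria;p__Actinobacteria;f__Bifidobacteriaceae;g__Bifidobacterium"

#: Documented placeholder primer pair used by the synthetic generators
#: (the real groEL primer sequences are configuration inputs).
DEFAULT_PRIMERS = PrimerPair(
    forward="GATTACGAATCGCATGCTTG",
    reverse="CCTTAGGCATCGGAATTCAA",
    max_mismatches=3,
)

#: The nine abundant species with baseline whole-cohort mean composite
#: abundances (percent of the whole community) used as log-scale baselines,
#: plus a genus-only lineage exercising the unclassified bucket.
DEFAULT_SPECIES_BASELINES: dict[str, float] = {
    "Bifidobacterium longum": 2.85,
    "Bifidobacterium pseudocatenulatum": 2.06,
    "Bifidobacterium adolescentis": 1.58,
    "Bifidobacterium breve": 0.42,
    "Bifidobacterium bifidum": 0.39,
    "Bifidobacterium animalis": 0.20,
    "Bifidobacterium dentium": 0.10,
    "Bifidobacterium angulatum": 0.092,
    "Bifidobacterium pseudolongum": 0.01,
    "Bifidobacterium sp.": 0.25,  # genus-only truth -> unclassified bucket
}

GENUS_ONLY = {"Bifidobacterium sp."}


@dataclass(frozen=True)
class Site:
    name: str
    lat: float
    lon: float
    alt: float
    zone: str
    ethnicity_probs: dict[str, float]
    staple_probs: dict[str, float]
    residence_probs: dict[str, float]


def default_sites() -> list[Site]:
    """Eight sites spanning the cohort's geographic envelope
    (latitude 23-50 N, longitude 75-130 E, altitude 3-3850 m)."""
    han = {"Han": 1.0}
    mixed_tib = {"Tibetan": 0.7, "Han": 0.3}
    mixed_uy = {"Uygur": 0.6, "Han": 0.4}
    rice = {"rice": 0.7, "rice_wheat": 0.2, "wheat": 0.1}
    wheat = {"wheat": 0.7, "rice_wheat": 0.2, "rice": 0.1}
    both = {"rice": 0.34, "wheat": 0.33, "rice_wheat": 0.33}
    urban = {"urban": 0.8, "rural": 0.2, "pastoral": 0.0}
    rural = {"rural": 0.8, "urban": 0.2, "pastoral": 0.0}
    pastoral = {"pastoral": 0.6, "rural": 0.4, "urban": 0.0}
    return [
        Site("S_south_coast", 23.1, 113.3, 20, "VII", han, rice, urban),
        Site("S_southwest", 25.0, 102.7, 1890, "VI", {"Naxi": 0.4, "Bai": 0.2, "Han": 0.4},
             rice, rural),
        Site("S_plateau", 29.7, 91.1, 3650, "IV2", mixed_tib, both, pastoral),
        Site("S_east", 31.2, 121.5, 5, "III2", han, both, urban),
        Site("S_central", 34.7, 113.6, 110, "II3", han, wheat, rural),
        Site("S_northwest", 39.5, 76.0, 1290, "IV1", mixed_uy, wheat, rural),
        Site("S_north", 40.0, 116.4, 50, "II2", {"Han": 0.8, "Hui": 0.2}, wheat, urban),
        Site("S_northeast", 49.2, 127.5, 240, "I", {"Han": 0.8, "Mongolian": 0.2},
             wheat, rural),
    ]


def default_effects() -> dict[str, dict[str, float]]:
    """Planted per-species log-fold effects (per z-unit for continuous
    terms, offsets for categorical levels)."""
    return {
        "latitude": {"Bifidobacterium adolescentis": 0.4,
                     "Bifidobacterium pseudolongum": 0.3,
                     "Bifidobacterium angulatum": -0.4},
        "longitude": {"Bifidobacterium pseudolongum": 0.3,
                      "Bifidobacterium longum": -0.2},
        "altitude": {"Bifidobacterium angulatum": 0.4,
                     "Bifidobacterium sp.": 0.3},
        "staple_food=wheat": {"Bifidobacterium adolescentis": 0.8,
                              "Bifidobacterium longum": 0.8},
        "ethnicity=Tibetan": {"Bifidobacterium sp.": 1.2,
                              "Bifidobacterium angulatum": 1.0},
        "residence=urban": {"Bifidobacterium dentium": -0.5},
        "residence=pastoral": {"Bifidobacterium breve": 0.4},
    }


def default_age_slopes() -> dict[str, tuple[float, float, float]]:
    """Piecewise log-slopes per year on the segments [0,16), [16,30),
    [30,inf), emulating the species' lifespan trajectories."""
    return {
        "Bifidobacterium longum": (-0.02, -0.02, -0.02),
        "Bifidobacterium bifidum": (-0.03, -0.03, -0.03),
        "Bifidobacterium animalis": (-0.10, -0.01, -0.01),
        "Bifidobacterium breve": (-0.08, -0.08, 0.0),
        "Bifidobacterium dentium": (-0.06, -0.06, 0.02),
        "Bifidobacterium adolescentis": (0.12, -0.03, -0.03),
        "Bifidobacterium pseudocatenulatum": (0.06, 0.0, 0.0),
        "Bifidobacterium angulatum": (0.05, 0.0, 0.0),
    }


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    n_samples: int = 600
    species_baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES_BASELINES))
    effects: dict[str, dict[str, float]] = field(default_factory=default_effects)
    age_slopes: dict[str, tuple[float, float, float]] = field(default_factory=default_age_slopes)
    change_points: tuple[float, float] = (16.0, 30.0)
    noise_sd: float = 1.0
    n_zotus: int = 40
    depth_mean: float = 15000.0
    depth_shape: float = 3.0
    min_depth: int = 2000
    bif16s_alpha: float = 2.0
    bif16s_beta: float = 30.0
    sites: list[Site] = field(default_factory=default_sites)
    months: tuple[str, ...] = ("April", "June", "August", "October")
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for site in self.sites:
            for probs in (site.ethnicity_probs, site.staple_probs, site.residence_probs):
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"site {site.name}: probabilities must sum to 1")


def _piecewise_age_term(age: float, slopes: tuple[float, float, float],
                        breaks: tuple[float, float]) -> float:
    b1, b2 = breaks
    s1, s2, s3 = slopes
    if age <= b1:
        return s1 * age
    if age <= b2:
        return s1 * b1 + s2 * (age - b1)
    return s1 * b1 + s2 * (b2 - b1) + s3 * (age - b2)


def _draw_age(rng: np.random.Generator) -> float:
    u = rng.random()
    if u < 0.10:
        return float(rng.uniform(0.05, 3))
    if u < 0.90:
        return float(rng.uniform(3, 75))
    return float(rng.uniform(75, 100))


def simulate_cohort(spec: CohortSpec) -> dict:
    """Generate a cohort: ZOTU counts, 16S genus fractions, metadata,
    species truth compositions and the planted-effect table."""
    rng = np.random.default_rng(spec.seed)
    species = list(spec.species_baselines)
    n_sp = len(species)
    if spec.n_zotus < n_sp:
        raise ValueError("need at least one ZOTU per species")

    # ZOTU allocation: one per species, the rest proportional to baseline
    zotu_species = list(species)
    baseline = np.array([spec.species_baselines[s] for s in species], dtype=float)
    extra = rng.choice(n_sp, size=spec.n_zotus - n_sp, p=baseline / baseline.sum())
    zotu_species += [species[i] for i in extra]
    zotu_ids = [f"ZOTU{i + 1}" for i in range(spec.n_zotus)]
    within_weights = rng.dirichlet(np.full(spec.n_zotus, 5.0))

    site_lats = np.array([s.lat for s in spec.sites])
    site_lons = np.array([s.lon for s in spec.sites])
    site_alts = np.array([s.alt for s in spec.sites])

    def z(vals: np.ndarray, x: float) -> float:
        return float((x - vals.mean()) / vals.std(ddof=1))

    log_base = np.log(baseline)
    meta_rows = []
    comp_rows = np.empty((spec.n_samples, n_sp))
    counts = np.zeros((spec.n_samples, spec.n_zotus), dtype=np.int64)
    bif16s = np.empty(spec.n_samples)

    def draw_cat(probs: dict[str, float]) -> str:
        names = list(probs)
        return names[rng.choice(len(names), p=np.array([probs[k] for k in names]))]

    for i in range(spec.n_samples):
        site = spec.sites[rng.integers(len(spec.sites))]
        ethnicity = draw_cat(site.ethnicity_probs)
        staple = draw_cat(site.staple_probs)
        residence = draw_cat(site.residence_probs)
        month = spec.months[rng.integers(len(spec.months))]
        sex = "female" if rng.random() < 0.5 else "male"
        age = _draw_age(rng)

        logab = log_base.copy()
        covs = {"latitude": z(site_lats, site.lat),
                "longitude": z(site_lons, site.lon),
                "altitude": z(site_alts, site.alt)}
        levels = {"staple_food": staple, "ethnicity": ethnicity,
                  "residence": residence, "sex": sex, "sampling_month": month}
        for term, per_species in spec.effects.items():
            if "=" in term:
                var, lev = term.split("=", 1)
                mult = 1.0 if levels.get(var) == lev else 0.0
            else:
                mult = covs.get(term, 0.0)
            if mult:
                for sp_name, eff in per_species.items():
                    logab[species.index(sp_name)] += eff * mult
        for sp_name, slopes in spec.age_slopes.items():
            logab[species.index(sp_name)] += _piecewise_age_term(age, slopes, spec.change_points)
        logab += rng.normal(0.0, spec.noise_sd, size=n_sp)
        comp = np.exp(logab - logab.max())
        comp /= comp.sum()
        comp_rows[i] = comp

        # The genus-level 16S fraction tracks the realized community total:
        # a Beta draw scaled by the latent bifidobacterial load relative to
        # baseline.  On the composite-abundance scale the within-genus
        # closure denominator then cancels exactly, so planted per-species
        # log effects are recovered as-is and unplanted species stay null --
        # mirroring the observation that staple wheat expands the genus as a
        # whole rather than redistributing a fixed genus share.  (The rare
        # clip at 0.99 keeps the fraction a valid proportion.)
        load_ratio = np.exp(logab).sum() / np.exp(log_base).sum()
        b_draw = rng.beta(spec.bif16s_alpha, spec.bif16s_beta)
        bif16s[i] = min(b_draw * load_ratio, 0.99)

        depth = int(max(spec.min_depth,
                        rng.negative_binomial(spec.depth_shape,
                                              spec.depth_shape / (spec.depth_shape + spec.depth_mean))))
        zotu_p = np.array([comp[species.index(zotu_species[k])] * within_weights[k]
                           for k in range(spec.n_zotus)])
        zotu_p /= zotu_p.sum()
        counts[i] = rng.multinomial(depth, zotu_p)

        meta_rows.append({
            "sample_id": f"S{i + 1:04d}", "site": site.name, "zone": site.zone,
            "latitude": site.lat, "longitude": site.lon, "altitude": site.alt,
            "age": age, "sex": sex, "ethnicity": ethnicity,
            "staple_food": staple, "residence": residence, "sampling_month": month,
        })

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = pd.DataFrame(counts, index=metadata.index, columns=zotu_ids)
    truth_comp = pd.DataFrame(comp_rows, index=metadata.index, columns=species)
    effect_rows = [
        {"term": term, "species": sp_name, "effect": eff}
        for term, per_species in spec.effects.items()
        for sp_name, eff in per_species.items()
    ]
    return {
        "table": table,
        "bif16s": pd.Series(bif16s, index=metadata.index, name="bif16s"),
        "metadata": metadata,
        "zotu_species": dict(zip(zotu_ids, zotu_species)),
        "truth_composition": truth_comp,
        "truth_effects": pd.DataFrame(effect_rows),
    }


def truth_lineage(species_name: str) -> TaxonomyPath:
    """Ranked lineage of a synthetic species (genus-only for the
    unclassified-bucket species)."""
    if species_name in GENUS_ONLY:
        return TaxonomyPath.from_string(GENUS_PREFIX)
    return TaxonomyPath.from_string(f"{GENUS_PREFIX};s__{species_name}")


def truth_assignments(zotu_species: dict[str, str]):
    """Ground-truth ZotuAssignments matching a simulated cohort."""
    from .classify import ZotuAssignment

    out = []
    for zotu_id, sp_name in zotu_species.items():
        tax = truth_lineage(sp_name)
        out.append(ZotuAssignment(zotu_id, "assigned", tax, "agree",
                                  400.0, 400.0, "rule3_agree"))
    return out


# ---------------------------------------------------------------------------
# reference-set simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i, c in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != c])
    return "".join(out)


OUTGROUP_PREFIX = "d__Bacteria;p__Firmicutes;f__Lactobacillaceae;g__Lactobacillus"


def simulate_refset(
    n_species: int = 6,
    n_variants_per_species: int = 3,
    primers: PrimerPair = DEFAULT_PRIMERS,
    amplicon_len: int = 460,
    species_divergence: float = 0.08,
    mutation_rate: float = 0.02,
    n_outgroup: int = 0,
    outgroup_divergence: float = 0.35,
    flank_len: int = 200,
    seed: Optional[int] = None,
) -> tuple[list[tuple[str, str]], dict[str, TaxonomyPath]]:
    """Genomes carrying a primer-flanked marker amplicon, plus truth taxonomy.

    The marker is conserved: each species' root amplicon diverges from a
    shared ancestral sequence by *species_divergence* per site, variants
    within a species by *mutation_rate*, and outgroup amplicons by the
    (much larger) *outgroup_divergence* — so in-group pairwise identities
    sit well above identities to the outgroup, as a single-copy marker
    database should.  Each amplicon is embedded in a random genome as
    ``flank + forward + amplicon + revcomp(reverse) + flank``.  Outgroup
    genomes carry a non-target genus lineage (identifiable by taxonomy).
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, amplicon_len)
    genomes: list[tuple[str, str]] = []
    taxonomy: dict[str, TaxonomyPath] = {}

    def embed(amp: str) -> str:
        return (_random_seq(rng, flank_len) + primers.forward + amp
                + revcomp(primers.reverse) + _random_seq(rng, flank_len))

    for s in range(n_species):
        sp_name = f"Bifidobacterium synthetica{s + 1}"
        root = _mutate(rng, ancestor, species_divergence)
        for v in range(n_variants_per_species):
            amp = root if v == 0 else _mutate(rng, root, mutation_rate)
            gid = f"G{s + 1:02d}_{v + 1}"
            genomes.append((gid, embed(amp)))
            taxonomy[gid] = TaxonomyPath.from_string(f"{GENUS_PREFIX};s__{sp_name}")
    for o in range(n_outgroup):
        gid = f"OG{o + 1:02d}"
        genomes.append((gid, embed(_mutate(rng, ancestor, outgroup_divergence))))
        taxonomy[gid] = TaxonomyPath.from_string(
            f"{OUTGROUP_PREFIX};s__Lactobacillus synthetica{o + 1}")
    return genomes, taxonomy


# ---------------------------------------------------------------------------
# hit-table simulation
# ---------------------------------------------------------------------------

_NONBIF = "d__Bacteria;p__Firmicutes;f__Lactobacillaceae;g__Lactobacillus;s__Lactobacillus gasseri"
_GENUS_BIF = GENUS_PREFIX
_SPECIES_BIF = f"{GENUS_PREFIX};s__Bifidobacterium longum"


def _hit_row(zotu: str, subject: str, bit: float, lineage: str) -> dict:
    return {"zotu_id": zotu, "subject_id": subject, "percent_identity": 95.0,
            "bit_score": bit, "evalue": 1e-50, "query_coverage": 98.0,
            "lineage": lineage}


def hit_tables_from_truth(zotu_species: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Agreeing NT/BIF hit tables whose lineages carry the true species
    of each ZOTU (classification then reproduces the truth exactly)."""
    nt_rows, bif_rows = [], []
    for zotu, sp_name in zotu_species.items():
        lineage = truth_lineage(sp_name).to_string()
        nt_rows.append(_hit_row(zotu, "nt_true", 240.0, lineage))
        bif_rows.append(_hit_row(zotu, "bif_true", 260.0, lineage))
    cols = ["zotu_id", "subject_id", "percent_identity", "bit_score",
            "evalue", "query_coverage", "lineage"]
    return pd.DataFrame(nt_rows, columns=cols), pd.DataFrame(bif_rows, columns=cols)


def simulate_hit_tables(rule_plan: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NT and BIF hit tables forcing a named arbitration rule per ZOTU.

    *rule_plan* maps ZOTU id -> one of ``rule1`` ... ``rule6``.  The
    emitted bit scores and lineages are engineered so classification
    fires exactly the named branch.
    """
    nt_rows: list[dict] = []
    bif_rows: list[dict] = []
    for zotu, rule in rule_plan.items():
        if rule == "rule1":
            pass  # no hits anywhere
        elif rule == "rule2":
            nt_rows.append(_hit_row(zotu, "nt_nonbif", 300.0, _NONBIF))
            bif_rows.append(_hit_row(zotu, "bif_sp", 250.0, _SPECIES_BIF))
        elif rule == "rule3":
            nt_rows.append(_hit_row(zotu, "nt_sp", 240.0, _SPECIES_BIF))
            bif_rows.append(_hit_row(zotu, "bif_sp", 260.0, _SPECIES_BIF))
        elif rule == "rule4":
            nt_rows.append(_hit_row(zotu, "nt_genus", 190.0, _GENUS_BIF))
            bif_rows.append(_hit_row(zotu, "bif_sp", 200.0, _SPECIES_BIF))
        elif rule == "rule5":
            nt_rows.append(_hit_row(zotu, "nt_genus", 150.0, _GENUS_BIF))
            bif_rows.append(_hit_row(zotu, "bif_sp", 200.0, _SPECIES_BIF))
        elif rule == "rule6":
            nt_rows.append(_hit_row(zotu, "nt_sp", 260.0, _SPECIES_BIF))
            bif_rows.append(_hit_row(zotu, "bif_genus", 200.0, _GENUS_BIF))
        else:
            raise ValueError(f"unknown rule {rule!r} for ZOTU {zotu}")
    cols = ["zotu_id", "subject_id", "percent_identity", "bit_score",
            "evalue", "query_coverage", "lineage"]
    return (pd.DataFrame(nt_rows, columns=cols), pd.DataFrame(bif_rows, columns=cols))
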