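"""Synthetic multi-species cervid diet data with the study's structure.

Generates every pipeline input — PCR-level read counts for the mammal and
plant markers (with extraction/negative/positive/primer-blank controls),
a MOTU catalog, sample metadata, step-point forage availability,
pellet-group counts and landscape covariates — plus the latent per-sample
diet proportions ("truth") used by recovery tests.

The default community emulates a two-landscape Swedish cervid system:

* a low-density *coastal-boreal* landscape (cervid index mean 0.43
  pellet groups / 100 m^2, SD 0.62; arable land 5.3% +- 7.9; habitat
  Shannon H' 1.95 +- 0.17) and a high-density *boreo-nemoral* landscape
  (4.88 +- 2.17; 15.7% +- 14.4; 2.10 +- 0.19);
* four deer species (moose, roe, red, fallow) whose diet Dirichlet means
  encode the browser-to-grazer gradient: moose winter/spring diets are
  pine-dominated (mean RRA > 0.5 boreo-nemoral, 0.35-0.40 coastal-boreal,
  ~0.15 in summer-autumn) and essentially graminoid-free (< 1%), while
  graminoid and forb use rises from roe over red to fallow deer;
* a 210-MOTU plant taxon pool spread over 77 family-level categories,
  with per-species evenness chosen so per-sample richness in the final
  filtered dataset falls in the reported ranges (moose lowest, fallow
  highest);
* within-species diet variability (Dirichlet concentration) that is
  higher in winter than in summer-autumn, producing the seasonal decline
  of intraspecific overlap.

Read counts are generated by a two-stage Dirichlet-multinomial: the
latent diet is drawn per sample, each of the three plant PCR replicates
perturbs it with replicate-level Dirichlet overdispersion, and reads are
a multinomial draw at a log-normal depth.  Failed replicates arise by two
mechanisms matching the two QC discard rules: low depth (< 1000 reads)
and control-like composition.  All randomness flows from a single master
seed through deterministically spawned child streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drivers
from .io_model import (LANDSCAPES, SEASONS, SPECIES, AvailabilityTable,
                       CovariateTable, MOTUCatalog, PelletCountTable,
                       ReadCountTable, SampleMetadata, taxonomy_path)

# ---------------------------------------------------------------------------
# Taxon pool

#: (family, food category, number of MOTUs) for the well-represented taxa.
MAJOR_GROUPS = [
    ("Pinaceae", "pine", 4),
    ("Pinaceae", "spruce", 3),
    ("Cupressaceae", "juniper", 2),
    ("Betulaceae", "birch", 6),
    ("Betulaceae", "alder", 3),
    ("Salicaceae", "willow", 6),
    ("Salicaceae", "poplar", 3),
    ("Ericaceae", "vaccinium", 8),
    ("Ericaceae", "heather", 2),
    ("Poaceae", "graminoids", 10),
    ("Poaceae", "cereals", 3),
    ("Juncaceae", "graminoids", 6),
    ("Cyperaceae", "graminoids", 4),
    ("Fabaceae", "forbs", 8),
    ("Asteraceae", "forbs", 8),
    ("Onagraceae", "forbs", 3),
    ("Ranunculaceae", "forbs", 5),
    ("Rosaceae", "other", 7),
]

#: Rarely eaten families filling the pool out to 77 family categories.
MINOR_FAMILIES = [
    "Apiaceae", "Brassicaceae", "Campanulaceae", "Caprifoliaceae",
    "Caryophyllaceae", "Cornaceae", "Crassulaceae", "Droseraceae",
    "Equisetaceae", "Geraniaceae", "Grossulariaceae", "Hypericaceae",
    "Lamiaceae", "Lentibulariaceae", "Liliaceae", "Linnaeaceae",
    "Lycopodiaceae", "Menyanthaceae", "Myricaceae", "Orchidaceae",
    "Orobanchaceae", "Oxalidaceae", "Papaveraceae", "Plantaginaceae",
    "Polygonaceae", "Polypodiaceae", "Primulaceae", "Pteridaceae",
    "Rhamnaceae", "Rubiaceae", "Santalaceae", "Sapindaceae",
    "Saxifragaceae", "Scrophulariaceae", "Solanaceae", "Thymelaeaceae",
    "Typhaceae", "Ulmaceae", "Urticaceae", "Violaceae", "Adoxaceae",
    "Amaranthaceae", "Araliaceae", "Athyriaceae", "Balsaminaceae",
    "Berberidaceae", "Boraginaceae", "Butomaceae", "Cannabaceae",
    "Celastraceae", "Ceratophyllaceae", "Cistaceae", "Convolvulaceae",
    "Cucurbitaceae", "Dennstaedtiaceae", "Dryopteridaceae", "Elaeagnaceae",
    "Fagaceae", "Gentianaceae", "Haloragaceae", "Iridaceae",
    "Juncaginaceae", "Malvaceae", "Nymphaeaceae",
]
MINOR_MOTUS_PER_FAMILY = ([2] * 55 + [1] * 9)  # 119 MOTUs over 64 families

FOOD_CATEGORIES = ("pine", "spruce", "juniper", "birch", "alder", "willow",
                   "poplar", "heather", "vaccinium", "forbs", "graminoids",
                   "cereals", "other")

#: Landscape short codes used in identifiers.
LCODE = {"coastal_boreal": "CB", "boreo_nemoral": "BN"}
SEASON_DATE = {"winter": "2017-01-20", "spring": "2017-04-25",
               "summer_autumn": "2017-08-10"}

# Category-level diet weights per species x season x landscape (normalized
# later).  They encode the reported qualitative structure: moose pine-heavy
# in winter/spring (more so boreo-nemoral) and graminoid-free; forbs and
# graminoids increasing from roe over red to fallow; red deer birch-rich in
# coastal-boreal summer; forbs in smaller deer's boreo-nemoral winter diets
# (supplementary feeding).
_BN, _CB = "boreo_nemoral", "coastal_boreal"
DIET_WEIGHTS: dict[tuple[str, str, str], dict[str, float]] = {
    ("moose", "winter", _BN): dict(pine=.60, vaccinium=.20, juniper=.05,
                                   birch=.05, willow=.03, spruce=.015,
                                   heather=.01, forbs=.015, poplar=.01,
                                   alder=.005, graminoids=.002, other=.02),
    ("moose", "winter", _CB): dict(pine=.38, vaccinium=.31, juniper=.04,
                                   birch=.09, willow=.06, spruce=.01,
                                   heather=.01, forbs=.03, poplar=.01,
                                   alder=.01, graminoids=.002, other=.04),
    ("moose", "spring", _BN): dict(pine=.56, vaccinium=.19, juniper=.06,
                                   birch=.07, willow=.05, spruce=.01,
                                   heather=.01, forbs=.02, poplar=.01,
                                   alder=.01, graminoids=.002, other=.02),
    ("moose", "spring", _CB): dict(pine=.37, vaccinium=.27, juniper=.04,
                                   birch=.11, willow=.09, spruce=.01,
                                   heather=.01, forbs=.04, poplar=.01,
                                   alder=.01, graminoids=.002, other=.03),
    ("moose", "summer_autumn", _BN): dict(pine=.15, vaccinium=.28,
                                          juniper=.02, birch=.25,
                                          willow=.15, spruce=.01,
                                          heather=.01, forbs=.04,
                                          poplar=.02, alder=.02,
                                          graminoids=.002, other=.05),
    ("moose", "summer_autumn", _CB): dict(pine=.15, vaccinium=.40,
                                          juniper=.01, birch=.20,
                                          willow=.12, spruce=.005,
                                          heather=.01, forbs=.04,
                                          poplar=.01, alder=.01,
                                          graminoids=.002, other=.04),
    ("roe", "winter", _BN): dict(vaccinium=.38, heather=.08,
                                 graminoids=.10, forbs=.10, birch=.08,
                                 willow=.04, spruce=.02, pine=.01,
                                 juniper=.005, poplar=.02, alder=.01,
                                 cereals=.01, other=.13),
    ("roe", "winter", _CB): dict(vaccinium=.44, heather=.09,
                                 graminoids=.08, forbs=.05, birch=.09,
                                 willow=.04, spruce=.01, pine=.01,
                                 juniper=.005, poplar=.02, alder=.01,
                                 other=.14),
    ("roe", "spring", _BN): dict(vaccinium=.38, heather=.07,
                                 graminoids=.13, forbs=.12, birch=.08,
                                 willow=.04, pine=.01, juniper=.005,
                                 spruce=.01, poplar=.02, alder=.01,
                                 other=.12),
    ("roe", "spring", _CB): dict(vaccinium=.42, heather=.08,
                                 graminoids=.11, forbs=.09, birch=.08,
                                 willow=.04, pine=.01, juniper=.005,
                                 spruce=.005, poplar=.02, alder=.01,
                                 other=.13),
    ("roe", "summer_autumn", _BN): dict(vaccinium=.22, heather=.04,
                                        graminoids=.10, forbs=.25,
                                        birch=.15, willow=.08, poplar=.03,
                                        alder=.02, pine=.01, spruce=.005,
                                        other=.14),
    ("roe", "summer_autumn", _CB): dict(vaccinium=.26, heather=.04,
                                        graminoids=.09, forbs=.23,
                                        birch=.15, willow=.08, poplar=.02,
                                        alder=.02, pine=.01, spruce=.005,
                                        other=.14),
    ("red", "winter", _BN): dict(vaccinium=.27, heather=.10,
                                 graminoids=.12, forbs=.24, cereals=.02,
                                 birch=.07, willow=.03, spruce=.02,
                                 pine=.02, juniper=.005, poplar=.01,
                                 alder=.01, other=.09),
    ("red", "winter", _CB): dict(vaccinium=.34, heather=.12,
                                 graminoids=.08, cereals=.03, forbs=.08,
                                 birch=.10, willow=.04, pine=.01,
                                 spruce=.01, juniper=.005, poplar=.01,
                                 alder=.01, other=.11),
    ("red", "spring", _BN): dict(vaccinium=.33, heather=.12,
                                 graminoids=.12, forbs=.13, birch=.09,
                                 willow=.04, pine=.02, spruce=.01,
                                 juniper=.005, poplar=.01, alder=.01,
                                 other=.11),
    ("red", "spring", _CB): dict(vaccinium=.36, heather=.12,
                                 graminoids=.09, forbs=.11, birch=.10,
                                 willow=.04, pine=.01, spruce=.01,
                                 juniper=.005, poplar=.01, alder=.01,
                                 other=.12),
    ("red", "summer_autumn", _BN): dict(vaccinium=.15, heather=.05,
                                        graminoids=.12, forbs=.22,
                                        birch=.20, willow=.06, poplar=.02,
                                        alder=.02, pine=.01, spruce=.01,
                                        other=.13),
    ("red", "summer_autumn", _CB): dict(vaccinium=.12, heather=.04,
                                        graminoids=.08, forbs=.15,
                                        birch=.35, willow=.06, poplar=.02,
                                        alder=.02, pine=.01, spruce=.005,
                                        other=.13),
    ("fallow", "winter", _BN): dict(vaccinium=.20, heather=.08,
                                    graminoids=.15, forbs=.24,
                                    cereals=.03, birch=.06, willow=.03,
                                    spruce=.04, pine=.02, juniper=.005,
                                    poplar=.01, alder=.01, other=.13),
    ("fallow", "winter", _CB): dict(vaccinium=.28, heather=.08,
                                    graminoids=.12, forbs=.12,
                                    cereals=.01, birch=.08, willow=.04,
                                    spruce=.02, pine=.01, juniper=.005,
                                    poplar=.01, alder=.01, other=.14),
    ("fallow", "spring", _BN): dict(vaccinium=.21, heather=.08,
                                    graminoids=.18, forbs=.18, birch=.07,
                                    willow=.03, spruce=.04, pine=.02,
                                    juniper=.005, poplar=.01, alder=.01,
                                    other=.14),
    ("fallow", "spring", _CB): dict(vaccinium=.26, heather=.07,
                                    graminoids=.14, forbs=.15, birch=.08,
                                    willow=.04, spruce=.02, pine=.02,
                                    juniper=.005, poplar=.01, alder=.01,
                                    other=.14),
    ("fallow", "summer_autumn", _BN): dict(vaccinium=.11, heather=.05,
                                           graminoids=.15, forbs=.40,
                                           birch=.08, willow=.04,
                                           spruce=.03, pine=.01,
                                           poplar=.01, alder=.01,
                                           other=.12),
    ("fallow", "summer_autumn", _CB): dict(vaccinium=.13, heather=.05,
                                           graminoids=.13, forbs=.38,
                                           birch=.09, willow=.04,
                                           spruce=.02, pine=.01,
                                           poplar=.01, alder=.01,
                                           other=.12),
}

#: Within-category MOTU weight decay: smaller = mass piled on one MOTU.
SPECIES_EVENNESS = {"moose": 0.30, "roe": 0.45, "red": 0.50, "fallow": 0.75}
#: Baseline mass spread uniformly over the whole pool (per MOTU).
FLOOR_MASS = {"moose": 2e-5, "roe": 1.5e-4, "red": 2e-4, "fallow": 7e-4}
#: Diet Dirichlet concentration by species (scaled per season below);
#: higher = individuals more alike = higher intraspecific overlap.
DIET_CONCENTRATION = {"moose": 40.0, "roe": 45.0, "red": 38.0,
                      "fallow": 30.0}
SEASON_CONCENTRATION = {"winter": 1.0, "spring": 0.85,
                        "summer_autumn": 0.40}

#: Step-point availability weights per landscape (before height scaling).
AVAIL_WEIGHTS = {
    _BN: dict(pine=.20, spruce=.24, birch=.15, vaccinium=.10, heather=.05,
              graminoids=.10, forbs=.05, willow=.02, juniper=.015,
              alder=.02, poplar=.01, cereals=.03, other=.035),
    _CB: dict(pine=.25, spruce=.23, birch=.14, vaccinium=.12, heather=.06,
              graminoids=.09, forbs=.04, willow=.02, juniper=.02,
              alder=.02, poplar=.01, cereals=.005, other=.035),
}
#: Tree-category availability multiplier per browsing-height range.
HEIGHT_TREE_FACTOR = {"0-1.5m": 0.80, "0-1.8m": 0.90, "0-2.3m": 1.00,
                      "0-3m": 1.15}
TREE_CATEGORIES = {"pine", "spruce", "birch", "alder", "poplar", "willow",
                   "juniper"}


@dataclass
class CommunitySpec:
    """All tunable parameters of the synthetic community."""

    n_transects: dict[str, int] = field(
        default_factory=lambda: {"coastal_boreal": 17, "boreo_nemoral": 16})
    #: expected fecal samples per transect x species x season
    expected_samples: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            (lsc, sp): 2.5 * {"moose": 1.2, "roe": 0.9, "red": 1.0,
                              "fallow": 0.8}[sp]
            * (0.6 if (lsc, sp) == ("coastal_boreal", "fallow") else 1.0)
            for lsc in LANDSCAPES for sp in SPECIES})
    n_motus: int = 210
    n_artifact_motus: int = 8
    artifact_rate: float = 0.01          # read share routed to artifacts
    diet_concentration: dict[str, float] = field(
        default_factory=lambda: dict(DIET_CONCENTRATION))
    season_concentration: dict[str, float] = field(
        default_factory=lambda: dict(SEASON_CONCENTRATION))
    replicate_overdispersion: float = 1 / 300.0   # 0 = identical replicates
    depth_meanlog: float = float(np.log(20_000.0))
    depth_sdlog: float = 0.5
    mammal_depth_meanlog: float = float(np.log(8_000.0))
    mammal_depth_sdlog: float = 0.5
    host_dominance: float = 0.93
    low_depth_rate: float = 0.03          # replicates failing by depth
    control_like_rate: float = 0.02       # replicates failing by profile
    contamination_reads: dict[str, float] = field(
        default_factory=lambda: {"extraction_blank": 300.0,
                                 "pcr_negative": 150.0,
                                 "primer_blank": 100.0,
                                 "pcr_positive": 20_000.0})
    n_controls: dict[str, int] = field(
        default_factory=lambda: {"extraction_blank": 8, "pcr_negative": 3,
                                 "pcr_positive": 2, "primer_blank": 12})
    putative_error: float = 0.1
    covariates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            _BN: dict(cervid_mean=4.88, cervid_sd=2.17, shannon_mean=2.10,
                      shannon_sd=0.19, arable_mean=0.157, arable_sd=0.144),
            _CB: dict(cervid_mean=0.43, cervid_sd=0.62, shannon_mean=1.95,
                      shannon_sd=0.17, arable_mean=0.053, arable_sd=0.079),
        })
    availability_concentration: float = 200.0
    seed: int = 0

    # -- derived taxon pool (built once in __post_init__) ------------------
    def __post_init__(self):
        self._build_pool()
        self._validate()

    def _build_pool(self):
        motus, families, categories = [], [], []
        i = 0
        for fam, cat, n in MAJOR_GROUPS:
            for j in range(n):
                motus.append(f"p{i:03d}_{cat}{j}")
                families.append(fam)
                categories.append(cat)
                i += 1
        for fam, n in zip(MINOR_FAMILIES, MINOR_MOTUS_PER_FAMILY):
            for j in range(n):
                motus.append(f"p{i:03d}_{fam.lower()[:6]}{j}")
                families.append(fam)
                categories.append("other")
                i += 1
        assert len(motus) == 210
        self.motu_ids = motus
        self.motu_family = dict(zip(motus, families))
        self.motu_category = dict(zip(motus, categories))
        self.artifact_ids = [f"x{i:02d}_artifact"
                             for i in range(self.n_artifact_motus)]
        # diet Dirichlet mean per (species, season, landscape)
        cat_members: dict[str, list[int]] = {}
        for k, m in enumerate(motus):
            cat_members.setdefault(categories[k], []).append(k)
        self.diet_means: dict[tuple[str, str, str], np.ndarray] = {}
        for (sp, sea, lsc), weights in DIET_WEIGHTS.items():
            mean = np.full(len(motus), FLOOR_MASS[sp])
            decay = SPECIES_EVENNESS[sp]
            for cat, w in weights.items():
                idx = cat_members[cat]
                if cat == "other":
                    shares = np.power(0.97, np.arange(len(idx)))
                else:
                    shares = np.power(decay, np.arange(len(idx)))
                shares = shares / shares.sum()
                mean[idx] += w * shares
            self.diet_means[(sp, sea, lsc)] = mean / mean.sum()
        # contamination profile: ubiquitous taxa reaching the blanks
        contam = np.zeros(len(motus))
        for cat, w in [("vaccinium", .35), ("birch", .25), ("pine", .2),
                       ("graminoids", .1), ("forbs", .1)]:
            idx = cat_members[cat]
            contam[idx[0]] = w
        self.contamination_profile = contam / contam.sum()

    def _validate(self):
        for key, mean in self.diet_means.items():
            if abs(mean.sum() - 1.0) > 1e-9 or (mean < 0).any():
                raise ValueError(f"invalid diet mean for {key}")
        for rate in (self.artifact_rate, self.low_depth_rate,
                     self.control_like_rate, self.putative_error):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for v in self.contamination_reads.values():
            if v < 0:
                raise ValueError("contamination_reads must be >= 0")
        if self.replicate_overdispersion < 0:
            raise ValueError("replicate_overdispersion must be >= 0")


def make_default_spec(**overrides) -> CommunitySpec:
    """The default community, parameterized from the study's results."""
    return CommunitySpec(**overrides)


# ---------------------------------------------------------------------------

MAMMAL_MOTUS = pd.DataFrame([
    # motu_id, length, similarity, taxonomy, exact
    ("mam_moose", 72, 100.0, taxonomy_path("Cervidae", "Alces", "moose"),
     True),
    ("mam_roe", 70, 100.0, taxonomy_path("Cervidae", "Capreolus", "roe"),
     True),
    ("mam_red", 74, 100.0, taxonomy_path("Cervidae", "Cervus", "red"),
     True),
    ("mam_fallow", 71, 100.0, taxonomy_path("Cervidae", "Dama", "fallow"),
     True),
    ("mam_bear", 76, 100.0, taxonomy_path("Ursidae", "Ursus", "bear"),
     True),
    ("mam_artifact", 36, 88.0, taxonomy_path("unassigned"), False),
    ("mam_unknown", 75, 91.0, taxonomy_path("unassigned"), False),
], columns=["motu_id", "length_bp", "best_similarity", "taxonomy",
            "is_reference_exact"])

PLANT_POSITIVE_MOTU = "p_positive_ctrl"


@dataclass
class SimulatedDataset:
    read_counts: ReadCountTable
    catalog: MOTUCatalog
    metadata: SampleMetadata
    availability: AvailabilityTable
    pellets: PelletCountTable
    covariates: CovariateTable
    truth: pd.DataFrame                  # sample x diet-MOTU latent p
    category_map: dict[str, str]
    spec: CommunitySpec


def _catalog(spec: CommunitySpec) -> MOTUCatalog:
    rows = []
    for i, m in enumerate(spec.motu_ids):
        fam = spec.motu_family[m]
        rows.append({"motu_id": m, "marker": "plant",
                     "length_bp": 20 + (i * 7) % 101,
                     "best_similarity": 96.0 + (i * 3) % 5,
                     "taxonomy": taxonomy_path(fam, f"{fam[:-4]}{i % 5}"),
                     "is_reference_exact": (i % 7) != 0})
    for j, a in enumerate(spec.artifact_ids):
        rows.append({"motu_id": a, "marker": "plant",
                     "length_bp": 25 + (j * 11) % 90,
                     "best_similarity": 85.0 + (j * 2) % 10,
                     "taxonomy": taxonomy_path("unassigned"),
                     "is_reference_exact": False})
    rows.append({"motu_id": PLANT_POSITIVE_MOTU, "marker": "plant",
                 "length_bp": 55, "best_similarity": 100.0,
                 "taxonomy": taxonomy_path("Apocynaceae", "Stephanotis"),
                 "is_reference_exact": True})
    mam = MAMMAL_MOTUS.copy()
    mam.insert(1, "marker", "mammal")
    return MOTUCatalog(pd.concat([pd.DataFrame(rows), mam],
                                 ignore_index=True))


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerating zero-mass components."""
    g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    total = g.sum()
    if total == 0:
        out = np.zeros_like(alpha)
        out[int(np.argmax(alpha))] = 1.0
        return out
    return g / total


def simulate_dataset(spec: CommunitySpec,
                     seed: int | None = None) -> SimulatedDataset:
    """Draw a complete synthetic dataset; identical seed, identical output."""
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    rng_design, rng_diet, rng_mam, rng_ctrl, rng_avail, rng_pellet, \
        rng_cov = [np.random.default_rng(s) for s in ss.spawn(7)]

    plant_cols = spec.motu_ids + spec.artifact_ids + [PLANT_POSITIVE_MOTU]
    all_motus = plant_cols + list(MAMMAL_MOTUS["motu_id"])
    n_diet = len(spec.motu_ids)
    col_index = {m: i for i, m in enumerate(all_motus)}

    count_rows: list[np.ndarray] = []
    row_meta: list[dict] = []
    meta_rows: list[dict] = []
    truth_rows: list[np.ndarray] = []
    truth_ids: list[str] = []

    sp_index = {sp: i for i, sp in enumerate(SPECIES)}
    mam_cols = [col_index[f"mam_{sp}"] for sp in SPECIES]

    for lsc in LANDSCAPES:
        transects = [f"{LCODE[lsc]}{t:02d}"
                     for t in range(1, spec.n_transects[lsc] + 1)]
        for tr in transects:
            for sea in SEASONS:
                for sp in SPECIES:
                    lam = spec.expected_samples[(lsc, sp)]
                    n = rng_design.poisson(lam)
                    for i in range(n):
                        sid = f"{tr}_{sea[:2]}_{sp}_{i + 1}"
                        # metadata with putative field ID
                        if rng_design.random() < spec.putative_error:
                            others = [s for s in SPECIES if s != sp]
                            put = others[rng_design.integers(len(others))]
                        else:
                            put = sp
                        meta_rows.append({
                            "sample_id": sid, "transect_id": tr,
                            "landscape": lsc, "season": sea,
                            "collection_date": SEASON_DATE[sea],
                            "putative_species": put})
                        # latent diet
                        theta = (spec.diet_concentration[sp]
                                 * spec.season_concentration[sea])
                        mean = spec.diet_means[(sp, sea, lsc)]
                        p = _dirichlet(rng_diet, theta * mean)
                        truth_rows.append(p)
                        truth_ids.append(sid)
                        # three plant PCR replicates
                        for rep in range(1, 4):
                            row = np.zeros(len(all_motus))
                            depth = int(rng_diet.lognormal(
                                spec.depth_meanlog, spec.depth_sdlog))
                            u = rng_diet.random()
                            if u < spec.low_depth_rate:
                                depth = int(rng_diet.integers(50, 1000))
                                comp = p
                            elif u < (spec.low_depth_rate
                                      + spec.control_like_rate):
                                comp = _dirichlet(
                                    rng_diet,
                                    60.0 * spec.contamination_profile)
                            else:
                                od = spec.replicate_overdispersion
                                comp = p if od == 0 else \
                                    _dirichlet(rng_diet, p / od)
                            full = np.zeros(len(all_motus))
                            full[:n_diet] = comp * (1 - spec.artifact_rate)
                            if spec.artifact_rate > 0:
                                arts = _dirichlet(
                                    rng_diet,
                                    np.full(len(spec.artifact_ids), 2.0))
                                full[n_diet:n_diet + len(spec.artifact_ids)
                                     ] = spec.artifact_rate * arts
                            row[:] = rng_diet.multinomial(depth, full /
                                                          full.sum())
                            count_rows.append(row)
                            row_meta.append({
                                "pcr_id": f"{sid}_p{rep}",
                                "sample_id": sid, "marker": "plant",
                                "replicate_index": rep,
                                "control_kind": "none"})
                        # mammal PCR
                        dom = spec.host_dominance
                        rest = 1.0 - dom
                        shares = _dirichlet(
                            rng_mam, 80.0 * np.array(
                                [dom, rest * .5, rest * .3, rest * .2]))
                        other = [s for s in SPECIES if s != sp]
                        cross = other[rng_mam.integers(len(other))]
                        mdepth = int(rng_mam.lognormal(
                            spec.mammal_depth_meanlog,
                            spec.mammal_depth_sdlog))
                        row = np.zeros(len(all_motus))
                        comp = np.zeros(len(all_motus))
                        comp[mam_cols[sp_index[sp]]] = shares[0]
                        comp[mam_cols[sp_index[cross]]] = shares[1]
                        comp[col_index["mam_artifact"]] = shares[2]
                        comp[col_index["mam_unknown"]] = shares[3]
                        row[:] = rng_mam.multinomial(mdepth, comp)
                        count_rows.append(row)
                        row_meta.append({
                            "pcr_id": f"{sid}_pM", "sample_id": sid,
                            "marker": "mammal", "replicate_index": 1,
                            "control_kind": "none"})

    # controls (plant marker)
    for kind, n in sorted(spec.n_controls.items()):
        lam = spec.contamination_reads.get(kind, 0.0)
        for i in range(n):
            depth = int(rng_ctrl.poisson(lam)) if lam > 0 else 0
            row = np.zeros(len(all_motus))
            if depth > 0:
                if kind == "pcr_positive":
                    row[col_index[PLANT_POSITIVE_MOTU]] = depth
                else:
                    comp = _dirichlet(rng_ctrl,
                                      40.0 * spec.contamination_profile)
                    row[:n_diet] = rng_ctrl.multinomial(depth, comp)
            count_rows.append(row)
            row_meta.append({"pcr_id": f"ctrl_{kind}_{i + 1}",
                             "sample_id": "", "marker": "plant",
                             "replicate_index": i + 1,
                             "control_kind": kind})

    counts = pd.DataFrame(np.array(count_rows, dtype=np.int64).reshape(
        -1, len(all_motus)), columns=all_motus)
    frame = pd.concat([pd.DataFrame(row_meta), counts], axis=1)
    read_counts = ReadCountTable(frame)
    metadata = SampleMetadata(pd.DataFrame(meta_rows,
                                           columns=SampleMetadata.FIXED))
    truth = pd.DataFrame(np.array(truth_rows).reshape(-1, n_diet),
                         columns=spec.motu_ids)
    truth.insert(0, "sample_id", truth_ids)

    # availability
    avail_rows = []
    for lsc in LANDSCAPES:
        base = AVAIL_WEIGHTS[lsc]
        for t in range(1, spec.n_transects[lsc] + 1):
            tr = f"{LCODE[lsc]}{t:02d}"
            for sea in SEASONS:
                for hr, tf in HEIGHT_TREE_FACTOR.items():
                    w = np.array([base[c] * (tf if c in TREE_CATEGORIES
                                             else 1.0)
                                  for c in FOOD_CATEGORIES])
                    w = w / w.sum()
                    p = _dirichlet(rng_avail,
                                   spec.availability_concentration * w)
                    p = p / p.sum()
                    # exact renormalization for the sum-to-one invariant
                    p[-1] = 1.0 - p[:-1].sum()
                    for c, v in zip(FOOD_CATEGORIES, p):
                        avail_rows.append({
                            "transect_id": tr, "season": sea,
                            "height_range": hr, "category": c,
                            "proportion": float(v)})
    availability = AvailabilityTable(pd.DataFrame(avail_rows))

    # pellet-group counts (large class on 100 m^2, small class on 10 m^2)
    pellet_rows = []
    index_targets: dict[str, float] = {}
    for lsc in LANDSCAPES:
        cv = spec.covariates[lsc]
        m, s = cv["cervid_mean"], cv["cervid_sd"]
        shape = (m / s) ** 2
        scale = s ** 2 / m
        for t in range(1, spec.n_transects[lsc] + 1):
            tr = f"{LCODE[lsc]}{t:02d}"
            target = float(rng_pellet.gamma(shape, scale))
            index_targets[tr] = target
            total_area = 16 * 100 + 16 * 10       # both classes surveyed
            expect_total = target * total_area / 100.0
            lam_large = 0.7 * expect_total / 16
            lam_small = 0.3 * expect_total / 16
            for plot in range(1, 17):
                surveyed = rng_pellet.random() > 0.01
                for cls, area, lam in (("large", 100, lam_large),
                                       ("small", 10, lam_small)):
                    pellet_rows.append({
                        "transect_id": tr, "year": 2017, "plot_id": plot,
                        "plot_area_m2": area, "species_class": cls,
                        "pellet_groups": int(rng_pellet.poisson(lam))
                        if surveyed else 0,
                        "surveyed": surveyed})
    pellets = PelletCountTable(pd.DataFrame(pellet_rows))

    # covariates: cervid index from the simulated pellet data
    idx = drivers.cervid_index(pellets)
    cov_rows = []
    for lsc in LANDSCAPES:
        cv = spec.covariates[lsc]
        for t in range(1, spec.n_transects[lsc] + 1):
            tr = f"{LCODE[lsc]}{t:02d}"
            h = max(0.1, rng_cov.normal(cv["shannon_mean"],
                                        cv["shannon_sd"]))
            a = float(np.clip(rng_cov.normal(cv["arable_mean"],
                                             cv["arable_sd"]), 0.0, 1.0))
            ci = idx.loc[idx["transect_id"] == tr, "cervid_index"]
            cov_rows.append({"transect_id": tr,
                             "cervid_index": float(ci.iloc[0]),
                             "habitat_shannon": h, "arable_prop": a})
    covariates = CovariateTable(pd.DataFrame(cov_rows))

    category_map = dict(spec.motu_category)
    return SimulatedDataset(read_counts=read_counts,
                            catalog=_catalog(spec), metadata=metadata,
                            availability=availability, pellets=pellets,
                            covariates=covariates, truth=truth,
                            category_map=category_map, spec=spec)


def spec_from_yaml(path) -> CommunitySpec:
    """Build a spec from a flat YAML document of scalar overrides."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(CommunitySpec)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown spec key(s): {sorted(unknown)}")
    return CommunitySpec(**data)
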