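"""Synthetic weight-loss cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised and validated without access to the (undeposited) real
cohort:

* a 4-component Dirichlet-multinomial community (Bact1 / Bact2 / Rum / Bif
  archetypes) at the species level, with a species -> genus taxonomy;
* covariate-linked enterotype membership (higher BMI raises the log-odds of
  Bact2 membership; younger women are tilted towards Bif), with intercepts
  calibrated so the marginal component prevalences match the configured
  mixture weights;
* clinical covariates drawn from the cohort's published marginal
  distributions (means and SDs), one row per subject x visit;
* paired baseline (V1) / 10%-weight-loss (V2) visits with stratum-specific
  enterotype transition matrices and per-species planted abundance shifts;
* per-read candidate-assignment tables with planted false positives, to
  exercise the two-step taxonomic confirmation filter;
* a species x KO pan-genome presence matrix plus a small module-definition
  fixture.

Every draw flows from the config seed through a single Generator, so a fixed
seed gives bit-identical output. Ground truth (component labels, read-level
false-positive flags, planted coefficients) is returned on a separate truth
channel that analysis stages never see.

The Bact2 archetype's low richness/evenness is planted structurally through
its low Dirichlet concentration (sum of alpha), not by conditioning on
realized richness — expected richness at fixed depth is monotone in the
concentration, which avoids circularity when downstream stages test
richness-linked dysbiosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_rng
from .containers import AbundanceTable, obesity_class

__all__ = [
    "GeneratorConfig",
    "CohortData",
    "default_taxonomy",
    "default_alphas",
    "sample_composition",
    "generate_cohort",
    "generate_read_assignments",
    "generate_pangenome",
    "module_fixture_text",
]

COMPONENTS = ("Bact1", "Bact2", "Rum", "Bif")

# species universe: genus -> member species epithets
_SPECIES = {
    "Bacteroides": ["fragilis", "vulgatus", "dorei", "uniformis", "thetaiotaomicron", "ovatus"],
    "Faecalibacterium": ["prausnitzii", "duncaniae"],
    "Bifidobacterium": ["adolescentis", "bifidum", "longum", "breve"],
    "Prevotella": ["copri", "stercorea"],
    "Akkermansia": ["muciniphila"],
    "Parabacteroides": ["distasonis", "merdae"],
    "Eubacterium": ["rectale", "hallii", "eligens"],
    "Streptococcus": ["thermophilus", "salivarius", "parasanguinis"],
    "Ruminococcus": ["bromii", "torques", "gnavus", "lactaris"],
    "Roseburia": ["intestinalis", "faecis", "hominis"],
    "Alistipes": ["putredinis", "finegoldii", "shahii"],
    "Blautia": ["obeum", "wexlerae", "hansenii"],
    "Dorea": ["formicigenerans", "longicatena"],
    "Coprococcus": ["comes", "eutactus", "catus"],
    "Methanobrevibacter": ["smithii"],
    "Lactobacillus": ["rhamnosus", "gasseri", "reuteri"],
}

# per-archetype genus mass profiles (normalized internally)
_GENUS_PROFILES = {
    "Bact1": {"Bacteroides": 0.42, "Faecalibacterium": 0.09, "Bifidobacterium": 0.03,
              "Alistipes": 0.08, "Parabacteroides": 0.07, "Blautia": 0.06,
              "Eubacterium": 0.06, "Ruminococcus": 0.05, "Roseburia": 0.04,
              "Prevotella": 0.02, "Akkermansia": 0.02, "Streptococcus": 0.02,
              "Dorea": 0.02, "Coprococcus": 0.03, "Methanobrevibacter": 0.005,
              "Lactobacillus": 0.015},
    "Bact2": {"Bacteroides": 0.68, "Faecalibacterium": 0.02, "Bifidobacterium": 0.02,
              "Alistipes": 0.05, "Parabacteroides": 0.08, "Blautia": 0.02,
              "Eubacterium": 0.02, "Ruminococcus": 0.02, "Roseburia": 0.01,
              "Prevotella": 0.01, "Akkermansia": 0.02, "Streptococcus": 0.02,
              "Dorea": 0.01, "Coprococcus": 0.02, "Methanobrevibacter": 0.005,
              "Lactobacillus": 0.015},
    "Rum": {"Bacteroides": 0.10, "Faecalibacterium": 0.30, "Bifidobacterium": 0.04,
            "Alistipes": 0.05, "Parabacteroides": 0.03, "Blautia": 0.08,
            "Eubacterium": 0.09, "Ruminococcus": 0.12, "Roseburia": 0.08,
            "Prevotella": 0.02, "Akkermansia": 0.02, "Streptococcus": 0.02,
            "Dorea": 0.03, "Coprococcus": 0.05, "Methanobrevibacter": 0.01,
            "Lactobacillus": 0.01},
    "Bif": {"Bacteroides": 0.13, "Faecalibacterium": 0.08, "Bifidobacterium": 0.38,
            "Alistipes": 0.04, "Parabacteroides": 0.03, "Blautia": 0.06,
            "Eubacterium": 0.05, "Ruminococcus": 0.05, "Roseburia": 0.04,
            "Prevotella": 0.01, "Akkermansia": 0.02, "Streptococcus": 0.05,
            "Dorea": 0.02, "Coprococcus": 0.02, "Methanobrevibacter": 0.005,
            "Lactobacillus": 0.015},
}

# Dirichlet concentrations (sum of alpha). Bact2 lowest -> lowest expected
# richness/evenness; Rum highest -> highest richness.
_CONCENTRATIONS = {"Bact1": 80.0, "Bact2": 25.0, "Rum": 160.0, "Bif": 100.0}

# default V1 -> V2 enterotype transition matrices (rows = origin, order COMPONENTS).
# LMP consumers leave Bact2 more often, echoing the planted supplement effect.
_T_LMP = np.array([
    [0.80, 0.04, 0.10, 0.06],
    [0.50, 0.34, 0.10, 0.06],
    [0.15, 0.03, 0.76, 0.06],
    [0.18, 0.03, 0.09, 0.70],
])
_T_NOLMP = np.array([
    [0.82, 0.06, 0.07, 0.05],
    [0.30, 0.55, 0.09, 0.06],
    [0.12, 0.04, 0.78, 0.06],
    [0.14, 0.04, 0.08, 0.74],
])

# clinical covariate marginals: mean (SD), cohort baseline
_COVARIATE_MARGINALS = {
    "age": (50.6, 9.9), "weight": (90.5, 16.3), "BMI": (32.8, 4.9),
    "waist": (106.5, 12.4), "fat_mass": (40.7, 4.7), "glycemia": (1.02, 0.22),
    "insulinemia": (14.9, 8.7), "HOMA_IR": (4.1, 3.1), "HbA1c": (5.8, 0.9),
    "total_cholesterol": (5.5, 1.1), "triglycerides": (1.6, 0.9),
    "HDL_cholesterol": (1.4, 0.4), "LDL_cholesterol": (3.4, 1.0),
    "ASAT": (24.0, 10.0), "ALAT": (30.2, 18.3), "GGT": (41.0, 40.9),
    "creatinine": (8.1, 1.5), "uricemia": (52.1, 16.3),
}

# mean V2 - V1 shifts applied to paired clinical rows (weight handled as -10%)
_VISIT_DELTAS = {
    "waist": -10.6, "fat_mass": -3.1, "glycemia": -0.06, "insulinemia": -3.8,
    "HOMA_IR": -1.8, "HbA1c": -0.6, "total_cholesterol": -0.6,
    "triglycerides": -0.5, "LDL_cholesterol": -0.3, "ASAT": -1.9,
    "ALAT": -5.4, "GGT": -16.0, "uricemia": -3.2,
}

# planted per-species V2 log-shifts on the Dirichlet parameters (weight-loss
# response: Akkermansia/Parabacteroides up, E. rectale / S. thermophilus /
# Bifidobacterium lineages down)
_VISIT_SPECIES_LOGSHIFTS = {
    "Akkermansia_muciniphila": 0.5,
    "Parabacteroides_distasonis": 0.4,
    "Methanobrevibacter_smithii": 0.3,
    "Eubacterium_rectale": -0.5,
    "Streptococcus_thermophilus": -0.4,
    "Bifidobacterium_adolescentis": -0.3,
    "Bifidobacterium_bifidum": -0.3,
}


@dataclass
class GeneratorConfig:
    """All planted parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 263 subjects of whom 163 have a
    paired 10%-weight-loss visit, 71.5% in the LMP supplement arm, four
    community archetypes with a 19.4% Bact2 mixture weight, a log(1.08)
    per-BMI-unit Bact2 log-odds link, and Table-1-style covariate marginals.
    """

    n_subjects: int = 263
    fraction_with_v2: float = 163 / 263
    pi: tuple = (0.28, 0.194, 0.33, 0.196)  # Bact1, Bact2, Rum, Bif
    concentrations: dict = field(default_factory=lambda: dict(_CONCENTRATIONS))
    genus_profiles: dict = field(default_factory=lambda: {k: dict(v) for k, v in _GENUS_PROFILES.items()})
    bact2_bmi_logodds: float = math.log(1.08)
    bif_age_logodds: float = -0.05
    bif_female_logodds: float = 0.8
    covariate_marginals: dict = field(default_factory=lambda: dict(_COVARIATE_MARGINALS))
    male_fraction: float = 55 / 263
    sas_fraction: float = 37 / 263
    n_centers: int = 5
    lmp_fraction: float = 188 / 263
    transition_lmp: np.ndarray = field(default_factory=lambda: _T_LMP.copy())
    transition_nolmp: np.ndarray = field(default_factory=lambda: _T_NOLMP.copy())
    visit_species_logshifts: dict = field(default_factory=lambda: dict(_VISIT_SPECIES_LOGSHIFTS))
    visit_clinical_deltas: dict = field(default_factory=lambda: dict(_VISIT_DELTAS))
    v2_lowdiv_concentration_logshift: float = 0.4
    depth_range: tuple = (15_000, 60_000)
    reads_per_sample: int = 20_000
    false_positive_rate: float = 0.10
    human_read_rate: float = 0.02
    identity_true: tuple = (0.92, 0.04)
    identity_false: tuple = (0.60, 0.08)
    aligned_true: tuple = (0.80, 0.10)
    aligned_false: tuple = (0.40, 0.10)
    n_kos: int = 40
    ko_presence_prob: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("mixture weights pi must sum to 1")
        for T in (np.asarray(self.transition_lmp), np.asarray(self.transition_nolmp)):
            if T.shape != (len(COMPONENTS), len(COMPONENTS)):
                raise ValueError("transition matrices must be K x K with K = 4")
            if not np.allclose(T.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must sum to 1")
        if not (0.0 <= self.false_positive_rate <= 1.0):
            raise ValueError("false_positive_rate must be in [0, 1]")


@dataclass
class CohortData:
    """Generator output bundle. ``truth`` is a test-only channel."""

    clinical: pd.DataFrame
    abundance_v1: AbundanceTable
    abundance_v2: AbundanceTable
    truth: dict


def default_taxonomy() -> pd.DataFrame:
    """Species universe as a (species_id, species_name, genus) table."""
    rows = [
        {"species_id": f"{genus}_{sp}", "species_name": f"{genus} {sp}", "genus": genus}
        for genus, species in _SPECIES.items()
        for sp in species
    ]
    return pd.DataFrame(rows)


def default_alphas(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Per-component species-level Dirichlet parameter vectors (K x J).

    Genus mass from the archetype profile is split across member species with
    a fixed geometrically decaying pattern (dominant species first), then
    scaled by the archetype concentration.
    """
    config = config or GeneratorConfig()
    tax = default_taxonomy()
    alphas = {}
    for comp in COMPONENTS:
        profile = config.genus_profiles[comp]
        total = sum(profile.values())
        row = {}
        for genus, species in _SPECIES.items():
            mass = profile.get(genus, 0.0) / total
            weights = np.array([0.5 ** i for i in range(len(species))])
            weights /= weights.sum()
            for sp, w in zip(species, weights):
                row[f"{genus}_{sp}"] = mass * w * config.concentrations[comp]
        alphas[comp] = row
    out = pd.DataFrame(alphas).T.reindex(columns=tax["species_id"])
    return out


def sample_composition(alpha: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet-multinomial draw: counts ~ Multinomial(depth, p), p ~ Dir(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise ValueError("Dirichlet parameters must be strictly positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = rng.dirichlet(alpha)
    return rng.multinomial(int(depth), p)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _membership_logits(config: GeneratorConfig, clinical_v1: pd.DataFrame) -> np.ndarray:
    """Covariate part of the multinomial-logit membership model (Bact1 = reference)."""
    n = len(clinical_v1)
    z = np.zeros((n, len(COMPONENTS)))
    bmi_mean = config.covariate_marginals["BMI"][0]
    age_mean = config.covariate_marginals["age"][0]
    z[:, COMPONENTS.index("Bact2")] = config.bact2_bmi_logodds * (clinical_v1["BMI"].to_numpy() - bmi_mean)
    z[:, COMPONENTS.index("Bif")] = (
        config.bif_age_logodds * (clinical_v1["age"].to_numpy() - age_mean)
        + config.bif_female_logodds * (clinical_v1["sex"].to_numpy() == "F")
    )
    return z


def _calibrate_intercepts(config: GeneratorConfig, z: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Choose component intercepts so the cohort-average membership probabilities
    equal the configured mixture weights despite the covariate links."""
    pi = np.asarray(config.pi, dtype=float)
    c = np.log(pi)
    for _ in range(n_iter):
        marg = _softmax(z + c).mean(axis=0)
        c = c + np.log(pi / marg)
        c -= c[0]
    return c


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    marg = config.covariate_marginals
    rows = {"subject_id": [f"S{i:04d}" for i in range(n)], "visit": ["V1"] * n}
    rows["sex"] = np.where(rng.random(n) < config.male_fraction, "M", "F")
    rows["center"] = [f"C{c}" for c in rng.integers(0, config.n_centers, size=n)]
    for var, (mu, sd) in marg.items():
        rows[var] = rng.normal(mu, sd, size=n)
    df = pd.DataFrame(rows)
    # physical floors; BMI >= 25 per the program's inclusion criterion
    df["age"] = df["age"].clip(18, 65)
    df["BMI"] = df["BMI"].clip(lower=25.0)
    for col in ("weight", "waist", "fat_mass", "glycemia", "insulinemia", "HOMA_IR",
                "HbA1c", "total_cholesterol", "triglycerides", "HDL_cholesterol",
                "LDL_cholesterol", "ASAT", "ALAT", "GGT", "creatinine", "uricemia"):
        df[col] = df[col].clip(lower=0.1)
    df["BSS"] = rng.integers(1, 8, size=n)
    df["SAS"] = rng.random(n) < config.sas_fraction
    df["CPAP"] = df["SAS"] & (rng.random(n) < 0.6)
    df["LMP"] = rng.random(n) < config.lmp_fraction
    df["obesity_class"] = df["BMI"].map(obesity_class)
    return df


def generate_cohort(config: GeneratorConfig | None = None) -> CohortData:
    """Generate the paired synthetic cohort (clinical + V1/V2 abundances + truth)."""
    config = config or GeneratorConfig()
    rng = stage_rng(config.seed, "generator")
    tax = default_taxonomy()
    taxonomy_map = dict(zip(tax["species_id"], tax["genus"]))
    alphas = default_alphas(config)
    species = list(alphas.columns)

    clinical_v1 = _draw_covariates(config, rng)
    z = _membership_logits(config, clinical_v1)
    intercepts = _calibrate_intercepts(config, z)
    probs = _softmax(z + intercepts)
    comp_idx_v1 = np.array([rng.choice(len(COMPONENTS), p=p) for p in probs])
    labels_v1 = np.array(COMPONENTS)[comp_idx_v1]

    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1,
                          size=config.n_subjects)
    counts_v1 = np.vstack([
        sample_composition(alphas.iloc[k].to_numpy(), d, rng)
        for k, d in zip(comp_idx_v1, depths)
    ])
    ids_v1 = [f"{s}_V1" for s in clinical_v1["subject_id"]]
    abundance_v1 = AbundanceTable(
        pd.DataFrame(counts_v1, index=ids_v1, columns=species), taxonomy=taxonomy_map
    )

    # paired V2 visit for the first configured fraction of subjects
    n_v2 = int(round(config.fraction_with_v2 * config.n_subjects))
    v2_subjects = clinical_v1["subject_id"].iloc[:n_v2].tolist()
    shift = np.ones(len(species))
    for sp, logfc in config.visit_species_logshifts.items():
        if sp in species:
            shift[species.index(sp)] = math.exp(logfc)

    rows_v2, counts_v2, ids_v2, labels_v2 = [], [], [], []
    T = {True: np.asarray(config.transition_lmp), False: np.asarray(config.transition_nolmp)}
    for i, subj in enumerate(clinical_v1["subject_id"]):
        if subj not in v2_subjects:
            continue
        lmp = bool(clinical_v1["LMP"].iloc[i])
        k1 = comp_idx_v1[i]
        k2 = rng.choice(len(COMPONENTS), p=T[lmp][k1])
        alpha2 = alphas.iloc[k2].to_numpy() * shift
        if COMPONENTS[k1] == "Bact2":
            # planted diversity improvement for baseline-dysbiotic subjects
            alpha2 = alpha2 * math.exp(config.v2_lowdiv_concentration_logshift)
        d2 = rng.integers(config.depth_range[0], config.depth_range[1] + 1)
        counts_v2.append(sample_composition(alpha2, d2, rng))
        ids_v2.append(f"{subj}_V2")
        labels_v2.append(COMPONENTS[k2])

        row = clinical_v1.iloc[i].copy()
        row["visit"] = "V2"
        w1 = row["weight"]
        row["weight"] = 0.9 * w1 + rng.normal(0, 1.0)
        row["BMI"] = clinical_v1["BMI"].iloc[i] * row["weight"] / w1
        for var, delta in config.visit_clinical_deltas.items():
            row[var] = max(0.1, row[var] + delta + rng.normal(0, abs(delta) / 2 + 0.01))
        row["obesity_class"] = obesity_class(row["BMI"])
        rows_v2.append(row)

    abundance_v2 = AbundanceTable(
        pd.DataFrame(np.vstack(counts_v2) if counts_v2 else np.empty((0, len(species))),
                     index=ids_v2, columns=species, dtype=int),
        taxonomy=taxonomy_map,
    )
    clinical = pd.concat([clinical_v1, pd.DataFrame(rows_v2)], ignore_index=True)

    truth = {
        "component_v1": dict(zip(clinical_v1["subject_id"], labels_v1)),
        "component_v2": dict(zip(v2_subjects, labels_v2)),
        "intercepts": dict(zip(COMPONENTS, intercepts)),
        "concentrations": dict(config.concentrations),
        "planted": {
            "bact2_bmi_logodds": config.bact2_bmi_logodds,
            "bif_age_logodds": config.bif_age_logodds,
            "bif_female_logodds": config.bif_female_logodds,
            "visit_species_logshifts": dict(config.visit_species_logshifts),
        },
    }
    return CohortData(clinical=clinical, abundance_v1=abundance_v1,
                      abundance_v2=abundance_v2, truth=truth)


def generate_read_assignments(
    abundance: AbundanceTable,
    reads_per_sample: int,
    false_positive_rate: float,
    seed: int,
    human_read_rate: float = 0.02,
    identity_true: tuple = (0.92, 0.04),
    identity_false: tuple = (0.60, 0.08),
    aligned_true: tuple = (0.80, 0.10),
    aligned_false: tuple = (0.40, 0.10),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read candidate taxonomic assignments with planted false positives.

    Each read's true taxon is drawn from the sample's composition; with
    probability ``false_positive_rate`` the candidate is swapped for a random
    wrong taxon whose confirmation identity / aligned fraction then come from
    the (low) false-assignment distributions. Returns (reads, truth); truth
    carries the per-read true taxon and false-positive flag and is never
    consumed by the analysis stages.
    """
    if not (0.0 <= false_positive_rate <= 1.0):
        raise ValueError("false_positive_rate must be in [0, 1]")
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    rng = stage_rng(seed, "reads")
    taxa = np.array(abundance.taxon_ids)
    rel = abundance.counts.div(abundance.counts.sum(axis=1), axis=0).to_numpy()
    reads, truths = [], []
    for s_i, sample in enumerate(abundance.sample_ids):
        n_counts = rng.multinomial(reads_per_sample, rel[s_i])
        true_idx = np.repeat(np.arange(len(taxa)), n_counts)
        true_taxon = taxa[true_idx]
        n = len(true_taxon)
        is_false = rng.random(n) < false_positive_rate
        candidate = true_taxon.copy()
        if is_false.any() and len(taxa) > 1:
            wrong_offsets = rng.integers(1, len(taxa), size=int(is_false.sum()))
            candidate[is_false] = taxa[(true_idx[is_false] + wrong_offsets) % len(taxa)]
        ident = np.where(
            is_false,
            rng.normal(*identity_false, size=n),
            rng.normal(*identity_true, size=n),
        ).clip(0, 1)
        alfrac = np.where(
            is_false,
            rng.normal(*aligned_false, size=n),
            rng.normal(*aligned_true, size=n),
        ).clip(0, 1)
        human = rng.random(n) < human_read_rate
        rid = [f"{sample}_r{j}" for j in range(n)]
        reads.append(pd.DataFrame({
            "read_id": rid, "sample_id": sample, "candidate_taxon": candidate,
            "classifier_score": rng.gamma(4.0, 50.0, size=n),
            "confirmed_identity": ident, "aligned_fraction": alfrac,
            "human_flag": human,
        }))
        truths.append(pd.DataFrame({
            "read_id": rid, "true_taxon": true_taxon, "false_positive": is_false,
        }))
    empty = pd.DataFrame(columns=["read_id", "sample_id", "candidate_taxon",
                                  "classifier_score", "confirmed_identity",
                                  "aligned_fraction", "human_flag"])
    reads_df = pd.concat(reads, ignore_index=True) if reads else empty
    truth_df = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return reads_df, truth_df


def generate_pangenome(
    n_species: int | None = None,
    n_kos: int = 40,
    presence_prob: float = 0.30,
    seed: int = 0,
    species_ids: list | None = None,
) -> tuple[pd.DataFrame, str]:
    """Binary species x KO presence matrix plus a module-definition fixture.

    Returns (presence, module_text). The fixture defines at least three
    modules of one to four steps, each step a set of alternative generated
    KO ids, in the plain-text module format the functional stage parses.
    """
    if not (0.0 <= presence_prob <= 1.0):
        raise ValueError("presence_prob must be in [0, 1]")
    if species_ids is None:
        if n_species is None or n_species < 1:
            raise ValueError("n_species must be >= 1 (or pass species_ids)")
        species_ids = [f"sp{i:03d}" for i in range(n_species)]
    if n_kos < 1:
        raise ValueError("n_kos must be >= 1")
    rng = stage_rng(seed, "pangenome")
    kos = [f"K{10000 + i:05d}" for i in range(n_kos)]
    mat = (rng.random((len(species_ids), n_kos)) < presence_prob).astype(int)
    presence = pd.DataFrame(mat, index=species_ids, columns=kos)
    return presence, module_fixture_text(kos)


def module_fixture_text(kos: list) -> str:
    """A small syntactically valid module-definition fixture over the given KOs."""
    k = list(kos)

    def pick(*idx):
        return ",".join(k[i % len(k)] for i in idx)

    blocks = [
        f"MODULE\tMF0001\tsugar degradation\n{pick(0)}\n{pick(1, 2)}\n{pick(3)}",
        f"MODULE\tMF0002\tamino acid degradation\n{pick(4, 5)}\n{pick(6)}",
        f"MODULE\tMF0003\tbutyrate production\n{pick(7)}\n{pick(8)}\n{pick(9, 10)}\n{pick(11)}",
        f"MODULE\tMF0004\tmethanogenesis\n{pick(12, 13, 14)}",
    ]
    return "\n\n".join(blocks) + "\n"
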