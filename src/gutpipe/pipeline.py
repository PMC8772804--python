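"""Orchestration of the baseline and longitudinal analyses.

The baseline run takes species counts and clinical covariates at the first
visit and produces: the rarefied table, alpha diversity, genus-level
Bray-Curtis ordination, DMM enterotypes with semantic labels (including the
Bact2 dysbiosis flag), univariate dbRDA effect sizes, and adjusted
richness/Bact2 association tables with BH q-values.

The longitudinal run adds the paired second visit: baseline-diversity
stratification, richness fold-change comparisons, enterotype transition
tables with chi-square tests, per-feature mixed models, the paired clinical
summary, and the propensity-matched supplement comparison.

Every written artifact embeds the configuration hash and master seed; all
randomness is derived from the master seed per stage, so identical configs
give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import association as assoc
from . import ecology, enterotype, longitudinal as longi, matching, taxprofile
from .config import AnalysisConfig, stage_seed
from .containers import AbundanceTable, validate_clinical
from .io import write_artifact

log = logging.getLogger("gutpipe")

__all__ = ["BaselineReport", "LongitudinalReport",
           "run_baseline_analysis", "run_longitudinal_analysis"]

_ADJUST = ("age", "sex", "center")
_DEFAULT_DBRDA = ("BSS", "weight", "ALAT", "BMI", "age")


@dataclass
class BaselineReport:
    config_hash: str
    seed: int
    rarefied: AbundanceTable
    diversity: pd.DataFrame
    genus_table: AbundanceTable
    best_k: int
    enterotypes: pd.DataFrame           # sample_id, component, label, responsibility
    evidence: pd.DataFrame              # per-K evidence/BIC
    dbrda: pd.DataFrame
    richness_assoc: pd.DataFrame
    bact2_assoc: pd.DataFrame
    tables: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        for name, df in {
            "rarefied_species": self.rarefied.counts,
            "alpha_diversity": self.diversity,
            "enterotype_assignments": self.enterotypes,
            "dmm_evidence": self.evidence,
            "dbrda_effects": self.dbrda,
            "richness_associations": self.richness_assoc,
            "bact2_associations": self.bact2_assoc,
            **self.tables,
        }.items():
            write_artifact(df, f"{outdir}/{name}.csv", self.config_hash, self.seed)


@dataclass
class LongitudinalReport:
    config_hash: str
    seed: int
    strata: pd.Series
    fold_changes: pd.Series
    fold_change_tests: dict
    transitions: dict                  # stratum -> (TransitionTable, stat, p)
    lmm_results: pd.DataFrame
    paired_clinical: pd.DataFrame
    match_result: matching.MatchResult

    def save(self, outdir) -> None:
        write_artifact(self.strata.to_frame(), f"{outdir}/strata.csv",
                       self.config_hash, self.seed)
        write_artifact(self.fold_changes.to_frame(), f"{outdir}/fold_changes.csv",
                       self.config_hash, self.seed)
        trans_rows = []
        for stratum, (table, stat, p) in self.transitions.items():
            for a in table.counts.index:
                for b in table.counts.columns:
                    trans_rows.append({"stratum": stratum, "from": a, "to": b,
                                       "count": int(table.counts.loc[a, b]),
                                       "chi2": stat, "p_value": p})
        write_artifact(pd.DataFrame(trans_rows), f"{outdir}/transitions.csv",
                       self.config_hash, self.seed, index=False)
        write_artifact(self.lmm_results, f"{outdir}/lmm_results.csv",
                       self.config_hash, self.seed)
        write_artifact(self.paired_clinical, f"{outdir}/paired_clinical.csv",
                       self.config_hash, self.seed)
        write_artifact(self.match_result.pairs, f"{outdir}/matched_pairs.csv",
                       self.config_hash, self.seed, index=False)
        write_artifact(self.match_result.balance, f"{outdir}/match_balance.csv",
                       self.config_hash, self.seed)


def _enterotype_stage(genus: AbundanceTable, config: AnalysisConfig):
    best_k, models = enterotype.select_k(
        genus, k_range=config.k_range, seed=stage_seed(config.seed, "enterotype"),
        n_restarts=config.dmm_restarts, tol=config.dmm_tol, max_iter=config.dmm_max_iter,
    )
    model = models[best_k]
    labels = enterotype.label_components(model)
    assignments = enterotype.assign_samples(model, genus)
    assignments["label"] = assignments["component"].map(labels)
    evidence = pd.DataFrame({
        "K": list(models),
        "laplace_evidence": [models[k].laplace_evidence for k in models],
        "bic": [models[k].bic for k in models],
        "log_likelihood": [models[k].log_likelihood for k in models],
    }).set_index("K")
    return best_k, model, labels, assignments, evidence


def run_baseline_analysis(
    config: AnalysisConfig,
    abundance: AbundanceTable,
    clinical: pd.DataFrame,
    dbrda_covariates=_DEFAULT_DBRDA,
) -> BaselineReport:
    """Run the full baseline (V1) analysis. See the module docstring."""
    if abundance.counts.empty:
        raise ValueError("empty abundance table")
    clinical = validate_clinical(clinical)
    cl_v1 = clinical[clinical["visit"] == "V1"].set_index("subject_id")
    if len(abundance.counts) < max(config.k_range):
        raise ValueError(
            f"{len(abundance.counts)} samples cannot support K up to {max(config.k_range)}")

    rarefied = taxprofile.rarefy(abundance, config.rarefaction_depth,
                                 seed=stage_seed(config.seed, "rarefaction"))
    diversity = ecology.alpha_diversity(rarefied)
    genus = taxprofile.collapse_rank(rarefied, "genus")
    dm = ecology.bray_curtis(genus)

    best_k, model, labels, assignments, evidence = _enterotype_stage(genus, config)

    # clinical rows aligned to the rarefied sample universe
    sample_subject = {s: s.rsplit("_", 1)[0] for s in rarefied.sample_ids}
    aligned = cl_v1.reindex([sample_subject[s] for s in rarefied.sample_ids])
    aligned.index = rarefied.sample_ids

    dbrda_rows = []
    ordination = ecology.pcoa(dm)
    for i, cov in enumerate(c for c in dbrda_covariates if c in aligned.columns):
        series = aligned[cov]
        if series.isna().any():
            log.info("dbRDA: skipping %s (missing values)", cov)
            continue
        eff = ecology.dbrda_univariate(
            dm, series, n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "dbrda") + i, ordination=ordination,
        )
        dbrda_rows.append({"covariate": eff.covariate, "r2": eff.r2,
                           "adj_r2": eff.adj_r2, "p_value": eff.p_value})
    dbrda = pd.DataFrame(dbrda_rows)

    analysis = aligned.copy()
    analysis["richness"] = diversity["richness"]
    analysis["bact2"] = (assignments["label"] == "Bact2").astype(float)
    covs = [c for c in ("BMI", "weight", "waist", "BSS", "ALAT", "uricemia")
            if c in analysis.columns]
    rich_rows, bact_rows = [], []
    for cov in covs:
        r = assoc.linear_assoc(analysis, "richness", cov, adjust=_ADJUST, standardize=True)
        rich_rows.append(vars(r))
        if analysis["bact2"].nunique() == 2:
            b = assoc.logistic_assoc(analysis, "bact2", cov, adjust=_ADJUST)
            bact_rows.append(vars(b))
    richness_assoc = pd.DataFrame(rich_rows)
    bact2_assoc = pd.DataFrame(bact_rows)
    for df in (richness_assoc, bact2_assoc):
        if len(df):
            df["q_value"] = assoc.bh_adjust(df["p_value"].to_numpy())

    return BaselineReport(
        config_hash=config.config_hash(), seed=config.seed,
        rarefied=rarefied, diversity=diversity, genus_table=genus,
        best_k=best_k, enterotypes=assignments, evidence=evidence,
        dbrda=dbrda, richness_assoc=richness_assoc, bact2_assoc=bact2_assoc,
    )


def run_longitudinal_analysis(
    config: AnalysisConfig,
    abundance_v1: AbundanceTable,
    abundance_v2: AbundanceTable,
    clinical: pd.DataFrame,
) -> LongitudinalReport:
    """Run the paired-visit analysis. See the module docstring."""
    clinical = validate_clinical(clinical)
    subjects_v1 = {s.rsplit("_", 1)[0] for s in abundance_v1.sample_ids}
    subjects_v2 = {s.rsplit("_", 1)[0] for s in abundance_v2.sample_ids}
    paired = sorted(subjects_v1 & subjects_v2)
    if len(paired) < 2:
        raise ValueError("need paired V1/V2 samples for at least 2 subjects")

    seed_r = stage_seed(config.seed, "rarefaction")
    rar_v1 = taxprofile.rarefy(abundance_v1, config.rarefaction_depth, seed=seed_r)
    rar_v2 = taxprofile.rarefy(abundance_v2, config.rarefaction_depth, seed=seed_r + 1)
    div_v1 = ecology.alpha_diversity(rar_v1)
    div_v2 = ecology.alpha_diversity(rar_v2)

    rich_v1 = div_v1["richness"].copy()
    rich_v1.index = [s.rsplit("_", 1)[0] for s in rich_v1.index]
    rich_v2 = div_v2["richness"].copy()
    rich_v2.index = [s.rsplit("_", 1)[0] for s in rich_v2.index]
    paired = sorted(set(paired) & set(rich_v1.index) & set(rich_v2.index))

    # median split on the full baseline cohort, applied to the paired subset
    strata_all = longi.stratify_by_median(rich_v1)
    strata = strata_all.loc[paired]
    fc, fc_tests = longi.compare_fold_changes(rich_v1.loc[paired], rich_v2.loc[paired], strata)

    genus_v1 = taxprofile.collapse_rank(rar_v1, "genus")
    genus_v2 = taxprofile.collapse_rank(rar_v2, "genus")
    best_k, model, labels, assign_v1, _ = _enterotype_stage(genus_v1, config)
    genus_v2_aligned = AbundanceTable(
        genus_v2.counts.reindex(columns=genus_v1.taxon_ids, fill_value=0),
        rarefaction_depth=None if set(genus_v2.taxon_ids) != set(genus_v1.taxon_ids)
        else genus_v2.rarefaction_depth,
    )
    assign_v2 = enterotype.assign_samples(model, genus_v2_aligned)
    lab_v1 = assign_v1["component"].map(labels)
    lab_v1.index = [s.rsplit("_", 1)[0] for s in lab_v1.index]
    lab_v2 = assign_v2["component"].map(labels)
    lab_v2.index = [s.rsplit("_", 1)[0] for s in lab_v2.index]

    transitions = {}
    for stratum in ("low", "high"):
        subj = [s for s in paired if strata.get(s) == stratum]
        if len(subj) >= 2:
            transitions[stratum] = longi.transition_test(
                lab_v1.loc[subj], lab_v2.loc[subj], stratum=stratum)

    # per-feature mixed models on filtered relative abundances
    rel_v1 = rar_v1.subset_samples([f"{s}_V1" for s in paired]).to_relative()
    rel_v2 = rar_v2.subset_samples([f"{s}_V2" for s in paired]).to_relative()
    filt = taxprofile.filter_features(
        AbundanceTable(pd.concat([rel_v1.counts, rel_v2.counts]), relative=True),
        config.feature_min_abundance, config.feature_min_prevalence)
    cl_v1 = clinical[clinical["visit"] == "V1"].set_index("subject_id")
    lmp = cl_v1["LMP"].reindex(paired) if "LMP" in cl_v1.columns else None
    lmm_rows = []
    stacked = filt.counts
    subj_of = [s.rsplit("_", 1)[0] for s in stacked.index]
    visit_of = [s.rsplit("_", 1)[1] for s in stacked.index]
    lmp_of = [bool(lmp.get(s)) for s in subj_of] if lmp is not None else None
    for feat in stacked.columns:
        res = longi.lmm_feature(stacked[feat].to_numpy(), visit_of, subj_of,
                                lmp=lmp_of, feature=feat)
        lmm_rows.append(vars(res))
    lmm_results = pd.DataFrame(lmm_rows).set_index("feature")
    ok = lmm_results["p_value"].notna()
    lmm_results.loc[ok, "q_value"] = assoc.bh_adjust(lmm_results.loc[ok, "p_value"].to_numpy())

    paired_clin = longi.paired_clinical(
        clinical[clinical["subject_id"].isin(paired)])

    match = matching.propensity_match(
        cl_v1.loc[cl_v1.index.isin(paired)].reset_index(), treatment="LMP",
        covariates=("age", "sex", "weight"))

    return LongitudinalReport(
        config_hash=config.config_hash(), seed=config.seed,
        strata=strata, fold_changes=fc, fold_change_tests=fc_tests,
        transitions=transitions, lmm_results=lmm_results,
        paired_clinical=paired_clin, match_result=match,
    )
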