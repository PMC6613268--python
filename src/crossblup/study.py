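"""Replicate driver: run the full scenario grid over sampled crossbred
subsets.

A *study* is: one (simulated or loaded) dataset; per trait, a sire-model fit
on all crossbred records giving corrected phenotypes; then ``n_replicates``
independently sampled family-matched crossbred subsets, each with its own
five-group cross-validation partition of the sires, on which every requested
scenario is run for every trait.  The same subset and partition are shared
by all scenarios and traits of a replicate, so scenario contrasts are
paired.

Variance components for the prediction models are estimated once per trait
x scenario by EM-REML on the first replicate's full reference data and
reused across replicates and folds (the conventional budget-conscious
choice); pass ``components`` to override.

Seeding: replicate ``r`` uses seed ``base_seed + r`` for its subset and
partition draws, so any single replicate can be reproduced in isolation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .blup import SireModel, VarianceComponents, build_design, reml_estimate, solve_mme
from .grm import single_breed_grm
from .io import Dataset
from .qc import QCThresholds, apply_qc
from .scenarios import (
    SCENARIOS,
    StudyData,
    _build_scenario_grm,
    evaluate_units,
    families_from_records,
    make_cv_groups,
    run_scenario,
    sample_matched_cb_subset,
)
from .simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["prepare_study_data", "run_replicates", "run_study"]

RESULT_COLUMNS = [
    "replicate", "scenario", "trait",
    "validation_correlation", "regression_coefficient", "n_units",
]


def _estimate_h2_cb(cb_records: pd.DataFrame, dataset: Dataset, policy, sire_components):
    """Crossbred heritability used in the reliability weights."""
    if isinstance(policy, (int, float)):
        return float(policy)
    if policy == "sire":
        c = sire_components
        return 4.0 * c.sigma2_s / (c.sigma2_s + c.sigma2_m + c.sigma2_e)
    if policy == "animal":
        ids = cb_records["animal_id"].tolist()
        geno = dataset.geno(ids)
        g = single_breed_grm(geno, geno.mean(axis=0) / 2.0, ids)
        design = build_design(cb_records, grm_ids=g.ids, model="animal")
        vc = reml_estimate(design, g, max_iter=300, tol=1e-6)
        return vc.h2
    raise ValueError(f"unknown h2 policy {policy!r}")


def prepare_study_data(
    dataset: Dataset,
    trait: str,
    h2_policy="animal",
    sire_components: VarianceComponents | None = None,
) -> StudyData:
    """Fit the sire model on all crossbred records of a trait and package
    the static inputs every replicate shares."""
    phen = dataset.phenotypes[dataset.phenotypes["trait"] == trait].reset_index(drop=True)
    cb = phen[phen["genetic_group"] == "CB"].reset_index(drop=True)
    if cb.empty:
        raise ValueError(f"no crossbred records for trait {trait!r}")
    model = SireModel(cb, dataset.pedigree)
    res = model.fit(components=sire_components)
    corrected = res.corrected_phenotypes()
    h2_cb = _estimate_h2_cb(cb, dataset, h2_policy, res.components)
    logger.info("trait %s: h2_cb=%.3f, sigma2_s=%.4f", trait, h2_cb, res.components.sigma2_s)
    return StudyData(trait, dataset, phen, corrected, h2_cb)


def _reference_components(spec, data: StudyData, cb_subset) -> VarianceComponents:
    """EM-REML on one scenario's full reference data (first replicate)."""
    if spec.reference_type == "PB":
        ref = data.pb_offspring
        pb_ids, cb_ids = ref, []
    else:
        ref = [a for a in cb_subset if a in set(data.cb_offspring)]
        pb_ids, cb_ids = [], ref
    if spec.grm_kind in ("multibreed",):  # one-group reference: reduces to single
        kind = SCENARIOS["CB-I"] if cb_ids else SCENARIOS["PB-A"]
    else:
        kind = spec
    grm = _build_scenario_grm(kind, data, pb_ids, cb_ids)
    records = data.phenotypes[data.phenotypes["animal_id"].isin(ref)]
    design = build_design(records, grm_ids=grm.ids, model="animal")
    vc = reml_estimate(design, grm, max_iter=300, tol=1e-6)
    vc.sigma2_a = max(vc.sigma2_a, 1e-6)
    return vc


def run_replicates(
    dataset: Dataset,
    scenarios,
    n_replicates: int,
    base_seed: int,
    traits=None,
    h2_policy="animal",
    components: dict | None = None,
    check_leakage: bool = True,
) -> pd.DataFrame:
    """Run the scenario grid on a prepared dataset.

    Returns the replicate-level results table (one row per replicate x
    scenario x trait).  ``components`` may pre-specify variance components
    per (trait, scenario-name); anything missing is REML-estimated on the
    first replicate's reference data.
    """
    trait_names = list(traits) if traits is not None else sorted(
        dataset.phenotypes["trait"].unique()
    )
    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}")

    data_by_trait = {t: prepare_study_data(dataset, t, h2_policy) for t in trait_names}
    first = data_by_trait[trait_names[0]]
    ped = dataset.pedigree
    pb_fams = families_from_records(
        first.phenotypes[first.phenotypes["genetic_group"] == "PB"], ped
    )
    cb_fams = families_from_records(
        first.phenotypes[first.phenotypes["genetic_group"] == "CB"], ped
    )
    sires_with_cb = first.sires_with_cb

    vc_cache: dict = dict(components or {})
    rows = []
    for r in range(n_replicates):
        seed_r = base_seed + r
        subset, _ = sample_matched_cb_subset(pb_fams, cb_fams, seed=seed_r)
        partition = make_cv_groups(sires_with_cb, n_groups=5, seed=seed_r)
        for t in trait_names:
            data = data_by_trait[t]
            for name in scenarios:
                spec = SCENARIOS[name]
                key = (t, name)
                if key not in vc_cache:
                    vc_cache[key] = _reference_components(spec, data, subset)
                    logger.info(
                        "components %s/%s: sigma2_a=%.4f sigma2_m=%.4f sigma2_e=%.4f",
                        t, name, vc_cache[key].sigma2_a,
                        vc_cache[key].sigma2_m, vc_cache[key].sigma2_e,
                    )
                units = run_scenario(
                    spec, data, subset, partition, vc_cache[key],
                    check_leakage=check_leakage,
                )
                corr, bias = evaluate_units(units, spec.validation_record)
                rows.append((r, name, t, corr, bias, len(units)))
        logger.info("replicate %d/%d done", r + 1, n_replicates)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_study(
    sim_config: SimConfig,
    scenarios,
    n_replicates: int,
    base_seed: int | None = None,
    run_qc: bool = True,
    qc_thresholds: QCThresholds = QCThresholds(),
    **kwargs,
):
    """Simulate a study population, clean it, and run the scenario grid.

    Returns ``(results, dataset)``.
    """
    seed = sim_config.seed if base_seed is None else base_seed
    population, phenotypes = simulate_study(sim_config, seed)
    dataset = Dataset.from_population(population, phenotypes)
    if run_qc:
        dataset, _ = apply_qc(dataset, qc_thresholds)
    results = run_replicates(dataset, scenarios, n_replicates, seed, **kwargs)
    return results, dataset
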