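"""Shared fixtures.

The expensive simulation-based fixtures are session-scoped so that the
parameter-recovery and scenario-contrast checks (which several tests share)
are computed once per run.
"""

import warnings

import numpy as np
import pytest

import crossblup as cb
from crossblup.blup import build_design, reml_estimate
from crossblup.grm import single_breed_grm

# a desk-scale study population: one early-weight-like trait with
# purebred-crossbred genetic correlation 0.8
STUDY_TRAIT = cb.TraitSpec("BW7", h2_pb=0.09, h2_cb=0.18, r_pc=0.80, day=7, dropout=0.0)

STUDY_CONFIG = cb.SimConfig(
    n_markers=900,
    n_qtl=250,
    n_sires=36,
    n_sires_both=30,
    n_sires_pb_only=2,
    n_sires_cb_only=4,
    n_pb_dams=120,
    n_cb_dams=260,
    n_dam_line_founders=80,
    n_pb_offspring=700,
    n_cb_offspring=1300,
    traits=(STUDY_TRAIT,),
    seed=20240,
)

SMALL_CONFIG = cb.SimConfig(
    n_markers=300,
    n_qtl=100,
    n_sires=20,
    n_sires_both=16,
    n_sires_pb_only=1,
    n_sires_cb_only=3,
    n_pb_dams=50,
    n_cb_dams=70,
    n_dam_line_founders=30,
    n_pb_offspring=250,
    n_cb_offspring=450,
    traits=(STUDY_TRAIT,),
    seed=11,
)


@pytest.fixture(scope="session")
def small_population():
    pop, phen = cb.simulate_study(SMALL_CONFIG)
    return pop, phen


@pytest.fixture(scope="session")
def small_dataset(small_population):
    pop, phen = small_population
    return cb.Dataset.from_population(pop, phen)


@pytest.fixture(scope="session")
def study_results():
    """30 replicates of the individual-record scenarios (full G vs
    sire-line breed-of-origin G) on one simulated study population."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        results, dataset = cb.run_study(
            STUDY_CONFIG,
            ["CB-I", "CB-I-BOA"],
            n_replicates=30,
            base_seed=77,
            h2_policy="animal",
        )
    return results, dataset


@pytest.fixture(scope="session")
def h2_recovery_estimates():
    """Animal-model EM-REML heritability estimates on crossbred records of
    20 independently simulated populations (true crossbred h2 = 0.23)."""
    estimates = []
    for s in range(20):
        cfg = cb.SimConfig(
            n_markers=1200, n_qtl=300,
            n_sires=30, n_sires_both=26, n_sires_pb_only=2, n_sires_cb_only=2,
            n_pb_dams=80, n_cb_dams=220, n_dam_line_founders=60,
            n_pb_offspring=200, n_cb_offspring=1000,
            traits=(cb.TraitSpec("BW35", 0.22, 0.23, 0.96, day=35, dropout=0.0),),
            seed=100 + s,
        )
        pop, phen = cb.simulate_study(cfg)
        ds = cb.Dataset.from_population(pop, phen)
        rec = ds.phenotypes[
            (ds.phenotypes["trait"] == "BW35") & (ds.phenotypes["genetic_group"] == "CB")
        ].reset_index(drop=True)
        ids = rec["animal_id"].tolist()
        geno = ds.geno(ids)
        g = single_breed_grm(geno, geno.mean(axis=0) / 2.0, ids)
        design = build_design(rec, grm_ids=g.ids, model="animal")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            vc = reml_estimate(design, g, max_iter=120, tol=1e-6)
        estimates.append(vc.h2)
    return np.array(estimates)


def realized_sire_correlation(r_pc: float, seed: int) -> float:
    """Realised correlation between purebred and crossbred true breeding
    values over the sires of one simulated population."""
    cfg = cb.SimConfig(
        n_markers=1000, n_qtl=500,
        n_sires=160, n_sires_both=150, n_sires_pb_only=5, n_sires_cb_only=5,
        n_pb_dams=40, n_cb_dams=40, n_dam_line_founders=30,
        n_pb_offspring=80, n_cb_offspring=80,
        traits=(cb.TraitSpec("T", 0.2, 0.2, r_pc, day=7, dropout=0.0),),
        seed=seed,
    )
    pop, _ = cb.simulate_study(cfg)
    sires = [a for a in pop.ids if a.startswith("S")]
    rows = pop.rows(sires)
    return float(np.corrcoef(pop.true_bv_pb["T"][rows], pop.true_bv_cb["T"][rows])[0, 1])


@pytest.fixture(scope="session")
def rpc_recovery():
    """Mean realised sire-level correlation for configured r_pc 0.80 / 0.96
    over 30 seeds each."""
    out = {}
    for r_pc in (0.80, 0.96):
        vals = [realized_sire_correlation(r_pc, 3000 + s) for s in range(30)]
        out[r_pc] = float(np.mean(vals))
    return out
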