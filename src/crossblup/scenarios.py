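"""Experimental design: matched crossbred sampling, cross-validation and
validation statistics.

The evaluation compares six scenarios differing in reference population
(purebred vs crossbred offspring), validation record (sire-level crossbred
offspring averages vs individual crossbred records) and relationship matrix
(multi-breed/single-breed G vs the breed-of-origin partial G), plus a
diagnostic scenario that predicts sires from dam-origin alleles only.

To give the purebred and crossbred reference populations a comparable family
structure, each replicate selects a crossbred subset family-matched to the
purebred full-sib family-size distribution: for every size s, as many
crossbred full-sib families as there are purebred families of that size (all
of them when fewer are available).  Validation uses five cross-validation
groups of sires such that validation animals have no offspring and no
paternal half-sibs in the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grm as grm_mod
from .blup import VarianceComponents, build_design, solve_mme

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "FamilySizeTable",
    "BROILER_FAMILY_COUNTS",
    "families_from_counts",
    "families_from_records",
    "sample_matched_cb_subset",
    "expected_overlap",
    "measure_overlap",
    "CVPartition",
    "make_cv_groups",
    "StudyData",
    "run_scenario",
    "reliability_weight",
    "weighted_correlation",
    "weighted_regression_bias",
    "scale_validation_correlation",
    "summarize_replicates",
    "win_fraction",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One reference/validation/GRM combination."""

    name: str
    reference_type: str  # "PB" | "CB"
    validation_record: str  # "offspring_average" | "individual"
    grm_kind: str  # "single" | "multibreed" | "boa_sire" | "boa_dam"


#: the scenario grid: -A validates sire GEBV on crossbred offspring
#: averages, -I validates crossbred GEBV on individual corrected records;
#: the BOA variants restrict crossbred relationships to sire-line alleles
#: and the DAM probe to dam-line alleles.
SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in [
        ScenarioSpec("PB-A", "PB", "offspring_average", "single"),
        ScenarioSpec("CB-A", "CB", "offspring_average", "multibreed"),
        ScenarioSpec("CB-A-BOA", "CB", "offspring_average", "boa_sire"),
        ScenarioSpec("PB-I", "PB", "individual", "multibreed"),
        ScenarioSpec("CB-I", "CB", "individual", "single"),
        ScenarioSpec("CB-I-BOA", "CB", "individual", "boa_sire"),
        ScenarioSpec("CB-A-DAM", "CB", "offspring_average", "boa_dam"),
    ]
}


# ---------------------------------------------------------------------------
# family-matched crossbred subsampling
# ---------------------------------------------------------------------------

#: Full-sib family-size distribution of the motivating broiler study
#: population (early body weight): number of purebred families and available
#: crossbred families per size.  Used as the printed-design input for
#: matched-sampling arithmetic.
BROILER_FAMILY_COUNTS = pd.DataFrame(
    {
        "family_size": range(1, 12),
        "n_pb_families": [1699, 653, 276, 117, 46, 13, 6, 2, 1, 0, 1],
        "n_cb_available": [4406, 1610, 607, 177, 60, 14, 3, 2, 1, 0, 0],
    }
)


@dataclass
class FamilySizeTable:
    """Per family size: purebred families, available and selected crossbred
    families."""

    table: pd.DataFrame  # family_size, n_pb_families, n_cb_available, n_selected

    @property
    def n_selected_animals(self) -> int:
        t = self.table
        return int((t["family_size"] * t["n_selected"]).sum())


def families_from_counts(counts: dict[int, int], prefix: str = "F") -> list[list[str]]:
    """Instantiate synthetic families (member-id lists) from size counts."""
    fams = []
    k = 0
    for size, n in sorted(counts.items()):
        for _ in range(n):
            k += 1
            fams.append([f"{prefix}{k}_{i}" for i in range(size)])
    return fams


def families_from_records(records: pd.DataFrame, pedigree: pd.DataFrame) -> list[list[str]]:
    """Full-sib families (same sire and same dam) among recorded animals."""
    sire_of = dict(zip(pedigree["animal_id"], pedigree["sire_id"]))
    df = records[["animal_id", "dam_id"]].drop_duplicates("animal_id").copy()
    df["sire_id"] = df["animal_id"].map(sire_of)
    return [g["animal_id"].tolist() for _, g in df.groupby(["sire_id", "dam_id"], sort=True)]


def sample_matched_cb_subset(pb_families, cb_families, seed=None):
    """Select crossbred families matching the purebred family-size profile.

    Parameters
    ----------
    pb_families
        list of purebred family member-lists, or a mapping size -> count.
    cb_families
        list of crossbred family member-lists.
    Returns
    -------
    (selected_animal_ids, FamilySizeTable)
    """
    rng = np.random.default_rng(seed)
    if isinstance(pb_families, dict):
        pb_counts = dict(pb_families)
    else:
        pb_counts = {}
        for fam in pb_families:
            pb_counts[len(fam)] = pb_counts.get(len(fam), 0) + 1
    by_size: dict[int, list] = {}
    for fam in cb_families:
        by_size.setdefault(len(fam), []).append(fam)

    rows = []
    selected: list = []
    for size in sorted(set(pb_counts) | set(by_size)):
        if size == 0:
            continue
        n_pb = pb_counts.get(size, 0)
        avail = by_size.get(size, [])
        n_sel = min(n_pb, len(avail))
        if n_sel > 0:
            idx = rng.choice(len(avail), size=n_sel, replace=False)
            for i in idx:
                selected.extend(avail[i])
        rows.append((size, n_pb, len(avail), n_sel))
    table = pd.DataFrame(rows, columns=["family_size", "n_pb_families", "n_cb_available", "n_selected"])
    return selected, FamilySizeTable(table)


def expected_overlap(n_selected: int, n_available: int) -> float:
    """Hypergeometric expectation of the fraction two independent selections
    of ``n_selected`` of ``n_available`` units have in common."""
    if n_selected == 0:
        return 0.0
    return n_selected / n_available


def measure_overlap(set_a, set_b) -> float:
    """|A intersect B| / |A| for equal-sized selections."""
    a, b = set(set_a), set(set_b)
    if not a:
        return 0.0
    return len(a & b) / len(a)


# ---------------------------------------------------------------------------
# cross-validation groups
# ---------------------------------------------------------------------------

@dataclass
class CVPartition:
    """A random near-even partition of sires into cross-validation groups."""

    groups: list[list[str]]

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    def all_sires(self) -> set:
        return {s for g in self.groups for s in g}


def make_cv_groups(sire_ids, n_groups: int = 5, seed=None) -> CVPartition:
    """Randomly partition sires into ``n_groups`` groups whose sizes differ
    by at most one.  All offspring later follow their sire's group, which
    enforces the no-offspring / no-paternal-half-sib validation constraint
    by construction."""
    sires = list(sire_ids)
    if len(sires) < n_groups:
        raise ValueError(f"cannot split {len(sires)} sires into {n_groups} groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sires))
    base, rem = divmod(len(sires), n_groups)
    groups = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        groups.append([sires[i] for i in perm[start: start + size]])
        start += size
    return CVPartition(groups)


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def reliability_weight(n: int, h2_cb: float) -> float:
    """Reliability of a crossbred offspring-average record of ``n`` offspring:
    (n h2/4) / (1 + (n-1) h2/4)."""
    if n < 1:
        raise ValueError("offspring count must be >= 1")
    return (0.25 * n * h2_cb) / (1.0 + 0.25 * (n - 1) * h2_cb)


def weighted_correlation(x, y, w) -> float:
    """Weighted Pearson correlation: weighted means and central second
    moments, all normalised by the weight sum."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    sw = w.sum()
    dx = x - (w @ x) / sw
    dy = y - (w @ y) / sw
    cov = (w * dx) @ dy / sw
    vx = (w * dx) @ dx / sw
    vy = (w * dy) @ dy / sw
    return float(cov / np.sqrt(vx * vy))


def weighted_regression_bias(gebv, records, w=None, multiplier: float = 1.0) -> float:
    """Weighted least-squares slope of validation records on GEBV, times the
    multiplier (2 for offspring averages, which carry half the sire's
    breeding value).  1 indicates no dispersion bias; < 1 over-dispersion."""
    gebv = np.asarray(gebv, float)
    records = np.asarray(records, float)
    w = np.ones_like(gebv) if w is None else np.asarray(w, float)
    sw = w.sum()
    dx = gebv - (w @ gebv) / sw
    dy = records - (w @ records) / sw
    slope = ((w * dx) @ dy) / ((w * dx) @ dx)
    return float(slope * multiplier)


def scale_validation_correlation(corr: float, mode: str, scale_value: float) -> float:
    """Put validation correlations on an accuracy-like common scale:
    individual-record correlations are divided by sqrt(h2_cb); offspring-
    average correlations by sqrt(mean validation-sire reliability)."""
    if mode not in {"individual", "offspring_average"}:
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < scale_value <= 1:
        raise ValueError("scale value must be in (0, 1]")
    return corr / np.sqrt(scale_value)


def summarize_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of validation correlation and bias per scenario x trait."""
    g = results.groupby(["scenario", "trait"])
    out = g.agg(
        mean_correlation=("validation_correlation", "mean"),
        sd_correlation=("validation_correlation", lambda v: v.std(ddof=1)),
        mean_bias=("regression_coefficient", "mean"),
        sd_bias=("regression_coefficient", lambda v: v.std(ddof=1)),
        n_replicates=("replicate", "nunique"),
    ).reset_index()
    return out


def win_fraction(results: pd.DataFrame, scenario_x: str, scenario_y: str, trait: str | None = None) -> float:
    """Fraction of replicates in which scenario X's validation correlation
    exceeds scenario Y's (paired by replicate; ties count 0.5)."""
    df = results if trait is None else results[results["trait"] == trait]
    x = df[df["scenario"] == scenario_x].set_index("replicate")["validation_correlation"]
    y = df[df["scenario"] == scenario_y].set_index("replicate")["validation_correlation"]
    common = x.index.intersection(y.index)
    if len(common) == 0:
        raise ValueError("no paired replicates between scenarios")
    diff = x.loc[common] - y.loc[common]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / len(common))


# ---------------------------------------------------------------------------
# running one scenario of one replicate
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Static per-trait inputs shared by all replicates and scenarios.

    ``corrected`` must cover *all* crossbred records of the trait (the sire
    model is fitted once per trait, not per replicate).
    """

    trait: str
    dataset: object  # crossblup.io.Dataset after QC
    phenotypes: pd.DataFrame  # this trait's records, PB + CB
    corrected: pd.DataFrame  # animal_id, sire_id, y_corrected for all CB
    h2_cb: float

    def __post_init__(self) -> None:
        ped = self.dataset.pedigree
        self.sire_of = dict(zip(ped["animal_id"], ped["sire_id"]))
        self._yc = dict(zip(self.corrected["animal_id"], self.corrected["y_corrected"]))
        grp = dict(zip(ped["animal_id"], ped["genetic_group"]))
        rec = self.phenotypes["animal_id"]
        self.pb_offspring = [a for a in rec if grp.get(a) == "PB"]
        self.cb_offspring = [a for a in rec if grp.get(a) == "CB"]
        self.sires_with_cb = sorted({self.sire_of[a] for a in self.cb_offspring})

    def y_corrected(self, animal_ids) -> np.ndarray:
        return np.array([self._yc[a] for a in animal_ids])


class LeakageError(AssertionError):
    """Reference/validation separation constraint violated."""


def _build_scenario_grm(spec: ScenarioSpec, data: StudyData, pb_ids, cb_ids) -> grm_mod.GRMatrix:
    ds = data.dataset
    geno_pb = ds.geno(pb_ids) if len(pb_ids) else np.empty((0, len(ds.marker_ids)))
    geno_cb = ds.geno(cb_ids) if len(cb_ids) else np.empty((0, len(ds.marker_ids)))
    if spec.grm_kind == "single":
        geno = np.vstack([geno_pb, geno_cb])
        p = geno.mean(axis=0) / 2.0
        return grm_mod.single_breed_grm(geno, p, list(pb_ids) + list(cb_ids))
    if spec.grm_kind == "multibreed":
        freqs = grm_mod.compute_allele_frequencies(genotypes_pb=geno_pb, genotypes_cb=geno_cb)
        return grm_mod.multibreed_grm(geno_pb, geno_cb, freqs, pb_ids, cb_ids)
    if spec.grm_kind == "boa_sire":
        boa = ds.boa_codes(cb_ids)
        freqs = grm_mod.compute_allele_frequencies(
            sire_genotypes=geno_pb, boa_sire_dosage=boa
        )
        return grm_mod.sire_partial_grm(geno_pb, boa, freqs.p_sireline, pb_ids, cb_ids)
    if spec.grm_kind == "boa_dam":
        boa = ds.boa_codes(cb_ids)
        # partition: total dosage = sire-origin + dam-origin allele
        dam_dos = np.where(
            boa == grm_mod.UNASSIGNED_BOA, grm_mod.UNASSIGNED_BOA, ds.geno(cb_ids) - boa
        ).astype(np.int8)
        freqs = grm_mod.compute_allele_frequencies(boa_dam_dosage=dam_dos)
        return grm_mod.dam_partial_grm(geno_pb, dam_dos, freqs.p_damline, pb_ids, cb_ids)
    raise ValueError(f"unknown GRM kind {spec.grm_kind!r}")


def run_scenario(
    spec: ScenarioSpec,
    data: StudyData,
    cb_subset,
    partition: CVPartition,
    components: VarianceComponents,
    check_leakage: bool = True,
) -> pd.DataFrame:
    """Run all cross-validation folds of one scenario for one replicate.

    For each fold the model is fitted on the fold's reference records with
    the scenario's relationship matrix (allele frequencies computed on the
    fold's analysis set, reference plus candidates); GEBV of the fold's
    validation units are collected, then pooled over folds.  Returns one row
    per validation unit: unit id, GEBV, validation record, weight, fold.

    Purebred offspring of sires outside the partition (sires without
    crossbred offspring) are part of every purebred reference set.
    """
    cb_subset = [a for a in cb_subset if a in set(data.cb_offspring)]
    subset_set = set(cb_subset)
    partition_sires = partition.all_sires()
    rows = []
    for fold, val_sires in enumerate(partition.groups):
        val_set = set(val_sires)
        if spec.reference_type == "PB":
            ref_ids = [a for a in data.pb_offspring if data.sire_of[a] not in val_set]
        else:
            ref_ids = [a for a in cb_subset if data.sire_of[a] not in val_set]
        if check_leakage:
            bad = [a for a in ref_ids if data.sire_of[a] in val_set]
            if bad:
                raise LeakageError(f"reference contains offspring of validation sires: {bad[:3]}")

        if spec.validation_record == "offspring_average":
            cand_sires = [
                s for s in val_sires
                if any(data.sire_of[a] == s for a in subset_set)
            ]
            candidates = cand_sires
        else:
            candidates = [a for a in cb_subset if data.sire_of[a] in val_set]
        if not candidates:
            continue

        ref_is_pb = spec.reference_type == "PB"
        cand_is_pb = spec.validation_record == "offspring_average"
        pb_ids = (ref_ids if ref_is_pb else []) + (candidates if cand_is_pb else [])
        cb_ids = (ref_ids if not ref_is_pb else []) + (candidates if not cand_is_pb else [])
        grm = _build_scenario_grm(spec, data, pb_ids, cb_ids)

        ref_records = data.phenotypes[data.phenotypes["animal_id"].isin(ref_ids)]
        design = build_design(ref_records, grm_ids=grm.ids, model="animal")
        solution = solve_mme(design, grm, components)
        gebv = solution.gebv.loc[candidates]

        if spec.validation_record == "offspring_average":
            for s in candidates:
                offs = [a for a in subset_set if data.sire_of[a] == s]
                yc = data.y_corrected(offs)
                rows.append(
                    (s, float(gebv.loc[s]), float(yc.mean()),
                     reliability_weight(len(offs), data.h2_cb), fold, len(offs))
                )
        else:
            yc = data.y_corrected(candidates)
            for a, g, r in zip(candidates, gebv.to_numpy(), yc):
                rows.append((a, float(g), float(r), 1.0, fold, 1))
    out = pd.DataFrame(
        rows, columns=["unit_id", "gebv", "record", "weight", "fold", "n_offspring"]
    )
    return out


def evaluate_units(units: pd.DataFrame, validation_record: str) -> tuple[float, float]:
    """Pooled validation correlation and dispersion-bias coefficient."""
    multiplier = 2.0 if validation_record == "offspring_average" else 1.0
    corr = weighted_correlation(units["gebv"], units["record"], units["weight"])
    bias = weighted_regression_bias(
        units["gebv"], units["record"], units["weight"], multiplier
    )
    return corr, bias
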