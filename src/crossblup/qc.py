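"""Phenotype and genotype quality control.

Filters follow the cleaning rules of the motivating broiler study:

* phenotype outliers beyond 3.5 within-group standard deviations removed,
  with mean and sd computed once per (recording day, genetic group) on the
  unfiltered group;
* markers on sex chromosomes / mitochondrial genome / unknown locations
  removed;
* markers and animals with a call rate strictly below 90% removed;
* markers with more than 1% Mendelian-inconsistent parent-offspring pairs
  removed, the remaining inconsistent pairs masked to missing on both sides;
* markers with a minor allele frequency strictly below 0.005 in either the
  genotype matrix or the sire-origin allele (BOA) matrix removed.

``apply_qc`` runs the filters in the fixed order location -> call rate ->
Mendelian -> MAF, then mode-imputes remaining missing genotypes within
genetic group.  All filters are idempotent and the report plus raw input
fully determine the filtered dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset, MISSING_BOA, MISSING_GENO

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_phenotype_outliers",
    "marker_location_filter",
    "filter_marker_callrate",
    "filter_animal_callrate",
    "mendelian_consistency",
    "maf_filter",
    "impute_missing_mode",
    "apply_qc",
]

BAD_CHROMOSOMES = {"sexZ", "sexW", "MT", "unknown", ""}


@dataclass(frozen=True)
class QCThresholds:
    outlier_sd: float = 3.5
    callrate: float = 0.90
    mendelian: float = 0.01
    maf: float = 0.005


@dataclass
class QCReport:
    """Everything removed or masked, each with exactly one reason."""

    removed_phenotypes: list = field(default_factory=list)  # (record_id, reason)
    removed_markers: list = field(default_factory=list)  # (marker_id, reason)
    removed_animals: list = field(default_factory=list)  # (animal_id, reason)
    masked_genotypes: list = field(default_factory=list)  # (animal_id, marker_id)
    flagged_animals: list = field(default_factory=list)  # (animal_id, reason)

    def extend(self, other: "QCReport") -> None:
        self.removed_phenotypes += other.removed_phenotypes
        self.removed_markers += other.removed_markers
        self.removed_animals += other.removed_animals
        self.masked_genotypes += other.masked_genotypes
        self.flagged_animals += other.flagged_animals

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("phenotype", i, r) for i, r in self.removed_phenotypes]
            + [("marker", i, r) for i, r in self.removed_markers]
            + [("animal", i, r) for i, r in self.removed_animals]
            + [("masked", f"{a}:{m}", "mendelian") for a, m in self.masked_genotypes]
            + [("animal_flag", i, r) for i, r in self.flagged_animals]
        )
        return pd.DataFrame(rows, columns=["entity_type", "id", "reason"])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def filter_phenotype_outliers(records: pd.DataFrame, group_keys=("trait", "batch", "genetic_group"), k: float = 3.5):
    """Drop records deviating more than ``k`` sd from their group mean.

    Mean and sd (sample, n-1) are computed once on the unfiltered group — a
    single pass, no re-estimation after removal.  Groups with fewer than two
    records are passed through untouched with a warning.
    """
    keep = np.ones(len(records), dtype=bool)
    report = QCReport()
    for key, idx in records.groupby(list(group_keys)).groups.items():
        vals = records.loc[idx, "value"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"outlier group {key} has <2 records; passed through")
            continue
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(k):
            continue
        bad = np.abs(vals - mu) > k * sd
        for i in np.asarray(idx)[bad]:
            keep[records.index.get_loc(i)] = False
            rec = records.loc[i]
            report.removed_phenotypes.append((f"{rec['animal_id']}|{rec['trait']}", "outlier"))
    return records[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# markers and animals
# ---------------------------------------------------------------------------

def marker_location_filter(marker_info: pd.DataFrame):
    """Keep autosomal markers with a known position."""
    chrom = marker_info["chromosome"].astype(str).fillna("unknown")
    pos_ok = marker_info["position_morgans"].notna()
    keep = (~chrom.isin(BAD_CHROMOSOMES) & pos_ok).to_numpy()
    report = QCReport(
        removed_markers=[(m, "location") for m in marker_info.loc[~keep, "marker_id"]]
    )
    return keep, report


def filter_marker_callrate(genotypes: np.ndarray, marker_ids, threshold: float = 0.90):
    """Keep markers whose fraction of non-missing calls is >= threshold."""
    called = (genotypes != MISSING_GENO).mean(axis=0) if len(genotypes) else np.ones(genotypes.shape[1])
    keep = called >= threshold
    report = QCReport(removed_markers=[(m, "callrate") for m in np.asarray(marker_ids)[~keep]])
    return keep, report


def filter_animal_callrate(genotypes: np.ndarray, animal_ids, threshold: float = 0.90):
    called = (genotypes != MISSING_GENO).mean(axis=1) if genotypes.shape[1] else np.ones(len(genotypes))
    keep = called >= threshold
    report = QCReport(removed_animals=[(a, "callrate") for a in np.asarray(animal_ids)[~keep]])
    return keep, report


def _parent_offspring_pairs(pedigree: pd.DataFrame, genotyped: set):
    pairs = []
    for _, row in pedigree.iterrows():
        child = row["animal_id"]
        if child not in genotyped:
            continue
        for parent in (row["sire_id"], row["dam_id"]):
            if parent != "0" and parent in genotyped:
                pairs.append((parent, child))
    return pairs


def mendelian_consistency(
    genotypes: np.ndarray,
    animal_ids,
    pedigree: pd.DataFrame,
    marker_ids,
    marker_threshold: float = 0.01,
    animal_threshold: float = 0.01,
):
    """Opposing-homozygote checks over all genotyped parent-offspring pairs.

    A pair is inconsistent at a marker iff the dosages are (0,2) or (2,0).
    Markers with an inconsistency fraction strictly above ``marker_threshold``
    (over evaluable pairs) are removed; on surviving markers both members of
    each inconsistent pair are masked to missing.  Animals with more than
    ``animal_threshold`` inconsistencies across markers are flagged.

    Returns ``(keep_marker_mask, masked_genotypes, report)`` where
    ``masked_genotypes`` is a boolean animals x markers mask (True = set to
    missing) aligned with the *input* marker axis.
    """
    row_of = {a: i for i, a in enumerate(animal_ids)}
    pairs = _parent_offspring_pairs(pedigree, set(animal_ids))
    n_markers = genotypes.shape[1]
    if not pairs:
        warnings.warn("no genotyped parent-offspring pairs; Mendelian filter is a no-op")
        return np.ones(n_markers, bool), np.zeros_like(genotypes, bool), QCReport()

    p_idx = np.array([row_of[p] for p, _ in pairs])
    o_idx = np.array([row_of[c] for _, c in pairs])
    gp = genotypes[p_idx]
    go = genotypes[o_idx]
    valid = (gp != MISSING_GENO) & (go != MISSING_GENO)
    inc = valid & (((gp == 0) & (go == 2)) | ((gp == 2) & (go == 0)))

    n_valid = valid.sum(axis=0)
    frac = np.divide(inc.sum(axis=0), n_valid, out=np.zeros(n_markers), where=n_valid > 0)
    keep = frac <= marker_threshold
    report = QCReport(removed_markers=[(m, "mendelian") for m in np.asarray(marker_ids)[~keep]])

    mask = np.zeros_like(genotypes, dtype=bool)
    inc_kept = inc[:, keep]
    pair_rows, marker_cols = np.nonzero(inc_kept)
    kept_marker_idx = np.nonzero(keep)[0]
    marker_arr = np.asarray(marker_ids)
    for r, c in zip(pair_rows, marker_cols):
        j = kept_marker_idx[c]
        for a in (p_idx[r], o_idx[r]):
            if not mask[a, j]:
                mask[a, j] = True
                report.masked_genotypes.append((animal_ids[a], marker_arr[j]))

    # per-animal inconsistency rate over evaluable (pair, marker) cells
    n_animals = len(animal_ids)
    a_inc = np.zeros(n_animals)
    a_val = np.zeros(n_animals)
    for idx in (p_idx, o_idx):
        np.add.at(a_inc, idx, inc.sum(axis=1))
        np.add.at(a_val, idx, valid.sum(axis=1))
    with np.errstate(invalid="ignore"):
        a_frac = np.divide(a_inc, a_val, out=np.zeros(n_animals), where=a_val > 0)
    for a in np.asarray(animal_ids)[a_frac > animal_threshold]:
        report.flagged_animals.append((a, "mendelian"))
    return keep, mask, report


def maf_filter(genotypes: np.ndarray, boa: np.ndarray, marker_ids, threshold: float = 0.005):
    """Remove markers with MAF strictly below threshold in the genotype
    matrix or among the sire-origin alleles of the BOA matrix."""
    n_markers = genotypes.shape[1]

    def _maf_from(mat, missing, n_alleles_per_obs):
        ok = mat != missing
        counts = np.where(ok, mat, 0).sum(axis=0).astype(float)
        total = ok.sum(axis=0) * n_alleles_per_obs
        p = np.divide(counts, total, out=np.full(n_markers, 0.5), where=total > 0)
        return np.minimum(p, 1.0 - p)

    maf_geno = _maf_from(genotypes, MISSING_GENO, 2)
    fail_geno = maf_geno < threshold
    if len(boa):
        maf_boa = _maf_from(boa, MISSING_BOA, 1)
        fail_boa = maf_boa < threshold
    else:
        fail_boa = np.zeros(n_markers, bool)
    keep = ~(fail_geno | fail_boa)
    marker_arr = np.asarray(marker_ids)
    report = QCReport(
        removed_markers=[
            (m, "maf_geno" if g else "maf_boa")
            for m, g, b in zip(marker_arr, fail_geno, fail_boa)
            if g or b
        ]
    )
    return keep, report


def impute_missing_mode(genotypes: np.ndarray, groups) -> np.ndarray:
    """Replace missing dosages by the within-group per-marker mode.

    Deterministic (ties broken toward the lower dosage); preserves allele
    frequencies approximately.  Falls back to the overall mode when a group
    has no called genotypes at a marker.
    """
    out = genotypes.copy()
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        rows = np.nonzero(groups == g)[0]
        block = out[rows]
        miss = block == MISSING_GENO
        if not miss.any():
            continue
        for j in np.nonzero(miss.any(axis=0))[0]:
            col = block[:, j]
            called = col[col != MISSING_GENO]
            pool = called if len(called) else out[:, j][out[:, j] != MISSING_GENO]
            mode = np.bincount(pool, minlength=3).argmax() if len(pool) else 0
            col[col == MISSING_GENO] = mode
            block[:, j] = col
        out[rows] = block
    return out


def apply_qc(dataset: Dataset, thresholds: QCThresholds = QCThresholds()):
    """Full cleaning pipeline in the fixed order
    location -> call rate -> Mendelian -> MAF, then mode imputation.

    Returns ``(clean_dataset, report)``.
    """
    report = QCReport()

    phen, rep = filter_phenotype_outliers(dataset.phenotypes, k=thresholds.outlier_sd)
    report.extend(rep)
    ds = Dataset(
        dataset.marker_info, dataset.animal_ids, dataset.genotypes.copy(),
        dataset.boa_ids, dataset.boa.copy(), dataset.pedigree, phen,
    )

    keep, rep = marker_location_filter(ds.marker_info)
    report.extend(rep)
    ds = ds.subset_markers(keep)

    keep, rep = filter_marker_callrate(ds.genotypes, ds.marker_ids, thresholds.callrate)
    report.extend(rep)
    ds = ds.subset_markers(keep)

    keep_a, rep = filter_animal_callrate(ds.genotypes, ds.animal_ids, thresholds.callrate)
    report.extend(rep)
    if not keep_a.all():
        ds = ds.subset_animals(ds.animal_ids[keep_a])

    keep, mask, rep = mendelian_consistency(
        ds.genotypes, ds.animal_ids, ds.pedigree, ds.marker_ids, thresholds.mendelian
    )
    report.extend(rep)
    geno = ds.genotypes.copy()
    geno[mask] = MISSING_GENO
    ds = Dataset(ds.marker_info, ds.animal_ids, geno, ds.boa_ids, ds.boa, ds.pedigree, ds.phenotypes)
    ds = ds.subset_markers(keep)

    keep, rep = maf_filter(ds.genotypes, ds.boa, ds.marker_ids, thresholds.maf)
    report.extend(rep)
    ds = ds.subset_markers(keep)

    groups = pd.Series(ds.animal_ids).map(
        dict(zip(ds.pedigree["animal_id"], ds.pedigree["genetic_group"]))
    ).fillna("unknown").to_numpy()
    geno = impute_missing_mode(ds.genotypes, groups)
    ds = Dataset(ds.marker_info, ds.animal_ids, geno, ds.boa_ids, ds.boa, ds.pedigree, ds.phenotypes)
    logger.info(
        "QC removed %d phenotypes, %d markers, %d animals; masked %d genotypes",
        len(report.removed_phenotypes), len(report.removed_markers),
        len(report.removed_animals), len(report.masked_genotypes),
    )
    return ds, report
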