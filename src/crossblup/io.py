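"""On-disk dataset formats.

A dataset is five plain-text files in one directory:

``markers.tsv``
    marker sidecar: marker_id, chromosome, position_morgans, counted_allele.
``genotypes.tsv``
    tab-separated, ``animal_id`` then one column per marker with
    counted-allele dosages in {0,1,2}; ``-1`` marks a missing call.
``boa.tsv``
    same shape, crossbred animals only; per marker the number of
    counted-allele copies on the sire-line-origin gamete (0/1), ``9`` when
    the origin could not be assigned.
``pedigree.csv``
    animal_id, sire_id, dam_id, genetic_group ("0" = unknown parent).
``phenotypes.csv``
    animal_id, trait, value, batch, pen, sex, age, dam_id, genetic_group.

Marker order in the wide files always matches the sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Population, LINE_CODES

__all__ = ["Dataset", "write_dataset", "read_dataset", "write_grm_csv"]

MISSING_GENO = -1
MISSING_BOA = 9


@dataclasses.dataclass
class Dataset:
    """In-memory image of the on-disk dataset."""

    marker_info: pd.DataFrame
    animal_ids: np.ndarray
    genotypes: np.ndarray  # (n_animals, n_markers) int8, -1 missing
    boa_ids: np.ndarray
    boa: np.ndarray  # (n_boa_animals, n_markers) int8, 9 unassigned
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.animal_ids), len(self.marker_info)):
            raise ValueError("genotype matrix shape does not match ids/markers")
        if self.boa.shape != (len(self.boa_ids), len(self.marker_info)):
            raise ValueError("BOA matrix shape does not match ids/markers")
        self._geno_row = {a: i for i, a in enumerate(self.animal_ids)}
        self._boa_row = {a: i for i, a in enumerate(self.boa_ids)}

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_info["marker_id"].to_numpy()

    def geno(self, animal_ids) -> np.ndarray:
        return self.genotypes[[self._geno_row[a] for a in animal_ids]]

    def boa_codes(self, animal_ids) -> np.ndarray:
        return self.boa[[self._boa_row[a] for a in animal_ids]]

    def has_genotype(self, animal_id) -> bool:
        return animal_id in self._geno_row

    @classmethod
    def from_population(cls, population: Population, phenotypes: pd.DataFrame) -> "Dataset":
        ped = population.pedigree
        cb_ids = population.group_ids("CB")
        boa = (
            population.sire_origin_dosage(cb_ids)
            if len(cb_ids)
            else np.empty((0, population.n_markers), dtype=np.int8)
        )
        return cls(
            marker_info=population.marker_map.copy(),
            animal_ids=population.ids.copy(),
            genotypes=population.genotypes().astype(np.int8),
            boa_ids=cb_ids,
            boa=boa.astype(np.int8),
            pedigree=ped.copy(),
            phenotypes=phenotypes.copy(),
        )

    def subset_markers(self, keep_mask: np.ndarray) -> "Dataset":
        return Dataset(
            marker_info=self.marker_info.loc[keep_mask].reset_index(drop=True),
            animal_ids=self.animal_ids,
            genotypes=self.genotypes[:, keep_mask],
            boa_ids=self.boa_ids,
            boa=self.boa[:, keep_mask],
            pedigree=self.pedigree,
            phenotypes=self.phenotypes,
        )

    def subset_animals(self, keep_ids) -> "Dataset":
        keep = set(keep_ids)
        gmask = np.array([a in keep for a in self.animal_ids])
        bmask = np.array([a in keep for a in self.boa_ids], dtype=bool)
        return Dataset(
            marker_info=self.marker_info,
            animal_ids=self.animal_ids[gmask],
            genotypes=self.genotypes[gmask],
            boa_ids=self.boa_ids[bmask] if len(self.boa_ids) else self.boa_ids,
            boa=self.boa[bmask] if len(self.boa_ids) else self.boa,
            pedigree=self.pedigree,
            phenotypes=self.phenotypes[self.phenotypes["animal_id"].isin(keep)].reset_index(drop=True),
        )


def _write_wide(path: Path, ids, matrix, marker_ids) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(marker_ids) + "\n")
        for aid, row in zip(ids, matrix):
            fh.write(str(aid) + "\t" + "\t".join(map(str, row.tolist())) + "\n")


def _read_wide(path: Path):
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    ids = df["animal_id"].to_numpy()
    mat = df.drop(columns="animal_id").to_numpy(dtype=np.int8)
    return ids, mat, df.columns[1:].to_numpy()


def write_dataset(dataset: Dataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.marker_info.to_csv(out / "markers.tsv", sep="\t", index=False)
    _write_wide(out / "genotypes.tsv", dataset.animal_ids, dataset.genotypes, dataset.marker_ids)
    _write_wide(out / "boa.tsv", dataset.boa_ids, dataset.boa, dataset.marker_ids)
    dataset.pedigree.to_csv(out / "pedigree.csv", index=False)
    dataset.phenotypes.to_csv(out / "phenotypes.csv", index=False)


def read_dataset(indir) -> Dataset:
    ind = Path(indir)
    marker_info = pd.read_csv(
        ind / "markers.tsv", sep="\t",
        dtype={"marker_id": str, "chromosome": str, "counted_allele": str},
    )
    ids, geno, cols = _read_wide(ind / "genotypes.tsv")
    if not np.array_equal(cols, marker_info["marker_id"].to_numpy()):
        raise ValueError("genotype columns do not match the marker sidecar")
    boa_ids, boa, bcols = _read_wide(ind / "boa.tsv")
    if len(boa_ids) and not np.array_equal(bcols, marker_info["marker_id"].to_numpy()):
        raise ValueError("BOA columns do not match the marker sidecar")
    pedigree = pd.read_csv(ind / "pedigree.csv", dtype=str)
    phenotypes = pd.read_csv(
        ind / "phenotypes.csv",
        dtype={"animal_id": str, "trait": str, "batch": str, "pen": str,
               "sex": str, "dam_id": str, "genetic_group": str},
    )
    return Dataset(marker_info, ids, geno, boa_ids, boa, pedigree, phenotypes)


def write_grm_csv(grm, path) -> None:
    """Long-format (id1, id2, value) export of a relationship matrix."""
    ids = list(grm.ids)
    n = len(ids)
    with open(path, "w") as fh:
        fh.write("id1,id2,value\n")
        for i in range(n):
            for j in range(i, n):
                fh.write(f"{ids[i]},{ids[j]},{grm.values[i, j]:.10g}\n")
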