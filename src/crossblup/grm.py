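"""Genomic relationship matrices for multi-breed and breed-of-origin GBLUP.

Four constructions are provided, all of the cross-product form ``W W'`` and
therefore symmetric positive semidefinite:

``single_breed_grm``
    VanRaden's G = M M' / sum 2 p_j (1 - p_j), with M the genotype matrix
    centred at 2 p_j.
``multibreed_grm``
    the two-group block matrix of multi-breed GBLUP: each
    group's block is centred and scaled with its own allele frequencies and
    the cross block uses the geometric mean of the two denominators.
``sire_partial_grm``
    the breed-of-origin partial matrix: for crossbred animals only the
    allele inherited from the sire line enters, as a centred 0/1 dosage
    ``T = t - p`` with p the sire-line allele frequency; purebred rows use
    full genotypes centred at 2p.  The expected diagonal for crossbred
    animals is 0.5.
``dam_partial_grm``
    the mirror image built from the dam-origin allele of each crossbred
    animal, used to probe the predictive value of dam-line alleles.

Frequencies are estimated with :func:`compute_allele_frequencies`; the
scaling denominator of every block uses the same frequency vector as its
centring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlleleFrequencies",
    "GRMatrix",
    "compute_allele_frequencies",
    "single_breed_grm",
    "multibreed_grm",
    "sire_partial_grm",
    "dam_partial_grm",
    "regularize",
]


class FrequencyError(ValueError):
    """A frequency could not be computed for a requested group."""


#: origin-indicator code for an allele whose line of origin is unassigned;
#: such entries enter partial matrices as the mean (a centred value of 0)
UNASSIGNED_BOA = 9


@dataclass
class AlleleFrequencies:
    """Counted-allele frequencies per marker for the groups of one analysis.

    ``p_sireline`` pools the purebred sires' alleles (two per animal) with
    the sire-origin alleles of the crossbred animals (one per animal);
    ``p_damline`` is the frequency among dam-origin alleles of crossbreds.
    """

    p_pb: np.ndarray | None = None
    p_cb: np.ndarray | None = None
    p_sireline: np.ndarray | None = None
    p_damline: np.ndarray | None = None


@dataclass
class GRMatrix:
    """A relationship matrix with its animal index and build metadata."""

    values: np.ndarray
    ids: list
    kind: str  # single | multibreed | boa_sire | boa_dam
    denominators: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate animal ids in GRM index")
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM shape does not match its index")
        self._row = {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, animal_ids) -> np.ndarray:
        idx = np.array([self._row[a] for a in animal_ids])
        return self.values[np.ix_(idx, idx)]

    def index_of(self, animal_ids) -> np.ndarray:
        return np.array([self._row[a] for a in animal_ids])


def compute_allele_frequencies(
    genotypes_pb: np.ndarray | None = None,
    genotypes_cb: np.ndarray | None = None,
    sire_genotypes: np.ndarray | None = None,
    boa_sire_dosage: np.ndarray | None = None,
    boa_dam_dosage: np.ndarray | None = None,
) -> AlleleFrequencies:
    """Frequencies for whichever variants the inputs allow.

    ``p_sireline`` = (counted alleles of the PB sires + counted sire-origin
    alleles of the CB offspring) / (2 n_sires + n_cb), following the pooled
    definition of the breed-of-origin matrix.  Monomorphic frequencies are
    allowed here; the MAF filter is responsible for removing them upstream.
    """
    out = AlleleFrequencies()
    if genotypes_pb is not None and len(genotypes_pb):
        out.p_pb = genotypes_pb.mean(axis=0) / 2.0
    if genotypes_cb is not None and len(genotypes_cb):
        out.p_cb = genotypes_cb.mean(axis=0) / 2.0
    if boa_sire_dosage is not None and len(boa_sire_dosage):
        ok = boa_sire_dosage != UNASSIGNED_BOA
        counted_cb = np.where(ok, boa_sire_dosage, 0).sum(axis=0).astype(float)
        n_cb = ok.sum(axis=0)
        if sire_genotypes is not None and len(sire_genotypes):
            n_s = len(sire_genotypes)
            out.p_sireline = (sire_genotypes.sum(axis=0) + counted_cb) / (2.0 * n_s + n_cb)
        else:
            with np.errstate(invalid="ignore"):
                out.p_sireline = np.divide(
                    counted_cb, n_cb, out=np.full(boa_sire_dosage.shape[1], 0.5),
                    where=n_cb > 0,
                )
    elif sire_genotypes is not None and len(sire_genotypes):
        out.p_sireline = sire_genotypes.mean(axis=0) / 2.0
    if boa_dam_dosage is not None and len(boa_dam_dosage):
        ok = boa_dam_dosage != UNASSIGNED_BOA
        counted = np.where(ok, boa_dam_dosage, 0).sum(axis=0).astype(float)
        n_ok = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out.p_damline = np.divide(
                counted, n_ok, out=np.full(boa_dam_dosage.shape[1], 0.5), where=n_ok > 0
            )
    return out


def _denominator(p: np.ndarray) -> float:
    d = float(np.sum(2.0 * p * (1.0 - p)))
    if d <= 0:
        raise FrequencyError("scaling denominator sum 2p(1-p) is zero; "
                             "remove monomorphic markers first")
    return d


def single_breed_grm(genotypes: np.ndarray, p: np.ndarray, ids, kind: str = "single") -> GRMatrix:
    """G = M M' / sum 2 p_j (1 - p_j), M centred at 2 p_j."""
    m = genotypes.astype(float) - 2.0 * p
    denom = _denominator(p)
    return GRMatrix(m @ m.T / denom, list(ids), kind, {"all": denom})


def multibreed_grm(
    genotypes_pb: np.ndarray,
    genotypes_cb: np.ndarray,
    freqs: AlleleFrequencies,
    ids_pb,
    ids_cb,
) -> GRMatrix:
    """Two-group block GRM; equals ``W W'`` with each animal's centred row
    scaled by the square root of its group denominator, hence PSD."""
    if genotypes_pb.shape[1] != genotypes_cb.shape[1]:
        raise ValueError("PB and CB genotype matrices must share the marker set")
    if freqs.p_pb is None or freqs.p_cb is None:
        raise FrequencyError("multibreed GRM needs p_pb and p_cb")
    d_pb = _denominator(freqs.p_pb)
    d_cb = _denominator(freqs.p_cb)
    w_pb = (genotypes_pb.astype(float) - 2.0 * freqs.p_pb) / np.sqrt(d_pb)
    w_cb = (genotypes_cb.astype(float) - 2.0 * freqs.p_cb) / np.sqrt(d_cb)
    w = np.vstack([w_pb, w_cb])
    return GRMatrix(
        w @ w.T, list(ids_pb) + list(ids_cb), "multibreed",
        {"PB": d_pb, "CB": d_cb},
    )


def sire_partial_grm(
    genotypes_pb: np.ndarray,
    boa_sire_dosage: np.ndarray,
    p_sireline: np.ndarray,
    ids_pb,
    ids_cb,
) -> GRMatrix:
    """Breed-of-origin partial GRM using sire-line alleles only.

    Crossbred rows contribute ``t_j - p_j`` with t the 0/1 sire-origin
    counted-allele dosage; purebred rows contribute genotypes centred at
    ``2 p_j``; one shared denominator ``sum 2 p_j (1 - p_j)``.  Entries with
    the unassigned-origin code enter as 0 (imputed at the mean).  With no
    purebred rows this reduces to T T' / sum 2p(1-p) over crossbreds.
    """
    if p_sireline is None:
        raise FrequencyError("sire-line frequencies required")
    denom = _denominator(p_sireline)
    blocks = []
    if len(ids_pb):
        blocks.append(genotypes_pb.astype(float) - 2.0 * p_sireline)
    if len(ids_cb):
        unassigned = boa_sire_dosage == UNASSIGNED_BOA
        t = boa_sire_dosage.astype(float)
        if t[~unassigned].min(initial=0) < 0 or t[~unassigned].max(initial=0) > 1:
            raise ValueError("sire-origin dosage must be 0/1 per marker")
        t = t - p_sireline
        t[unassigned] = 0.0
        blocks.append(t)
    w = np.vstack(blocks) / np.sqrt(denom)
    return GRMatrix(w @ w.T, list(ids_pb) + list(ids_cb), "boa_sire", {"sireline": denom})


def dam_partial_grm(
    genotypes_pb: np.ndarray,
    boa_dam_dosage: np.ndarray,
    p_damline: np.ndarray,
    ids_pb,
    ids_cb,
) -> GRMatrix:
    """Partial GRM from the dam-origin allele of each crossbred animal.

    Purebred (sire) rows are centred at ``2 p_j`` with the dam-line
    frequencies so that the whole matrix stays a single cross-product.
    """
    if p_damline is None:
        raise FrequencyError("dam-line frequencies required")
    denom = _denominator(p_damline)
    blocks = []
    if len(ids_pb):
        blocks.append(genotypes_pb.astype(float) - 2.0 * p_damline)
    if len(ids_cb):
        unassigned = boa_dam_dosage == UNASSIGNED_BOA
        t = boa_dam_dosage.astype(float) - p_damline
        t[unassigned] = 0.0
        blocks.append(t)
    w = np.vstack(blocks) / np.sqrt(denom)
    return GRMatrix(w @ w.T, list(ids_pb) + list(ids_cb), "boa_dam", {"damline": denom})


def regularize(grm: GRMatrix, epsilon: float = 1e-6) -> GRMatrix:
    """Add ``epsilon`` to the diagonal (recorded in metadata) so the matrix
    is safely invertible in mixed-model equations."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return grm
    values = grm.values + epsilon * np.eye(len(grm.ids))
    meta = dict(grm.denominators)
    meta["epsilon"] = meta.get("epsilon", 0.0) + epsilon
    return GRMatrix(values, list(grm.ids), grm.kind, meta)
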