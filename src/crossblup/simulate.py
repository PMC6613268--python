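"""Synthetic three-way terminal-cross populations.

Generates the data structure the crossbred-prediction analysis assumes: a
purebred sire line A, two dam lines B and C with drifted allele frequencies,
F1 (B x C) dams, purebred (A x A) and three-way crossbred (A x F1) offspring,
phased genotypes with per-allele line-of-origin labels, correlated purebred/
crossbred QTL effects, and phenotypes with batch x pen x sex x age fixed
effects plus maternal permanent-environment effects.

Every stochastic step draws from a :class:`numpy.random.Generator`; a run is
fully reproduced by the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LineSpec",
    "TraitSpec",
    "SimConfig",
    "TraitArchitecture",
    "Population",
    "DEFAULT_TRAITS",
    "sample_line_frequencies",
    "gene_drop",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "simulate_study",
]

#: integer codes for the three parental lines used in origin-label arrays
LINE_CODES = {"A": 0, "B": 1, "C": 2}
LINE_NAMES = {v: k for k, v in LINE_CODES.items()}

PB = "PB"
CB = "CB"
F1 = "F1"
FOUNDER_GROUPS = {"A": "founderA", "B": "founderB", "C": "founderC"}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class StructuralError(ValueError):
    """Pedigree / mating structure violates its preconditions."""


@dataclass(frozen=True)
class LineSpec:
    """One parental line and its drift from the shared ancestral frequencies.

    ``divergence`` plays the role of a Wright fixation index: line
    frequencies are drawn from a Balding-Nichols beta distribution around the
    ancestral frequency, so the expected pairwise Hudson-type Fst between two
    lines with divergence F is approximately F.
    """

    line_id: str
    divergence: float = 0.15

    def __post_init__(self) -> None:
        if self.line_id not in LINE_CODES:
            raise ConfigurationError(f"unknown line id {self.line_id!r}")
        if not 0.0 <= self.divergence < 1.0:
            raise ConfigurationError(
                f"divergence must be in [0, 1), got {self.divergence}"
            )


@dataclass(frozen=True)
class TraitSpec:
    """A trait with separate purebred and crossbred genetic definitions."""

    name: str
    h2_pb: float
    h2_cb: float
    r_pc: float
    day: int = 7  # nominal age at measurement, days
    dropout: float = 0.0  # fraction of records lost (mortality)

    def __post_init__(self) -> None:
        for h in (self.h2_pb, self.h2_cb):
            if not 0.0 < h < 1.0:
                raise ConfigurationError(f"heritability must be in (0,1), got {h}")
        if not -1.0 <= self.r_pc <= 1.0:
            raise ConfigurationError(f"r_pc must be in [-1,1], got {self.r_pc}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0,1)")


#: the two body-weight traits of the motivating broiler study:
#: an early weight with (h2_PB, h2_CB, r_pc) = (0.09, 0.18, 0.80) and a later
#: weight with (0.22, 0.23, 0.96); the later trait loses ~4% of records to
#: mortality between the two weighings.
DEFAULT_TRAITS = (
    TraitSpec("BW7", h2_pb=0.09, h2_cb=0.18, r_pc=0.80, day=7, dropout=0.0),
    TraitSpec("BW35", h2_pb=0.22, h2_cb=0.23, r_pc=0.96, day=35, dropout=0.04),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic three-way-cross study population.

    Default counts mirror the motivating broiler dataset: 161 line-A sires
    (135 with both purebred and crossbred offspring, 5 purebred-only, 21
    crossbred-only), 628 purebred dams, 1028 F1 dams, ~4700 purebred and
    ~10500 crossbred phenotyped offspring.
    """

    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    n_markers: int = 2000
    n_qtl: int = 400
    n_sires: int = 161
    n_sires_both: int = 135
    n_sires_pb_only: int = 5
    n_sires_cb_only: int = 21
    n_pb_dams: int = 628
    n_cb_dams: int = 1028
    n_dam_line_founders: int = 150  # per dam line (B and C)
    n_pb_offspring: int = 4700
    n_cb_offspring: int = 10500
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    var_maternal: float = 0.05
    fixed_effect_sd: float = 0.5
    divergence: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    # geometric family-size parameters; the study data's family-size
    # distribution is near-geometric (p ~ 0.60 purebred, 0.64 crossbred)
    pb_family_geom_p: float = 0.60
    cb_family_geom_p: float = 0.64
    max_family_size: int = 11
    n_batches: int = 5
    pens_per_batch: int = 4
    pen_mixing: float = 0.05
    seed: int = 2024

    def __post_init__(self) -> None:
        if self.n_sires_both + self.n_sires_pb_only + self.n_sires_cb_only != self.n_sires:
            raise ConfigurationError(
                "n_sires_both + n_sires_pb_only + n_sires_cb_only must equal n_sires"
            )
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "n_markers": self.n_markers,
            "n_qtl": self.n_qtl,
            "n_sires": self.n_sires,
            "n_pb_dams": self.n_pb_dams,
            "n_cb_dams": self.n_cb_dams,
            "n_dam_line_founders": self.n_dam_line_founders,
            "n_pb_offspring": self.n_pb_offspring,
            "n_cb_offspring": self.n_cb_offspring,
            "n_batches": self.n_batches,
            "pens_per_batch": self.pens_per_batch,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.n_qtl > self.n_markers:
            raise ConfigurationError("n_qtl cannot exceed n_markers")
        if self.chrom_length_morgans < 0:
            raise ConfigurationError("chromosome length must be >= 0")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("ancestral_freq_range must be within (0,1)")
        if not traits_unique([t.name for t in self.traits]):
            raise ConfigurationError("trait names must be unique")

    def line_specs(self) -> tuple[LineSpec, LineSpec, LineSpec]:
        return (
            LineSpec("A", self.divergence),
            LineSpec("B", self.divergence),
            LineSpec("C", self.divergence),
        )

    def scaled(self, **overrides) -> "SimConfig":
        """Return a copy with some fields replaced (convenience for tests)."""
        return replace(self, **overrides)


def traits_unique(names: list[str]) -> bool:
    return len(names) == len(set(names))


@dataclass
class TraitArchitecture:
    """QTL positions and paired purebred/crossbred substitution effects."""

    trait: str
    qtl_indices: np.ndarray
    alpha_pb: np.ndarray
    alpha_cb: np.ndarray
    effect_correlation: float


@dataclass
class Population:
    """A simulated pedigree with phased genotypes and origin labels.

    ``haplotypes`` and ``origins`` are (n_animals, 2, n_markers) arrays;
    gamete 0 is always the paternal gamete.  Origin labels use
    :data:`LINE_CODES`.  ``true_bv_pb``/``true_bv_cb`` map trait name to the
    per-animal true breeding value under the purebred / crossbred trait
    definition; ``true_bv_cb_sire`` holds the sire-line (line-A allele)
    component of the crossbred breeding value.
    """

    pedigree: pd.DataFrame
    haplotypes: np.ndarray
    origins: np.ndarray
    marker_map: pd.DataFrame
    chrom_lengths: np.ndarray
    true_bv_pb: dict[str, np.ndarray] = field(default_factory=dict)
    true_bv_cb: dict[str, np.ndarray] = field(default_factory=dict)
    true_bv_cb_sire: dict[str, np.ndarray] = field(default_factory=dict)
    architectures: dict[str, TraitArchitecture] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._row = {a: i for i, a in enumerate(self.pedigree["animal_id"])}

    # -- indexing ---------------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["animal_id"].to_numpy()

    @property
    def n_animals(self) -> int:
        return len(self.pedigree)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def rows(self, animal_ids) -> np.ndarray:
        return np.array([self._row[a] for a in animal_ids], dtype=int)

    def group_ids(self, group: str) -> np.ndarray:
        mask = self.pedigree["genetic_group"] == group
        return self.pedigree.loc[mask, "animal_id"].to_numpy()

    # -- genotype views ---------------------------------------------------
    def genotypes(self, animal_ids=None) -> np.ndarray:
        """Counted-allele dosages in {0,1,2}, animals x markers."""
        h = self.haplotypes
        if animal_ids is not None:
            h = h[self.rows(animal_ids)]
        return h.sum(axis=1).astype(np.int8)

    def paternal_gamete_is_line(self, animal_ids, line: str = "A") -> np.ndarray:
        code = LINE_CODES[line]
        rows = self.rows(animal_ids)
        return (self.origins[rows, 0, :] == code).all(axis=1)

    def sire_origin_dosage(self, animal_ids) -> np.ndarray:
        """Counted-allele dosage (0/1) on the sire-line-origin gamete of CB
        animals.

        By construction gamete 0 of a crossbred animal is the paternal
        (line-A) gamete; this is asserted rather than assumed.
        """
        rows = self.rows(animal_ids)
        if not (self.origins[rows, 0, :] == LINE_CODES["A"]).all():
            raise StructuralError("paternal gamete of a CB animal is not all line A")
        return self.haplotypes[rows, 0, :].astype(np.int8)

    def dam_origin_dosage(self, animal_ids) -> np.ndarray:
        """Counted-allele dosage (0/1) on the maternal (dam-line) gamete."""
        rows = self.rows(animal_ids)
        return self.haplotypes[rows, 1, :].astype(np.int8)


# ---------------------------------------------------------------------------
# founder allele frequencies
# ---------------------------------------------------------------------------

def sample_line_frequencies(
    n_markers: int,
    line_specs,
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9),
    seed=None,
) -> dict[str, np.ndarray]:
    """Draw per-line counted-allele frequencies around shared ancestral ones.

    Uses Balding-Nichols sampling: for ancestral frequency p and divergence F
    the line frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and
    variance F p(1-p).  ``divergence = 0`` returns the ancestral frequencies
    unchanged.
    """
    if n_markers < 1:
        raise ConfigurationError("need at least one marker")
    specs = list(line_specs)
    if len({s.line_id for s in specs}) != len(specs):
        raise ConfigurationError("line ids must be distinct")
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_freq_range
    if not (0.0 < lo <= hi < 1.0):
        raise ConfigurationError("ancestral_freq_range must be within (0,1)")
    p_anc = rng.uniform(lo, hi, size=n_markers)
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        f = spec.divergence
        if f == 0.0:
            out[spec.line_id] = p_anc.copy()
            continue
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p = rng.beta(a, b)
        out[spec.line_id] = np.clip(p, 1e-4, 1.0 - 1e-4)
    return out


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Markers evenly spread over equally long autosomes."""
    m = config.n_markers
    n_chr = config.n_chromosomes
    counts = np.full(n_chr, m // n_chr)
    counts[: m % n_chr] += 1
    rows = []
    k = 0
    for c in range(n_chr):
        L = config.chrom_length_morgans
        for i in range(counts[c]):
            pos = (i + 0.5) / counts[c] * L if counts[c] else 0.0
            rows.append((f"M{k:05d}", str(c + 1), pos, "1"))
            k += 1
    mm = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_morgans", "counted_allele"])
    lengths = np.full(n_chr, config.chrom_length_morgans)
    return mm, lengths


def _chromosome_slices(marker_map: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    slices = []
    chroms = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_morgans"].to_numpy(dtype=float)
    start = 0
    for c in pd.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        stop = idx[-1] + 1
        if not np.array_equal(idx, np.arange(idx[0], stop)):
            raise StructuralError("marker map must be grouped by chromosome")
        slices.append((slice(idx[0], stop), pos[idx[0]: stop]))
        start = stop
    return slices


def _meiosis(haps, origs, chrom_slices, chrom_lengths, rng):
    """One recombinant gamete (alleles + origin labels) from a parent.

    Crossover counts are Poisson per chromosome with mean equal to the map
    length in Morgans (no interference); crossover positions are uniform.
    """
    m = haps.shape[1]
    gamete = np.empty(m, dtype=np.uint8)
    gorig = np.empty(m, dtype=np.uint8)
    cols = np.arange(m)
    for (sl, pos), length in zip(chrom_slices, chrom_lengths):
        start = rng.integers(2)
        k = rng.poisson(length) if length > 0 else 0
        if k == 0:
            phase = np.full(pos.shape, start, dtype=np.int64)
        else:
            xpos = np.sort(rng.uniform(0.0, length, size=k))
            phase = (start + np.searchsorted(xpos, pos)) % 2
        gamete[sl] = haps[phase, cols[sl]]
        gorig[sl] = origs[phase, cols[sl]]
    return gamete, gorig


def gene_drop(
    founders: dict[str, tuple[np.ndarray, str]],
    matings,
    marker_map: pd.DataFrame,
    chrom_lengths,
    seed=None,
) -> Population:
    """Drop founder gametes through a list of matings.

    Parameters
    ----------
    founders
        ``animal_id -> (haplotypes (2, m) uint8, line_id)``.  Founder origin
        labels are the founder's own line.
    matings
        iterable of ``(child_id, sire_id, dam_id, genetic_group)`` in an
        order where every parent appears (as founder or earlier child)
        before its offspring.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = np.asarray(chrom_lengths, dtype=float)
    chrom_slices = _chromosome_slices(marker_map)
    m = len(marker_map)

    matings = list(matings)
    n = len(founders) + len(matings)
    haps = np.empty((n, 2, m), dtype=np.uint8)
    origs = np.empty((n, 2, m), dtype=np.uint8)
    ped_rows = []
    row_of: dict[str, int] = {}

    for i, (aid, (fh, line)) in enumerate(founders.items()):
        fh = np.asarray(fh, dtype=np.uint8)
        if fh.shape != (2, m):
            raise StructuralError(f"founder {aid} haplotypes have shape {fh.shape}")
        haps[i] = fh
        origs[i] = LINE_CODES[line]
        row_of[aid] = i
        ped_rows.append((aid, "0", "0", FOUNDER_GROUPS[line]))

    for j, (child, sire, dam, group) in enumerate(matings):
        if sire not in row_of or dam not in row_of:
            raise StructuralError(f"mating for {child} references unknown parent")
        i = len(founders) + j
        pat, pat_o = _meiosis(haps[row_of[sire]], origs[row_of[sire]], chrom_slices, chrom_lengths, rng)
        mat, mat_o = _meiosis(haps[row_of[dam]], origs[row_of[dam]], chrom_slices, chrom_lengths, rng)
        haps[i, 0], origs[i, 0] = pat, pat_o
        haps[i, 1], origs[i, 1] = mat, mat_o
        row_of[child] = i
        ped_rows.append((child, sire, dam, group))

    ped = pd.DataFrame(ped_rows, columns=["animal_id", "sire_id", "dam_id", "genetic_group"])
    return Population(ped, haps, origs, marker_map.copy(), chrom_lengths)


# ---------------------------------------------------------------------------
# mating design
# ---------------------------------------------------------------------------

def _family_sizes(n_offspring, geom_p, max_size, rng):
    sizes = []
    total = 0
    while total < n_offspring:
        s = min(int(rng.geometric(geom_p)), max_size)
        s = min(s, n_offspring - total)
        sizes.append(s)
        total += s
    return sizes


def _make_families(sire_ids, dam_ids, n_offspring, geom_p, max_size, rng):
    """Full-sib families (sire, dam, size) with geometric size distribution.

    Every sire is guaranteed at least one family; a repeated (sire, dam)
    draw extends the existing family rather than creating a duplicate.
    """
    sizes = _family_sizes(n_offspring, geom_p, max_size, rng)
    rng.shuffle(sizes)
    fam: dict[tuple[str, str], int] = {}
    sire_ids = list(sire_ids)
    for i, s in enumerate(sizes):
        sire = sire_ids[i % len(sire_ids)] if i < len(sire_ids) else rng.choice(sire_ids)
        dam = rng.choice(dam_ids)
        fam[(sire, dam)] = fam.get((sire, dam), 0) + s
    return [(s, d, c) for (s, d), c in fam.items()]


# ---------------------------------------------------------------------------
# QTL effects and true breeding values
# ---------------------------------------------------------------------------

def assign_qtl_effects(
    population: Population,
    n_qtl: int,
    h2_pb: float,
    h2_cb: float,
    r_pc: float,
    seed=None,
    trait: str = "trait",
) -> TraitArchitecture:
    """Sample correlated purebred/crossbred QTL effects and fill true BVs.

    Effect pairs are drawn from a zero-mean bivariate normal with correlation
    ``r_pc`` and then rescaled so that the realised additive variance equals
    ``h2_pb`` among purebred offspring (for the purebred effects) and
    ``h2_cb`` among crossbred offspring (for the crossbred effects), taking
    total phenotypic variance as 1.  The crossbred breeding value of an
    animal sums the crossbred effects over both alleles; its sire-line
    component sums them over line-A-origin alleles only.
    """
    if not -1.0 <= r_pc <= 1.0:
        raise ConfigurationError(f"r_pc must be in [-1,1], got {r_pc}")
    if n_qtl > population.n_markers:
        raise ConfigurationError("n_qtl cannot exceed the number of markers")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(population.n_markers, size=n_qtl, replace=False))
    z = rng.standard_normal((n_qtl, 2))
    a_pb = z[:, 0]
    a_cb = r_pc * z[:, 0] + np.sqrt(max(0.0, 1.0 - r_pc**2)) * z[:, 1]

    dos = population.genotypes()[:, qtl].astype(float)
    ped = population.pedigree
    pb_rows = (ped["genetic_group"] == PB).to_numpy()
    cb_rows = (ped["genetic_group"] == CB).to_numpy()
    base_pb = pb_rows if pb_rows.any() else np.ones(len(ped), bool)
    base_cb = cb_rows if cb_rows.any() else np.ones(len(ped), bool)

    def _scale(alpha, rows, target):
        v = np.var(dos[rows] @ alpha)
        if v <= 0:
            raise ConfigurationError("no genetic variance at sampled QTL")
        return alpha * np.sqrt(target / v)

    a_pb = _scale(a_pb, base_pb, h2_pb)
    a_cb = _scale(a_cb, base_cb, h2_cb)

    arch = TraitArchitecture(trait, qtl, a_pb, a_cb, r_pc)
    population.architectures[trait] = arch
    population.true_bv_pb[trait] = dos @ a_pb
    population.true_bv_cb[trait] = dos @ a_cb

    bv_sire = np.full(len(ped), np.nan)
    cb_ids = ped.loc[cb_rows, "animal_id"].to_numpy()
    if len(cb_ids):
        sire_dos = population.sire_origin_dosage(cb_ids)[:, qtl].astype(float)
        bv_sire[population.rows(cb_ids)] = sire_dos @ a_cb
    population.true_bv_cb_sire[trait] = bv_sire
    return arch


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    population: Population,
    config: SimConfig,
    seed=None,
    traits=None,
) -> pd.DataFrame:
    """Phenotype records for all purebred and crossbred offspring.

    A record is fixed class effect (batch x pen x sex x age, one normal draw
    per observed level) + the animal's own-trait true breeding value (PB
    animals express the purebred trait definition, CB animals the crossbred
    one) + a maternal permanent-environment effect per dam + residual, on a
    total-phenotypic-variance-1 scale.  Pens within a batch are allocated
    predominantly to one genetic group; ``pen_mixing`` is the probability
    that an animal is housed with the other group.
    """
    rng = np.random.default_rng(seed)
    traits = list(traits if traits is not None else config.traits)
    ped = population.pedigree
    off = ped[ped["genetic_group"].isin([PB, CB])].reset_index(drop=True)
    if off["dam_id"].eq("0").any():
        raise StructuralError("phenotyped animal without a dam")
    n = len(off)
    for t in traits:
        if t.name not in population.true_bv_pb:
            raise StructuralError(f"trait {t.name!r} has no QTL architecture")

    # housing design, shared across traits
    batch = rng.integers(config.n_batches, size=n)
    sex = np.where(rng.integers(2, size=n) == 0, "M", "F")
    npens = config.pens_per_batch
    is_cb = (off["genetic_group"] == CB).to_numpy()
    frac_cb = is_cb.mean()
    n_cb_pens = int(np.clip(round(npens * frac_cb), 1 if is_cb.any() else 0, npens - (1 if (~is_cb).any() else 0)))
    cb_pens = np.arange(n_cb_pens)
    pb_pens = np.arange(n_cb_pens, npens)
    pen = np.empty(n, dtype=int)
    mix = rng.random(n) < config.pen_mixing
    for i in range(n):
        own = cb_pens if is_cb[i] else pb_pens
        other = pb_pens if is_cb[i] else cb_pens
        pool = other if (mix[i] and len(other)) else own
        pen[i] = pool[rng.integers(len(pool))]
    pen_label = np.array([f"b{b + 1}p{p + 1}" for b, p in zip(batch, pen)])
    batch_label = np.array([f"b{b + 1}" for b in batch])

    dam_ids = off["dam_id"].to_numpy()
    all_dams = pd.unique(dam_ids)
    rows_off = population.rows(off["animal_id"])

    frames = []
    for t in traits:
        age = t.day + rng.integers(-1, 2, size=n)
        level_keys = pd.Series(
            [f"{b}|{p}|{s}|{a}" for b, p, s, a in zip(batch_label, pen_label, sex, age)]
        )
        levels = pd.unique(level_keys)
        eff = dict(zip(levels, rng.normal(0.0, config.fixed_effect_sd, size=len(levels))))
        fixed = level_keys.map(eff).to_numpy()

        m_eff = dict(zip(all_dams, rng.normal(0.0, np.sqrt(config.var_maternal), size=len(all_dams))))
        maternal = np.array([m_eff[d] for d in dam_ids])

        bv = np.where(
            is_cb,
            population.true_bv_cb[t.name][rows_off],
            population.true_bv_pb[t.name][rows_off],
        )
        var_e = np.where(is_cb, 1.0 - t.h2_cb, 1.0 - t.h2_pb) - config.var_maternal
        if (var_e <= 0).any():
            raise ConfigurationError("h2 + var_maternal must stay below 1")
        resid = rng.normal(0.0, 1.0, size=n) * np.sqrt(var_e)

        value = fixed + bv + maternal + resid
        df = pd.DataFrame(
            {
                "animal_id": off["animal_id"],
                "trait": t.name,
                "value": value,
                "batch": batch_label,
                "pen": pen_label,
                "sex": sex,
                "age": age,
                "dam_id": dam_ids,
                "genetic_group": off["genetic_group"].to_numpy(),
            }
        )
        if t.dropout > 0:
            keep = rng.random(n) >= t.dropout
            df = df[keep].reset_index(drop=True)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# full study generator
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig, seed=None):
    """Simulate a complete study population and its phenotype table.

    Returns ``(population, phenotypes)``.  All randomness derives from
    ``seed`` (defaults to ``config.seed``) through named
    :class:`numpy.random.SeedSequence` children, so identical configurations
    reproduce bit-identical populations.
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_freq, s_found, s_mate, s_drop, s_qtl, s_phen = ss.spawn(6)

    freqs = sample_line_frequencies(
        config.n_markers, config.line_specs(), config.ancestral_freq_range, s_freq
    )
    rng_f = np.random.default_rng(s_found)
    marker_map, chrom_lengths = _marker_map(config)

    def draw_founders(prefix, count, line):
        p = freqs[line]
        out = {}
        for i in range(count):
            h = (rng_f.random((2, config.n_markers)) < p).astype(np.uint8)
            out[f"{prefix}{i + 1:04d}"] = (h, line)
        return out

    founders = {}
    founders.update(draw_founders("S", config.n_sires, "A"))
    founders.update(draw_founders("PD", config.n_pb_dams, "A"))
    founders.update(draw_founders("BF", config.n_dam_line_founders, "B"))
    founders.update(draw_founders("CF", config.n_dam_line_founders, "C"))

    sires = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    rng_m = np.random.default_rng(s_mate)
    order = rng_m.permutation(config.n_sires)
    both = [sires[i] for i in order[: config.n_sires_both]]
    pb_only = [sires[i] for i in order[config.n_sires_both: config.n_sires_both + config.n_sires_pb_only]]
    cb_only = [sires[i] for i in order[config.n_sires_both + config.n_sires_pb_only:]]

    matings = []
    # F1 dams: one B founder x one C founder each
    f1_dams = []
    for i in range(config.n_cb_dams):
        b = f"BF{rng_m.integers(config.n_dam_line_founders) + 1:04d}"
        c = f"CF{rng_m.integers(config.n_dam_line_founders) + 1:04d}"
        did = f"FD{i + 1:04d}"
        matings.append((did, b, c, F1))
        f1_dams.append(did)

    pb_dams = [f"PD{i + 1:04d}" for i in range(config.n_pb_dams)]
    pb_fams = _make_families(
        both + pb_only, pb_dams, config.n_pb_offspring,
        config.pb_family_geom_p, config.max_family_size, rng_m,
    )
    cb_fams = _make_families(
        both + cb_only, f1_dams, config.n_cb_offspring,
        config.cb_family_geom_p, config.max_family_size, rng_m,
    )
    k = 0
    for sire, dam, size in pb_fams:
        for _ in range(size):
            k += 1
            matings.append((f"P{k:05d}", sire, dam, PB))
    k = 0
    for sire, dam, size in cb_fams:
        for _ in range(size):
            k += 1
            matings.append((f"X{k:05d}", sire, dam, CB))

    population = gene_drop(founders, matings, marker_map, chrom_lengths, s_drop)

    rng_q = np.random.default_rng(s_qtl)
    for t in config.traits:
        assign_qtl_effects(
            population, config.n_qtl, t.h2_pb, t.h2_cb, t.r_pc,
            seed=rng_q.integers(2**31), trait=t.name,
        )
    phenotypes = simulate_phenotypes(population, config, seed=s_phen)
    return population, phenotypes
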