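"""GBLUP animal model, sire model, EM-REML and corrected phenotypes.

The model is the classical univariate animal model

    y = X b + L m + Z a + e,

with a single combined batch x pen x sex x age fixed-effect class (X), a
maternal permanent-environment effect per dam (m ~ N(0, I sigma2_m)),
additive values a ~ N(0, G sigma2_a) with G a genomic relationship matrix,
and residuals e ~ N(0, I sigma2_e).  The sire model replaces Z a by T s with
independent sire effects s ~ N(0, I sigma2_s); its solutions give the
corrected phenotypes y_c = T s_hat + e_hat used as validation records.

Estimation is expectation-maximisation REML on the observed-record scale
(P-matrix form, monotone in the restricted likelihood); prediction solves
Henderson's mixed-model equations, through which animals without records
receive GEBV via their genomic covariances with the reference animals.

The statsmodels-style entry points are :class:`GBLUP` and :class:`SireModel`
whose ``fit`` returns a results object; ``build_design``, ``reml_estimate``,
``solve_mme`` and ``corrected_phenotypes`` are the underlying functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .grm import GRMatrix, regularize

__all__ = [
    "DesignBundle",
    "VarianceComponents",
    "MMESolution",
    "build_design",
    "solve_mme",
    "reml_estimate",
    "corrected_phenotypes",
    "GBLUP",
    "SireModel",
]


class NumericalError(RuntimeError):
    """A linear-algebra step failed (non-PSD matrix, singular system)."""


@dataclass
class DesignBundle:
    """Incidence structure of one model fit.

    Incidences are stored as integer level indices per record; dense
    matrices are assembled on demand.  ``animal_levels`` is the full GRM
    index for the animal model (so candidates without records keep a level).
    """

    y: np.ndarray
    X: np.ndarray
    fixed_levels: list
    dam_index: np.ndarray
    dam_levels: list
    model: str  # "animal" | "sire"
    animal_index: np.ndarray | None = None  # record -> position in animal_levels
    animal_levels: list | None = None
    sire_index: np.ndarray | None = None
    sire_levels: list | None = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n or len(self.dam_index) != n:
            raise ValueError("design row counts disagree")
        if self.model == "animal" and (self.animal_index is None or len(self.animal_index) != n):
            raise ValueError("animal model needs an animal incidence per record")
        if self.model == "sire" and (self.sire_index is None or len(self.sire_index) != n):
            raise ValueError("sire model needs a sire incidence per record")

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class VarianceComponents:
    """REML variance components on the phenotypic scale."""

    sigma2_a: float | None = None
    sigma2_m: float = 0.0
    sigma2_e: float = 1.0
    sigma2_s: float | None = None
    loglik: float | None = None
    converged: bool = True
    n_iter: int = 0
    loglik_trace: list = field(default_factory=list)

    @property
    def h2(self) -> float | None:
        if self.sigma2_a is None:
            return None
        tot = self.sigma2_a + self.sigma2_m + self.sigma2_e
        return self.sigma2_a / tot

    def validate(self) -> None:
        for name in ("sigma2_a", "sigma2_m", "sigma2_e", "sigma2_s"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class MMESolution:
    """Solutions of Henderson's mixed-model equations."""

    fixed: pd.Series
    maternal: pd.Series
    gebv: pd.Series | None
    sire: pd.Series | None
    residuals: np.ndarray
    components: VarianceComponents
    loglik: float | None = None


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _one_hot(index: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((len(index), n_levels))
    out[np.arange(len(index)), index] = 1.0
    return out


def _drop_rank_deficient(X: np.ndarray, labels: list):
    """Deterministic pivoted-QR column selection to full rank."""
    if X.shape[1] == 0:
        return X, labels
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if len(diag) else 0.0)
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [labels[i] for i in keep]


def build_design(
    phenotypes: pd.DataFrame,
    grm_ids=None,
    model: str = "animal",
    pedigree: pd.DataFrame | None = None,
) -> DesignBundle:
    """Design matrices for one trait's records.

    The fixed effect is the single combined batch|pen|sex|age class (one
    column per observed combination; a one-factor dummy coding is full rank
    by construction, but a pivoted-QR guard is applied anyway).  Maternal
    levels are the distinct dams with records.  For the animal model,
    additive levels are the full GRM index and every record's animal must be
    in it; for the sire model, sire identities come from the pedigree.
    """
    if phenotypes["animal_id"].duplicated().any():
        raise ValueError("at most one record per animal per design")
    y = phenotypes["value"].to_numpy(dtype=float)
    combo = (
        phenotypes["batch"].astype(str) + "|" + phenotypes["pen"].astype(str)
        + "|" + phenotypes["sex"].astype(str) + "|" + phenotypes["age"].astype(str)
    )
    fixed_codes, fixed_levels = pd.factorize(combo)
    X = _one_hot(fixed_codes, len(fixed_levels))
    X, fixed_levels = _drop_rank_deficient(X, list(fixed_levels))

    dam_codes, dam_levels = pd.factorize(phenotypes["dam_id"])

    if model == "animal":
        if grm_ids is None:
            raise ValueError("animal model requires a GRM index")
        pos = {a: i for i, a in enumerate(grm_ids)}
        missing = [a for a in phenotypes["animal_id"] if a not in pos]
        if missing:
            raise ValueError(f"records for animals missing from the GRM: {missing[:5]}")
        animal_index = np.array([pos[a] for a in phenotypes["animal_id"]])
        return DesignBundle(
            y, X, list(fixed_levels), dam_codes, list(dam_levels), "animal",
            animal_index=animal_index, animal_levels=list(grm_ids),
        )
    if model == "sire":
        if pedigree is None:
            raise ValueError("sire model requires a pedigree for sire identities")
        sire_of = dict(zip(pedigree["animal_id"], pedigree["sire_id"]))
        sires = phenotypes["animal_id"].map(sire_of)
        if sires.isna().any() or (sires == "0").any():
            raise ValueError("every record needs a known sire for the sire model")
        sire_codes, sire_levels = pd.factorize(sires)
        return DesignBundle(
            y, X, list(fixed_levels), dam_codes, list(dam_levels), "sire",
            sire_index=sire_codes, sire_levels=list(sire_levels),
        )
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# REML (expectation-maximisation, P-matrix form)
# ---------------------------------------------------------------------------

def _record_covariances(design: DesignBundle, grm: GRMatrix | None):
    """Per-record covariance structures C_k = Z_k K_k Z_k' and level counts."""
    terms: dict[str, tuple[np.ndarray, int]] = {}
    if design.model == "animal":
        rows = grm.index_of([design.animal_levels[i] for i in design.animal_index])
        terms["additive"] = (grm.values[np.ix_(rows, rows)], design.n_records)
    else:
        s = design.sire_index
        terms["sire"] = ((s[:, None] == s[None, :]).astype(float), len(design.sire_levels))
    d = design.dam_index
    terms["maternal"] = ((d[:, None] == d[None, :]).astype(float), len(design.dam_levels))
    return terms


def _reml_loglik_terms(V, X, y):
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except sla.LinAlgError as exc:
        raise NumericalError("phenotypic covariance matrix is not PD") from exc
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv = sla.cho_solve((c, low), np.eye(len(y)), check_finite=False)
    vinv_x = vinv @ X
    xtvx = X.T @ vinv_x
    cx, lowx = sla.cho_factor(xtvx, lower=True, check_finite=False)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx)))
    beta = sla.cho_solve((cx, lowx), vinv_x.T @ y, check_finite=False)
    p = vinv - vinv_x @ sla.cho_solve((cx, lowx), vinv_x.T, check_finite=False)
    py = p @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return ll, p, py, beta


def reml_estimate(
    design: DesignBundle,
    grm: GRMatrix | None = None,
    init: VarianceComponents | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponents:
    """EM-REML for (sigma2_a, sigma2_m, sigma2_e) or the sire-model set.

    Updates are the classical expectation-maximisation steps expressed with
    the projection matrix P,

        sigma2_k <- sigma2_k + sigma2_k^2 / q_k * (y'P C_k P y - tr(P C_k)),

    which keep every component positive and make the restricted
    log-likelihood non-decreasing.  Iteration stops when the likelihood
    changes by less than ``tol``; non-convergence returns the best iterate
    with ``converged=False`` and a warning.
    """
    y, X = design.y, design.X
    n = design.n_records
    terms = _record_covariances(design, grm)
    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0

    sig: dict[str, float] = {}
    if init is not None:
        init.validate()
        for k in terms:
            v = init.sigma2_a if k == "additive" else (
                init.sigma2_s if k == "sire" else init.sigma2_m)
            sig[k] = v if v and v > 0 else 0.1 * vary
        sig["residual"] = init.sigma2_e if init.sigma2_e > 0 else 0.5 * vary
    else:
        share = vary / (len(terms) + 2.0)
        for k in terms:
            sig[k] = share
        sig["residual"] = 2.0 * share

    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = sig["residual"] * np.eye(n)
        for k, (C, _) in terms.items():
            V += sig[k] * C
        ll, p, py, _ = _reml_loglik_terms(V, X, y)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        for k, (C, q) in terms.items():
            cpy = C @ py
            quad = float(py @ cpy)
            tr = float(np.sum(p * C))
            sig[k] = max(sig[k] + sig[k] ** 2 / q * (quad - tr), 1e-12)
        quad_e = float(py @ py)
        tr_e = float(np.trace(p))
        sig["residual"] = max(
            sig["residual"] + sig["residual"] ** 2 / n * (quad_e - tr_e), 1e-12
        )
    if not converged:
        warnings.warn(f"EM-REML did not converge in {max_iter} iterations")

    out = VarianceComponents(
        sigma2_a=sig.get("additive"),
        sigma2_m=sig["maternal"],
        sigma2_e=sig["residual"],
        sigma2_s=sig.get("sire"),
        loglik=ll_prev if not converged else ll,
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
    )
    return out


def reml_loglik(design: DesignBundle, grm: GRMatrix | None, components: VarianceComponents) -> float:
    """Restricted log-likelihood at the given components (for diagnostics
    and for independent cross-checks of the EM fixed point)."""
    terms = _record_covariances(design, grm)
    n = design.n_records
    V = components.sigma2_e * np.eye(n)
    for k, (C, _) in terms.items():
        s = components.sigma2_a if k == "additive" else (
            components.sigma2_s if k == "sire" else components.sigma2_m)
        V += (s or 0.0) * C
    ll, _, _, _ = _reml_loglik_terms(V, design.X, design.y)
    return ll


# ---------------------------------------------------------------------------
# Henderson mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(
    design: DesignBundle,
    grm: GRMatrix | None,
    components: VarianceComponents,
    epsilon: float = 1e-6,
    compute_loglik: bool = False,
) -> MMESolution:
    """Solve the mixed-model equations at fixed variance components.

    For the animal model the additive equations span the full GRM index, so
    unphenotyped candidates receive GEBV through their genomic covariances
    with the reference animals.  G is regularised with ``epsilon`` on the
    diagonal before inversion.
    """
    components.validate()
    y, X = design.y, design.X
    n = design.n_records
    p = X.shape[1]
    qm = len(design.dam_levels)
    L = _one_hot(design.dam_index, qm)

    if design.model == "animal":
        if components.sigma2_a is None or components.sigma2_a <= 0:
            raise ValueError("animal model requires sigma2_a > 0")
        qa = len(grm.ids)
        Z = np.zeros((n, qa))
        Z[np.arange(n), design.animal_index] = 1.0
        greg = regularize(grm, epsilon)
        try:
            c, low = sla.cho_factor(greg.values, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise NumericalError(
                "GRM is not positive definite after regularisation; "
                f"min eigenvalue ~ {np.linalg.eigvalsh(greg.values).min():.3e}"
            ) from exc
        ginv = sla.cho_solve((c, low), np.eye(qa), check_finite=False)
        lam_u = components.sigma2_e / components.sigma2_a
        ulab = grm.ids
    else:
        if components.sigma2_s is None or components.sigma2_s <= 0:
            raise ValueError("sire model requires sigma2_s > 0")
        qa = len(design.sire_levels)
        Z = _one_hot(design.sire_index, qa)
        ginv = np.eye(qa)
        lam_u = components.sigma2_e / components.sigma2_s
        ulab = design.sire_levels

    lam_m = np.inf if components.sigma2_m == 0 else components.sigma2_e / components.sigma2_m
    if np.isinf(lam_m):
        # maternal variance at the boundary: drop the term
        L = np.zeros((n, 0))
        qm = 0

    size = p + qm + qa
    C = np.zeros((size, size))
    rhs = np.concatenate([X.T @ y, L.T @ y, Z.T @ y])
    C[:p, :p] = X.T @ X
    C[:p, p:p + qm] = X.T @ L
    C[:p, p + qm:] = X.T @ Z
    C[p:p + qm, :p] = L.T @ X
    C[p:p + qm, p:p + qm] = L.T @ L + lam_m * np.eye(qm)
    C[p:p + qm, p + qm:] = L.T @ Z
    C[p + qm:, :p] = Z.T @ X
    C[p + qm:, p:p + qm] = Z.T @ L
    C[p + qm:, p + qm:] = Z.T @ Z + lam_u * ginv

    try:
        sol = sla.solve(C, rhs, assume_a="pos", check_finite=False)
    except sla.LinAlgError:
        sol, *_ = np.linalg.lstsq(C, rhs, rcond=None)

    b = sol[:p]
    m = sol[p:p + qm]
    u = sol[p + qm:]
    fitted = X @ b + (L @ m if qm else 0.0) + Z @ u
    resid = y - fitted

    maternal = pd.Series(m, index=design.dam_levels[:qm], name="maternal")
    fixed = pd.Series(b, index=design.fixed_levels, name="fixed")
    gebv = pd.Series(u, index=ulab, name="gebv") if design.model == "animal" else None
    sire = pd.Series(u, index=ulab, name="sire") if design.model == "sire" else None
    ll = reml_loglik(design, grm, components) if compute_loglik else None
    return MMESolution(fixed, maternal, gebv, sire, resid, components, ll)


def corrected_phenotypes(
    phenotypes_cb: pd.DataFrame,
    pedigree: pd.DataFrame,
    components: VarianceComponents | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Corrected phenotypes y_c = y - X b_hat - L m_hat = T s_hat + e_hat.

    Fits the sire model once on *all* supplied crossbred records of one
    trait (REML components estimated here unless given) and removes the
    estimated fixed and maternal effects from each record.
    """
    traits = phenotypes_cb["trait"].unique()
    if len(traits) != 1:
        raise ValueError("corrected_phenotypes expects records of a single trait")
    design = build_design(phenotypes_cb, model="sire", pedigree=pedigree)
    if components is None:
        components = reml_estimate(design, max_iter=max_iter, tol=tol)
        if components.sigma2_s is not None:
            components.sigma2_s = max(components.sigma2_s, 1e-8)
    sol = solve_mme(design, None, components)
    qm = len(sol.maternal)
    L = _one_hot(design.dam_index, len(design.dam_levels))[:, :qm]
    yc = design.y - design.X @ sol.fixed.to_numpy() - (L @ sol.maternal.to_numpy() if qm else 0.0)
    sire_of = dict(zip(pedigree["animal_id"], pedigree["sire_id"]))
    out = phenotypes_cb[["animal_id", "trait", "dam_id"]].copy()
    out["sire_id"] = out["animal_id"].map(sire_of)
    out["y_corrected"] = yc
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class GBLUP:
    """Genomic BLUP animal model for one trait.

    Parameters
    ----------
    phenotypes
        records of a single trait (columns animal_id, value, batch, pen,
        sex, age, dam_id).
    grm
        :class:`~crossblup.grm.GRMatrix` whose index covers every recorded
        animal; additional index entries are treated as candidates and
        receive GEBV.

    Examples
    --------
    >>> model = GBLUP(records, grm)             # doctest: +SKIP
    >>> res = model.fit()                       # doctest: +SKIP
    >>> res.gebv.loc[candidate_ids]             # doctest: +SKIP
    """

    def __init__(self, phenotypes: pd.DataFrame, grm: GRMatrix):
        self.grm = grm
        self.design = build_design(phenotypes, grm_ids=grm.ids, model="animal")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grm: GRMatrix, trait: str) -> "GBLUP":
        sub = df[df["trait"] == trait].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no records for trait {trait!r}")
        return cls(sub, grm)

    def fit(
        self,
        components: VarianceComponents | None = None,
        max_iter: int = 500,
        tol: float = 1e-8,
    ) -> "GBLUPResults":
        if components is None:
            components = reml_estimate(self.design, self.grm, max_iter=max_iter, tol=tol)
        solution = solve_mme(self.design, self.grm, components)
        return GBLUPResults(self, components, solution)


class GBLUPResults:
    """Fitted GBLUP model: variance components, solutions and GEBV."""

    def __init__(self, model: GBLUP, components: VarianceComponents, solution: MMESolution):
        self.model = model
        self.components = components
        self.solution = solution

    @property
    def gebv(self) -> pd.Series:
        return self.solution.gebv

    @property
    def h2(self) -> float:
        return self.components.h2

    @property
    def resid(self) -> np.ndarray:
        return self.solution.residuals

    def summary(self) -> str:
        c = self.components
        lines = [
            "GBLUP animal model",
            "==================",
            f"records:        {self.model.design.n_records}",
            f"GRM animals:    {len(self.model.grm.ids)} ({self.model.grm.kind})",
            f"fixed levels:   {len(self.model.design.fixed_levels)}",
            f"dams:           {len(self.model.design.dam_levels)}",
            f"sigma2_a:       {c.sigma2_a:.5f}",
            f"sigma2_m:       {c.sigma2_m:.5f}",
            f"sigma2_e:       {c.sigma2_e:.5f}",
            f"h2:             {c.h2:.4f}",
            f"REML loglik:    {c.loglik if c.loglik is None else round(c.loglik, 4)}"
            f" (converged={c.converged}, iter={c.n_iter})",
        ]
        return "\n".join(lines)


class SireModel:
    """Sire model used to produce corrected phenotypes for validation."""

    def __init__(self, phenotypes: pd.DataFrame, pedigree: pd.DataFrame):
        self.phenotypes = phenotypes.reset_index(drop=True)
        self.pedigree = pedigree
        self.design = build_design(self.phenotypes, model="sire", pedigree=pedigree)

    def fit(
        self,
        components: VarianceComponents | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> "SireModelResults":
        if components is None:
            components = reml_estimate(self.design, max_iter=max_iter, tol=tol)
        solution = solve_mme(self.design, None, components)
        return SireModelResults(self, components, solution)


class SireModelResults:
    def __init__(self, model: SireModel, components: VarianceComponents, solution: MMESolution):
        self.model = model
        self.components = components
        self.solution = solution

    def corrected_phenotypes(self) -> pd.DataFrame:
        design = self.model.design
        qm = len(self.solution.maternal)
        L = _one_hot(design.dam_index, len(design.dam_levels))[:, :qm]
        yc = design.y - design.X @ self.solution.fixed.to_numpy()
        if qm:
            yc = yc - L @ self.solution.maternal.to_numpy()
        sire_of = dict(zip(self.model.pedigree["animal_id"], self.model.pedigree["sire_id"]))
        out = self.model.phenotypes[["animal_id", "trait", "dam_id"]].copy()
        out["sire_id"] = out["animal_id"].map(sire_of)
        out["y_corrected"] = yc
        return out

    def summary(self) -> str:
        c = self.components
        return "\n".join(
            [
                "Sire model",
                "==========",
                f"records:   {self.model.design.n_records}",
                f"sires:     {len(self.model.design.sire_levels)}",
                f"sigma2_s:  {c.sigma2_s:.5f}",
                f"sigma2_m:  {c.sigma2_m:.5f}",
                f"sigma2_e:  {c.sigma2_e:.5f}",
            ]
        )
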