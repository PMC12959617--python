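"""Phylogenetic regression and multilevel models for heat tolerance.

Two model families are provided.

* PGLS with Pagel's λ for species-level responses (habitat thermal maxima
  and variability against realm and absolute latitude): the residual
  correlation is ``λ``-scaled Brownian, with λ estimated by maximising the
  profile likelihood over [0, 1].

* Linear mixed models for record-level heat tolerance with phylogenetic and
  species random intercepts (optionally population nested in species).  The
  phylogenetic effect is fully Brownian (λ fixed at 1) with its magnitude
  carried by its variance component; fitting is by REML, with an optional
  seeded MCMC backend (emcee) returning posterior summaries of the same
  shape.

Fixed-effect structures mirror the three heat-tolerance models: a latitude
model with cubic signed-latitude terms and their acclimation interactions
(model 1), a habitat model with maximum habitat temperature, thermal
variability and its acclimation interaction (model 2), and the habitat model
extended with realm contrasts (model 3).  All three carry an orthogonalised
quadratic acclimation term whose basis is stored with the fit so new-data
predictions and derivative (ARR) calculations reuse it exactly.

Mixed-model likelihoods use a Woodbury factorisation: with random-effect
loadings ``U`` the marginal covariance is ``V = σ²ₑI + U Uᵀ`` and all GLS
quantities reduce to solves against the (number-of-levels sized) capacitance
matrix, so each REML objective evaluation costs far less than a dense
n-by-n factorisation.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
from scipy import stats

__all__ = [
    "ModelId",
    "ModelSpec",
    "Design",
    "PhyloFit",
    "ConvergenceError",
    "MissingTipError",
    "phylo_correlation",
    "tree_tip_labels",
    "build_design",
    "fit_pgls",
    "fit_mixed",
    "fit_species_intercept_model",
    "r_squared",
]

CI_LEVEL = 0.95
_Z95 = stats.norm.ppf(0.5 + CI_LEVEL / 2)

REALM_LEVELS = ("marine", "freshwater", "brackish")  # marine is the reference


class ConvergenceError(RuntimeError):
    """Optimiser failed; carries the deviance trace for inspection."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class MissingTipError(KeyError):
    def __init__(self, names: Sequence[str]):
        super().__init__(f"species missing from tree: {', '.join(sorted(names))}")
        self.names = list(names)


class ModelId(str, enum.Enum):
    MODEL1 = "model1"
    MODEL2 = "model2"
    MODEL3 = "model3"
    PGLS_EXPOSURE = "pgls_exposure"
    DURATION = "duration_model"


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, on which response, with which random structure."""

    model_id: ModelId
    response: str = "heat_tolerance_std"
    random_terms: tuple[str, ...] = ("phylogeny", "species")
    backend: str = "reml"  # or "mcmc"

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", ModelId(self.model_id))
        allowed = {"phylogeny", "species", "population_in_species"}
        unknown = set(self.random_terms) - allowed
        if unknown:
            raise ValueError(f"unknown random terms: {unknown}")


# ---------------------------------------------------------------------------
# Phylogenetic correlation structure


def tree_tip_labels(tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_correlation(tree, species: Sequence[str], lam: float = 1.0) -> np.ndarray:
    """Among-species correlation implied by Brownian motion on the tree.

    Under Brownian evolution the trait covariance of two tips is the shared
    root-to-tip path length; normalising by the tip depths gives a
    correlation with unit diagonal.  Pagel's λ scales the off-diagonal
    entries, interpolating between a star phylogeny (λ = 0) and the full
    Brownian structure (λ = 1).  Warns if the tree is not ultrametric to
    within 1% of its depth.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    species = list(species)
    labels = {t.label: i for i, t in enumerate(tree.taxon_namespace)}
    missing = [s for s in species if s not in labels]
    if missing:
        raise MissingTipError(missing)

    tree.calc_node_root_distances()
    depth = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    depths = np.array([depth[s] for s in species])
    max_depth = depths.max()
    if max_depth <= 0:
        raise ValueError("tree has zero depth")
    if np.ptp(list(depth.values())) > 0.01 * max_depth:
        warnings.warn(
            "tree is not ultrametric; the lambda transform assumes "
            "contemporaneous tips", stacklevel=2,
        )

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(species)
    shared = np.zeros((n, n))
    for i, si in enumerate(species):
        shared[i, i] = depths[i]
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[si], taxa[species[j]])
            shared[i, j] = shared[j, i] = 0.5 * (depths[i] + depths[j] - dij)
    corr = shared / np.sqrt(np.outer(depths, depths))
    off = corr - np.diag(np.diag(corr))
    return np.eye(n) + lam * off


# ---------------------------------------------------------------------------
# Design matrices


@dataclass
class _AcctBasis:
    """Orthogonalised quadratic in standardised acclimation temperature.

    The column is the residual of AccT² on {1, AccT} over the fitted sample,
    scaled to unit norm: p₂(x) = (x² − a − b·x)/s.  Storing (a, b, s) lets
    predictions on new data and the analytic derivative reuse the exact
    fitted basis.
    """

    a: float
    b: float
    s: float

    @classmethod
    def fit(cls, x: np.ndarray) -> "_AcctBasis":
        x = np.asarray(x, float)
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: constant acclimation values")
        basis = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(basis, x * x, rcond=None)
        resid = x * x - basis @ coef
        s = float(np.linalg.norm(resid))
        if s == 0:
            raise ValueError("degenerate design: quadratic term collinear")
        return cls(a=float(coef[0]), b=float(coef[1]), s=s)

    def value(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return (x * x - self.a - self.b * x) / self.s

    def derivative(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return (2.0 * x - self.b) / self.s


def _realm_dummies(
    realm: np.ndarray, levels: Sequence[str]
) -> dict[str, np.ndarray]:
    """Treatment contrasts against the marine reference.

    ``levels`` are the non-reference levels represented in the fitted
    sample; values outside the reference plus those levels are rejected (a
    level absent at fit time cannot be predicted)."""
    realm = np.asarray(realm, dtype=object)
    unknown = set(np.unique(realm)) - {REALM_LEVELS[0], *levels}
    if unknown:
        raise ValueError(f"unknown or unfitted realm level(s): {sorted(unknown)}")
    return {lvl: (realm == lvl).astype(float) for lvl in levels}


@dataclass
class Design:
    """A fixed-effect design with enough metadata to rebuild rows for new data."""

    model_id: ModelId
    names: list[str]
    acct_basis: _AcctBasis | None = None
    realm_levels: tuple[str, ...] = REALM_LEVELS[1:]

    def matrix(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """Design matrix for (arrays of) predictor values.

        Recognised keys depend on the model: ``acclimation_std``,
        ``latitude``, ``abs_latitude``, ``max_habitat_temp``,
        ``thermal_variability``, ``realm``, ``log_duration``.
        """
        get = lambda k: np.asarray(data[k], float)
        mid = self.model_id
        if mid is ModelId.MODEL1:
            lat, acct = get("latitude"), get("acclimation_std")
            cols = [
                np.ones_like(lat), lat, lat**2, lat**3,
                acct, acct * lat, acct * lat**2, acct * lat**3,
                self.acct_basis.value(acct),
            ]
        elif mid in (ModelId.MODEL2, ModelId.MODEL3):
            maxt, tvar = get("max_habitat_temp"), get("thermal_variability")
            acct = get("acclimation_std")
            cols = [
                np.ones_like(maxt), maxt, tvar, acct, acct * tvar,
                self.acct_basis.value(acct),
            ]
            if mid is ModelId.MODEL3:
                dummies = _realm_dummies(
                    np.asarray(data["realm"]), self.realm_levels
                )
                cols += list(dummies.values())
                cols += [acct * d for d in dummies.values()]
        elif mid is ModelId.PGLS_EXPOSURE:
            alat = get("abs_latitude")
            cols = [np.ones_like(alat)]
            cols += list(
                _realm_dummies(np.asarray(data["realm"]), self.realm_levels).values()
            )
            cols += [alat, alat**2]
        elif mid is ModelId.DURATION:
            ld = get("log_duration")
            cols = [np.ones_like(ld), ld]
        else:  # pragma: no cover
            raise ValueError(mid)
        X = np.column_stack(cols)
        if X.shape[1] != len(self.names):
            raise AssertionError("design width mismatch")
        return X

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id.value,
            "names": self.names,
            "realm_levels": list(self.realm_levels),
        }
        if self.acct_basis is not None:
            d["acct_basis"] = [self.acct_basis.a, self.acct_basis.b, self.acct_basis.s]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Design":
        basis = d.get("acct_basis")
        return cls(
            model_id=ModelId(d["model_id"]),
            names=list(d["names"]),
            acct_basis=None if basis is None else _AcctBasis(*basis),
            realm_levels=tuple(d.get("realm_levels", REALM_LEVELS[1:])),
        )


def _column_names(mid: ModelId, realm_levels: Sequence[str]) -> list[str]:
    if mid is ModelId.MODEL1:
        return [
            "intercept", "lat", "lat^2", "lat^3", "acct", "acct:lat",
            "acct:lat^2", "acct:lat^3", "acct_q2",
        ]
    if mid is ModelId.MODEL2:
        return [
            "intercept", "max_habitat_temp", "thermal_variability", "acct",
            "acct:tvar", "acct_q2",
        ]
    if mid is ModelId.MODEL3:
        return (
            _column_names(ModelId.MODEL2, realm_levels)
            + [f"realm[{lvl}]" for lvl in realm_levels]
            + [f"acct:realm[{lvl}]" for lvl in realm_levels]
        )
    if mid is ModelId.PGLS_EXPOSURE:
        return (
            ["intercept"]
            + [f"realm[{lvl}]" for lvl in realm_levels]
            + ["abs_lat", "abs_lat^2"]
        )
    if mid is ModelId.DURATION:
        return ["intercept", "log_duration"]
    raise ValueError(mid)  # pragma: no cover


def build_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, Design]:
    """Response vector and design matrix for one of the named models.

    The table must use the package's canonical column names (as produced by
    the harmonisation and exposure stages).  The orthogonal quadratic
    acclimation basis is fitted on this sample and kept in the returned
    :class:`Design`.  Raises on rank-deficient designs, naming the
    offending columns.
    """
    mid = spec.model_id
    realm_levels: tuple[str, ...] = REALM_LEVELS[1:]
    if mid in (ModelId.MODEL3, ModelId.PGLS_EXPOSURE):
        present = set(np.unique(np.asarray(table["realm"], dtype=object)))
        unknown = present - set(REALM_LEVELS)
        if unknown:
            raise ValueError(f"unknown realm level(s): {sorted(unknown)}")
        realm_levels = tuple(l for l in REALM_LEVELS[1:] if l in present)
    design = Design(
        model_id=mid, names=_column_names(mid, realm_levels),
        realm_levels=realm_levels,
    )
    data = {c: table[c].to_numpy() for c in table.columns}
    if "latitude" in table.columns and "abs_latitude" not in data:
        data["abs_latitude"] = np.abs(data["latitude"].astype(float))
    if mid in (ModelId.MODEL1, ModelId.MODEL2, ModelId.MODEL3):
        design.acct_basis = _AcctBasis.fit(
            np.asarray(table["acclimation_std"], float)
        )
    X = design.matrix(data)
    y = table[spec.response].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [design.names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return y, X, design


# ---------------------------------------------------------------------------
# Fit container


@dataclass
class PhyloFit:
    """Coefficients, variance components and fit statistics of one model."""

    model_id: ModelId
    backend: str
    coef: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, p
    varcomp: dict[str, float]  # name -> sigma^2 (includes "residual")
    lambda_: float | None
    r2_marginal: float
    r2_conditional: float
    log_likelihood: float
    n_obs: int
    n_species: int
    design: Design
    coef_cov: np.ndarray | None = None
    seed: int | None = None
    n_iterations: int | None = None
    trace: list[float] = field(default_factory=list, repr=False)

    @property
    def coefficients(self) -> pd.Series:
        return self.coef["estimate"]

    def predict(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """Fixed-effect prediction for new data (uses the stored basis)."""
        X = self.design.matrix(data)
        return X @ self.coef["estimate"].to_numpy()

    def predict_se(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """SE of the fixed-effect prediction, from the coefficient covariance."""
        if self.coef_cov is None:
            raise ValueError("fit carries no coefficient covariance")
        X = self.design.matrix(data)
        return np.sqrt(np.einsum("ij,jk,ik->i", X, self.coef_cov, X))

    # -- serialisation -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "model_id": self.model_id.value,
            "backend": self.backend,
            "coef": {
                "index": list(self.coef.index),
                "columns": list(self.coef.columns),
                "data": self.coef.to_numpy().tolist(),
            },
            "varcomp": self.varcomp,
            "lambda": self.lambda_,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "n_species": self.n_species,
            "design": self.design.to_dict(),
            "coef_cov": None if self.coef_cov is None else self.coef_cov.tolist(),
            "seed": self.seed,
            "n_iterations": self.n_iterations,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PhyloFit":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        coef = pd.DataFrame(
            payload["coef"]["data"],
            index=payload["coef"]["index"],
            columns=payload["coef"]["columns"],
        )
        cov = payload.get("coef_cov")
        return cls(
            model_id=ModelId(payload["model_id"]),
            backend=payload["backend"],
            coef=coef,
            varcomp={k: float(v) for k, v in payload["varcomp"].items()},
            lambda_=payload.get("lambda"),
            r2_marginal=payload["r2_marginal"],
            r2_conditional=payload["r2_conditional"],
            log_likelihood=payload["log_likelihood"],
            n_obs=payload["n_obs"],
            n_species=payload["n_species"],
            design=Design.from_dict(payload["design"]),
            coef_cov=None if cov is None else np.asarray(cov),
            seed=payload.get("seed"),
            n_iterations=payload.get("n_iterations"),
        )


def _coef_table(
    names: Sequence[str], beta: np.ndarray, se: np.ndarray, df: float | None = None
) -> pd.DataFrame:
    if df is None:
        p = 2 * stats.norm.sf(np.abs(beta / se))
        crit = _Z95
    else:
        p = 2 * stats.t.sf(np.abs(beta / se), df)
        crit = stats.t.ppf(0.5 + CI_LEVEL / 2, df)
    return pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - crit * se,
            "ci_high": beta + crit * se,
            "p": p,
        },
        index=list(names),
    )


def r_squared(fit: PhyloFit, X: np.ndarray) -> tuple[float, float]:
    """Marginal and conditional R² (variance-partition definition).

    Marginal: variance of the fixed-effect predictions over the total
    (fixed + summed random variances + residual); conditional adds the
    random-effect variances to the numerator.
    """
    beta = fit.coef["estimate"].to_numpy()
    var_fixed = float(np.var(X @ beta))
    var_random = sum(v for k, v in fit.varcomp.items() if k != "residual")
    var_resid = fit.varcomp.get("residual", 0.0)
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("zero total variance; R^2 undefined")
    return var_fixed / total, (var_fixed + var_random) / total


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda


def fit_pgls(
    y: np.ndarray,
    X: np.ndarray,
    tree,
    species: Sequence[str],
    design: Design | None = None,
    lambda_fixed: float | None = None,
) -> PhyloFit:
    """Generalised least squares with λ-scaled Brownian residual correlation.

    One row per species.  λ is profiled over [0, 1] (grid scan plus bounded
    refinement) unless ``lambda_fixed`` is given; at λ = 0 the estimates
    coincide with OLS.  t statistics use n − p residual degrees of freedom.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if len(species) != n:
        raise ValueError("species labels must match rows")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient PGLS design")

    C = phylo_correlation(tree, species, lam=1.0)
    evals, evecs = np.linalg.eigh(C)
    yt = evecs.T @ y
    Xt = evecs.T @ X

    def profile(lam: float) -> tuple[float, np.ndarray, float]:
        w = lam * evals + (1.0 - lam)
        w = np.maximum(w, 1e-12)
        sw = 1.0 / np.sqrt(w)
        Xw = Xt * sw[:, None]
        yw = yt * sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        neg2ll = float(np.log(w).sum() + n * np.log(rss / n))
        return neg2ll, beta, rss

    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
    else:
        grid = np.linspace(0, 1, 21)
        grid_vals = [profile(g)[0] for g in grid]
        g0 = grid[int(np.argmin(grid_vals))]
        lo, hi = max(0.0, g0 - 0.05), min(1.0, g0 + 0.05)
        res = opt.minimize_scalar(
            lambda l: profile(l)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x) if profile(res.x)[0] <= min(grid_vals) else float(g0)

    neg2ll, beta, rss = profile(lam_hat)
    w = np.maximum(lam_hat * evals + (1.0 - lam_hat), 1e-12)
    Xw = Xt / np.sqrt(w)[:, None]
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    names = design.names if design is not None else [f"x{j}" for j in range(p)]
    coef = _coef_table(names, beta, se, df=n - p)

    var_fixed = float(np.var(X @ beta))
    # split the GLS residual variance into its phylogenetic share (lambda)
    var_phylo = lam_hat * sigma2
    var_resid = (1.0 - lam_hat) * sigma2
    total = var_fixed + sigma2
    fit = PhyloFit(
        model_id=design.model_id if design is not None else ModelId.PGLS_EXPOSURE,
        backend="pgls",
        coef=coef,
        varcomp={"phylogeny": var_phylo, "residual": var_resid},
        lambda_=lam_hat,
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_phylo) / total,
        log_likelihood=-0.5 * (neg2ll + n * (1 + np.log(2 * np.pi))),
        n_obs=n,
        n_species=n,
        design=design if design is not None else Design(ModelId.PGLS_EXPOSURE, names),
        coef_cov=cov,
    )
    return fit


# ---------------------------------------------------------------------------
# Linear mixed models via Woodbury REML


class _MixedWorkspace:
    """Precomputed cross-products for fast REML objective evaluations.

    Random structure j contributes loading ``Z_j L_j σ_j`` with ``L_j`` the
    Cholesky factor of its level-correlation (identity for iid intercepts,
    the Brownian correlation for the phylogenetic term).  All σ-free
    cross-products are formed once; each objective evaluation only rescales
    blocks and factorises the capacitance matrix.
    """

    def __init__(
        self, y: np.ndarray, X: np.ndarray,
        structures: list[tuple[str, np.ndarray, np.ndarray | None]],
    ):
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.names = [name for name, _, _ in structures]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.blocks: list[np.ndarray] = []  # B_j = Z_j @ L_j  (n x q_j)
        for _, Z, corr in structures:
            if corr is None:
                self.blocks.append(Z)
            else:
                # eigen-based PSD square root tolerates tiny negative modes
                ev, evec = np.linalg.eigh(corr)
                L = evec * np.sqrt(np.maximum(ev, 0.0))
                self.blocks.append(Z @ L)
        self.q = [B.shape[1] for B in self.blocks]
        self.Q = int(np.sum(self.q))
        B = np.hstack(self.blocks) if self.blocks else np.zeros((self.n, 0))
        self.B = B
        self.BtB = B.T @ B
        self.BtX = B.T @ X
        self.Bty = B.T @ y
        self.offsets = np.concatenate([[0], np.cumsum(self.q)])

    def _scale(self, sig: np.ndarray) -> np.ndarray:
        s = np.empty(self.Q)
        for j, sj in enumerate(sig):
            s[self.offsets[j]:self.offsets[j + 1]] = sj
        return s

    def gls(self, sigma2: np.ndarray, sigma2_e: float):
        """GLS building blocks at the given variance components.

        Returns (beta, cov_unscaled=XtViX^-1, quad=y'Py, logdetV, logdetXtViX).
        """
        s = self._scale(np.sqrt(sigma2))
        M = sigma2_e * np.eye(self.Q) + (s[:, None] * self.BtB) * s[None, :]
        cf = sla.cho_factor(M, lower=True)
        logdetM = 2.0 * np.log(np.diag(cf[0])).sum()
        logdetV = (self.n - self.Q) * np.log(sigma2_e) + logdetM

        BtX_s = s[:, None] * self.BtX
        Bty_s = s * self.Bty
        XtViX = (self.XtX - BtX_s.T @ sla.cho_solve(cf, BtX_s)) / sigma2_e
        XtViy = (self.Xty - BtX_s.T @ sla.cho_solve(cf, Bty_s)) / sigma2_e
        ytViy = (self.yty - Bty_s @ sla.cho_solve(cf, Bty_s)) / sigma2_e
        cfx = sla.cho_factor(XtViX, lower=True)
        beta = sla.cho_solve(cfx, XtViy)
        logdetXtViX = 2.0 * np.log(np.diag(cfx[0])).sum()
        quad = float(ytViy - beta @ XtViy)
        return beta, XtViX, quad, logdetV, logdetXtViX

    def reml_deviance(self, log_params: np.ndarray) -> float:
        sigma2 = np.exp(log_params[:-1])
        sigma2_e = float(np.exp(log_params[-1]))
        try:
            _, _, quad, logdetV, logdetX = self.gls(sigma2, sigma2_e)
        except np.linalg.LinAlgError:
            return np.inf
        return logdetV + logdetX + quad


def _build_structures(
    tree, species_ids: np.ndarray, random_terms: Sequence[str],
    population_ids: np.ndarray | None,
) -> tuple[list[tuple[str, np.ndarray, np.ndarray | None]], int]:
    codes, levels = pd.factorize(species_ids, sort=True)
    n = len(species_ids)
    Zs = np.zeros((n, len(levels)))
    Zs[np.arange(n), codes] = 1.0
    structures: list[tuple[str, np.ndarray, np.ndarray | None]] = []
    for term in random_terms:
        if term == "phylogeny":
            if tree is None:
                raise ValueError("phylogeny random term requires a tree")
            C = phylo_correlation(tree, list(levels), lam=1.0)
            structures.append(("phylogeny", Zs, C))
        elif term == "species":
            structures.append(("species", Zs, None))
        elif term == "population_in_species":
            if population_ids is None:
                raise ValueError("population term requires population ids")
            pcodes, plevels = pd.factorize(population_ids, sort=True)
            Zp = np.zeros((n, len(plevels)))
            Zp[np.arange(n), pcodes] = 1.0
            structures.append(("population_in_species", Zp, None))
    return structures, len(levels)


def fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    tree,
    species_ids: Sequence[str],
    spec: ModelSpec,
    design: Design | None = None,
    population_ids: Sequence | None = None,
    seed: int | None = None,
    mcmc_steps: int = 600,
    mcmc_burn: int = 200,
) -> PhyloFit:
    """Fit a linear mixed model with phylogenetic/species random intercepts.

    The default backend maximises the restricted likelihood over the
    variance components (Nelder–Mead on their logs); the phylogenetic random
    effect is correlated by the full Brownian structure (λ = 1), its
    magnitude carried by σ²_phylo.  The ``mcmc`` backend samples the
    variance components under the same marginal likelihood (flat priors on
    the log variances) with emcee and draws coefficients from their
    conditional Gaussian; both backends return the same ``PhyloFit`` shape.

    Confidence intervals are Wald 95% intervals (posterior quantiles for
    MCMC).  A variance component collapsing to the boundary produces a
    warning, not an error.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    species_ids = np.asarray(species_ids)
    structures, n_species = _build_structures(
        tree, species_ids, spec.random_terms,
        None if population_ids is None else np.asarray(population_ids),
    )
    ws = _MixedWorkspace(y, X, structures)
    k = len(structures)

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = max(float(np.var(y - X @ ols_beta)), 1e-6)
    x0 = np.log(np.r_[np.full(k, resid_var / (k + 1)), resid_var / 2])

    trace: list[float] = []

    def objective(phi: np.ndarray) -> float:
        val = ws.reml_deviance(phi)
        if np.isfinite(val) and (not trace or val < trace[-1]):
            trace.append(val)
        return val

    res = opt.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000},
    )
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError("REML optimisation failed", trace)
    phi = res.x
    sigma2 = np.exp(phi[:-1])
    sigma2_e = float(np.exp(phi[-1]))

    total_var = sigma2.sum() + sigma2_e
    for name, s2 in zip(ws.names, sigma2):
        if s2 < 1e-6 * total_var:
            warnings.warn(
                f"variance component '{name}' collapsed to the boundary",
                stacklevel=2,
            )

    beta, XtViX, quad, logdetV, logdetX = ws.gls(sigma2, sigma2_e)
    cov = np.linalg.inv(XtViX)
    n, p = X.shape
    reml_ll = -0.5 * (logdetV + logdetX + quad + (n - p) * np.log(2 * np.pi))
    varcomp = {name: float(s2) for name, s2 in zip(ws.names, sigma2)}
    varcomp["residual"] = sigma2_e

    if spec.backend == "mcmc":
        return _mcmc_refit(
            ws, spec, design, varcomp, phi, n_species, seed, mcmc_steps, mcmc_burn,
        )

    se = np.sqrt(np.diag(cov))
    names = design.names if design is not None else [f"x{j}" for j in range(p)]
    coef = _coef_table(names, beta, se, df=None)
    fit = PhyloFit(
        model_id=design.model_id if design is not None else spec.model_id,
        backend="reml",
        coef=coef,
        varcomp=varcomp,
        lambda_=None,
        r2_marginal=0.0,
        r2_conditional=0.0,
        log_likelihood=float(reml_ll),
        n_obs=n,
        n_species=n_species,
        design=design if design is not None else Design(spec.model_id, list(names)),
        coef_cov=cov,
        seed=seed,
        trace=trace,
    )
    fit.r2_marginal, fit.r2_conditional = r_squared(fit, X)
    return fit


def _mcmc_refit(
    ws: _MixedWorkspace, spec: ModelSpec, design: Design | None,
    reml_varcomp: dict, phi_hat: np.ndarray, n_species: int,
    seed: int | None, steps: int, burn: int,
) -> PhyloFit:
    """Posterior sampling of the variance components, then of coefficients.

    The marginal likelihood of the log variances (fixed effects integrated
    out under a flat prior) is the REML likelihood, so sampling the
    variance parameters against it and then drawing β from its conditional
    Gaussian yields draws from the joint posterior.
    """
    import emcee

    ndim = len(phi_hat)
    nwalkers = max(8, 2 * ndim + 2)
    rng = np.random.default_rng(0 if seed is None else seed)

    def log_prob(phi: np.ndarray) -> float:
        if np.any(np.abs(phi) > 18):
            return -np.inf
        val = ws.reml_deviance(phi)
        return -0.5 * val if np.isfinite(val) else -np.inf

    p0 = phi_hat + 0.05 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(
        0 if seed is None else seed
    ).get_state()
    sampler.run_mcmc(p0, steps, progress=False)
    chain = sampler.get_chain(discard=burn, thin=4, flat=True)

    betas, sigs = [], []
    for phi in chain:
        sigma2 = np.exp(phi[:-1])
        sigma2_e = float(np.exp(phi[-1]))
        beta, XtViX, *_ = ws.gls(sigma2, sigma2_e)
        L = np.linalg.cholesky(np.linalg.inv(XtViX))
        betas.append(beta + L @ rng.standard_normal(ws.p))
        sigs.append(np.r_[sigma2, sigma2_e])
    betas = np.asarray(betas)
    sigs = np.asarray(sigs)

    est = betas.mean(axis=0)
    se = betas.std(axis=0, ddof=1)
    lo, hi = np.percentile(betas, [2.5, 97.5], axis=0)
    p_two = 2 * np.minimum((betas > 0).mean(axis=0), (betas < 0).mean(axis=0))
    names = design.names if design is not None else [f"x{j}" for j in range(ws.p)]
    coef = pd.DataFrame(
        {"estimate": est, "se": se, "ci_low": lo, "ci_high": hi, "p": p_two},
        index=list(names),
    )
    varcomp = {n_: float(v) for n_, v in zip(ws.names, sigs[:, :-1].mean(axis=0))}
    varcomp["residual"] = float(sigs[:, -1].mean())
    fit = PhyloFit(
        model_id=design.model_id if design is not None else spec.model_id,
        backend="mcmc",
        coef=coef,
        varcomp=varcomp,
        lambda_=None,
        r2_marginal=0.0,
        r2_conditional=0.0,
        log_likelihood=float(np.max(sampler.get_log_prob(flat=True))),
        n_obs=ws.n,
        n_species=n_species,
        design=design if design is not None else Design(spec.model_id, list(names)),
        coef_cov=np.cov(betas.T),
        seed=seed,
        n_iterations=steps,
    )
    fit.r2_marginal, fit.r2_conditional = r_squared(fit, ws.X)
    return fit


# ---------------------------------------------------------------------------
# Fast species-intercept regression (duration-slope bootstrap inner loop)


def fit_species_intercept_model(
    y: np.ndarray, x: np.ndarray, species: np.ndarray, tree=None
) -> float:
    """Slope of ``y ~ x`` with a species random intercept; returns the slope.

    Without a tree this profiles the single variance ratio γ = σ²_sp/σ²_e in
    closed form per group (block-diagonal Woodbury), which keeps the
    bootstrap inner loop fast.  With a tree it defers to the general REML
    machinery with phylogenetic + species intercepts.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if tree is not None:
        spec = ModelSpec(ModelId.DURATION, random_terms=("phylogeny", "species"))
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_mixed(y, X, tree, species, spec)
        return float(fit.coef["estimate"].iloc[1])

    codes, levels = pd.factorize(np.asarray(species), sort=True)
    order = np.argsort(codes, kind="stable")
    y, x, codes = y[order], x[order], codes[order]
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    X = np.column_stack([np.ones_like(x), x])
    n, p = X.shape

    sum_X = np.add.reduceat(X, starts, axis=0)
    sum_y = np.add.reduceat(y, starts)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def neg2reml(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        f = g / (1.0 + g * counts)  # per-group shrink factor
        A = XtX - (sum_X * f[:, None]).T @ sum_X
        b = Xty - (sum_X * f[:, None]).T @ sum_y
        q = yty - float(f @ (sum_y**2))
        sign, logdetA = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        if rss <= 0 or sign <= 0:
            return np.inf
        return (
            float(np.log1p(g * counts).sum()) + logdetA + (n - p) * np.log(rss)
        )

    res = opt.minimize_scalar(neg2reml, bounds=(-12.0, 12.0), method="bounded")
    g = float(np.exp(res.x))
    f = g / (1.0 + g * counts)
    A = XtX - (sum_X * f[:, None]).T @ sum_X
    b = Xty - (sum_X * f[:, None]).T @ sum_y
    beta = np.linalg.solve(A, b)
    return float(beta[1])
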