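"""REML mixed models for trial analysis: BLUEs, BLUPs, heritability, G x E.

The workhorse model is the alpha-lattice analysis

    y_ijk = mu + g_i + r_j + b_k(j) + e_ijk

with genotype g either fixed (BLUE model) or random (BLUP model), replicate
r and incomplete block b(j) random, and iid Normal residuals.  Variance
components are estimated by REML: monotone EM steps on the mixed-model
equations (cheap, guaranteed ascent) followed by Fisher-scoring polish with
step halving (fast terminal convergence); variances are constrained
nonnegative and boundary hits are flagged.

Pedigree information enters through the additive (numerator) relationship
matrix A — twice the coefficient of parentage — built by the tabular
method; correlated genotype effects g ~ N(0, A sigma_g^2) are reduced to
independent effects by multiplying the genotype design with a Cholesky
factor of A.  The genotype-by-environment model adds an independent g x e
term and per-environment design terms.

Heritability: broad-sense H^2 (repeatability) and narrow-sense h^2_a are
reported on an entry-mean basis by default (sigma_g^2 over the variance of
a genotype mean), with a plot basis available; standard errors come from
the inverse expected-information matrix via the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .trial import Pedigree

__all__ = [
    "RandomTerm",
    "MixedModelSpec",
    "VarianceComponents",
    "MixedModelFit",
    "blue_spec",
    "blup_spec",
    "fit_reml",
    "reml_loglik",
    "compute_blues",
    "compute_blups",
    "broad_sense_heritability",
    "narrow_sense_heritability",
    "additive_relationship",
    "RelationshipMatrix",
    "fit_gxe",
    "spearman_with_test",
    "adjust_for_flights",
]

_MAX_EM_ITER = 500
_EM_TOL = 1e-8
_BOUND_FRAC = 1e-10  # component below this fraction of var(y) pins to the boundary


class RankError(np.linalg.LinAlgError):
    """Fixed-effect design is rank deficient."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class RandomTerm:
    """One random term: an (interaction of) grouping factor(s), optionally
    with a relationship matrix over the levels of the term."""

    factors: tuple[str, ...]
    relationship: np.ndarray | None = None
    relationship_ids: tuple[str, ...] | None = None

    @property
    def name(self) -> str:
        return ":".join(self.factors)


@dataclass(frozen=True)
class MixedModelSpec:
    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()

    def __post_init__(self) -> None:
        n_geno = ("genotype" in self.fixed) + sum(
            t.factors == ("genotype",) for t in self.random
        )
        if n_geno != 1:
            raise ValueError("the genotype term must appear exactly once (fixed or random)")


def blue_spec(response: str = "ph_cm") -> MixedModelSpec:
    """Genotype fixed; replicate and block-within-replicate random."""
    return MixedModelSpec(
        response=response,
        fixed=("genotype",),
        random=(RandomTerm(("rep",)), RandomTerm(("rep", "block"))),
    )


def blup_spec(response: str = "ph_cm") -> MixedModelSpec:
    """Genotype random (shrunken predictions); design terms random."""
    return MixedModelSpec(
        response=response,
        fixed=(),
        random=(RandomTerm(("genotype",)), RandomTerm(("rep",)), RandomTerm(("rep", "block"))),
    )


@dataclass
class VarianceComponents:
    components: dict[str, float]  # term name -> variance
    sigma2_e: float
    cov: np.ndarray  # asymptotic covariance, order: components..., sigma2_e
    names: list[str]  # row/col labels of cov
    boundary: dict[str, bool]
    n_iter: int
    converged: bool
    grad_norm: float


@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    vc: VarianceComponents
    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    blups: dict[str, pd.Series]  # term name -> level-indexed predictions
    loglik: float
    n: int
    p: int
    data: pd.DataFrame
    _X_col_means: np.ndarray | None = None


# ---------------------------------------------------------------------------
# design construction


def _term_levels(data: pd.DataFrame, factors: tuple[str, ...]) -> pd.Series:
    s = data[factors[0]].astype(str)
    for f in factors[1:]:
        s = s + "/" + data[f].astype(str)
    return s


def _dummies(codes: pd.Series, drop_first: bool = False) -> tuple[np.ndarray, list[str]]:
    levels = sorted(codes.unique())
    if drop_first:
        levels_used = levels[1:]
    else:
        levels_used = levels
    idx = {lv: j for j, lv in enumerate(levels_used)}
    Z = np.zeros((len(codes), len(levels_used)))
    for i, c in enumerate(codes):
        j = idx.get(c)
        if j is not None:
            Z[i, j] = 1.0
    return Z, levels_used


def _fixed_design(data: pd.DataFrame, fixed: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones((len(data), 1))]
    names = ["(intercept)"]
    for f in fixed:
        Z, lv = _dummies(data[f].astype(str), drop_first=True)
        cols.append(Z)
        names.extend(f"{f}[{v}]" for v in lv)
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased columns via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        r = np.linalg.matrix_rank(X)
        aliased = [names[j] for j in piv[r:]]
        raise RankError(f"fixed-effect design is rank deficient; aliased: {aliased}")
    return X, names


def _chol_with_ridge(A: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.cholesky(A + ridge * np.eye(A.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "relationship matrix not positive semidefinite even after ridge"
            ) from exc


def _random_designs(
    data: pd.DataFrame, random: tuple[RandomTerm, ...]
) -> tuple[list[np.ndarray], list[list[str]], list[np.ndarray | None]]:
    Zs, level_lists, Ls = [], [], []
    for term in random:
        codes = _term_levels(data, term.factors)
        if term.relationship is not None:
            ids = list(term.relationship_ids or [])
            if not ids:
                raise ValueError(f"term {term.name}: relationship matrix needs level ids")
            missing = sorted(set(codes.unique()) - set(ids))
            if missing:
                raise ValueError(f"term {term.name}: levels missing from relationship: {missing}")
            idx = {lv: j for j, lv in enumerate(ids)}
            Z = np.zeros((len(codes), len(ids)))
            for i, c in enumerate(codes):
                Z[i, idx[c]] = 1.0
            L = _chol_with_ridge(np.asarray(term.relationship, dtype=float))
            Zs.append(Z @ L)
            level_lists.append(ids)
            Ls.append(L)
        else:
            Z, lv = _dummies(codes, drop_first=False)
            Zs.append(Z)
            level_lists.append(lv)
            Ls.append(None)
    return Zs, level_lists, Ls


# ---------------------------------------------------------------------------
# restricted likelihood machinery


def _build_V(sigmas: np.ndarray, sigma_e: float, Zs: list[np.ndarray], n: int) -> np.ndarray:
    V = sigma_e * np.eye(n)
    for s, Z in zip(sigmas, Zs):
        if s > 0:
            V += s * (Z @ Z.T)
    return V


def reml_loglik(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    sigmas: np.ndarray,
    sigma_e: float,
) -> float:
    """Restricted log-likelihood at the given variance components."""
    n, p = X.shape
    V = _build_V(np.asarray(sigmas, float), float(sigma_e), Zs, n)
    cf = linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    Py = Viy - ViX @ beta
    return -0.5 * (logdetV + logdetXtViX + float(y @ Py) + (n - p) * math.log(2 * math.pi))


def _P_matrix(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    cf = linalg.cho_factor(V, lower=True)
    Vi = linalg.cho_solve(cf, np.eye(V.shape[0]))
    ViX = Vi @ X
    XtViX_inv = np.linalg.inv(X.T @ ViX)
    return Vi - ViX @ XtViX_inv @ ViX.T


def _score_and_info(
    y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], sigmas: np.ndarray, sigma_e: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """REML score and expected information for (sigmas..., sigma_e)."""
    n = len(y)
    V = _build_V(sigmas, sigma_e, Zs, n)
    P = _P_matrix(V, X)
    Py = P @ y
    m = len(Zs)
    score = np.zeros(m + 1)
    PZ = [P @ Z for Z in Zs]
    for i, Z in enumerate(Zs):
        trPVi = float(np.sum(Z * PZ[i]))  # tr(P Z Z') = sum(Z o PZ)
        quad = float((Py @ Z) @ (Z.T @ Py))
        score[i] = -0.5 * (trPVi - quad)
    score[m] = -0.5 * (np.trace(P) - float(Py @ Py))
    info = np.zeros((m + 1, m + 1))
    ZtPZ = [[Zs[i].T @ PZ[j] for j in range(m)] for i in range(m)]
    for i in range(m):
        for j in range(i, m):
            val = 0.5 * float(np.sum(ZtPZ[i][j] * ZtPZ[j][i].T))
            info[i, j] = info[j, i] = val
        # cross with residual: 0.5 tr(P Vi P) = 0.5 ||P Z_i||_F^2
        val = 0.5 * float(np.sum(PZ[i] * PZ[i]))
        info[i, m] = info[m, i] = val
    info[m, m] = 0.5 * float(np.sum(P * P))
    return score, info, P


# ---------------------------------------------------------------------------
# the REML driver


def fit_reml(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelFit:
    """REML fit of a variance-components mixed model.

    EM steps on the mixed-model equations (monotone in the restricted
    likelihood) run until the components stabilize, then Fisher scoring with
    step halving polishes the estimates to tight tolerance.  Variances are
    kept nonnegative; a component collapsing to zero is pinned there and
    flagged as a boundary estimate.
    """
    needed = [spec.response, *spec.fixed]
    for t in spec.random:
        needed.extend(t.factors)
    data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    for col in dict.fromkeys(needed):
        if col not in data.columns:
            raise KeyError(f"column {col!r} missing from data")
    y = data[spec.response].to_numpy(dtype=float)
    X, fixed_names = _fixed_design(data, spec.fixed)
    n, p = X.shape
    if n <= p + len(spec.random):
        raise ValueError(f"{n} rows cannot support {p} fixed parameters plus variance terms")
    Zs, level_lists, Ls = _random_designs(data, spec.random)
    m = len(Zs)
    var_y = float(np.var(y))
    if var_y == 0.0:
        return _constant_response_fit(data, spec, y, X, fixed_names, Zs, level_lists, Ls)

    W = np.hstack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    q = [Z.shape[1] for Z in Zs]
    offs = np.concatenate([[p], p + np.cumsum(q)]).astype(int)
    slices = [slice(offs[i], offs[i + 1]) for i in range(m)]

    sigmas = np.full(m, var_y / (2 * max(m, 1)))
    sigma_e = var_y / 2.0
    bound_tol = _BOUND_FRAC * var_y
    trace: list[dict] = []
    converged = False
    it = 0
    max_em = 60  # scoring finishes the job; EM only needs to reach the basin
    for it in range(1, max_em + 1):
        lam = np.where(sigmas > bound_tol, sigma_e / np.maximum(sigmas, bound_tol), 1e12)
        # tiny ridge keeps the MME factorizable when sigma_e collapses on
        # noiseless data (random-effect dummies are collinear with X)
        ridge = 1e-10 * float(np.mean(np.diag(WtW)))
        C = WtW.copy()
        for k in range(m):
            idx = np.arange(slices[k].start, slices[k].stop)
            C[idx, idx] += lam[k] + ridge
        cf = linalg.cho_factor(C, lower=True)
        sol = linalg.cho_solve(cf, Wty)
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]))
        new_sigmas = np.empty(m)
        for k in range(m):
            u = sol[slices[k]]
            trace_kk = float(np.trace(Cinv[slices[k], slices[k]]))
            new_sigmas[k] = (float(u @ u) + sigma_e * trace_kk) / q[k]
        new_sigma_e = max((yty - float(sol @ Wty)) / (n - p), 1e-12 * var_y)
        delta = max(
            abs(new_sigma_e - sigma_e) / max(sigma_e, 1e-12),
            max(
                (abs(ns - s) / max(s, 1e-12) for ns, s in zip(new_sigmas, sigmas)),
                default=0.0,
            ),
        )
        sigmas, sigma_e = new_sigmas, new_sigma_e
        trace.append({"iter": it, "sigmas": sigmas.copy(), "sigma_e": sigma_e, "delta": delta})
        if delta < 1e-4:  # hand over to scoring once EM has stabilized coarsely
            break

    # Fisher-scoring polish (guarded ascent; quadratic terminal convergence)
    e_floor = 1e-12 * var_y
    free = sigmas > bound_tol
    ll = reml_loglik(y, X, Zs, sigmas, sigma_e)
    grad_norm = np.inf
    if sigma_e <= 2 * e_floor:
        # perfect fit: residual variance pinned at the boundary, nothing
        # for scoring to improve
        converged = True
        grad_norm = 0.0
    for _ in range(100 if not converged else 0):
        it += 1
        score, info, _ = _score_and_info(y, X, Zs, sigmas, sigma_e)
        active = np.concatenate([free, [True]])
        grad_norm = float(np.linalg.norm(score[active]))
        sub_info = info[np.ix_(active, active)]
        try:
            step_act = np.linalg.solve(sub_info + 1e-12 * np.eye(sub_info.shape[0]), score[active])
        except np.linalg.LinAlgError:
            break
        step = np.zeros(m + 1)
        step[active] = step_act
        scale = 1.0
        improved = False
        for _half in range(30):
            cand = np.concatenate([sigmas, [sigma_e]]) + scale * step
            cand[:m] = np.maximum(cand[:m], 0.0)
            cand[m] = max(cand[m], 1e-12 * var_y)
            ll_cand = reml_loglik(y, X, Zs, cand[:m], cand[m])
            if ll_cand >= ll - 1e-12:
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
        moved = float(np.max(np.abs(cand - np.concatenate([sigmas, [sigma_e]]))))
        sigmas, sigma_e, ll = cand[:m], float(cand[m]), ll_cand
        free = sigmas > bound_tol
        trace.append({"iter": it, "sigmas": sigmas.copy(), "sigma_e": sigma_e, "ll": ll})
        if sigma_e <= 2 * e_floor:
            converged = True
            break
        if moved < _EM_TOL * max(var_y, 1.0) and grad_norm < 1e-6 * max(var_y, 1.0):
            converged = True
            break
    at_boundary = sigma_e <= 2 * e_floor or any(s <= bound_tol for s in sigmas)
    if not converged and not at_boundary and grad_norm > 1e-3 * max(var_y, 1.0):
        # genuine interior non-convergence only; residual gradients at a
        # variance boundary are expected and flagged instead
        raise ConvergenceError(
            f"REML did not converge after {it} iterations (|grad|={grad_norm:.3g})", trace
        )
    converged = True

    sigmas = np.where(sigmas < bound_tol, 0.0, sigmas)
    score, info, P = _score_and_info(y, X, Zs, np.maximum(sigmas, 0.0), sigma_e)
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        cov = np.full((m + 1, m + 1), np.nan)

    # GLS fixed effects and BLUPs at the estimates
    V = _build_V(sigmas, sigma_e, Zs, n)
    cf = linalg.cho_factor(V, lower=True)
    ViX = linalg.cho_solve(cf, X)
    XtViX = X.T @ ViX
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (ViX.T @ y)
    Py = linalg.cho_solve(cf, y) - ViX @ (cov_beta @ (ViX.T @ y))
    blups: dict[str, pd.Series] = {}
    for k, term in enumerate(spec.random):
        u = sigmas[k] * (Zs[k].T @ Py)
        if Ls[k] is not None:
            u = Ls[k] @ u  # back to the correlated (original) scale
        blups[term.name] = pd.Series(u, index=level_lists[k], name=term.name)

    ll = reml_loglik(y, X, Zs, sigmas, sigma_e)
    names = [t.name for t in spec.random] + ["residual"]
    vc = VarianceComponents(
        components={t.name: float(s) for t, s in zip(spec.random, sigmas)},
        sigma2_e=float(sigma_e),
        cov=cov,
        names=names,
        boundary={t.name: bool(s == 0.0) for t, s in zip(spec.random, sigmas)},
        n_iter=it,
        converged=converged,
        grad_norm=grad_norm,
    )
    return MixedModelFit(
        spec=spec,
        vc=vc,
        beta=beta,
        cov_beta=cov_beta,
        fixed_names=fixed_names,
        blups=blups,
        loglik=ll,
        n=n,
        p=p,
        data=data,
        _X_col_means=X.mean(axis=0),
    )


def _constant_response_fit(data, spec, y, X, fixed_names, Zs, level_lists, Ls):
    """Degenerate all-equal response: every variance zero, mu = the constant."""
    n, p = X.shape
    m = len(Zs)
    beta = np.zeros(p)
    beta[0] = y[0]
    blups = {
        t.name: pd.Series(np.zeros(len(lv)), index=lv, name=t.name)
        for t, lv in zip(spec.random, level_lists)
    }
    vc = VarianceComponents(
        components={t.name: 0.0 for t in spec.random},
        sigma2_e=0.0,
        cov=np.zeros((m + 1, m + 1)),
        names=[t.name for t in spec.random] + ["residual"],
        boundary={t.name: True for t in spec.random},
        n_iter=0,
        converged=True,
        grad_norm=0.0,
    )
    return MixedModelFit(
        spec=spec,
        vc=vc,
        beta=beta,
        cov_beta=np.zeros((p, p)),
        fixed_names=fixed_names,
        blups=blups,
        loglik=float("nan"),
        n=n,
        p=p,
        data=data,
        _X_col_means=X.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# genotype values


def compute_blues(fit: MixedModelFit) -> pd.DataFrame:
    """Per-genotype adjusted means (BLUEs) with standard errors.

    The genotype must be a fixed term.  Each BLUE is the estimable contrast
    intercept + genotype effect, with any other fixed factors averaged at
    their observed distribution.
    """
    if "genotype" not in fit.spec.fixed:
        raise ValueError("compute_blues requires genotype as a fixed term")
    levels = sorted(fit.data["genotype"].astype(str).unique())
    prefix = "genotype["
    rows = []
    for g in levels:
        c = np.array(fit._X_col_means, dtype=float)
        c[0] = 1.0
        for j, name in enumerate(fit.fixed_names):
            if name.startswith(prefix):
                c[j] = 1.0 if name == f"genotype[{g}]" else 0.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        rows.append({"genotype": g, "blue": est, "se": se})
    return pd.DataFrame(rows).set_index("genotype")


def compute_blups(fit: MixedModelFit) -> pd.Series:
    """Shrunken per-genotype predictions from the mixed-model equations."""
    if "genotype" not in fit.blups:
        raise ValueError("compute_blups requires genotype as a random term")
    return fit.blups["genotype"]


# ---------------------------------------------------------------------------
# heritability


def _h2_delta_se(vc: VarianceComponents, grad: dict[str, float]) -> float:
    g = np.array([grad.get(name, 0.0) for name in vc.names])
    return float(np.sqrt(max(g @ vc.cov @ g, 0.0)))


def broad_sense_heritability(
    vc: VarianceComponents, n_rep: int, basis: str = "entry_mean"
) -> tuple[float, float]:
    """Broad-sense heritability (repeatability) of genotype means.

    entry_mean (default): H^2 = s2g / (s2g + s2e / n_rep); plot basis
    divides by the full per-plot variance.  Returns (H^2, SE) with the SE
    from the delta method on the component covariance.
    """
    if "genotype" not in vc.components:
        raise ValueError("heritability needs a genotype variance (genotype-random fit)")
    s2g = vc.components["genotype"]
    s2e = vc.sigma2_e
    others = {k: v for k, v in vc.components.items() if k != "genotype"}
    if basis == "entry_mean":
        denom = s2g + s2e / n_rep
        if denom == 0:
            raise ZeroDivisionError("all variance components are zero; H^2 undefined")
        h2 = s2g / denom
        grad = {
            "genotype": (denom - s2g) / denom**2,
            "residual": -s2g / denom**2 / n_rep,
        }
    elif basis == "plot":
        denom = s2g + sum(others.values()) + s2e
        if denom == 0:
            raise ZeroDivisionError("all variance components are zero; H^2 undefined")
        h2 = s2g / denom
        grad = {"genotype": (denom - s2g) / denom**2}
        for k in others:
            grad[k] = -s2g / denom**2
        grad["residual"] = -s2g / denom**2
    else:
        raise ValueError("basis must be 'entry_mean' or 'plot'")
    return float(h2), _h2_delta_se(vc, grad)


def narrow_sense_heritability(
    vc: VarianceComponents,
    n_env: int,
    n_rep: int,
    basis: str = "entry_mean",
) -> tuple[float, float]:
    """Narrow-sense heritability from a pedigree G x E fit.

    entry_mean: h2a = s2a / (s2a + s2ge / n_env + s2e / (n_env * n_rep));
    plot: s2a over the sum of every component.
    """
    if "genotype" not in vc.components:
        raise ValueError("needs an additive genotype variance")
    s2a = vc.components["genotype"]
    s2ge = next((v for k, v in vc.components.items() if ":" in k and "genotype" in k), 0.0)
    ge_name = next((k for k in vc.components if ":" in k and "genotype" in k), None)
    s2e = vc.sigma2_e
    if basis == "entry_mean":
        denom = s2a + s2ge / n_env + s2e / (n_env * n_rep)
        if denom == 0:
            raise ZeroDivisionError("zero total variance")
        h2 = s2a / denom
        grad = {
            "genotype": (denom - s2a) / denom**2,
            "residual": -s2a / denom**2 / (n_env * n_rep),
        }
        if ge_name:
            grad[ge_name] = -s2a / denom**2 / n_env
    elif basis == "plot":
        denom = s2a + sum(v for k, v in vc.components.items() if k != "genotype") + s2e
        if denom == 0:
            raise ZeroDivisionError("zero total variance")
        h2 = s2a / denom
        grad = {k: -s2a / denom**2 for k in vc.components}
        grad["genotype"] = (denom - s2a) / denom**2
        grad["residual"] = -s2a / denom**2
    else:
        raise ValueError("basis must be 'entry_mean' or 'plot'")
    return float(h2), _h2_delta_se(vc, grad)


# ---------------------------------------------------------------------------
# pedigree relationship matrix


@dataclass
class RelationshipMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal = 1 + inbreeding coefficient

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


def additive_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    Founders: A_ii = 1, A_ij = 0.  Offspring k of (s, d):
    A_ki = (A_si + A_di) / 2 for i != k and A_kk = 1 + A_sd / 2; an unknown
    parent contributes as an unrelated non-inbred founder (its terms are 0).
    """
    ids = pedigree.individuals
    pos = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for k, ind in enumerate(ids):
        p1, p2 = pedigree.records[ind]
        i1 = pos[p1] if p1 is not None else None
        i2 = pos[p2] if p2 is not None else None
        for i in range(k):
            val = 0.0
            if i1 is not None:
                val += 0.5 * A[i1, i]
            if i2 is not None:
                val += 0.5 * A[i2, i]
            A[k, i] = A[i, k] = val
        if i1 is not None and i2 is not None:
            A[k, k] = 1.0 + 0.5 * A[i1, i2]
        else:
            A[k, k] = 1.0
    return RelationshipMatrix(ids, A)


# ---------------------------------------------------------------------------
# genotype-by-environment model


def fit_gxe(
    data: pd.DataFrame,
    relationship: RelationshipMatrix | None = None,
    response: str = "ph_cm",
    env: str = "year",
) -> MixedModelFit:
    """Pedigree G x E model over two or more environments (years).

    Fixed environment means; random genotype (covariance A sigma_a^2 when a
    relationship is given), independent genotype x environment deviations,
    and replicate/block design terms nested in environment.
    """
    envs = sorted(data[env].astype(str).unique())
    if len(envs) < 2:
        raise ValueError("G x E interaction needs data from >= 2 environments")
    geno_term: RandomTerm
    if relationship is not None:
        genos = sorted(data["genotype"].astype(str).unique())
        sub = relationship.submatrix([g for g in relationship.ids if g in set(genos)])
        missing = set(genos) - set(sub.ids)
        if missing:
            raise ValueError(f"genotypes missing from relationship matrix: {sorted(missing)}")
        geno_term = RandomTerm(("genotype",), relationship=sub.values, relationship_ids=tuple(sub.ids))
    else:
        geno_term = RandomTerm(("genotype",))
    random: list[RandomTerm] = [geno_term, RandomTerm(("genotype", env))]
    if "rep" in data.columns:
        random.append(RandomTerm((env, "rep")))
    if "block" in data.columns and "rep" in data.columns:
        random.append(RandomTerm((env, "rep", "block")))
    spec = MixedModelSpec(response=response, fixed=(env,), random=tuple(random))
    return fit_reml(data, spec)


# ---------------------------------------------------------------------------
# rank concordance and flight adjustment


def spearman_with_test(
    x, y, ci: str = "fisher", conf: float = 0.95
) -> dict[str, float]:
    """Spearman rank correlation with a t-test and confidence interval.

    rho is the Pearson correlation of average ranks; the p-value uses
    t = rho sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.  The default
    interval is Fisher-z; ``ci="linear"`` uses the half-width
    1.96 (1 - rho) / (n - 2) sometimes printed with prediction-accuracy
    figures (kept verbatim as an option despite its odd dimensions).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-13:
        rho = math.copysign(1.0, rho)
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    z = stats.norm.ppf(0.5 + conf / 2)
    if ci == "fisher":
        fz = math.atanh(max(min(rho, 1 - 1e-12), -1 + 1e-12))
        hw = z / math.sqrt(n - 3) if n > 3 else float("inf")
        lo, hi = math.tanh(fz - hw), math.tanh(fz + hw)
    elif ci == "linear":
        hw = z * (1 - rho) / (n - 2)
        lo, hi = rho - hw, rho + hw
    else:
        raise ValueError("ci must be 'fisher' or 'linear'")
    return {"rho": rho, "p_value": p, "n": n, "ci_low": float(lo), "ci_high": float(hi)}


def adjust_for_flights(records: pd.DataFrame, response: str = "ph_cm") -> pd.Series:
    """Single height per plot from repeated flights at one growth stage.

    Additive two-way fixed-effects fit (plot + flight); the adjusted plot
    mean is the plot effect plus the average flight effect, so with one
    flight the observations pass through unchanged.  Plots absent from
    every flight are returned as NaN.
    """
    df = records.dropna(subset=[response])
    plots = sorted(records["plot_id"].astype(str).unique())
    flights = sorted(df["flight"].astype(str).unique())
    if len(flights) == 0:
        raise ValueError("no flights in records")
    observed = sorted(df["plot_id"].astype(str).unique())
    if len(flights) == 1:
        vals = df.groupby(df["plot_id"].astype(str))[response].mean()
        return vals.reindex(plots)
    Xp, plot_names = _dummies(df["plot_id"].astype(str), drop_first=True)
    Xf, flight_names = _dummies(df["flight"].astype(str), drop_first=True)
    X = np.hstack([np.ones((len(df), 1)), Xp, Xf])
    coef, *_ = np.linalg.lstsq(X, df[response].to_numpy(dtype=float), rcond=None)
    b0 = coef[0]
    plot_eff = dict(zip(plot_names, coef[1 : 1 + len(plot_names)]))
    flight_eff = coef[1 + len(plot_names) :]
    mean_flight = float(np.sum(flight_eff)) / len(flights)  # reference flight effect = 0
    out = {}
    for pid in observed:
        out[pid] = b0 + plot_eff.get(pid, 0.0) + mean_flight
    return pd.Series(out, name=response).reindex(plots)
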