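"""Linear mixed models: two-stage fitting, REML, BLUPs, PEV, backsolve.

The package's modelling surface follows the Model/Results convention: a
model object is built from data, ``fit()`` estimates the parameters, and
the returned Results object carries estimates, BLUPs, prediction error
variance (PEV) matrices and a ``summary()`` table.

Three models are provided:

``StageOneLMM``
    Stage 1 of the two-stage validation pipeline: a fixed-effects model
    ``y = location + block(location) + genotype + error`` with i.i.d.
    residuals within each location but heterogeneous variances across
    locations, fitted by iterated feasible GLS.  Its product is the vector
    of centered genotype BLUEs ``g_hat`` and the per-location residual
    variances.

``GBLUP``
    Stage 2: ``g_hat = intercept + a + e`` with ``a ~ MVN(0, K sigma2_a*)``
    for a user-supplied relationship matrix K (G, GN, identity, ...) and
    i.i.d. residuals.  REML is exact here: the likelihood is profiled over
    the variance ratio on the eigenbasis of K and the remaining 1-D
    problem is solved numerically.  The results object exposes the BLUPs
    and the PEV matrix from Henderson's mixed-model equations.

``MultiLocationLMM``
    The multi-environment model ``y = location + block(location) + a + aL
    + e`` with ``a ~ MVN(0, G sigma2_a*)``, independent per-location
    additive-by-location effects ``aL_l ~ MVN(0, G sigma2_aL_l*)`` and
    heterogeneous residual variances by location.  Fitted by EM-REML with
    optional average-information (AI) acceleration.

A note on scale: when the covariance structure K does not have unit
overall variance (the VanRaden G never does), the REML scaler
``sigma2_a*`` is not interpretable as the additive variance of the
effect; it is only a scaling factor.  The estimators in
:mod:`pevsim.varest` deal with extracting an actual variance from these
fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize

from .relmat import CenteredMarkers, CovStructure, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "StageOneLMM",
    "StageOneResults",
    "GBLUP",
    "GBLUPResults",
    "MultiLocationLMM",
    "MultiLocationResults",
    "fit_stage1",
    "fit_k_model",
    "fit_multi",
    "blup_and_pev",
    "backsolve_marker_effects",
]


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the parameter trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class IdentifiabilityError(ValueError):
    """The fixed-effect design is rank deficient after constraints."""


# ---------------------------------------------------------------------------
# Stage 1: fixed-effects model with heterogeneous residual variances
# ---------------------------------------------------------------------------


def _design_with_levels(values: pd.Series, prefix: str, drop_first: bool = True):
    """Treatment-coded dummy matrix and the level order used."""
    levels = list(pd.unique(values))
    start = 1 if drop_first else 0
    cols = {f"{prefix}{lv}": (values == lv).to_numpy(float) for lv in levels[start:]}
    return cols, levels


@dataclass
class StageOneResults:
    """Genotype BLUEs and residual variances from the stage-1 fixed model."""

    g_hat: pd.Series  # centered genotype BLUEs
    location_effects: pd.Series
    block_effects: pd.Series
    residual_variances: dict
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    degenerate: bool = False

    def summary(self) -> str:
        lines = ["Stage-1 fixed-effects model (iterated FGLS)"]
        lines.append(f"  genotypes: {len(self.g_hat)}  iterations: {self.n_iter}"
                     f"  converged: {self.converged}")
        for loc, v in self.residual_variances.items():
            lines.append(f"  residual variance [{loc}]: {v:.6g}")
        if self.degenerate:
            lines.append("  WARNING: a residual variance is numerically zero (degenerate)")
        return "\n".join(lines)


class StageOneLMM:
    """Fixed-effects stage-1 model for a multi-location RCBD phenotype table.

    Parameters
    ----------
    data : long-format DataFrame with columns for genotype, location,
        block and the response value.
    """

    def __init__(self, data: pd.DataFrame, genotype: str = "genotype",
                 location: str = "location", block: str = "block", value: str = "value"):
        required = [genotype, location, block, value]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise InvalidInputError(f"phenotype table lacks columns: {missing}")
        data = data.dropna(subset=[value]).reset_index(drop=True)
        if data.empty:
            raise InvalidInputError("no observations")
        self.data = data
        self.cols = dict(genotype=genotype, location=location, block=block, value=value)

    def _build_design(self):
        d = self.data
        g, l, b = self.cols["genotype"], self.cols["location"], self.cols["block"]
        n = len(d)
        cols = {"intercept": np.ones(n)}
        loc_cols, loc_levels = _design_with_levels(d[l].astype(str), "loc:")
        cols.update(loc_cols)
        # blocks nested within location: drop the first block in each location
        blk_names = []
        for loc in loc_levels:
            sub = d[l].astype(str) == loc
            blocks = list(pd.unique(d.loc[sub, b].astype(str)))
            for blk in blocks[1:]:
                name = f"blk:{loc}:{blk}"
                cols[name] = (sub & (d[b].astype(str) == blk)).to_numpy(float)
                blk_names.append(name)
        gen_cols, gen_levels = _design_with_levels(d[g].astype(str), "gen:")
        cols.update(gen_cols)
        X = np.column_stack(list(cols.values()))
        return X, list(cols.keys()), loc_levels, gen_levels

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> StageOneResults:
        d = self.data
        y = d[self.cols["value"]].to_numpy(float)
        X, names, loc_levels, gen_levels = self._build_design()
        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # identify aliased columns from the pivoted QR
            _, _, piv = sla.qr(X, mode="economic", pivoting=True)
            aliased = [names[piv[i]] for i in range(rank, p)]
            raise IdentifiabilityError(
                f"design is rank deficient; aliased levels: {aliased}")
        loc_idx = d[self.cols["location"]].astype(str).to_numpy()
        sigma2 = {loc: 1.0 for loc in loc_levels}
        beta = np.zeros(p)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = np.array([1.0 / max(sigma2[loc], 1e-12) for loc in loc_idx])
            Xw = X * w[:, None]
            XtWX = X.T @ Xw
            beta = np.linalg.solve(XtWX, Xw.T @ y)
            resid = y - X @ beta
            # effective residual df per location from the weighted hat matrix
            Hdiag = np.einsum("ij,jk,ik->i", X, np.linalg.inv(XtWX), Xw)
            new = {}
            for loc in loc_levels:
                m = loc_idx == loc
                df = m.sum() - Hdiag[m].sum()
                new[loc] = float(resid[m] @ resid[m] / max(df, 1e-8))
            rel = max(abs(new[loc] - sigma2[loc]) / max(sigma2[loc], 1e-12)
                      for loc in loc_levels)
            sigma2 = new
            if rel < tol:
                converged = True
                break
        degenerate = any(v < 1e-12 for v in sigma2.values())
        if degenerate:
            warnings.warn("a per-location residual variance is numerically zero",
                          RuntimeWarning, stacklevel=2)
        est = dict(zip(names, beta))
        g_eff = pd.Series({lv: est.get(f"gen:{lv}", 0.0) for lv in gen_levels})
        g_hat = g_eff - g_eff.mean()
        loc_eff = pd.Series({lv: est.get(f"loc:{lv}", 0.0) for lv in loc_levels})
        blk_eff = pd.Series({k[4:]: v for k, v in est.items() if k.startswith("blk:")})
        return StageOneResults(
            g_hat=g_hat, location_effects=loc_eff, block_effects=blk_eff,
            residual_variances=sigma2, fitted=X @ beta, residuals=y - X @ beta,
            converged=converged, n_iter=it, degenerate=degenerate)


def fit_stage1(phenotypes: pd.DataFrame, **kwargs) -> StageOneResults:
    """Convenience wrapper: build and fit a :class:`StageOneLMM`."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("tol", "max_iter") if k in kwargs}
    return StageOneLMM(phenotypes, **kwargs).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# Stage 2: single-kernel GBLUP model with exact profiled REML
# ---------------------------------------------------------------------------


@dataclass
class GBLUPResults:
    """REML estimates, BLUPs and PEV for the single-kernel model."""

    sigma2_a_star: float
    sigma2_eps: float
    intercept: float
    loglik: float
    converged: bool
    n_iter: int
    kind: str
    boundary: bool
    model: "GBLUP" = field(repr=False)

    @property
    def ratio(self) -> float:
        return self.sigma2_a_star / self.sigma2_eps if self.sigma2_eps > 0 else np.inf

    def blups(self) -> np.ndarray:
        """Mean-centered BLUPs of the additive effect."""
        a, _ = self._blup_pev()
        return a

    def pev(self) -> np.ndarray:
        """Prediction error variance matrix from the mixed-model equations."""
        _, P = self._blup_pev()
        return P

    def _blup_pev(self):
        if not hasattr(self, "_cache"):
            self._cache = self.model._blup_pev(self.sigma2_a_star, self.sigma2_eps)
        return self._cache

    def summary(self) -> str:
        lines = [f"GBLUP REML fit (K kind = {self.kind}, n = {self.model.n})"]
        lines.append(f"  sigma2_a* = {self.sigma2_a_star:.6g}")
        lines.append(f"  sigma2_e  = {self.sigma2_eps:.6g}")
        lines.append(f"  restricted loglik = {self.loglik:.6f}")
        if self.boundary:
            lines.append("  NOTE: variance ratio at boundary")
        return "\n".join(lines)


class GBLUP:
    """Single-random-effect model ``y = 1 mu + a + e``, ``a ~ MVN(0, K s2a)``.

    REML is computed exactly by rotating onto the eigenbasis of K and
    profiling the restricted likelihood over the variance ratio
    ``lambda = sigma2_a* / sigma2_e``.
    """

    def __init__(self, y: np.ndarray, K: CovStructure | np.ndarray, min_n: int = 10):
        self.y = np.asarray(y, dtype=float).ravel()
        if isinstance(K, CovStructure):
            self.kind = K.kind
            Kmat = K.matrix
        else:
            Kmat = np.asarray(K, dtype=float)
            self.kind = "custom"
        if Kmat.shape[0] != Kmat.shape[1]:
            raise InvalidInputError("K must be square")
        if np.max(np.abs(Kmat - Kmat.T)) > 1e-8:
            raise InvalidInputError("K must be symmetric")
        if self.y.shape[0] != Kmat.shape[0]:
            raise InvalidInputError("response and K dimensions disagree")
        if self.y.shape[0] < min_n:
            raise InvalidInputError(f"need at least {min_n} observations")
        self.K = 0.5 * (Kmat + Kmat.T)
        self.n = self.y.shape[0]
        self._eig = None

    def _eigen(self):
        if self._eig is None:
            w, U = np.linalg.eigh(self.K)
            self._eig = (np.clip(w, 0.0, None), U)
        return self._eig

    # restricted log-likelihood for given lambda, profiled over sigma2_e
    def _profile(self, lam: float):
        d, U = self._eigen()
        yt = U.T @ self.y
        xt = U.T @ np.ones(self.n)
        v = 1.0 + lam * d  # V / sigma2_e on the eigenbasis
        vi = 1.0 / v
        xvx = float(np.sum(xt * vi * xt))
        xvy = float(np.sum(xt * vi * yt))
        beta = xvy / xvx
        r = yt - beta * xt
        quad = float(np.sum(r * vi * r))
        df = self.n - 1
        s2e = quad / df
        ll = -0.5 * (df * np.log(s2e) + np.sum(np.log(v)) + np.log(xvx) + df)
        return ll, s2e, beta

    def loglik(self, sigma2_a: float, sigma2_e: float) -> float:
        """Restricted log-likelihood at an arbitrary (s2a, s2e) point."""
        d, U = self._eigen()
        yt = U.T @ self.y
        xt = U.T @ np.ones(self.n)
        v = sigma2_a * d + sigma2_e
        if np.any(v <= 0):
            return -np.inf
        vi = 1.0 / v
        xvx = float(np.sum(xt * vi * xt))
        xvy = float(np.sum(xt * vi * yt))
        beta = xvy / xvx
        r = yt - beta * xt
        quad = float(np.sum(r * vi * r))
        return -0.5 * (np.sum(np.log(v)) + np.log(xvx) + quad)

    def fit(self, ratio_tol: float = 1e-10, max_iter: int = 200) -> GBLUPResults:
        d, _ = self._eigen()
        dmax = d.max() if d.size else 0.0
        if dmax <= 0:
            raise InvalidInputError("K has no positive eigenvalues")
        # flat-likelihood detection: K proportional to I on the contrast space
        if (d.max() - d.min()) < 1e-12 * max(dmax, 1.0):
            warnings.warn(
                "K is proportional to the identity: additive and residual "
                "variances are confounded; returning the boundary solution",
                RuntimeWarning, stacklevel=2)
            ll, s2e, beta = self._profile(0.0)
            return GBLUPResults(0.0, s2e * 1.0, beta, ll, True, 1, self.kind,
                                boundary=True, model=self)

        d_all, U = self._eigen()
        yt = U.T @ self.y
        xt = U.T @ np.ones(self.n)
        df = self.n - 1

        def score(loglam):
            # d/d(lambda) of the profiled restricted loglik (envelope form)
            lam = 10.0 ** loglam
            v = 1.0 + lam * d_all
            vi = 1.0 / v
            xvx = float(np.sum(xt * vi * xt))
            beta = float(np.sum(xt * vi * yt)) / xvx
            r = yt - beta * xt
            quad = float(np.sum(r * r * vi))
            dquad = -float(np.sum(d_all * (r * vi) ** 2))
            tr_term = float(np.sum(d_all * vi))
            x_term = float(np.sum(d_all * (xt * vi) ** 2)) / xvx
            return -0.5 * (df * dquad / quad + tr_term - x_term)

        grid = np.linspace(-10.0, 10.0, 81)
        sc = np.array([score(t) for t in grid])
        n_iter = len(grid)
        candidates = [0.0]  # the lambda = 0 boundary is always compared
        for i in range(len(grid) - 1):
            if sc[i] > 0 >= sc[i + 1]:
                root = optimize.brentq(score, grid[i], grid[i + 1],
                                       xtol=1e-14, maxiter=max_iter)
                candidates.append(float(10.0 ** root))
                n_iter += 1
        if sc[-1] > 0:  # likelihood still increasing at the upper end
            candidates.append(float(10.0 ** grid[-1]))
        evaluated = [(self._profile(lam), lam) for lam in candidates]
        (ll, s2e, beta), lam = max(evaluated, key=lambda t: t[0][0])
        boundary = lam == 0.0
        return GBLUPResults(lam * s2e, s2e, beta, ll, True, n_iter, self.kind,
                            boundary=boundary, model=self)

    def _blup_pev(self, sigma2_a: float, sigma2_e: float):
        """BLUPs and PEV via the P-matrix form of Henderson's MME.

        a_hat = s2a K P y and PEV = s2a K - s2a K P K s2a, where P is the
        REML projection for V = K s2a + I s2e and X = 1.  This equals the
        random-effect block of the inverse MME coefficient matrix and is
        well defined for singular K (no K inverse is formed).
        """
        n = self.n
        if sigma2_a <= 0:
            return np.zeros(n), np.zeros((n, n))
        V = sigma2_a * self.K + sigma2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        ViX = Vi @ X
        P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
        a_hat = sigma2_a * (self.K @ (P @ self.y))
        KPK = self.K @ P @ self.K
        pev = sigma2_a * self.K - sigma2_a**2 * KPK
        pev = 0.5 * (pev + pev.T)
        return a_hat - a_hat.mean(), pev


def fit_k_model(g_hat: np.ndarray, K: CovStructure | np.ndarray, **kwargs) -> GBLUPResults:
    """Convenience wrapper: REML fit of the stage-2 single-kernel model."""
    return GBLUP(g_hat, K, min_n=kwargs.pop("min_n", 10)).fit(**kwargs)


def blup_and_pev(fit: GBLUPResults | "MultiLocationResults", term: str = "additive"):
    """BLUPs (mean-centered) and PEV matrix for a random term of a fit."""
    if isinstance(fit, GBLUPResults):
        if term not in ("additive", "a"):
            raise InvalidInputError(f"GBLUP has a single random term, not {term!r}")
        return fit.blups(), fit.pev()
    if not fit.converged:
        raise ConvergenceError("fit did not converge; BLUPs unavailable")
    if term not in fit.blups:
        raise InvalidInputError(f"unknown random term {term!r}")
    return fit.blups[term], fit.pev[term]


def backsolve_marker_effects(Z: CenteredMarkers | np.ndarray, a_hat: np.ndarray) -> np.ndarray:
    """Additive marker effects from additive values: beta = Z'(ZZ')^+ a.

    Whenever ``a_hat`` lies in the row space of Z (GBLUP solutions always
    do), ``Z beta`` reproduces ``a_hat``.
    """
    Zm = Z.values if isinstance(Z, CenteredMarkers) else np.asarray(Z, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float).ravel()
    if Zm.shape[0] != a_hat.shape[0]:
        raise InvalidInputError("Z rows and a_hat length disagree")
    ZZt = Zm @ Zm.T
    return Zm.T @ np.linalg.pinv(ZZt, rcond=1e-10) @ a_hat


# ---------------------------------------------------------------------------
# Multi-location model (additive + additive-by-location + het residuals)
# ---------------------------------------------------------------------------


@dataclass
class MultiLocationResults:
    """REML scalers, BLUPs and PEV matrices for the multi-location model."""

    reml_scalers: dict  # {'additive': s2a*, 'axl:<loc>': s2aL*}
    residual_variances: dict  # {loc: s2e_loc}
    fixed_estimates: dict
    blups: dict  # per-term mean-centered BLUP vectors
    pev: dict  # per-term PEV matrices
    loglik: float
    converged: bool
    n_iter: int

    def summary(self) -> str:
        lines = ["Multi-location REML fit (EM/AI)"]
        for k, v in self.reml_scalers.items():
            lines.append(f"  {k}: {v:.6g}")
        for k, v in self.residual_variances.items():
            lines.append(f"  residual [{k}]: {v:.6g}")
        lines.append(f"  restricted loglik = {self.loglik:.6f}"
                     f"  ({self.n_iter} iterations, converged={self.converged})")
        return "\n".join(lines)


class MultiLocationLMM:
    """Multi-environment mixed model with G-structured genetic effects.

    ``y = location + block(location) + a + aL + e`` where
    ``a ~ MVN(0, G s2a*)``, each location's interaction deviation
    ``aL_l ~ MVN(0, G s2aL_l*)`` independently, and residuals are i.i.d.
    within location with heterogeneous variances across locations.

    Singular relationship matrices are handled by reparametrizing each
    G-structured effect on the eigenbasis of G (effects live in the range
    of G; the effective number of levels is rank(G)).
    """

    def __init__(self, data: pd.DataFrame, G: CovStructure | np.ndarray,
                 genotype: str = "genotype", location: str = "location",
                 block: str = "block", value: str = "value"):
        for c in (genotype, location, block, value):
            if c not in data.columns:
                raise InvalidInputError(f"phenotype table lacks column {c!r}")
        data = data.dropna(subset=[value]).reset_index(drop=True)
        self.data = data
        self.cols = dict(genotype=genotype, location=location, block=block, value=value)
        self.gen_levels = list(pd.unique(data[genotype].astype(str)))
        self.loc_levels = list(pd.unique(data[location].astype(str)))
        if len(self.loc_levels) < 2:
            raise InvalidInputError("multi-location model needs >= 2 locations")
        counts = data.groupby([location, genotype]).size()
        if counts.max() < 2 and data.groupby(location).size().min() <= len(self.gen_levels):
            # replication within location can also come from blocks
            nblk = data.groupby(location)[block].nunique().min()
            if nblk < 2:
                raise InvalidInputError("need replication within each location")
        Gmat = G.matrix if isinstance(G, CovStructure) else np.asarray(G, dtype=float)
        if Gmat.shape[0] != len(self.gen_levels):
            raise InvalidInputError("G dimension does not match genotype count")
        self.G = 0.5 * (Gmat + Gmat.T)

    def _prepare(self):
        d = self.data
        g, l, b, v = (self.cols[k] for k in ("genotype", "location", "block", "value"))
        y = d[v].to_numpy(float)
        n = len(d)
        gen_idx = pd.Categorical(d[g].astype(str), categories=self.gen_levels).codes
        loc_arr = d[l].astype(str).to_numpy()
        # fixed design
        cols = {"intercept": np.ones(n)}
        for loc in self.loc_levels[1:]:
            cols[f"loc:{loc}"] = (loc_arr == loc).astype(float)
        for loc in self.loc_levels:
            sub = loc_arr == loc
            blocks = list(pd.unique(d.loc[sub, b].astype(str)))
            for blk in blocks[1:]:
                cols[f"blk:{loc}:{blk}"] = (sub & (d[b].astype(str) == blk)).to_numpy(float)
        X = np.column_stack(list(cols.values()))
        names = list(cols.keys())
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise IdentifiabilityError("fixed-effect design is rank deficient")
        # eigen square root of G (range-space reparametrization)
        w, U = np.linalg.eigh(self.G)
        keep = w > 1e-10 * max(w.max(), 1.0)
        T = U[:, keep] * np.sqrt(w[keep])  # n_g x r
        r = T.shape[1]
        Zg = np.zeros((n, len(self.gen_levels)))
        Zg[np.arange(n), gen_idx] = 1.0
        terms = []  # (name, Ztilde, q, Z_incidence)
        terms.append(("additive", Zg @ T, r, Zg))
        for loc in self.loc_levels:
            m = (loc_arr == loc).astype(float)
            Zl = Zg * m[:, None]
            terms.append((f"axl:{loc}", Zl @ T, r, Zl))
        res_groups = [(f"eps:{loc}", (loc_arr == loc)) for loc in self.loc_levels]
        return y, X, names, terms, res_groups, T

    def fit(self, tol: float = 1e-8, max_iter: int = 200, use_ai: bool = True
            ) -> MultiLocationResults:
        y, X, names, terms, res_groups, T = self._prepare()
        n = len(y)
        vary = float(np.var(y, ddof=1))
        k_rand = len(terms)
        theta = np.full(k_rand + len(res_groups), vary / (k_rand + 1))
        Zt = [t[1] for t in terms]
        q = np.array([t[2] for t in terms] + [int(m.sum()) for _, m in res_groups])
        masks = [m for _, m in res_groups]
        floor = 1e-10 * vary

        def build_V(th):
            V = np.zeros((n, n))
            for k, Z in enumerate(Zt):
                if th[k] > 0:
                    V += th[k] * (Z @ Z.T)
            rdiag = np.zeros(n)
            for j, m in enumerate(masks):
                rdiag[m] = max(th[k_rand + j], floor)
            V[np.diag_indices(n)] += rdiag
            return V

        def reml_ll(th):
            V = build_V(th)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -np.inf, None, None
            Vi = np.linalg.inv(V)
            ViX = Vi @ X
            XtViX = X.T @ ViX
            P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
            Py = P @ y
            ll = -0.5 * (2 * np.sum(np.log(np.diag(L)))
                         + np.linalg.slogdet(XtViX)[1] + float(y @ Py))
            return ll, P, Py

        def dV_products(P, Py):
            # y'P V_k P y and tr(P V_k) per component
            yq = np.empty(len(theta))
            tr = np.empty(len(theta))
            for k, Z in enumerate(Zt):
                ZtPy = Z.T @ Py
                yq[k] = float(ZtPy @ ZtPy)
                PZ = P @ Z
                tr[k] = float(np.sum(Z * PZ))
            for j, m in enumerate(masks):
                yq[k_rand + j] = float(Py[m] @ Py[m])
                tr[k_rand + j] = float(np.trace(P[np.ix_(m, m)]))
            return yq, tr

        ll, P, Py = reml_ll(theta)
        if P is None:
            raise ConvergenceError("initial V not positive definite")
        converged = False
        it = 0
        trace = []
        pinned = np.zeros(k_rand, dtype=bool)
        for it in range(1, max_iter + 1):
            yq, tr = dV_products(P, Py)
            # active-set pinning: a small component whose REML score is
            # negative is a boundary candidate; freeze it at 0 whenever the
            # restricted likelihood is indifferent to doing so (EM alone
            # approaches such boundaries geometrically slowly)
            if it % 10 == 0:
                cand_pin = ((theta[:k_rand] < 1e-1 * vary)
                            & (yq[:k_rand] - tr[:k_rand] < 0) & ~pinned)
                if cand_pin.any():
                    trial = theta.copy()
                    trial[:k_rand][cand_pin] = 0.0
                    ll_t, P_t, Py_t = reml_ll(trial)
                    if P_t is not None and ll_t >= ll - 1e-6:
                        pinned |= cand_pin
                        theta, ll, P, Py = trial, ll_t, P_t, Py_t
                        yq, tr = dV_products(P, Py)
                    else:
                        # not indifferent to the boundary yet: halve the
                        # creeping components if that improves the likelihood
                        trial = theta.copy()
                        trial[:k_rand][cand_pin] *= 0.5
                        ll_t, P_t, Py_t = reml_ll(trial)
                        if P_t is not None and ll_t >= ll:
                            theta, ll, P, Py = trial, ll_t, P_t, Py_t
                            yq, tr = dV_products(P, Py)
            new = None
            if use_ai and it > 3:
                # average-information step
                nT = len(theta)
                PVPy = []
                for k, Z in enumerate(Zt):
                    PVPy.append(P @ (Z @ (Z.T @ Py)))
                for j, m in enumerate(masks):
                    v = np.zeros(n)
                    v[m] = Py[m]
                    PVPy.append(P @ v)
                AI = 0.5 * np.array([[float(Py @ (
                    (Zt[a] @ (Zt[a].T @ PVPy[b])) if a < k_rand else
                    np.where(masks[a - k_rand], PVPy[b], 0.0)))
                    for b in range(nT)] for a in range(nT)])
                score = 0.5 * (yq - tr)
                try:
                    step = np.linalg.solve(AI + 1e-10 * np.eye(nT), score)
                    for frac in (1.0, 0.5, 0.2, 0.05):
                        cand = np.clip(theta + frac * step, 0.0, None)
                        cand[:k_rand][pinned] = 0.0
                        cand[k_rand:] = np.maximum(cand[k_rand:], floor)
                        ll_c, P_c, Py_c = reml_ll(cand)
                        if P_c is not None and ll_c >= ll - 1e-10:
                            new, ll_new, P_new, Py_new = cand, ll_c, P_c, Py_c
                            break
                except np.linalg.LinAlgError:
                    pass
            if new is None:
                # EM update: theta_k += theta_k^2 (y'P V_k P y - tr(P V_k)) / q_k
                cand = theta + theta**2 * (yq - tr) / q
                cand = np.clip(cand, 0.0, None)
                # random-term components creeping below numerical relevance
                # are truncated to the zero boundary outright
                cand[:k_rand][cand[:k_rand] < 1e-8 * vary] = 0.0
                cand[k_rand:] = np.maximum(cand[k_rand:], floor)
                ll_new, P_new, Py_new = reml_ll(cand)
                new = cand
            # components pinned near the zero boundary are judged on an
            # absolute scale so EM boundary-creep cannot stall convergence
            rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-4 * vary))
            trace.append(new.copy())
            theta, ll, P, Py = new, ll_new, P_new, Py_new
            if rel < tol:
                converged = True
                break
        if not converged:
            # EM creeps geometrically near flat directions; accept a
            # plateaued solution (absolute movement below 1e-4 var(y)),
            # otherwise raise with the parameter trace attached
            last = np.max(np.abs(trace[-1] - trace[-2])) if len(trace) > 1 else np.inf
            if last > 1e-4 * vary:
                raise ConvergenceError(
                    f"REML did not converge in {max_iter} iterations", trace=trace)
        # fixed effects at the final variances
        V = build_V(theta)
        Vi = np.linalg.inv(V)
        ViX = Vi @ X
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, ViX.T @ y)
        Pfin = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = Pfin @ y
        scalers = {}
        blups = {}
        pevs = {}
        for k, (name, Ztil, _, Zinc) in enumerate(terms):
            th = float(theta[k])
            scalers[name] = th
            if th <= 0:
                blups[name] = np.zeros(self.G.shape[0])
                pevs[name] = np.zeros_like(self.G)
                continue
            GZt = self.G @ Zinc.T
            a_hat = th * (GZt @ Py)
            cov_ahat = th**2 * (GZt @ Pfin @ GZt.T)
            pev = th * self.G - cov_ahat
            blups[name] = a_hat - a_hat.mean()
            pevs[name] = 0.5 * (pev + pev.T)
        resid = {loc: float(theta[k_rand + j]) for j, loc in enumerate(self.loc_levels)}
        fixed = dict(zip(names, beta))
        return MultiLocationResults(
            reml_scalers=scalers, residual_variances=resid, fixed_estimates=fixed,
            blups=blups, pev=pevs, loglik=ll, converged=True, n_iter=it)


def fit_multi(phenotypes: pd.DataFrame, G, **kwargs) -> MultiLocationResults:
    """Convenience wrapper: build and fit a :class:`MultiLocationLMM`."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("tol", "max_iter", "use_ai") if k in kwargs}
    return MultiLocationLMM(phenotypes, G, **kwargs).fit(**fit_kwargs)
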