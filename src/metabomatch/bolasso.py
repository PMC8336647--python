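"""L1-penalized conditional logistic regression and BoLasso selection.

The penalized objective on 1:1 pair differences is::

    f(beta) = (1/n) sum_i log(1 + exp(-beta' d_i)) + lambda * ||beta||_1

minimized by cyclic coordinate descent on the local quadratic (IRLS)
approximation with warm starts along a descending lambda grid — the glmnet
strategy, specialized to the intercept-free difference likelihood.  At
``beta = 0`` the unpenalized gradient is ``-(1/(2n)) sum_i d_i``, so the
smallest penalty that zeroes every coefficient is
``lambda_max = max_j |sum_i d_ij| / (2n)``.

Model selection follows the one-standard-error cross-validation rule
(largest lambda whose CV deviance is within one SE of the minimum), and
stability is assessed by the bootstrap lasso (BoLasso): the lasso with
CV-selected penalty is refitted on pair-resampled bootstrap replicates and
each variable's selection frequency across replicates is reported;
variables selected in at least 90% of replicates form the stable set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import PairDifferences

__all__ = [
    "LassoPath",
    "CVResult",
    "SelectionReport",
    "PenalizedPairedLogit",
    "clogit_lasso_path",
    "cv_lambda_1se",
    "bolasso",
]

_KKT_TOL = 1e-7
_CD_TOL = 1e-9
_MAX_SWEEPS = 10_000


class LassoConvergenceError(RuntimeError):
    pass


@dataclass
class LassoPath:
    """Coefficients along a descending penalty grid."""

    lambdas: np.ndarray
    coefs: pd.DataFrame  # index lambda position, columns features
    loglik: np.ndarray  # unpenalized conditional log-likelihood per lambda
    feature_names: list[str]

    def coef_at(self, lam: float) -> pd.Series:
        """Coefficients at the grid point closest to ``lam``."""
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs.iloc[i]

    def support_at(self, lam: float) -> np.ndarray:
        return self.coef_at(lam).to_numpy() != 0.0


@dataclass
class CVResult:
    """Cross-validated deviance profile and the one-SE penalty choice."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float


@dataclass
class SelectionReport:
    """BoLasso per-variable bootstrap selection frequencies."""

    frequencies: pd.Series
    threshold: float
    B: int
    seed: int
    n_failures: int = 0

    @property
    def selected(self) -> list[str]:
        return list(self.frequencies.index[self.frequencies >= self.threshold])

    def to_tsv(self, path) -> None:
        out = self.frequencies.rename("selection_frequency").to_frame()
        out["selected"] = out["selection_frequency"] >= self.threshold
        out["B"] = self.B
        out["threshold"] = self.threshold
        out["seed"] = self.seed
        out.to_csv(path, sep="\t", index_label="feature")


def _as_matrix(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, PairDifferences):
        return D.values, D.feature_names
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), list(D.columns)
    M = np.atleast_2d(np.asarray(D, dtype=float))
    return M, [f"x{j}" for j in range(M.shape[1])]


class PenalizedPairedLogit:
    """L1-penalized 1:1 conditional logistic model on pair differences."""

    def __init__(self, D):
        self.D, self.feature_names = _as_matrix(D)
        self.n, self.p = self.D.shape

    @property
    def lambda_max(self) -> float:
        return float(np.max(np.abs(self.D.sum(axis=0))) / (2.0 * self.n))

    def lambda_grid(self, n_lambdas: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
        lmax = self.lambda_max
        return np.geomspace(lmax, lmax * min_ratio, n_lambdas)

    # -- solver ------------------------------------------------------------
    def _gradient(self, beta: np.ndarray) -> np.ndarray:
        mu = expit(self.D @ beta)
        return -(self.D.T @ (1.0 - mu)) / self.n

    def _fit_one(self, lam: float, beta: np.ndarray, budget: list[int]) -> np.ndarray:
        """Solve at one lambda by active-set IRLS coordinate descent."""
        D, n = self.D, self.n
        active = list(np.flatnonzero(beta))
        while True:
            if active:
                DaT = np.ascontiguousarray(D[:, active].T)  # rows contiguous
                ba = beta[active].copy()
                for _outer in range(100):
                    eta = ba @ DaT
                    mu = expit(eta)
                    w = np.clip(mu * (1.0 - mu), 1e-10, None)
                    z = eta + (1.0 - mu) / w
                    wDaT = DaT * w
                    a = (wDaT * DaT).sum(axis=1) / n
                    r = z - eta
                    outer_delta = 0.0
                    for _sweep in range(_MAX_SWEEPS):
                        budget[0] += 1
                        if budget[0] > _MAX_SWEEPS:
                            raise LassoConvergenceError(
                                f"coordinate descent exceeded {_MAX_SWEEPS} sweeps at lambda={lam:.6g}"
                            )
                        delta = 0.0
                        for jj in range(len(active)):
                            bj = ba[jj]
                            rho = wDaT[jj] @ r / n + a[jj] * bj
                            nb = np.sign(rho) * max(abs(rho) - lam, 0.0) / a[jj]
                            if nb != bj:
                                r -= DaT[jj] * (nb - bj)
                                ba[jj] = nb
                                delta = max(delta, abs(nb - bj))
                        outer_delta = max(outer_delta, delta)
                        if delta < _CD_TOL:
                            break
                    if outer_delta < _CD_TOL:
                        break
                beta[active] = ba
            # full KKT screen: admit violators, stop when none remain
            g = self._gradient(beta)
            nz = beta != 0
            viol = (~nz) & (np.abs(g) > lam + _KKT_TOL / 10)
            stat_ok = not nz.any() or np.max(np.abs(g[nz] + lam * np.sign(beta[nz]))) < _KKT_TOL
            if not viol.any() and stat_ok:
                return beta
            active = sorted(set(active) | set(np.flatnonzero(viol)))

    def fit_path(self, lambdas: np.ndarray | None = None, **grid_kw) -> LassoPath:
        """Warm-started coefficient path along a descending lambda grid."""
        lambdas = self.lambda_grid(**grid_kw) if lambdas is None else np.asarray(lambdas, float)
        if np.any(np.diff(lambdas) > 0):
            lambdas = np.sort(lambdas)[::-1]
        coefs = np.zeros((len(lambdas), self.p))
        ll = np.zeros(len(lambdas))
        beta = np.zeros(self.p)
        for i, lam in enumerate(lambdas):
            budget = [0]
            beta = self._fit_one(lam, beta, budget)
            coefs[i] = beta
            ll[i] = -np.logaddexp(0.0, -(self.D @ beta)).sum()
        return LassoPath(
            lambdas,
            pd.DataFrame(coefs, columns=self.feature_names),
            ll,
            self.feature_names,
        )


def clogit_lasso_path(D, lambdas: np.ndarray | None = None, **grid_kw) -> LassoPath:
    """Convenience wrapper: coefficient path for pair differences ``D``."""
    return PenalizedPairedLogit(D).fit_path(lambdas, **grid_kw)


def _held_out_deviance(Dtest: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Mean per-pair conditional deviance at every lambda (rows of coefs)."""
    eta = Dtest @ coefs.T  # n_test x n_lambda
    return 2.0 * np.logaddexp(0.0, -eta).mean(axis=0)


def cv_lambda_1se(
    D, folds: int = 5, lambdas: np.ndarray | None = None, seed: int = 0, **grid_kw
) -> CVResult:
    """K-fold cross-validation of the penalty with the one-SE rule.

    Pairs (never individual subjects) are partitioned into folds; each
    fold's error is the mean held-out conditional binomial deviance, the SE
    is the SD of fold errors over ``sqrt(folds)``, and ``lambda_1se`` is the
    largest penalty whose mean deviance is within one SE of the minimum.
    """
    M, names = _as_matrix(D)
    n = M.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} pairs for {folds}-fold CV, got {n}")
    model = PenalizedPairedLogit(M)
    grid = model.lambda_grid(**grid_kw) if lambdas is None else np.sort(np.asarray(lambdas, float))[::-1]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_dev = np.empty((folds, len(grid)))
    for f, test_idx in enumerate(np.array_split(perm, folds)):
        if len(test_idx) == 0:
            raise ValueError(f"fold {f} is empty")
        train = np.setdiff1d(perm, test_idx)
        path = PenalizedPairedLogit(M[train]).fit_path(grid)
        fold_dev[f] = _held_out_deviance(M[test_idx], path.coefs.to_numpy())
    mean = fold_dev.mean(axis=0)
    se = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean))
    ok = mean <= mean[i_min] + se[i_min]
    i_1se = int(np.flatnonzero(ok)[0])  # grid is descending: first hit = largest lambda
    return CVResult(grid, mean, se, float(grid[i_min]), float(grid[i_1se]))


def bolasso(
    D,
    B: int = 100,
    folds: int = 5,
    threshold: float = 0.90,
    seed: int = 0,
    **grid_kw,
) -> SelectionReport:
    """Bootstrap-lasso (BoLasso) selection frequencies over matched pairs.

    For each of ``B`` bootstrap replicates the matched pairs are resampled
    with replacement as units, the penalty is chosen by ``folds``-fold CV
    with the one-SE rule, the lasso is refitted at that penalty on the full
    replicate, and the nonzero support is recorded.  Replicate failures are
    excluded with a warning; more than 10% failures raise.
    """
    M, names = _as_matrix(D)
    n = M.shape[0]
    ss = np.random.SeedSequence(seed)
    counts = np.zeros(M.shape[1])
    n_fail = 0
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, n)
        Mb = M[idx]
        # fold assignment seeded per replicate from the master seed
        cv_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            cv = cv_lambda_1se(Mb, folds=folds, seed=cv_seed, **grid_kw)
            path = PenalizedPairedLogit(Mb).fit_path(cv.lambdas)
            counts += path.support_at(cv.lambda_1se)
        except (LassoConvergenceError, ValueError) as err:
            n_fail += 1
            warnings.warn(f"bootstrap replicate {b} failed and was excluded: {err}")
    n_ok = B - n_fail
    if n_fail > 0.10 * B:
        raise LassoConvergenceError(f"{n_fail}/{B} bootstrap replicates failed")
    freqs = pd.Series(counts / n_ok, index=pd.Index(names, name="feature"))
    return SelectionReport(freqs, threshold, B=n_ok, seed=seed, n_failures=n_fail)
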