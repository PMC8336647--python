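"""Variable clustering around latent principal components.

Standardized metabolite variables are clustered agglomeratively so that
each cluster stays homogeneous in the sense of its leading principal
component: the homogeneity of a cluster is the largest eigenvalue
``lambda_1`` of the cluster's correlation matrix (the variance explained by
its first PC), and the criterion ``H = sum over clusters of lambda_1`` is
greedily preserved — each step merges the pair of clusters whose merge
loses the least homogeneity.  One unit-variance first-PC score per cluster
("representative") summarizes the cluster for downstream regression, and
representatives can be residualized on BMI so selection operates on
BMI-independent variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .data import AnalysisMatrix

__all__ = ["ClusterSet", "VariableClustering", "cluster_variables", "residualize_on_bmi"]


def _lambda1(R: np.ndarray, members: list[int]) -> float:
    if len(members) == 1:
        return 1.0
    sub = R[np.ix_(members, members)]
    return float(eigh(sub, eigvals_only=True, subset_by_index=(len(members) - 1,) * 2)[0])


@dataclass
class ClusterSet:
    """A cut of the variable-clustering tree.

    ``assignment`` maps feature -> cluster id (0..k-1, ordered by lowest
    member feature index); ``homogeneity`` holds each cluster's leading
    eigenvalue; ``representatives`` the unit-variance first-PC scores;
    ``merge_history`` one row per executed merge with its homogeneity loss.
    """

    k: int
    assignment: pd.Series
    homogeneity: pd.Series
    representatives: pd.DataFrame
    merge_history: pd.DataFrame

    @property
    def total_homogeneity(self) -> float:
        return float(self.homogeneity.sum())

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])


class VariableClustering:
    """Model object: builds the full merge path once, cuts at any k.

    Parameters
    ----------
    X : AnalysisMatrix or DataFrame
        Subject x feature matrix; features are internally standardized and
        clustering operates on their correlation matrix.
    """

    def __init__(self, X):
        frame = X.X if isinstance(X, AnalysisMatrix) else X
        vals = frame.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant column {frame.columns[sd == 0][0]!r}")
        self.Xs = (vals - vals.mean(axis=0)) / sd
        self.features = list(frame.columns)
        self.index = frame.index
        self.R = np.corrcoef(self.Xs, rowvar=False).reshape(len(self.features), len(self.features))
        self._path = None  # list of merges: (members_a, members_b, loss, H_after)

    # -- merge path --------------------------------------------------------
    def _build_path(self) -> None:
        p = len(self.features)
        clusters: dict[int, list[int]] = {j: [j] for j in range(p)}
        lam: dict[int, float] = {j: 1.0 for j in range(p)}
        merged_lam: dict[tuple[int, int], float] = {}

        def loss(a: int, b: int) -> float:
            key = (a, b) if a < b else (b, a)
            if key not in merged_lam:
                merged_lam[key] = _lambda1(self.R, clusters[a] + clusters[b])
            return lam[a] + lam[b] - merged_lam[key]

        path = []
        H = float(p)
        while len(clusters) > 1:
            ids = sorted(clusters, key=lambda c: min(clusters[c]))
            best = None
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    l = loss(a, b)
                    # ties broken by lowest member feature index (determinism)
                    cand = (l, min(clusters[a]), min(clusters[b]), a, b)
                    if best is None or cand < best:
                        best = cand
            l, _, _, a, b = best
            new_members = sorted(clusters[a] + clusters[b])
            H -= l
            path.append((clusters[a], clusters[b], l, H))
            key = (a, b) if a < b else (b, a)
            new_lam = merged_lam[key]
            for c in (a, b):
                del clusters[c], lam[c]
            merged_lam = {k2: v for k2, v in merged_lam.items() if a not in k2 and b not in k2}
            clusters[a] = new_members
            lam[a] = new_lam
        self._path = path

    @property
    def path(self):
        if self._path is None:
            self._build_path()
        return self._path

    def default_k(self, max_loss_fraction: float = 0.05) -> int:
        """Elbow rule: merge while each merge loses < ``max_loss_fraction`` of current H."""
        p = len(self.features)
        H = float(p)
        k = p
        for _, _, l, H_after in self.path:
            if l >= max_loss_fraction * H:
                break
            k -= 1
            H = H_after
        return max(k, 1)

    def fit(self, k: int | None = None) -> ClusterSet:
        """Cut the tree at ``k`` clusters and extract PC representatives."""
        p = len(self.features)
        if k is None:
            k = self.default_k()
        if not 1 <= k <= p:
            raise ValueError(f"k must be in [1, {p}], got {k}")
        # replay the first p-k merges over singleton sets
        parent = list(range(p))

        def find(j):
            while parent[j] != j:
                parent[j] = parent[parent[j]]
                j = parent[j]
            return j

        history = []
        for step, (ma, mb, l, H_after) in enumerate(self.path[: p - k]):
            ra, rb = find(ma[0]), find(mb[0])
            parent[max(ra, rb)] = min(ra, rb)
            history.append(
                {
                    "step": step + 1,
                    "cluster_a": self.features[min(ma)],
                    "cluster_b": self.features[min(mb)],
                    "loss": l,
                    "total_H_after": H_after,
                }
            )
        roots = sorted({find(j) for j in range(p)})
        relabel = {r: i for i, r in enumerate(roots)}
        assign = pd.Series(
            [relabel[find(j)] for j in range(p)], index=pd.Index(self.features, name="feature")
        )
        lam1, reps = {}, {}
        for cid in range(k):
            members = np.flatnonzero(assign.values == cid)
            lam1[cid] = _lambda1(self.R, list(members))
            reps[cid] = self._representative(list(members))
        representatives = pd.DataFrame(reps, index=self.index)
        representatives.columns = [f"cluster_{c:03d}" for c in representatives.columns]
        return ClusterSet(
            k=k,
            assignment=assign,
            homogeneity=pd.Series(lam1, name="lambda1"),
            representatives=representatives,
            merge_history=pd.DataFrame(history),
        )

    def _representative(self, members: list[int]) -> np.ndarray:
        """Unit-variance first-PC score, oriented positively toward members."""
        sub = self.Xs[:, members]
        if len(members) == 1:
            return sub[:, 0]
        Rc = self.R[np.ix_(members, members)]
        w, v = eigh(Rc, subset_by_index=(len(members) - 1,) * 2)
        vec = v[:, 0]
        if vec.sum() < 0:  # mean correlation with members ∝ sum of loadings
            vec = -vec
        score = sub @ vec
        return score / score.std(ddof=1)


def cluster_variables(X, k: int | None = None) -> ClusterSet:
    """Cluster standardized variables and extract PCA representatives."""
    return VariableClustering(X).fit(k)


def residualize_on_bmi(representatives: pd.DataFrame, bmi: pd.Series) -> pd.DataFrame:
    """Residuals of each representative on an intercept + BMI (least squares).

    The residuals are mean-zero and orthogonal to BMI, so downstream
    selection sees only metabolite variation not explained by adiposity.
    """
    b = bmi.reindex(representatives.index).to_numpy(dtype=float)
    if np.isnan(b).any():
        raise ValueError("BMI has missing values; impute covariates first")
    if b.std() == 0:
        raise ValueError("BMI is constant; cannot residualize")
    Z = np.column_stack([np.ones_like(b), b])
    Y = representatives.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ coef
    return pd.DataFrame(resid, index=representatives.index, columns=representatives.columns)
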