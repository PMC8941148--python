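"""Community composition analysis: count filtering, variance-stabilising
transform, Bray-Curtis dissimilarity, and distance-based linear models.

DistLM regresses a dissimilarity matrix on environmental predictors via
the Gower-centred inner-product matrix G = -1/2 J (D o D) J.  For a hat
matrix H built from m centred predictors,

    pseudo-F = [tr(HGH)/m] / [tr((I-H)G(I-H)) / (n-m-1)]

with significance by permutation: unrestricted label permutation for
marginal (single-predictor) tests and Freedman-Lane residual permutation
under the reduced model for sequential tests.  Forward selection uses
adjusted R^2 (AIC offered as an alternative); dbRDA is the
eigen-ordination of the fitted variation HGH.

The variance-stabilising transform is a re-derivation of the
negative-binomial common-dispersion case (median-of-ratios size factors,
method-of-moments dispersion, closed-form NB variance integral); it is
not a bit-exact clone of any reference implementation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "rare_filter",
    "size_factors",
    "estimate_dispersion",
    "vst",
    "bray_curtis",
    "DistLM",
    "DistLMResults",
    "dbrda",
]


# --------------------------------------------------------------------------
# count-table preparation
# --------------------------------------------------------------------------

def rare_filter(
    counts: pd.DataFrame, min_count: int = 3, prevalence: float = 0.20
) -> pd.DataFrame:
    """Drop rare ASVs: keep a column only if its count exceeds
    ``min_count`` (strictly) in at least ``ceil(prevalence * n_samples)``
    samples.  Idempotent."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    n = len(counts)
    need = math.ceil(prevalence * n)
    keep = (counts > min_count).sum(axis=0) >= need
    if not keep.any():
        raise ValueError(
            f"rare filter removed every ASV (n_samples={n}, "
            f"threshold >{min_count} in >={need} samples)"
        )
    return counts.loc[:, keep]


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (one per sample/row).

    Uses only ASVs with non-zero counts in every sample, the standard
    reference-set choice."""
    x = np.asarray(counts, float)
    allpos = (x > 0).all(axis=0)
    if not allpos.any():
        raise ValueError("no ASV present in all samples; cannot form reference")
    logx = np.log(x[:, allpos])
    logref = logx.mean(axis=0)
    return np.exp(np.median(logx - logref, axis=1))


def estimate_dispersion(counts: pd.DataFrame | np.ndarray, s: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion alpha on normalised counts:
    Var(x/s) ~ mu * mean(1/s) + alpha * mu^2 pooled over ASVs."""
    q = np.asarray(counts, float) / s[:, None]
    mu = q.mean(axis=0)
    v = q.var(axis=0, ddof=1)
    pos = mu > 0
    shot = np.mean(1.0 / s)
    num = np.sum(v[pos] - mu[pos] * shot)
    den = np.sum(mu[pos] ** 2)
    return num / den if den > 0 else 0.0


def vst(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilising transform for NB counts, common dispersion.

    Normalised counts q = x / s_j are mapped through the closed-form
    integral of 1/sqrt(Var(q)) for Var = q + alpha q^2:

        f(q) = log2( (1 + 2 a q + 2 sqrt(a q (1 + a q))) / (4 a) )

    which is log2-like for large counts.  If the pooled dispersion is
    non-positive (under-dispersed data) falls back to log2(q + 1) with a
    warning.
    """
    s = size_factors(counts)
    q = counts.to_numpy(float) / s[:, None]
    alpha = estimate_dispersion(counts, s)
    if alpha <= 0:
        warnings.warn(
            f"non-positive dispersion estimate ({alpha:.3g}); "
            "falling back to log2(q + 1)",
            stacklevel=2,
        )
        t = np.log2(q + 1.0)
    else:
        aq = alpha * q
        t = np.log2((1.0 + 2.0 * aq + 2.0 * np.sqrt(aq * (1.0 + aq))) / (4.0 * alpha))
    return pd.DataFrame(t, index=counts.index, columns=counts.columns)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (rows).

    Negative entries (possible after a variance-stabilising transform)
    are clipped to zero with a warning, since Bray-Curtis requires
    non-negative abundances."""
    x = table.to_numpy(float)
    if (x < 0).any():
        warnings.warn(
            "negative entries clipped to 0 before Bray-Curtis", stacklevel=2
        )
        x = np.clip(x, 0.0, None)
    zero_rows = (x.sum(axis=1) == 0).sum()
    if zero_rows >= 2:
        raise ValueError(
            "two or more all-zero samples: Bray-Curtis undefined for that pair"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in table.index])


# --------------------------------------------------------------------------
# DistLM / dbRDA
# --------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d * d) @ j


def _hat(xc: np.ndarray) -> np.ndarray:
    """Projection onto the column space of the centred predictors."""
    q, r = np.linalg.qr(xc)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max()))
    q = q[:, : int(rank)]
    return q @ q.T


def _pseudo_f(g: np.ndarray, h: np.ndarray, m: int) -> tuple[float, float]:
    """(pseudo-F, explained trace) for hat matrix h of rank m."""
    n = g.shape[0]
    hgh = float(np.trace(h @ g @ h))
    res = float(np.trace(g)) - hgh
    return (hgh / m) / (res / (n - m - 1)), hgh


class DistLM:
    """Distance-based linear model of a dissimilarity matrix on
    environmental predictors.

    Parameters
    ----------
    distance : skbio DistanceMatrix (or square ndarray).
    predictors : DataFrame of sample covariates, rows aligned with the
        distance matrix; standardised internally.
    """

    def __init__(self, distance, predictors: pd.DataFrame):
        if isinstance(distance, DistanceMatrix):
            d = distance.data
        else:
            d = np.asarray(distance, float)
            if not np.allclose(d, d.T):
                raise ValueError("distance matrix is not symmetric")
        self.n = d.shape[0]
        if self.n < 5:
            raise ValueError("need at least 5 samples")
        if len(predictors) != self.n:
            raise ValueError("predictor rows must match distance matrix size")
        if predictors.isna().any().any():
            raise ValueError("missing values in predictors")
        sd = predictors.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(f"constant predictors: {bad}")
        self.predictor_names = list(predictors.columns)
        self.x = ((predictors - predictors.mean()) / sd).to_numpy(float)
        self.g = _gower_center(d)
        self.total_ss = float(np.trace(self.g))

    # -- permutation engines ---------------------------------------------

    def _perms(self, n_perms: int, rng: np.random.Generator):
        """Yield permutations; exhaustive when n! <= n_perms."""
        if math.factorial(self.n) <= n_perms:
            yield from (np.array(p) for p in itertools.permutations(range(self.n)))
        else:
            for _ in range(n_perms):
                yield rng.permutation(self.n)

    def _marginal_test(
        self, col: int, n_perms: int, rng: np.random.Generator
    ) -> tuple[float, float, float]:
        xc = self.x[:, [col]]
        h = _hat(xc)
        f_obs, hgh = _pseudo_f(self.g, h, 1)
        exhaustive = math.factorial(self.n) <= n_perms
        hits = total = 0
        for perm in self._perms(n_perms, rng):
            hp = _hat(xc[perm])
            f_p, _ = _pseudo_f(self.g, hp, 1)
            hits += f_p >= f_obs - 1e-12
            total += 1
        if exhaustive:
            p = hits / total
        else:
            p = (hits + 1) / (total + 1)
        return f_obs, p, 100.0 * hgh / self.total_ss

    def _sequential_test(
        self, selected: list[int], candidate: int, n_perms: int,
        rng: np.random.Generator,
    ) -> tuple[float, float]:
        """Freedman-Lane test of ``candidate`` given ``selected``."""
        n = self.n
        h0 = (
            _hat(self.x[:, selected]) if selected else np.zeros((n, n))
        )
        full_cols = selected + [candidate]
        h = _hat(self.x[:, full_cols])
        m = len(full_cols)

        def f_stat(g: np.ndarray) -> float:
            hgh = float(np.trace(h @ g @ h))
            h0gh0 = float(np.trace(h0 @ g @ h0))
            res = float(np.trace(g)) - hgh
            return (hgh - h0gh0) / (res / (n - m - 1))

        f_obs = f_stat(self.g)
        gres = (np.eye(n) - h0) @ self.g @ (np.eye(n) - h0)
        gfit = self.g - gres
        hits = total = 0
        for perm in self._perms(n_perms, rng):
            gp = gfit + gres[np.ix_(perm, perm)]
            hits += f_stat(gp) >= f_obs - 1e-12
            total += 1
        if math.factorial(n) <= n_perms:
            return f_obs, hits / total
        return f_obs, (hits + 1) / (total + 1)

    def _adj_r2(self, cols: list[int]) -> float:
        if not cols:
            return 0.0
        h = _hat(self.x[:, cols])
        r2 = float(np.trace(h @ self.g @ h)) / self.total_ss
        m = len(cols)
        if self.n - m - 1 <= 0:
            return -np.inf
        return 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - m - 1)

    def _aic(self, cols: list[int]) -> float:
        # distance-based AIC as used in forward selection: n log(RSS/n) + 2m
        h = _hat(self.x[:, cols]) if cols else np.zeros((self.n, self.n))
        rss = self.total_ss - float(np.trace(h @ self.g @ h))
        return self.n * np.log(rss / self.n) + 2.0 * (len(cols) + 1)

    def fit(
        self,
        n_perms: int = 9999,
        seed: int | None = None,
        select: str = "adjR2",
    ) -> "DistLMResults":
        """Marginal tests for every predictor plus forward selection.

        ``select``: 'adjR2' (default) maximises adjusted R^2, 'aic'
        minimises a distance-based AIC."""
        rng = np.random.default_rng(seed)
        marg = pd.DataFrame(
            [
                (name, *self._marginal_test(i, n_perms, rng))
                for i, name in enumerate(self.predictor_names)
            ],
            columns=["predictor", "pseudo_F", "p_value", "pct_explained"],
        )

        remaining = list(range(len(self.predictor_names)))
        selected: list[int] = []
        seq_rows = []
        crit = self._adj_r2 if select == "adjR2" else self._aic
        better = (lambda a, b: a > b) if select == "adjR2" else (lambda a, b: a < b)
        current = crit(selected) if select == "adjR2" else self._aic([])
        while remaining:
            scores = [(crit(selected + [c]), c) for c in remaining]
            best_score, best_col = (
                max(scores) if select == "adjR2" else min(scores)
            )
            if not better(best_score, current):
                break
            f_seq, p_seq = self._sequential_test(selected, best_col, n_perms, rng)
            selected.append(best_col)
            remaining.remove(best_col)
            h = _hat(self.x[:, selected])
            cum = 100.0 * float(np.trace(h @ self.g @ h)) / self.total_ss
            seq_rows.append(
                {
                    "step": len(selected),
                    "predictor": self.predictor_names[best_col],
                    "criterion": best_score,
                    "pseudo_F": f_seq,
                    "p_value": p_seq,
                    "pct_cumulative": cum,
                }
            )
            current = best_score
        sequential = pd.DataFrame(
            seq_rows,
            columns=[
                "step", "predictor", "criterion", "pseudo_F", "p_value",
                "pct_cumulative",
            ],
        )
        total_pct = (
            float(sequential["pct_cumulative"].iloc[-1]) if len(sequential) else 0.0
        )
        return DistLMResults(
            model=self,
            marginal=marg,
            sequential=sequential,
            selected=[self.predictor_names[i] for i in selected],
            total_pct_explained=total_pct,
            n_perms=n_perms,
            seed=seed,
            criterion=select,
        )


@dataclass
class DistLMResults:
    model: DistLM
    marginal: pd.DataFrame
    sequential: pd.DataFrame
    selected: list[str]
    total_pct_explained: float
    n_perms: int
    seed: int | None
    criterion: str

    def summary(self) -> str:
        lines = [
            f"DistLM ({self.model.n} samples, {self.n_perms} permutations, "
            f"selection: {self.criterion})",
            "Marginal tests:",
            self.marginal.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            f"Forward selection -> {self.selected} "
            f"({self.total_pct_explained:.1f}% explained)",
        ]
        if len(self.sequential):
            lines.append(
                self.sequential.to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)


@dataclass
class DbRDAResult:
    eigenvalues: np.ndarray
    scores: np.ndarray  # samples x axes
    biplot: pd.DataFrame  # predictor correlations with axes
    explained_trace: float


def dbrda(distance, predictors: pd.DataFrame, n_axes: int | None = None) -> DbRDAResult:
    """Distance-based redundancy analysis ordination of the fitted
    variation HGH; sample scores are eigenvectors scaled by the square
    roots of the eigenvalues, predictor arrows are correlations of the
    (standardised) predictors with the axis scores."""
    model = DistLM(distance, predictors)
    h = _hat(model.x)
    hgh = h @ model.g @ h
    hgh = (hgh + hgh.T) / 2
    evals, evecs = np.linalg.eigh(hgh)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]))
    if not pos.any():
        raise ValueError("degenerate fit: no positive eigenvalues")
    evals, evecs = evals[pos], evecs[:, pos]
    if n_axes is not None:
        evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    scores = evecs * np.sqrt(evals)
    corr = np.array(
        [
            [np.corrcoef(model.x[:, i], scores[:, k])[0, 1] for k in range(len(evals))]
            for i in range(model.x.shape[1])
        ]
    )
    biplot = pd.DataFrame(
        corr,
        index=model.predictor_names,
        columns=[f"dbRDA{k + 1}" for k in range(len(evals))],
    )
    return DbRDAResult(
        eigenvalues=evals,
        scores=scores,
        biplot=biplot,
        explained_trace=float(np.trace(hgh)),
    )
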