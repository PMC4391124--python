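"""Latent class analysis of dichotomous frailty components.

A latent class model with C classes over J binary items has mixing
proportions pi_c and conditional probabilities p_cj = P(item j positive |
class c); the likelihood of a response pattern x is

    P(x) = sum_c pi_c * prod_j p_cj^x_j (1 - p_cj)^(1 - x_j)

Parameters are estimated by multi-start EM on the pattern-frequency table
(2^J cells). Model comparison uses AIC/BIC with k = (C-1) + JC free
parameters and a Pearson chi-square over all response patterns. Fitting the
five frailty components with 1/2/3 classes tests whether they aggregate
into a syndrome: an adequate >=2-class fit with rising per-class conditional
probabilities is the internal-construct-validity signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "LatentClassModel",
    "tabulate_patterns",
    "fit_lca",
    "information_criteria",
    "pearson_gof",
    "compare_models",
    "pattern_matrix",
]


def pattern_matrix(n_items: int) -> np.ndarray:
    """All 2^n_items binary patterns, lexicographic, as a (2^J, J) array."""
    codes = np.arange(1 << n_items)
    bits = (codes[:, None] >> np.arange(n_items - 1, -1, -1)[None, :]) & 1
    return bits.astype(float)


def tabulate_patterns(x: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Complete response-pattern frequency table of an n x J binary matrix.

    All 2^J cells are present (zeros retained), ordered lexicographically
    over the item columns. Raises on any entry outside {0, 1}.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D binary matrix")
    bad = ~np.isin(arr, (0.0, 1.0)).all(axis=1)
    if bad.any():
        raise ValueError(f"non-binary entry at row {int(np.flatnonzero(bad)[0])}")
    n_items = arr.shape[1]
    weights = 1 << np.arange(n_items - 1, -1, -1)
    codes = (arr.astype(np.int64) @ weights)
    counts = np.bincount(codes, minlength=1 << n_items)
    return pd.DataFrame(
        {
            "pattern": [format(i, f"0{n_items}b") for i in range(1 << n_items)],
            "count": counts,
        }
    )


def _counts_from_patterns(patterns) -> np.ndarray:
    if isinstance(patterns, pd.DataFrame):
        counts = patterns["count"].to_numpy(dtype=float)
    else:
        counts = np.asarray(patterns, dtype=float)
    m = counts.size
    if m & (m - 1) or m < 2:
        raise ValueError("pattern table length must be a power of two")
    if (counts < 0).any():
        raise ValueError("pattern counts must be non-negative")
    return counts


def _pattern_loglik(x: np.ndarray, mixing: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """log P(pattern) for every row of x under (mixing, cond)."""
    logp = x @ np.log(cond).T + (1.0 - x) @ np.log(1.0 - cond).T  # (P, C)
    logp = logp + np.log(mixing)[None, :]
    m = logp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(logp - m).sum(axis=1, keepdims=True))).ravel()


def information_criteria(
    loglik: float, n_classes: int, n: int, n_items: int = 5
) -> dict:
    """AIC/BIC with k = (C-1) + J*C free parameters.

    Returns full-precision values plus integer-truncated forms (floor), the
    convention used when quoting these criteria in published comparisons.
    """
    k = (n_classes - 1) + n_items * n_classes
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n)
    return {
        "n_params": k,
        "aic": aic,
        "bic": bic,
        "aic_int": int(np.floor(aic)),
        "bic_int": int(np.floor(bic)),
    }


class LatentClassModel(BaseEstimator):
    """Latent class model for binary items, estimated by multi-start EM.

    Parameters
    ----------
    n_classes : int, default 2
        Number of latent classes (1-5 supported).
    n_starts : int, default 20
        Random EM initialisations; the best converged likelihood wins.
    tol : float, default 1e-8
        Convergence threshold on the relative log-likelihood change.
    max_iter : int, default 1000
    random_state : int or None
        Seed for the initialisations.

    Attributes
    ----------
    weights_ : ndarray (n_classes,)
        Mixing proportions, classes ordered by expected number of positive
        items (least to most affected; ties broken by descending weight).
    conditionals_ : ndarray (n_classes, n_items)
        P(item positive | class).
    loglik_ : float
    n_params_, aic_, bic_ : model-comparison quantities (k = 6C-1 for J=5).
    converged_ : bool
    n_iter_, n_starts_used_ : EM bookkeeping.
    loglik_path_ : per-iteration log-likelihood of the winning start.
    """

    _EPS = 1e-6  # conditional-probability clamp against log(0) absorbing states

    def __init__(
        self,
        n_classes: int = 2,
        n_starts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 1000,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None) -> "LatentClassModel":
        """Fit from an n x J binary matrix."""
        return self.fit_patterns(tabulate_patterns(X))

    def fit_patterns(self, patterns) -> "LatentClassModel":
        """Fit from a complete 2^J pattern-frequency table."""
        counts = _counts_from_patterns(patterns)
        n_items = int(np.log2(counts.size))
        if not 1 <= self.n_classes <= 5:
            raise ValueError("n_classes must be between 1 and 5")
        if counts.sum() < 1:
            raise ValueError("pattern table is empty")
        x = pattern_matrix(n_items)
        n = counts.sum()

        if self.n_classes == 1:
            # Closed form: the one-class MLE is the item-independence model.
            p = np.clip((counts @ x) / n, self._EPS, 1.0 - self._EPS)[None, :]
            mixing = np.array([1.0])
            ll = float(counts @ _pattern_loglik(x, mixing, p))
            self._finalize(mixing, p, ll, counts, x, True, 0, 1, [ll])
            return self

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_starts)):
            res = self._em_single(counts, x, rng)
            if best is None or (res[4] and not best[4]) or (
                res[4] == best[4] and res[2] > best[2]
            ):
                best = res
        mixing, cond, ll, path, converged, n_iter = (
            best[0], best[1], best[2], best[3], best[4], best[5],
        )
        self._finalize(mixing, cond, ll, counts, x, converged, n_iter,
                       max(1, self.n_starts), path)
        return self

    def _em_single(self, counts, x, rng):
        c = self.n_classes
        n_items = x.shape[1]
        mixing = rng.dirichlet(np.full(c, 5.0))
        cond = rng.uniform(0.2, 0.8, size=(c, n_items))
        prev = -np.inf
        path = []
        converged = False
        for it in range(1, self.max_iter + 1):
            # E-step: posterior class responsibilities per pattern
            logp = x @ np.log(cond).T + (1.0 - x) @ np.log(1.0 - cond).T
            logp += np.log(np.clip(mixing, 1e-300, None))[None, :]
            m = logp.max(axis=1, keepdims=True)
            p_pat = np.exp(logp - m)
            denom = p_pat.sum(axis=1, keepdims=True)
            resp = p_pat / denom
            ll = float(counts @ (m.ravel() + np.log(denom.ravel())))
            if path and ll < path[-1] - 1e-8:
                raise RuntimeError("EM log-likelihood decreased")  # should never fire
            path.append(ll)
            if prev > -np.inf and abs(ll - prev) <= self.tol * (abs(prev) + 1e-12):
                converged = True
                break
            prev = ll
            # M-step: closed-form updates
            w = resp * counts[:, None]  # (P, C)
            cls_tot = w.sum(axis=0)
            mixing = cls_tot / counts.sum()
            cond = (w.T @ x) / np.clip(cls_tot[:, None], 1e-300, None)
            cond = np.clip(cond, self._EPS, 1.0 - self._EPS)
        return mixing, cond, ll, path, converged, it

    def _finalize(self, mixing, cond, ll, counts, x, converged, n_iter,
                  n_starts_used, path):
        # Relabel: ascending expected component count, ties by weight desc.
        expected = cond.sum(axis=1)
        order = np.lexsort((-mixing, expected))
        self.weights_ = mixing[order]
        self.conditionals_ = cond[order]
        self.loglik_ = ll
        self.converged_ = bool(converged)
        self.n_iter_ = int(n_iter)
        self.n_starts_used_ = int(n_starts_used)
        self.loglik_path_ = list(path)
        self.n_items_ = x.shape[1]
        self.n_obs_ = float(counts.sum())
        ic = information_criteria(ll, self.n_classes, int(round(self.n_obs_)),
                                  n_items=self.n_items_)
        self.n_params_ = ic["n_params"]
        self.aic_ = ic["aic"]
        self.bic_ = ic["bic"]
        if not converged:
            warnings.warn("no EM start converged; results flagged converged_=False",
                          stacklevel=2)

    # -- inference --------------------------------------------------------
    def score_patterns(self, patterns) -> float:
        """Direct log-likelihood of a pattern table at the fitted parameters."""
        counts = _counts_from_patterns(patterns)
        x = pattern_matrix(int(np.log2(counts.size)))
        return float(counts @ _pattern_loglik(x, self.weights_, self.conditionals_))

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class probabilities for each row of a binary matrix."""
        x = np.asarray(X, dtype=float)
        logp = x @ np.log(self.conditionals_).T + (1.0 - x) @ np.log(
            1.0 - self.conditionals_
        ).T
        logp += np.log(self.weights_)[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def expected_counts(self) -> np.ndarray:
        """Model-expected frequency of every response pattern."""
        x = pattern_matrix(self.n_items_)
        return self.n_obs_ * np.exp(
            _pattern_loglik(x, self.weights_, self.conditionals_)
        )


def fit_lca(
    patterns,
    n_classes: int,
    starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> LatentClassModel:
    """Functional wrapper: fit a latent class model to a pattern table."""
    model = LatentClassModel(
        n_classes=n_classes, n_starts=starts, tol=tol, max_iter=max_iter,
        random_state=seed,
    )
    return model.fit_patterns(patterns)


def pearson_gof(model: LatentClassModel, patterns) -> tuple[float, int, float]:
    """Pearson chi-square over all 2^J response patterns.

    chi2 = sum (O - E)^2 / E; df = 2^J - 1 - k; p from the upper tail.
    Near-zero expected cells contribute through a guarded denominator and
    raise a sparse-cell warning.
    """
    counts = _counts_from_patterns(patterns)
    if counts.size != 1 << model.n_items_:
        raise ValueError("pattern table does not match the fitted model")
    if abs(counts.sum() - model.n_obs_) > 1e-9:
        raise ValueError("pattern table total differs from the fitted data")
    expected = model.expected_counts()
    if (expected < 1e-12).any():
        warnings.warn("near-empty expected cells in Pearson chi-square",
                      stacklevel=2)
    chi2 = float(((counts - expected) ** 2 / np.clip(expected, 1e-12, None)).sum())
    df = counts.size - 1 - model.n_params_
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, df, p


def compare_models(
    patterns,
    class_range=(1, 2, 3),
    starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit a model per class count and tabulate fit statistics.

    One row per class count: loglik, AIC, BIC (full precision and integer-
    truncated), Pearson chi-square with df and p, plus flags marking the
    AIC- and BIC-minimising rows. The log-likelihood must be non-decreasing
    in the class count; a decrease beyond 1e-6 marks a trapped start and
    triggers one refit with triple the starts.
    """
    class_range = sorted(class_range)
    if not set(class_range) <= {1, 2, 3, 4, 5}:
        raise ValueError("class_range must be within 1-5")
    counts = _counts_from_patterns(patterns)
    rows = []
    models: dict[int, LatentClassModel] = {}
    prev_ll = -np.inf
    for i, c in enumerate(class_range):
        model = fit_lca(counts, c, starts=starts, tol=tol, max_iter=max_iter,
                        seed=None if seed is None else seed + c)
        if model.loglik_ < prev_ll - 1e-6:
            model = fit_lca(counts, c, starts=3 * starts, tol=tol,
                            max_iter=max_iter,
                            seed=None if seed is None else seed + 1000 + c)
        prev_ll = max(prev_ll, model.loglik_)
        chi2, df, p = pearson_gof(model, counts)
        models[c] = model
        rows.append(
            {
                "n_classes": c,
                "loglik": model.loglik_,
                "n_params": model.n_params_,
                "aic": model.aic_,
                "bic": model.bic_,
                "aic_int": int(np.floor(model.aic_)),
                "bic_int": int(np.floor(model.bic_)),
                "chi2": chi2,
                "chi2_df": df,
                "chi2_p": p,
                "converged": model.converged_,
            }
        )
    table = pd.DataFrame(rows)
    table["best_aic"] = table["aic"] == table["aic"].min()
    table["best_bic"] = table["bic"] == table["bic"].min()
    table.attrs["models"] = models
    return table
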