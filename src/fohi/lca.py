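"""Latent class analysis of binned category-score profiles.

The three category scores per unit are binned into four ordered groups
(below 40.01, 40.01-50, 50.01-60, above 60) and the resulting categorical
response patterns are modeled as a finite mixture of multinomial classes:

    P(x) = sum_k pi_k * prod_j rho[k, j, x_j]

fit by EM with random multi-start, with the class count selected by BIC
over a candidate range (2-6 by default) and units assigned to their modal
posterior class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class LcaError(ValueError):
    pass


#: Upper edges of the four score groups (scores rounded to 2 decimals first).
BIN_EDGES = (40.0, 50.0, 60.0)


def bin_scores(scores):
    """Map 0-100 scores to group codes 1..4.

    Scores are rounded to 2 decimals (the reporting precision) so the group
    boundaries "below 40.01" / "40.01-50" / "50.01-60" / "above 60" are
    exhaustive: <= 40.00 -> 1, 40.01-50.00 -> 2, 50.01-60.00 -> 3,
    > 60.00 -> 4. Accepts a scalar or an array; returns int codes.
    """
    x = np.asarray(scores, dtype=float)
    if np.any(x < 0) or np.any(x > 100):
        raise LcaError("scores must lie in [0, 100]")
    r = np.round(x, 2)
    codes = np.ones_like(r, dtype=int)
    for edge in BIN_EDGES:
        codes += (r > edge).astype(int)
    if codes.shape == ():
        return int(codes)
    return codes


def bin_profiles(category_scores: pd.DataFrame) -> pd.DataFrame:
    """Bin each category-score column into group codes 1..4."""
    return pd.DataFrame(
        {c: bin_scores(category_scores[c].to_numpy()) for c in category_scores.columns},
        index=category_scores.index,
    )


@dataclass
class LCAModel:
    """Fitted multinomial latent class model.

    ``rho[k, j, c]`` is the probability that a unit in class k responds with
    category c+1 on item j. Classes are canonicalized by descending
    prevalence. ``n_parameters = (K-1) + K * sum_j (C_j - 1)``.
    """

    n_classes: int
    prevalences: np.ndarray            # (K,)
    rho: np.ndarray                    # (K, J, C_max); unused cells are 0
    n_categories: tuple[int, ...]      # C_j per item
    items: list[str]
    log_likelihood: float
    n_parameters: int
    bic: float
    posterior: pd.DataFrame            # units x K


def _as_codes(profiles: pd.DataFrame, n_categories) -> tuple[np.ndarray, tuple[int, ...]]:
    X = pd.DataFrame(profiles).to_numpy()
    if X.size == 0:
        raise LcaError("empty profile table")
    if not np.issubdtype(X.dtype, np.number):
        raise LcaError("profiles must be integer category codes")
    Xi = X.astype(int)
    if not np.array_equal(Xi, X):
        raise LcaError("profiles must be integer category codes")
    if (Xi < 1).any():
        raise LcaError("category codes start at 1")
    J = Xi.shape[1]
    if n_categories is None:
        cats = tuple(int(Xi[:, j].max()) for j in range(J))
    else:
        cats = tuple(int(c) for c in n_categories)
        for j in range(J):
            if Xi[:, j].max() > cats[j]:
                raise LcaError(f"item {j}: code exceeds n_categories={cats[j]}")
    return Xi, cats


def _loglik_matrix(Xi, pi, rho):
    """log P(x_i, class k): (n, K)."""
    n, J = Xi.shape
    K = pi.size
    ll = np.tile(np.log(pi), (n, 1))
    for j in range(J):
        ll += np.log(rho[:, j, Xi[:, j] - 1]).T
    return ll


def lca_em_fit(
    profiles: pd.DataFrame,
    n_classes: int,
    *,
    n_starts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
    n_categories=None,
) -> LCAModel:
    """Fit a K-class multinomial mixture by EM with random multi-start.

    Each start draws initial prevalences and item-response rows from a flat
    Dirichlet; EM alternates posterior responsibilities (E) and weighted
    frequency estimates (M), stops when the log-likelihood gain drops below
    ``tol``, and the best start is kept. Response probabilities are floored
    at 1e-6 (renormalized) to avoid zero-probability degeneracy; the
    log-likelihood is asserted non-decreasing across iterations. Classes are
    reordered by descending prevalence, so reported parameters are
    deterministic given the seed.
    """
    df = pd.DataFrame(profiles)
    Xi, cats = _as_codes(df, n_categories)
    n, J = Xi.shape
    K = int(n_classes)
    if K < 1:
        raise LcaError("n_classes must be >= 1")
    if K >= n:
        raise LcaError(f"n_classes={K} must be smaller than n_units={n}")
    C_max = max(cats)
    rng = np.random.default_rng(seed)
    floor = 1e-6

    onehot = np.zeros((J, n, C_max))
    for j in range(J):
        onehot[j, np.arange(n), Xi[:, j] - 1] = 1.0

    best = None
    for _ in range(max(1, n_starts)):
        pi = rng.dirichlet(np.ones(K))
        rho = np.zeros((K, J, C_max))
        for j in range(J):
            rho[:, j, : cats[j]] = rng.dirichlet(np.ones(cats[j]), size=K)
        prev_ll = -np.inf
        for _it in range(max_iter):
            ll_mat = _loglik_matrix(Xi, pi, rho)
            m = ll_mat.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(ll_mat - m).sum(axis=1))
            ll = float(lse.sum())
            # flooring of rho can perturb the exact EM ascent by O(floor)
            assert ll >= prev_ll - 1e-7 * max(1.0, abs(prev_ll)), (
                "EM log-likelihood decreased"
            )
            tau = np.exp(ll_mat - lse[:, None])
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                prev_ll = ll
                break
            prev_ll = ll
            nk = tau.sum(axis=0)
            pi = np.maximum(nk / n, floor)
            pi = pi / pi.sum()
            for j in range(J):
                counts = tau.T @ onehot[j]          # (K, C_max)
                block = counts[:, : cats[j]] + 0.0
                block = np.maximum(block / block.sum(axis=1, keepdims=True), floor)
                rho[:, j, : cats[j]] = block / block.sum(axis=1, keepdims=True)
        if best is None or prev_ll > best[0]:
            best = (prev_ll, pi.copy(), rho.copy())

    ll, pi, rho = best
    order = np.argsort(-pi, kind="stable")
    pi = pi[order]
    rho = rho[order]
    ll_mat = _loglik_matrix(Xi, pi, rho)
    m = ll_mat.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(ll_mat - m).sum(axis=1))
    tau = np.exp(ll_mat - lse[:, None])
    p = (K - 1) + K * sum(c - 1 for c in cats)
    bic = -2.0 * ll + p * np.log(n)
    return LCAModel(
        n_classes=K,
        prevalences=pi,
        rho=rho,
        n_categories=cats,
        items=list(df.columns),
        log_likelihood=ll,
        n_parameters=p,
        bic=float(bic),
        posterior=pd.DataFrame(
            tau, index=df.index, columns=[f"class_{k + 1}" for k in range(K)]
        ),
    )


def select_by_bic(
    profiles: pd.DataFrame,
    k_range=range(2, 7),
    *,
    n_starts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
    n_categories=None,
) -> tuple[LCAModel, pd.DataFrame]:
    """Fit every class count in ``k_range`` and keep the lowest-BIC model.

    Per-K seeds are spawned deterministically from ``seed``. Returns the
    winning model and the K-vs-(loglik, parameters, BIC) table.
    """
    ks = list(k_range)
    if not ks:
        raise LcaError("empty class range")
    children = np.random.SeedSequence(seed).spawn(len(ks))
    rows = []
    best_model = None
    for k, child in zip(ks, children):
        model = lca_em_fit(
            profiles,
            k,
            n_starts=n_starts,
            max_iter=max_iter,
            tol=tol,
            seed=child,
            n_categories=n_categories,
        )
        rows.append(
            {
                "n_classes": k,
                "log_likelihood": model.log_likelihood,
                "n_parameters": model.n_parameters,
                "bic": model.bic,
            }
        )
        if best_model is None or model.bic < best_model.bic:
            best_model = model
    return best_model, pd.DataFrame(rows).set_index("n_classes")


def assign_classes(model: LCAModel) -> pd.DataFrame:
    """Modal posterior assignment per unit; ties break to the lower class."""
    tau = model.posterior.to_numpy()
    modal = tau.argmax(axis=1)  # argmax returns the first (lowest) maximum
    return pd.DataFrame(
        {
            "class": modal + 1,
            "max_posterior": tau[np.arange(tau.shape[0]), modal],
        },
        index=model.posterior.index,
    )
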