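"""Unsupervised population-structure inference.

Contains a genotype PCA, a BIC-guided k-means cluster search (an analogue
of adegenet's ``find.clusters``), a maximum-likelihood admixture model
fitted by EM, replicate-run machinery with greedy Q-matrix alignment, and
the Evanno delta-K statistic over replicate likelihoods.

The admixture model treats each individual i's genotype at locus l as
2 binomial draws with ALT probability ``sum_k q_ik p_kl``:

    lnL = sum_il [ g_il ln(sum_k q_ik p_kl) + (2 - g_il) ln(sum_k q_ik (1 - p_kl)) ]

with missing genotypes skipped.  The EM updates are the standard
frequency/ancestry decoupled updates and increase lnL monotonically.  This
is the maximum-likelihood analogue of Bayesian MCMC admixture inference:
replicate-mean lnL stands in for the posterior mean model likelihood, so
only plateau and delta-K *patterns* are comparable across tools, not
absolute likelihood values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import GenotypeMatrix

P_EPS = 1e-6  # cluster allele frequencies clamped to [P_EPS, 1 - P_EPS]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray          # n_samples x n_axes
    explained_share: np.ndarray  # per retained axis, sums to <= 1
    loadings: np.ndarray         # n_loci_used x n_axes
    locus_means: np.ndarray      # imputation/centring means (dropped loci excluded)
    kept_loci: np.ndarray        # boolean mask over input loci


def pca_genotypes(
    matrix: GenotypeMatrix, n_axes: int = 10, scale: bool = False
) -> PCAResult:
    """PCA of the dosage matrix with per-locus mean imputation.

    Missing dosages are imputed with the locus mean, columns are centred
    (optionally scaled to unit variance), and the top ``min(n_axes, rank)``
    axes are returned.  Sign convention: the largest-magnitude loading on
    each axis is positive.  All-missing loci are dropped with a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.dosages.copy()
    obs = ~np.isnan(X)
    kept = obs.any(axis=0)
    if not kept.all():
        warnings.warn(
            f"dropped {int((~kept).sum())} all-missing locus/loci", stacklevel=2
        )
    X = X[:, kept]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X, axis=0)
    ix = np.where(np.isnan(X))
    X[ix] = means[ix[1]]
    Xc = X - means
    if scale:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    m = min(n_axes, rank)
    if m == 0:
        raise ValueError("matrix has no polymorphic locus")
    # fix signs: largest-|loading| entry positive per axis
    for j in range(m):
        peak = np.argmax(np.abs(Vt[j]))
        if Vt[j, peak] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :m] * S[:m]
    total_var = (Xc**2).sum()
    share = (S[:m] ** 2) / total_var if total_var > 0 else np.zeros(m)
    return PCAResult(
        scores=scores,
        explained_share=share,
        loadings=Vt[:m].T,
        locus_means=means,
        kept_loci=kept,
    )


# ---------------------------------------------------------------------------
# BIC cluster search (find.clusters analogue)
# ---------------------------------------------------------------------------


def find_clusters_bic(
    matrix: GenotypeMatrix,
    k_range: tuple[int, int] = (1, 8),
    n_pcs: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """K-means over PC scores for each k, scored by BIC(k) = n ln(WSS/n) + k ln(n).

    Returns the BIC curve (columns k, bic; skipped k omitted with a notice)
    and the cluster labels at the BIC-minimising k.  Multiple seeded k-means
    restarts (``n_init=10``) make the search deterministic given ``seed``.

    By default all principal axes (up to rank) are retained at this stage,
    following the cited clustering practice: the unstructured axes then
    dominate the within-cluster sum of squares, so extra clusters stop
    paying once the real structure is exhausted.  Retaining only a few
    informative axes makes the BIC curve decrease indefinitely.
    """
    k_lo, k_hi = k_range
    n = matrix.n_samples
    if not (1 <= k_lo <= k_hi <= n):
        raise ValueError(f"k_range must lie within [1, {n}]")
    scores = pca_genotypes(matrix, n_axes=n_pcs or matrix.n_samples).scores
    n_distinct = len(np.unique(scores.round(12), axis=0))
    rows = []
    labels_by_k = {}
    for k in range(k_lo, k_hi + 1):
        if k > n_distinct:
            warnings.warn(f"k={k} exceeds distinct points; skipped", stacklevel=2)
            continue
        if k == 1:
            wss = ((scores - scores.mean(axis=0)) ** 2).sum()
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
            wss = km.inertia_
            labels = km.labels_
        bic = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        rows.append({"k": k, "bic": bic})
        labels_by_k[k] = labels
    curve = pd.DataFrame(rows)
    best_k = int(curve.loc[curve["bic"].idxmin(), "k"])
    return curve, labels_by_k[best_k]


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray          # n_samples x K, rows sum to 1
    P: np.ndarray          # K x n_loci, in [P_EPS, 1 - P_EPS]
    loglik: float
    seed: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default=None, repr=False)

    def validate(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-12).any() or (self.Q > 1 + 1e-12).any():
            raise ValueError("Q entries outside [0,1]")
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValueError("P entries outside [0,1]")


def admixture_em(
    matrix: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> AdmixtureFit:
    """Fit the K-cluster admixture model by EM.

    Q is initialised from per-sample Dirichlet(1) draws and P from pooled
    frequencies with seeded jitter; convergence when the lnL gain drops
    below ``tol`` (or ``max_iter`` is reached).  Deterministic given seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    G = matrix.dosages
    M = ~np.isnan(G)
    if not M.any():
        raise ValueError("matrix has no observed genotypes")
    g = np.where(M, G, 0.0)
    gc = np.where(M, 2.0 - G, 0.0)  # REF-allele counts, 0 where missing
    n, L = G.shape
    rng = np.random.default_rng(seed)

    Q = rng.dirichlet(np.ones(K), size=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled = np.nanmean(G, axis=0) / 2.0
    pooled = np.nan_to_num(pooled, nan=0.5)
    P = np.clip(
        pooled[None, :] + rng.normal(0, 0.05, size=(K, L)), P_EPS, 1 - P_EPS
    )

    denom_q = 2.0 * M.sum(axis=1, keepdims=True).astype(float)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F1 = np.clip(Q @ P, 1e-300, None)          # P(ALT draw) per (i, l)
        F0 = np.clip(Q @ (1.0 - P), 1e-300, None)
        ll = float((g * np.log(F1) + gc * np.log(F0)).sum())
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            prev = ll
            break
        prev = ll
        # E-step responsibilities, accumulated into the M-step sums
        ra = g / F1   # n x L
        rb = gc / F0
        QP_a = np.einsum("il,ik,kl->ik", ra, Q, P)
        QP_b = np.einsum("il,ik,kl->ik", rb, Q, 1.0 - P)
        Q_new = (QP_a + QP_b) / denom_q
        num_p = np.einsum("il,ik,kl->kl", ra, Q, P)
        den_p = num_p + np.einsum("il,ik,kl->kl", rb, Q, 1.0 - P)
        with np.errstate(invalid="ignore", divide="ignore"):
            P_new = np.where(den_p > 0, num_p / den_p, P)
        Q = Q_new / Q_new.sum(axis=1, keepdims=True)
        P = np.clip(P_new, P_EPS, 1 - P_EPS)
    else:
        # budget exhausted after a parameter update: report the lnL of the
        # returned (Q, P), keeping loglik consistent with the fit
        F1 = np.clip(Q @ P, 1e-300, None)
        F0 = np.clip(Q @ (1.0 - P), 1e-300, None)
        prev = float((g * np.log(F1) + gc * np.log(F0)).sum())
        trace.append(prev)

    fit = AdmixtureFit(
        K=K,
        Q=Q,
        P=P,
        loglik=prev,
        seed=seed,
        n_iter=it,
        converged=converged,
        loglik_trace=np.array(trace),
    )
    fit.validate()
    return fit


# ---------------------------------------------------------------------------
# replicate runs, alignment, Evanno
# ---------------------------------------------------------------------------


def align_q_to_reference(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Greedy column permutation of Q maximising correlation with Q_ref.

    Columns of ``Q_ref`` are matched one at a time to the most-correlated
    unused column of ``Q`` (ties by column index).  Returns the permutation
    ``perm`` such that ``Q[:, perm]`` aligns with ``Q_ref``.
    """
    K = Q.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = Q_ref[:, i], Q[:, j]
            sa, sb = a.std(), b.std()
            corr[i, j] = (
                np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else (1.0 if i == j else 0.0)
            )
    perm = np.full(K, -1)
    used = set()
    # highest correlations claimed first
    order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
    for i, j in order:
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm


@dataclass
class ReplicateRuns:
    """All replicate admixture fits plus the per-K likelihood summaries."""

    logliks: dict[int, list[float]]
    best_fits: dict[int, AdmixtureFit]
    aligned_q: dict[int, list[np.ndarray]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for K in sorted(self.logliks):
            ll = np.asarray(self.logliks[K], dtype=float)
            rows.append(
                {
                    "K": K,
                    "mean_lnL": ll.mean(),
                    "sd_lnL": ll.std(ddof=1) if len(ll) > 1 else 0.0,
                    "n_runs": len(ll),
                }
            )
        return pd.DataFrame(rows)


def replicate_likelihood_table(
    matrix: GenotypeMatrix,
    k_range: tuple[int, int] = (1, 8),
    n_runs: int = 10,
    base_seed: int = 0,
    max_iter: int = 50,
    tol: float = 0.0,
) -> ReplicateRuns:
    """Run ``n_runs`` seeded admixture fits for each K in ``k_range``.

    Per K the best-lnL fit is retained and every replicate Q matrix is
    aligned to it by greedy column permutation (the run-alignment analogue
    of cluster-matching across replicate runs).

    Unlike a single :func:`admixture_em` fit, the replicate protocol runs
    every fit for the same fixed iteration budget (``tol=0``), mirroring the
    fixed-sweep design of replicate MCMC runs: likelihoods are then
    comparable across runs and K, and the replicate spread reflects both
    multimodality and unfinished hill-climbing.  Running each fit to full
    convergence instead makes the maximum-likelihood curve increase almost
    deterministically with K (by roughly half the parameter count per extra
    cluster), which has no plateau.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2 for replicate standard deviations")
    k_lo, k_hi = k_range
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn((k_hi - k_lo + 1) * n_runs)]
    logliks: dict[int, list[float]] = {}
    fits: dict[int, list[AdmixtureFit]] = {}
    si = 0
    for K in range(k_lo, k_hi + 1):
        fits[K] = []
        logliks[K] = []
        for _ in range(n_runs):
            fit = admixture_em(matrix, K, seed=seeds[si], max_iter=max_iter, tol=tol)
            si += 1
            fits[K].append(fit)
            logliks[K].append(fit.loglik)
    best = {K: fits[K][int(np.argmax(logliks[K]))] for K in fits}
    aligned = {}
    for K in fits:
        ref = best[K].Q
        aligned[K] = [f.Q[:, align_q_to_reference(f.Q, ref)] for f in fits[K]]
    return ReplicateRuns(logliks=logliks, best_fits=best, aligned_q=aligned)


def evanno_delta_k(logliks: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table: mean/sd lnL per K and delta-K at interior K values.

    delta-K(K) = |mean_lnL(K+1) - 2 mean_lnL(K) + mean_lnL(K-1)| / sd_lnL(K),
    undefined (NaN, flagged) where sd_lnL(K) = 0 or K is an endpoint.
    """
    ks = sorted(logliks)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    mean = {k: float(np.mean(logliks[k])) for k in ks}
    sd = {
        k: float(np.std(logliks[k], ddof=1)) if len(logliks[k]) > 1 else 0.0
        for k in ks
    }
    rows = []
    for k in ks:
        dk = np.nan
        defined = False
        if ks[0] < k < ks[-1] and sd[k] > 0:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
            defined = True
        rows.append(
            {"K": k, "mean_lnL": mean[k], "sd_lnL": sd[k], "deltaK": dk,
             "deltaK_defined": defined}
        )
    return pd.DataFrame(rows)


def plateau_k(summary: pd.DataFrame) -> int:
    """Smallest K whose mean lnL gain to K+1 falls below sd_lnL(K).

    Operationalises "the mean likelihood plateaued at K": the first K where
    the improvement from adding a cluster is within replicate noise.  Falls
    back to the largest K if no plateau is reached.
    """
    df = summary.sort_values("K").reset_index(drop=True)
    for i in range(len(df) - 1):
        gain = df.loc[i + 1, "mean_lnL"] - df.loc[i, "mean_lnL"]
        if gain < df.loc[i, "sd_lnL"]:
            return int(df.loc[i, "K"])
    return int(df["K"].iloc[-1])
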