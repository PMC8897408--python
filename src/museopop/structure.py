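"""Genotype-likelihood PCA, admixture EM and the Evanno Delta-K criterion.

PCA works on posterior-mean genotype dosages: per site the likelihood
triple is combined with a Hardy-Weinberg prior at the site's allele
frequency, missing individuals are mean-imputed, and sites are standardised
by ``sqrt(2 f (1 - f))`` before the individual-by-individual covariance is
eigendecomposed. This single-pass expectation is a deliberate
simplification of iterative individual-allele-frequency estimators: it
preserves the clustering structure that the analysis is used to display.

Admixture proportions maximise

    sum_i sum_s log sum_g GL_isg * P(g | h_is),   h_is = sum_k Q_ik F_sk

with ``P(g | h) = Binomial(2, h)``, via EM from random starts. Replicate
runs over a K range feed the Evanno Delta-K statistic,
``|L''(K)| / sd(L(K))``, whose argmax over interior K estimates the number
of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .likelihoods import ml_allele_frequency
from .simulate import stage_rng

_EPS = 1e-9


# ---------------------------------------------------------------------------
# expected dosages and PCA
# ---------------------------------------------------------------------------

def expected_genotypes(gl: np.ndarray, freqs: np.ndarray,
                       missing: np.ndarray | None = None) -> np.ndarray:
    """Posterior-mean minor-allele dosage per individual per site.

    ``gl`` is (S, N, 3) natural-log likelihoods; the prior is HWE at the
    per-site frequency. Missing entries are imputed at the prior mean
    ``2 * f``.
    """
    f = np.clip(np.asarray(freqs, dtype=np.float64), 1e-6, 1 - 1e-6)
    pri = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=1)[:, None, :]
    w = np.exp(gl) * pri
    tot = np.maximum(w.sum(axis=2), 1e-300)
    dose = (w[..., 1] + 2.0 * w[..., 2]) / tot
    if missing is not None:
        dose = np.where(missing, 2.0 * f[:, None], dose)
    return dose


@dataclass
class PCAResult:
    covariance: np.ndarray      # (N, N)
    eigenvalues: np.ndarray     # descending
    coordinates: np.ndarray     # (N, N) columns = PCs, scaled by sqrt(eigval)
    n_sites_used: int
    n_sites_skipped: int


def pca(dosage: np.ndarray, freqs: np.ndarray | None = None) -> PCAResult:
    """PCA of a (sites x individuals) expected-dosage matrix.

    Sites are centred at ``2 f`` and scaled by ``sqrt(2 f (1 - f))``;
    zero-variance sites are skipped (their count is reported).
    """
    S, N = dosage.shape
    if N < 2 or S < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 sites")
    if freqs is None:
        freqs = dosage.mean(axis=1) / 2.0
    f = np.asarray(freqs, dtype=np.float64)
    keep = (f > 0) & (f < 1) & (dosage.std(axis=1) > 0)
    X = (dosage[keep] - 2 * f[keep, None]) / np.sqrt(2 * f[keep, None] * (1 - f[keep, None]))
    cov = X.T @ X / max(keep.sum(), 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    return PCAResult(cov, vals, coords, int(keep.sum()), int((~keep).sum()))


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureModel:
    k: int
    q: np.ndarray           # (N, K), rows sum to 1
    f: np.ndarray           # (S, K) cluster allele frequencies
    log_likelihood: float
    log_likelihood_path: np.ndarray
    seed: int
    n_iter: int


def _admixture_loglik(lik: np.ndarray, h: np.ndarray) -> float:
    pri = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=-1)
    per = np.maximum((lik * pri).sum(axis=-1), 1e-300)
    return float(np.log(per).sum())


def _em_iterate(lik, q, f, max_iter, tol):
    """Run EM updates; returns (q, f, path, n_iter).

    The allele-to-cluster attribution is factorised into rank-K matrix
    products (no S x N x K temporaries), which is exact and keeps replicate
    grids over K tractable.
    """
    lik0, lik1, lik2 = lik[..., 0], lik[..., 1], lik[..., 2]
    path = []
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        h = np.clip(f @ q.T, _EPS, 1 - _EPS)               # (S, N)
        one_h = 1.0 - h
        w0 = lik0 * one_h * one_h
        w1 = lik1 * 2.0 * h * one_h
        w2 = lik2 * h * h
        tot = np.maximum(w0 + w1 + w2, 1e-300)
        ll = float(np.log(tot).sum())
        path.append(ll)
        e_der = (w1 + 2.0 * w2) / tot                      # (S, N)
        rd = e_der / h
        ra = (2.0 - e_der) / one_h
        q_new = q * (rd.T @ f + ra.T @ (1.0 - f))          # (N, K)
        fa = f * (rd @ q)                                  # (S, K)
        fb = (1.0 - f) * (ra @ q)
        q = q_new / q_new.sum(axis=1, keepdims=True)
        f = np.clip(fa / np.maximum(fa + fb, 1e-300), _EPS, 1 - _EPS)
        if tol is not None and ll - prev < tol and it > 1:
            prev = ll
            break
        prev = ll
    return q, f, path, it


def admixture_em(gl: np.ndarray, k: int, seed: int = 0,
                 max_iter: int = 2000, tol: float = 1e-6,
                 site_freqs: np.ndarray | None = None,
                 n_starts: int = 4, burn_in: int = 40) -> AdmixtureModel:
    """EM fit of the K-cluster admixture model to genotype likelihoods.

    ``gl`` is (S, N, 3) natural-log. Each run draws ``n_starts`` random
    initialisations (Q from a flat Dirichlet; each cluster's frequencies
    seeded from a randomly chosen individual's posterior dosages shrunk
    toward the site frequency), advances each for ``burn_in`` iterations,
    and continues the best to convergence — a standard guard against the
    local optima that plague admixture likelihoods at intermediate K. The
    continued run stops when the log-likelihood gain drops below ``tol``
    (monotone by construction) or at ``max_iter``.
    """
    S, N, _ = gl.shape
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > N:
        raise ValueError(f"K={k} exceeds the {N} individuals")
    rng = stage_rng(seed, "admixture", 0)
    lik = np.exp(np.asarray(gl, dtype=np.float64))        # (S, N, 3)
    if site_freqs is None:
        site_freqs, _ = ml_allele_frequency(gl)
    e_dose = expected_genotypes(gl, site_freqs)

    def init():
        q0 = rng.dirichlet(np.ones(k), size=N)             # (N, K)
        seeds_ind = rng.choice(N, size=min(k, N), replace=False)
        f0 = np.empty((S, k))
        for j in range(k):
            base = e_dose[:, seeds_ind[j % len(seeds_ind)]] / 2.0
            f0[:, j] = 0.7 * base + 0.3 * site_freqs
        return q0, np.clip(f0 + rng.normal(0.0, 0.01, size=(S, k)),
                           1e-4, 1 - 1e-4)

    best = None
    for _ in range(max(1, n_starts)):
        q0, f0 = init()
        q1, f1, path1, _ = _em_iterate(lik, q0, f0, burn_in, None)
        if best is None or path1[-1] > best[2][-1]:
            best = (q1, f1, path1)
    q, f, _ = best
    q, f, path, it = _em_iterate(lik, q, f, max_iter, tol)
    h = np.clip(f @ q.T, _EPS, 1 - _EPS)
    final_ll = _admixture_loglik(lik, h)
    path.append(final_ll)
    return AdmixtureModel(k=k, q=q, f=f, log_likelihood=final_ll,
                          log_likelihood_path=np.array(path), seed=seed,
                          n_iter=it)


def replicate_runs(gl: np.ndarray, k_values: Sequence[int] = range(1, 11),
                   reps: int = 15, seed: int = 0, max_iter: int = 2000,
                   tol: float = 1e-6):
    """Independent EM replicates per K; returns (table, best models).

    The table records every replicate's seed and final log-likelihood so
    any run can be reproduced bit-for-bit; the best model per K is the
    replicate with the highest log-likelihood.
    """
    import pandas as pd

    site_freqs, _ = ml_allele_frequency(gl)
    rows = []
    best: dict[int, AdmixtureModel] = {}
    for k in k_values:
        for rep in range(reps):
            rep_seed = int(np.random.SeedSequence(
                seed, spawn_key=(STAGE_REPLICATE, k, rep)).generate_state(1)[0] % (2 ** 31))
            model = admixture_em(gl, k, seed=rep_seed, max_iter=max_iter,
                                 tol=tol, site_freqs=site_freqs)
            rows.append({"K": k, "rep": rep, "seed": rep_seed,
                         "logL": model.log_likelihood, "n_iter": model.n_iter})
            if k not in best or model.log_likelihood > best[k].log_likelihood:
                best[k] = model
    return pd.DataFrame(rows), best


STAGE_REPLICATE = 1002   # spawn-key namespace for replicate seeds


# ---------------------------------------------------------------------------
# Evanno Delta-K
# ---------------------------------------------------------------------------

@dataclass
class DeltaKTable:
    k: np.ndarray
    mean_logl: np.ndarray
    sd_logl: np.ndarray
    l_prime: np.ndarray       # L'(K) = mean L(K) - mean L(K-1); NaN at ends
    l_doubleprime: np.ndarray  # |L'(K+1) - L'(K)|; NaN at ends
    delta_k: np.ndarray       # |L''(K)| / sd(L(K)); NaN where undefined
    best_k: int | None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "K": self.k, "mean_logL": self.mean_logl, "sd_logL": self.sd_logl,
            "L_prime": self.l_prime, "L_doubleprime": self.l_doubleprime,
            "deltaK": self.delta_k,
        })


def delta_k(table) -> DeltaKTable:
    """Evanno Delta-K from a replicate log-likelihood table.

    Needs >= 3 distinct K with >= 2 replicates each. Delta-K is defined
    only for interior K; K values with zero replicate scatter are excluded
    from the argmax with a warning.
    """
    import warnings

    grouped = table.groupby("K")["logL"]
    ks = np.array(sorted(table["K"].unique()))
    if len(ks) < 3:
        raise ValueError("Delta-K needs at least 3 K values")
    if (grouped.count() < 2).any():
        raise ValueError("Delta-K needs >= 2 replicates per K")
    means = grouped.mean().loc[ks].to_numpy()
    sds = grouped.std(ddof=1).loc[ks].to_numpy()
    n = len(ks)
    lp = np.full(n, np.nan)
    lp[1:] = means[1:] - means[:-1]
    lpp = np.full(n, np.nan)
    lpp[1:-1] = np.abs(lp[2:] - lp[1:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        dk = lpp / sds
    if np.any((sds == 0) & np.isfinite(lpp)):
        warnings.warn("zero replicate scatter at some K; Delta-K undefined there")
        dk = np.where(sds == 0, np.nan, dk)
    best = None
    if np.isfinite(dk).any():
        best = int(ks[np.nanargmax(dk)])
    return DeltaKTable(k=ks, mean_logl=means, sd_logl=sds, l_prime=lp,
                       l_doubleprime=lpp, delta_k=dk, best_k=best)


def align_q_columns(reference: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy column matching for display, resolving EM label switching."""
    k = q.shape[1]
    used = set()
    order = []
    for col in range(k):
        sims = [(-np.inf if j in used else float(reference[:, col] @ q[:, j]), j)
                for j in range(k)]
        j = max(sims)[1]
        used.add(j)
        order.append(j)
    return q[:, order]
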