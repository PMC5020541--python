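"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

Cells play the role of documents and discretised expression levels the role
of word counts: cell ``d`` emits ``counts[w, d]`` tokens of gene ``w``.  The
model is

    phi_k   ~ Dirichlet_V(beta),   k = 1..K   (per-topic gene distributions)
    theta_d ~ Dirichlet_K(alpha),  d = 1..M   (per-cell topic distributions)

and inference integrates theta and phi out, sampling only the token-topic
assignments z with the standard collapsed conditional

    p(z = k | rest)  propto  (n_dk + alpha_k) (n_kw + beta_w) / (n_k + sum beta).

Determinism: cells are processed in lexicographic cell-id order and each
cell draws from its own RNG substream keyed by (seed, canonical cell rank),
with tokens laid out in lexicographic gene-id order.  Fits are therefore
bit-identical under any permutation of the input rows or columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln

from .io import CountMatrix


class ConfigurationError(ValueError):
    pass


@dataclass
class TopicModel:
    """Fitted LDA state.

    theta : (M, K) posterior-mean per-cell topic distributions (rows sum to 1).
    phi : (K, V) posterior-mean per-topic gene distributions (rows sum to 1).
    alpha, beta : Dirichlet prior weight vectors (length K and V).
    assignments : final topic of every token, in canonical (cell, gene) order.
    loglik_trace : complete-data log likelihood log p(w, z) per sweep.
    """

    theta: np.ndarray
    phi: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    K: int
    cell_ids: list[str]
    gene_ids: list[str]
    assignments: np.ndarray
    loglik_trace: np.ndarray
    seed: int
    groups: dict[str, str] | None = None
    group_order: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(self.theta > 0) and np.all(self.phi > 0)
        assert len(self.alpha) == self.K
        assert len(self.beta) == self.phi.shape[1]

    @property
    def n_cells(self) -> int:
        return self.theta.shape[0]

    @property
    def n_genes(self) -> int:
        return self.phi.shape[1]

    def to_json_dict(self) -> dict:
        return {
            "K": int(self.K), "seed": int(self.seed),
            "cell_ids": self.cell_ids, "gene_ids": self.gene_ids,
            "alpha": self.alpha.tolist(), "beta": self.beta.tolist(),
            "theta": self.theta.tolist(), "phi": self.phi.tolist(),
            "groups": self.groups, "group_order": self.group_order,
            "provenance": {k: v for k, v in self.provenance.items()
                           if isinstance(v, (str, int, float, bool, type(None)))},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TopicModel":
        return cls(theta=np.array(d["theta"]), phi=np.array(d["phi"]),
                   alpha=np.array(d["alpha"]), beta=np.array(d["beta"]),
                   K=d["K"], cell_ids=d["cell_ids"], gene_ids=d["gene_ids"],
                   assignments=np.empty(0, dtype=np.int32),
                   loglik_trace=np.empty(0), seed=d["seed"],
                   groups=d.get("groups"), group_order=d.get("group_order"),
                   provenance=d.get("provenance", {}))


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_sweep(token_gene, cell_ptr, z, ndk, nkw, nk, alpha, beta,
                 beta_sum, u):  # pragma: no cover - exercised via fit_lda
    M = cell_ptr.shape[0] - 1
    K = ndk.shape[1]
    cum = np.empty(K)
    for d in range(M):
        for i in range(cell_ptr[d], cell_ptr[d + 1]):
            w = token_gene[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                p = (ndk[d, kk] + alpha[kk]) * (nkw[kk, w] + beta[w]) \
                    / (nk[kk] + beta_sum)
                total += p
                cum[kk] = total
            r = u[i] * total
            knew = 0
            while cum[knew] < r and knew < K - 1:
                knew += 1
            z[i] = knew
            ndk[d, knew] += 1
            nkw[knew, w] += 1
            nk[knew] += 1


@njit(cache=True)
def _conditional_probs(token_gene, cell_ptr, z, ndk, nkw, nk, alpha, beta,
                       beta_sum, out):  # pragma: no cover
    """Normalised conditional probability of each token's current assignment."""
    M = cell_ptr.shape[0] - 1
    K = ndk.shape[1]
    for d in range(M):
        for i in range(cell_ptr[d], cell_ptr[d + 1]):
            w = token_gene[i]
            k = z[i]
            total = 0.0
            pk = 0.0
            for kk in range(K):
                ndkk = ndk[d, kk] - (1 if kk == k else 0)
                nkww = nkw[kk, w] - (1 if kk == k else 0)
                nkk = nk[kk] - (1 if kk == k else 0)
                p = (ndkk + alpha[kk]) * (nkww + beta[w]) / (nkk + beta_sum)
                total += p
                if kk == k:
                    pk = p
            out[i] = pk / total


# ---------------------------------------------------------------------------
# Token layout
# ---------------------------------------------------------------------------

def _canonical_tokens(c: CountMatrix):
    """Expand counts into token arrays in canonical (cell-id, gene-id) order.

    Returns gene order, cell order (argsort indices into the input),
    token gene indices (into the sorted gene list) and cell pointer array.
    """
    gene_order = np.argsort(np.array(c.gene_ids))
    cell_order = np.argsort(np.array(c.cell_ids))
    counts = c.counts[np.ix_(gene_order, cell_order)]
    V, M = counts.shape
    token_gene_parts = []
    cell_ptr = np.zeros(M + 1, dtype=np.int64)
    for d in range(M):
        col = counts[:, d]
        nz = np.nonzero(col)[0]
        toks = np.repeat(nz.astype(np.int32), col[nz])
        token_gene_parts.append(toks)
        cell_ptr[d + 1] = cell_ptr[d] + toks.size
    token_gene = (np.concatenate(token_gene_parts) if token_gene_parts
                  else np.empty(0, dtype=np.int32))
    return gene_order, cell_order, token_gene, cell_ptr


def _cell_streams(seed: int, M: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, r])))
            for r in range(M)]


def _counts_from_z(z, token_gene, cell_ptr, K, V):
    M = cell_ptr.shape[0] - 1
    ndk = np.zeros((M, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    for d in range(M):
        sl = slice(cell_ptr[d], cell_ptr[d + 1])
        np.add.at(ndk[d], z[sl], 1)
        np.add.at(nkw, (z[sl], token_gene[sl]), 1)
    nk = nkw.sum(axis=1)
    return ndk, nkw, nk


def _joint_loglik(ndk, nkw, nk, alpha, beta):
    """Complete-data log likelihood log p(w, z | alpha, beta), collapsed."""
    return _word_loglik(nkw, nk, beta) + _z_loglik(ndk, alpha)


def _word_loglik(nkw, nk, beta):
    K = nkw.shape[0]
    beta_sum = beta.sum()
    return float(
        K * (gammaln(beta_sum) - gammaln(beta).sum())
        + gammaln(nkw + beta).sum() - gammaln(nk + beta_sum).sum())


def _z_loglik(ndk, alpha):
    M = ndk.shape[0]
    alpha_sum = alpha.sum()
    nd = ndk.sum(axis=1)
    return float(
        M * (gammaln(alpha_sum) - gammaln(alpha).sum())
        + gammaln(ndk + alpha).sum() - gammaln(nd + alpha_sum).sum())


def _as_prior(x, n: int, name: str) -> np.ndarray:
    v = np.full(n, float(x)) if np.isscalar(x) else np.asarray(x, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"{name} must be scalar or length-{n} vector")
    if np.any(v <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return v


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_core(token_gene, cell_ptr, K, alpha, beta, sweeps, burn_in, thin,
              streams, z_init=None, debug_checks=False):
    M = cell_ptr.shape[0] - 1
    V = beta.shape[0]
    N = token_gene.shape[0]
    beta_sum = float(beta.sum())

    if z_init is None:
        z = np.empty(N, dtype=np.int32)
        for d in range(M):
            sl = slice(cell_ptr[d], cell_ptr[d + 1])
            z[sl] = streams[d].integers(0, K, sl.stop - sl.start, dtype=np.int32)
    else:
        z = z_init.astype(np.int32).copy()
    ndk, nkw, nk = _counts_from_z(z, token_gene, cell_ptr, K, V)

    theta_acc = np.zeros((M, K))
    phi_acc = np.zeros((K, V))
    n_samples = 0
    loglik = np.empty(sweeps)
    word_ll = np.empty(sweeps)
    u = np.empty(N)
    nd = ndk.sum(axis=1)
    for s in range(sweeps):
        for d in range(M):
            sl = slice(cell_ptr[d], cell_ptr[d + 1])
            u[sl] = streams[d].random(sl.stop - sl.start)
        _gibbs_sweep(token_gene, cell_ptr, z, ndk, nkw, nk,
                     alpha, beta, beta_sum, u)
        if debug_checks:
            assert np.array_equal(ndk.sum(axis=1), nd)
            assert np.array_equal(nkw.sum(axis=1), nk)
        word_ll[s] = _word_loglik(nkw, nk, beta)
        loglik[s] = word_ll[s] + _z_loglik(ndk, alpha)
        if s >= burn_in and (s - burn_in) % thin == 0:
            theta_acc += (ndk + alpha) / (nd + alpha.sum())[:, None]
            phi_acc += (nkw + beta) / (nk + beta_sum)[:, None]
            n_samples += 1
    theta = theta_acc / n_samples
    phi = phi_acc / n_samples
    theta /= theta.sum(axis=1, keepdims=True)
    phi /= phi.sum(axis=1, keepdims=True)
    return theta, phi, z, ndk, nkw, nk, loglik, word_ll


def fit_lda(c: CountMatrix, K: int, alpha=None, beta: float | np.ndarray = 0.1,
            sweeps: int = 800, burn_in: int = 200, thin: int = 10,
            seed: int = 0, debug_checks: bool = False) -> TopicModel:
    """Fit an LDA topic model to a count matrix by collapsed Gibbs sampling.

    Parameters
    ----------
    K : number of topics (>= 2).
    alpha : symmetric prior weight for per-cell topic distributions;
        default 50/K.  Scalar or length-K vector.
    beta : symmetric prior weight for per-topic gene distributions
        (default 0.1).  Scalar or length-V vector.
    sweeps, burn_in, thin : Gibbs schedule; theta and phi are posterior
        means over every ``thin``-th post-burn-in sweep.
    seed : master seed; every cell gets its own substream so results do not
        depend on row or column order of the input.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if sweeps <= burn_in or burn_in < 0:
        raise ValueError("need sweeps > burn_in >= 0")
    n_expressed = int(np.count_nonzero(c.counts.sum(axis=1)))
    if K > n_expressed:
        raise ConfigurationError(
            f"K={K} exceeds the {n_expressed} distinct expressed genes")
    if alpha is None:
        alpha = 50.0 / K
    V, M = c.counts.shape
    alpha = _as_prior(alpha, K, "alpha")
    beta = _as_prior(beta, V, "beta")

    gene_order, cell_order, token_gene, cell_ptr = _canonical_tokens(c)
    if token_gene.size == 0:
        raise ValueError("total token count is zero")
    beta_sorted = beta[gene_order]
    streams = _cell_streams(seed, M)
    theta_s, phi_s, z, *_rest, loglik, _wll = _fit_core(
        token_gene, cell_ptr, K, alpha, beta_sorted, sweeps, burn_in, thin,
        streams, debug_checks=debug_checks)

    # map back from canonical order to input order
    theta = np.empty_like(theta_s)
    theta[cell_order] = theta_s
    phi = np.empty_like(phi_s)
    phi[:, gene_order] = phi_s
    return TopicModel(theta=theta, phi=phi, alpha=alpha, beta=beta, K=K,
                      cell_ids=list(c.cell_ids), gene_ids=list(c.gene_ids),
                      assignments=z, loglik_trace=loglik, seed=seed,
                      groups=c.groups, group_order=c.group_order,
                      provenance=dict(c.provenance, sweeps=sweeps,
                                      burn_in=burn_in, thin=thin))


def perplexity(model: TopicModel, c: CountMatrix) -> float:
    """Per-token perplexity of counts under the fitted theta and phi."""
    order = {g: i for i, g in enumerate(model.gene_ids)}
    rows = [order[g] for g in c.gene_ids]
    probs = model.theta @ model.phi[:, rows]  # (M, V') cell x gene token probs
    counts = c.counts.T  # cells x genes
    N = counts.sum()
    ll = float((counts * np.log(probs)).sum())
    return math.exp(-ll / N)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def select_topic_count(c: CountMatrix, k_min: int = 2, k_max: int = 10,
                       seed: int = 0, sweeps: int = 300, burn_in: int = 100,
                       thin: int = 10, alpha=None, beta=0.1,
                       worst_fraction: float = 0.05):
    """Scan K = k_min..k_max and pick the best penalised log-posterior.

    Each fit after the first is warm-started from the previous model's
    assignments, with the new topic seeded from the ``worst_fraction`` of
    tokens that had the lowest conditional probability under the previous
    model (an iterative-residual style scan).  The score for K is a
    MAP-style penalised log posterior: the multinomial mixture log
    likelihood at the posterior-mean theta and phi (z marginalised out),

        sum_{d,w} n_dw log( theta_d . phi_[:,w] ),

    minus a BIC penalty (df/2) log N with df = K(V-1) + M(K-1) free
    parameters and N the total token count.  The z-conditional likelihood
    log p(w | z) is *not* used: it keeps improving with K long past the
    true structure, whereas the mixture likelihood plateaus.

    Returns ``(best_K, scores)`` with ``scores`` a dict K -> score.
    """
    if not (2 <= k_min < k_max):
        raise ValueError("need 2 <= k_min < k_max")
    V, M = c.counts.shape
    gene_order, cell_order, token_gene, cell_ptr = _canonical_tokens(c)
    if token_gene.size == 0:
        raise ValueError("total token count is zero")
    N = token_gene.shape[0]
    beta_vec = _as_prior(beta, V, "beta")[gene_order]

    scores: dict[int, float] = {}
    z_prev = None
    for K in range(k_min, k_max + 1):
        alpha_vec = _as_prior(50.0 / K if alpha is None else alpha, K, "alpha")
        streams = _cell_streams(seed, M)
        if z_prev is None:
            z_init = None
        else:
            # seed the new topic from the worst-fit tokens of the last model
            ndk, nkw, nk = _counts_from_z(z_prev, token_gene, cell_ptr, K - 1, V)
            cond = np.empty(N)
            a_prev = _as_prior(50.0 / (K - 1) if alpha is None else alpha,
                               K - 1, "alpha")
            _conditional_probs(token_gene, cell_ptr, z_prev, ndk, nkw, nk,
                               a_prev, beta_vec, float(beta_vec.sum()), cond)
            n_move = max(1, int(worst_fraction * N))
            worst = np.argsort(cond, kind="stable")[:n_move]
            z_init = z_prev.copy()
            z_init[worst] = K - 1  # the fresh topic's index
        theta_s, phi_s, z, ndk, nkw, nk, _ll, _wll = _fit_core(
            token_gene, cell_ptr, K, alpha_vec, beta_vec, sweeps, burn_in,
            thin, streams, z_init=z_init)
        # mixture log likelihood of the counts at posterior-mean theta, phi
        counts_sorted = np.zeros((M, V))
        for d in range(M):
            sl = slice(cell_ptr[d], cell_ptr[d + 1])
            np.add.at(counts_sorted[d], token_gene[sl], 1)
        mix_ll = float((counts_sorted * np.log(theta_s @ phi_s)).sum())
        df = K * (V - 1) + M * (K - 1)
        scores[K] = mix_ll - 0.5 * df * math.log(N)
        z_prev = z
    best_K = max(sorted(scores), key=lambda k: scores[k])
    return best_K, scores
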