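"""Exponential-kernel mixture EM shared by both denoising stages.

Reads (flowgrams in stage one, weighted unique sequences in stage two) are
modelled as draws from a mixture of L true sequences, the density of read i
under component j falling off as ``exp(-d_ij / sigma)`` for the stage's
distance d.  Component centres are restricted to sequences actually observed
in the data, so the full read x candidate distance matrix ``C`` can be
computed once; every E and M step below is then pure indexing and matrix
algebra on ``C``.

The M step picks, for each component, the candidate minimising the
responsibility-weighted total distance to all reads (ties break to the lowest
candidate index, so callers should order candidates by abundance descending
then sequence lexicographic for deterministic runs); the E step is the usual
softmax of ``log tau_j - d_ij / sigma`` computed in log space.  The observed
-data log-likelihood (up to the constant ``-N log sigma``, which the
exponential kernel's normaliser contributes identically to every component
and iteration) is tracked and is non-decreasing, the standard EM guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp

__all__ = ["MixtureState", "init_complete_linkage", "e_step", "m_step", "run_em"]


@dataclass
class MixtureState:
    """EM state: per-component candidate index, weights tau, responsibilities."""

    candidate_idx: np.ndarray  # (L,) index into the candidate set
    tau: np.ndarray  # (L,) mixture weights, sum to 1
    resp: np.ndarray  # (N, L) responsibilities, rows sum to 1
    sigma: float
    log_likelihood: float = np.nan
    ll_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return len(self.candidate_idx)

    def active(self) -> np.ndarray:
        """Components with non-zero weight; tau = 0 ones are retained inactive."""
        return np.nonzero(self.tau > 0)[0]

    def hard_assignments(self) -> np.ndarray:
        """Argmax responsibility per read (ties -> lowest component index)."""
        return np.argmax(self.resp, axis=1)


def init_complete_linkage(distances: np.ndarray, cutoff: float) -> np.ndarray:
    """Complete-linkage partition of a symmetric distance matrix at ``cutoff``.

    Returns 0-based cluster labels; every within-cluster pair merged at height
    <= cutoff.  Initialises the EM (each read fully responsible to its
    cluster) and fixes the starting number of components L.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty input")
    n = distances.shape[0]
    if distances.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    d = distances.copy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    tree = linkage(condensed, method="complete")
    labels = fcluster(tree, t=cutoff, criterion="distance") - 1
    return labels.astype(np.int64)


def e_step(dists: np.ndarray, tau: np.ndarray, sigma: float) -> np.ndarray:
    """Responsibilities z_ij = tau_j exp(-d_ij/sigma) / sum_k (...), log-space."""
    tau = np.asarray(tau, dtype=float)
    if not np.any(tau > 0):
        raise ValueError("all mixture weights are zero")
    with np.errstate(divide="ignore"):
        log_w = np.log(tau)[None, :] - np.asarray(dists, dtype=float) / sigma
    log_norm = logsumexp(log_w, axis=1, keepdims=True)
    return np.exp(log_w - log_norm)


def m_step(
    C: np.ndarray, resp: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate re-selection and weight update.

    For each component j the new centre is the candidate k minimising
    ``sum_i w_i z_ij C[i, k]`` (full scan over the cached matrix); new
    ``tau_j = sum_i w_i z_ij / sum_i w_i``.
    """
    n = C.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wz = resp * w[:, None]  # N x L
    scores = wz.T @ C  # L x P
    idx = np.argmin(scores, axis=1)
    tau = wz.sum(axis=0) / w.sum()
    return idx, tau


def _log_likelihood(
    C: np.ndarray, idx: np.ndarray, tau: np.ndarray, sigma: float, w: np.ndarray
) -> float:
    with np.errstate(divide="ignore"):
        log_w = np.log(tau)[None, :] - C[:, idx] / sigma
    return float((w * logsumexp(log_w, axis=1)).sum())


def run_em(
    C: np.ndarray,
    init_labels: np.ndarray,
    sigma: float,
    weights: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MixtureState:
    """Iterate M step / distance refresh / E step to convergence.

    ``C`` is the N x P read-to-candidate distance matrix; ``init_labels``
    gives the initial hard clustering (typically from
    :func:`init_complete_linkage`).  Convergence is ``max |delta z| < tol``
    or ``max_iter`` iterations, in which case the best state is returned with
    ``converged=False``.
    """
    n = C.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    n_components = int(init_labels.max()) + 1
    resp = np.zeros((n, n_components))
    resp[np.arange(n), init_labels] = 1.0

    trace: list[float] = []
    state = None
    for it in range(1, max_iter + 1):
        idx, tau = m_step(C, resp, w)
        ll = _log_likelihood(C, idx, tau, sigma, w)
        trace.append(ll)
        new_resp = e_step(C[:, idx], tau, sigma)
        delta = float(np.abs(new_resp - resp).max())
        resp = new_resp
        if delta < tol:
            state = MixtureState(idx, tau, resp, sigma, ll, trace, converged=True, n_iter=it)
            break
    if state is None:
        import warnings

        warnings.warn(f"EM did not converge in {max_iter} iterations")
        state = MixtureState(idx, tau, resp, sigma, trace[-1], trace, converged=False, n_iter=max_iter)
    return state
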