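"""Compiled inner loop of the Gibbs sampler.

The kernel performs sequential single-site updates: for each gene in the
given update order it recomputes the local field from the *current*
labels (earlier updates within the same sweep already applied), records
the conditional probability, and redraws the label. Randomness comes in
as a pre-generated uniform matrix so that determinism is controlled
entirely by the caller's NumPy generator.

Networks are passed as stacked CSR arrays: ``indptr`` has shape
(K, n+1) with entries indexing directly into the concatenated
``indices`` array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_adjacency", "run_sweeps"]


def pack_adjacency(adjacencies) -> tuple[np.ndarray, np.ndarray]:
    """Stack K scipy CSR adjacencies into (indptr (K, n+1), indices (nnz,))."""
    K = len(adjacencies)
    n = adjacencies[0].shape[0]
    indptr = np.zeros((K, n + 1), dtype=np.int64)
    chunks = []
    offset = 0
    for k, a in enumerate(adjacencies):
        indptr[k] = a.indptr.astype(np.int64) + offset
        chunks.append(a.indices.astype(np.int64))
        offset += len(a.indices)
    indices = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    return indptr, indices


@njit(cache=True)
def run_sweeps(labels, indptr, indices, alpha_vec, beta, gamma,
               order, uniforms, probs_out):
    """Run ``uniforms.shape[0]`` sequential sweeps in place.

    Parameters
    ----------
    labels : int8 (n,), modified in place
    indptr, indices : packed multi-network adjacency
    alpha_vec : float64 (n,) per-gene field
    beta, gamma : float64 (K,)
    order : int64 (S, u) update order per sweep (unclamped genes only)
    uniforms : float64 (S, u) pre-drawn uniforms
    probs_out : float64 (S, n); conditional probabilities written for each
        updated gene, untouched positions keep their preset values
    """
    S, u = order.shape
    K = beta.shape[0]
    for s in range(S):
        for t in range(u):
            i = order[s, t]
            field = alpha_vec[i]
            for k in range(K):
                m1 = 0
                start = indptr[k, i]
                end = indptr[k, i + 1]
                for jj in range(start, end):
                    m1 += labels[indices[jj]]
                deg = end - start
                m0 = deg - m1
                field += (beta[k] - 1.0) * m0 + (gamma[k] - beta[k]) * m1
            if field >= 0.0:
                p = 1.0 / (1.0 + np.exp(-field))
            else:
                e = np.exp(field)
                p = e / (1.0 + e)
            probs_out[s, i] = p
            labels[i] = 1 if uniforms[s, t] < p else 0
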