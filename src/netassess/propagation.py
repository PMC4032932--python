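"""Guilt-by-association scoring by label propagation over the composite graph.

Scores minimize  Σ_i (f_i − y_i)² + Σ_ij w_ij (f_i − f_j)²,  i.e. they solve
the linear system (I + L) f = y with L = D − W the combinatorial Laplacian of
the composite network.  (I + L) is symmetric positive definite, so the
solution exists and is unique; isolated genes get f_i = y_i exactly.  Under
the auto-negatives convention every gene is labeled (+1 training positives,
−1 everything else), so no unlabeled-bias term is needed, and the ranking
metrics downstream are invariant to the affine scale of y.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .datamodel import GeneIndex
from .integration import CombinedNetwork, LabelVector

#: graphs below this size are solved densely; larger ones use conjugate gradients
DENSE_THRESHOLD = 500


class ComputationError(RuntimeError):
    """Numerical failure (e.g. solver non-convergence)."""


def make_bias(train_pos, universe: GeneIndex) -> LabelVector:
    """±1 bias vector: +1 for training positives, −1 for every other gene."""
    if not train_pos:
        raise ValueError("training positive set is empty")
    y = -np.ones(len(universe))
    for g in train_pos:
        try:
            y[universe.lookup[g]] = 1.0
        except KeyError:
            raise ValueError(f"positive gene {g!r} is not in the universe") from None
    return LabelVector(y=y)


def propagate(
    composite: CombinedNetwork,
    bias: LabelVector,
    tol: float = 1e-9,
    maxiter: int = 10_000,
    dense_threshold: int = DENSE_THRESHOLD,
) -> np.ndarray:
    """Solve (I + L) f = y for the per-gene score vector f."""
    W = composite.composite
    n = W.shape[0]
    if bias.y.size != n:
        raise ValueError("bias and composite are over different gene universes")
    d = np.asarray(W.sum(axis=1)).ravel()
    y = bias.y
    if n < dense_threshold:
        M = np.diag(1.0 + d) - W.toarray()
        return np.linalg.solve(M, y)
    M = sp.diags(1.0 + d) - W
    f, info = spla.cg(M, y, rtol=tol, atol=0.0, maxiter=maxiter)
    if info != 0:
        residual = float(np.linalg.norm(M @ f - y))
        raise ComputationError(
            f"label propagation did not converge in {maxiter} iterations "
            f"(residual {residual:.3e})"
        )
    return f


def rank_candidates(scores: np.ndarray, exclude, index: GeneIndex) -> list[str]:
    """Genes outside *exclude*, by descending score; ties by ascending identifier."""
    exclude = set(exclude)
    return sorted(
        (s for s in index.symbols if s not in exclude),
        key=lambda s: (-scores[index.lookup[s]], s),
    )
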