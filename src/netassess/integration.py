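"""Network integration: combine normalized networks into one composite graph.

Each input network is first symmetrically degree-normalized,
``w'_ij = w_ij / sqrt(d_i d_j)``, which makes the composite invariant to
per-network rescaling.  Per-network combination weights come from one of

* ``equal`` — every network gets weight 1/k;
* ``unregularized`` — ordinary least squares of a label-derived target on
  the network entries, fitted for the single query term;
* ``simultaneous`` — the same regression stacked over a whole collection of
  terms at once, yielding one shared weight vector.

The regression target is built from the centered label vector ȳ with
ȳ_i = n_neg/n for positives and −n_pos/n for negatives; the target value for
a gene pair (i, j) is ȳ_i·ȳ_j.  Only off-diagonal upper-triangle pairs where
at least one network has a nonzero entry enter the fit (plus an intercept
column), which keeps the all-zero pairs from flooding the system.  Networks
receiving non-positive weights are removed and the system re-solved until
all surviving weights are positive; if nothing survives (or the design is
singular) the combiner falls back to equal weights.

The ``automatic`` selector uses the simultaneous algorithm for queries with
fewer than five training positives and the unregularized algorithm for five
or more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datamodel import AnnotationSet, GeneIndex, Network

log = logging.getLogger(__name__)

_COND_LIMIT = 1e12  # treat worse-conditioned normal equations as singular


@dataclass(frozen=True)
class LabelVector:
    """Per-gene ±1 labels under the auto-negatives convention."""

    y: np.ndarray

    @property
    def n_pos(self) -> int:
        return int(np.count_nonzero(self.y > 0))

    @property
    def n_neg(self) -> int:
        return int(self.y.size - np.count_nonzero(self.y > 0))


@dataclass
class CombinedNetwork:
    """Per-source weights plus the weighted-sum composite graph."""

    weights: dict[str, float]
    composite: sp.csr_matrix
    index: GeneIndex


def normalize_network(net: Network) -> Network:
    """Symmetric degree normalization ``w'_ij = w_ij / sqrt(d_i d_j)``.

    Isolated nodes are untouched (they have no entries).  The result is
    memoized on the input network.
    """
    if net._normalized is not None:
        return net._normalized
    W = net.matrix
    d = np.asarray(W.sum(axis=1)).ravel()
    inv = np.zeros_like(d)
    nz = d > 0
    inv[nz] = 1.0 / np.sqrt(d[nz])
    coo = W.tocoo()
    # scale by the single product inv_i*inv_j so symmetry is bitwise exact
    data = coo.data * (inv[coo.row] * inv[coo.col])
    Wn = sp.coo_matrix((data, (coo.row, coo.col)), shape=W.shape).tocsr()
    out = Network(net.name, net.group, Wn, net.index)
    net._normalized = out
    return out


def build_target(labels: LabelVector) -> np.ndarray:
    """Centered label vector ȳ whose outer products are the regression targets.

    ȳ_i = n_neg/n for positives, −n_pos/n for negatives; the target for a
    gene pair (i, j) is ȳ_i·ȳ_j.
    """
    n_pos, n_neg = labels.n_pos, labels.n_neg
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"need at least one positive and one negative label (got {n_pos} / {n_neg})"
        )
    n = labels.y.size
    return np.where(labels.y > 0, n_neg / n, -n_pos / n)


def _check_common_index(nets: list[Network]) -> GeneIndex:
    if not nets:
        raise ValueError("no networks to combine")
    index = nets[0].index
    for net in nets[1:]:
        if net.index is not index and net.index != index:
            raise ValueError("networks must share one gene index; run resolve() first")
    return index


def _composite(nets: list[Network], weights: dict[str, float]) -> CombinedNetwork:
    index = _check_common_index(nets)
    n = len(index)
    comp = sp.csr_matrix((n, n))
    for net in nets:
        w = weights.get(net.name, 0.0)
        if w > 0:
            comp = comp + w * normalize_network(net).matrix
    return CombinedNetwork(weights=weights, composite=comp.tocsr(), index=index)


def combine_equal(nets: list[Network]) -> CombinedNetwork:
    """Equal weighting: every network contributes 1/k of its normalized form."""
    index = _check_common_index(nets)
    k = len(nets)
    return _composite(nets, {net.name: 1.0 / k for net in nets})


def _dedupe(norm: list[Network]) -> list[Network]:
    # identical entry vectors collapse; lexicographically first name survives
    unique: list[Network] = []
    for cand in sorted(norm, key=lambda n: n.name):
        if any((cand.matrix != u.matrix).nnz == 0 for u in unique):
            continue
        unique.append(cand)
    return unique


def _normal_equations(
    norm: list[Network], ybars: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Assemble X'X and X'y over the union support (intercept first)."""
    ups = [sp.triu(m.matrix, k=1).tocsr() for m in norm]
    pat = None
    for u in ups:
        b = u.copy()
        b.data = np.ones_like(b.data)
        pat = b if pat is None else pat + b
    pat.data = np.ones_like(pat.data)
    m = pat.nnz
    k = len(ups)
    A = np.zeros((k + 1, k + 1))
    A[0, 0] = m
    for d in range(k):
        s = ups[d].sum()
        A[0, d + 1] = A[d + 1, 0] = s
        for e in range(d, k):
            v = ups[d].multiply(ups[e]).sum()
            A[d + 1, e + 1] = A[e + 1, d + 1] = v
    # stacking repeats the predictor rows once per term, so the Gram matrix
    # is the single-term one times the number of terms
    A *= len(ybars)
    b = np.zeros(k + 1)
    for ybar in ybars:
        b[0] += float(ybar @ (pat @ ybar))
        for d in range(k):
            b[d + 1] += float(ybar @ (ups[d] @ ybar))
    return A, b, m


def _solve_weights(
    nets: list[Network], ybars: list[np.ndarray]
) -> tuple[dict[str, float] | None, str]:
    """OLS weights with iterative elimination of non-positive entries.

    Returns ``(None, reason)`` when the system is singular or no network
    survives, signalling the equal-weights fallback.
    """
    active = _dedupe([normalize_network(n) for n in nets])
    while active:
        A, b, m = _normal_equations(active, ybars)
        if m == 0:
            return None, "eliminated"
        if np.linalg.cond(A) > _COND_LIMIT:
            return None, "singular"
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return None, "singular"
        if not np.all(np.isfinite(beta)):
            return None, "singular"
        w = beta[1:]
        if np.all(w > 0):
            return {net.name: float(wi) for net, wi in zip(active, w)}, "ok"
        active = [net for net, wi in zip(active, w) if wi > 0]
    return None, "eliminated"


def _finish(
    nets: list[Network], solved: dict[str, float] | None, reason: str
) -> CombinedNetwork:
    if solved is None:
        if reason == "singular":
            log.warning("regression design singular; falling back to equal weights")
        else:
            log.debug("all networks eliminated; falling back to equal weights")
        return combine_equal(nets)
    return _composite(nets, {net.name: solved.get(net.name, 0.0) for net in nets})


def combine_unregularized(nets: list[Network], labels: LabelVector) -> CombinedNetwork:
    """Per-query least-squares weighting (for queries with ≥5 training genes)."""
    _check_common_index(nets)
    ybar = build_target(labels)
    return _finish(nets, *_solve_weights(nets, [ybar]))


def combine_simultaneous(
    nets: list[Network], sw_annotations: AnnotationSet
) -> CombinedNetwork:
    """One shared weight vector fitted over all terms of a collection at once.

    Every usable term (≥1 positive and ≥1 negative after restriction to the
    gene universe) contributes its regression rows; the predictor columns are
    the same network entries for each term, so the stacked normal equations
    are the per-term ones summed.
    """
    index = _check_common_index(nets)
    if not sw_annotations.terms:
        raise ValueError("simultaneous weighting needs a non-empty term collection")
    n = len(index)
    ybars = []
    for term in sorted(sw_annotations.terms):
        pos = [index.lookup[g] for g in sw_annotations.terms[term] if g in index]
        if not pos or len(pos) == n:
            continue
        y = -np.ones(n)
        y[pos] = 1.0
        ybars.append(build_target(LabelVector(y)))
    if not ybars:
        raise ValueError("no usable terms for simultaneous weighting")
    return _finish(nets, *_solve_weights(nets, ybars))


def combine_automatic(
    nets: list[Network],
    labels: LabelVector,
    sw_annotations: AnnotationSet,
    sw_combined: CombinedNetwork | None = None,
) -> CombinedNetwork:
    """Dispatch on training-positive count: <5 → simultaneous, ≥5 → unregularized.

    *sw_combined* may carry a precomputed simultaneous combination (it does
    not depend on the query labels), used verbatim for the <5 branch.
    """
    if labels.n_pos < 1 or labels.n_neg < 1:
        # surfaces the same precondition failure build_target would raise
        build_target(labels)
    if labels.n_pos < 5:
        if sw_combined is not None:
            return sw_combined
        return combine_simultaneous(nets, sw_annotations)
    return combine_unregularized(nets, labels)
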