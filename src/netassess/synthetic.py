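"""Synthetic gene universes, gold standards and networks with planted signal.

The generator plants guilt-by-association structure with a co-annotation
(planted-partition) construction: gene pairs sharing a term are connected
with probability ``p_in``, all other pairs with probability ``p_out``.  With
``p_in > p_out`` the network is informative for recovering the terms; with
``p_in = p_out`` it is pure noise.  Terms may overlap in membership, as GO
terms do.  Edge weights default to uniform(0.1, 1.0) so that degree
normalization is actually exercised.

An overlap trio (A, B, C) is also provided: A and B live on disjoint gene
blocks, and C bridges both, so genes of A's block reach genes of B's block
only when all three networks are integrated — the synergy scenario that
motivates assessing networks in combination rather than in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .datamodel import (
    AnnotationSet,
    GeneIndex,
    Network,
    write_annotation_file,
    write_network_file,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scenario (defaults are the desk-scale study conditions)."""

    n_genes: int = 300
    n_terms: int = 30
    term_size_range: tuple[int, int] = (5, 10)
    p_in: float = 0.8
    p_out: float = 0.02
    weight_law: tuple = ("uniform", 0.1, 1.0)
    seed: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if self.n_genes < 1 or self.n_terms < 1:
            raise ValueError("n_genes and n_terms must be positive")
        if self.weight_law[0] not in ("constant", "uniform"):
            raise ValueError("weight_law must be ('constant', w) or ('uniform', lo, hi)")


def gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream])


def _draw_weights(rng: np.random.Generator, spec: SyntheticSpec, k: int) -> np.ndarray:
    law = spec.weight_law
    if law[0] == "constant":
        return np.full(k, float(law[1]) if len(law) > 1 else 1.0)
    return rng.uniform(float(law[1]), float(law[2]), size=k)


def _network_from_pairs(
    rows: np.ndarray, cols: np.ndarray, weights: np.ndarray, index: GeneIndex, name: str, group: str
) -> Network:
    n = len(index)
    mat = sp.coo_matrix(
        (np.concatenate([weights, weights]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    return Network(name, group, mat, index)


def make_annotations(spec: SyntheticSpec) -> AnnotationSet:
    """Terms with sizes uniform in the configured range; members sampled without replacement."""
    lo, hi = spec.term_size_range
    if hi > spec.n_genes:
        raise ValueError("term sizes cannot exceed the number of genes")
    rng = _rng(spec, 0)
    genes = gene_names(spec.n_genes)
    terms: dict[str, set[str]] = {}
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        terms[f"T{t:04d}"] = {genes[i] for i in members}
    return AnnotationSet(terms=terms)


def make_coannotation_network(
    annotations: AnnotationSet,
    spec: SyntheticSpec,
    p_in: float | None = None,
    p_out: float | None = None,
    name: str = "coann",
    group: str = "synth",
    stream: int = 1,
) -> Network:
    """Planted-partition network: within-term pairs at *p_in*, others at *p_out*."""
    p_in = spec.p_in if p_in is None else p_in
    p_out = spec.p_out if p_out is None else p_out
    rng = _rng(spec, stream)
    n = spec.n_genes
    index = GeneIndex(gene_names(n))
    in_term = np.zeros((n, n), dtype=bool)
    for genes in annotations.terms.values():
        idx = [index.lookup[g] for g in genes if g in index]
        in_term[np.ix_(idx, idx)] = True
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(in_term[iu, ju], p_in, p_out)
    hit = rng.random(prob.size) < prob
    weights = _draw_weights(rng, spec, int(hit.sum()))
    return _network_from_pairs(iu[hit], ju[hit], weights, index, name, group)


def make_noise_network(
    spec: SyntheticSpec, name: str = "noise", group: str = "synth", stream: int = 2
) -> Network:
    """Annotation-independent background network (edge probability p_out everywhere)."""
    empty = AnnotationSet(terms={})
    return make_coannotation_network(
        empty, spec, p_in=spec.p_out, p_out=spec.p_out, name=name, group=group, stream=stream
    )


def make_overlap_trio(
    spec: SyntheticSpec, stream: int = 5, p_within: float = 0.15
) -> tuple[Network, Network, Network]:
    """Networks A, B on disjoint gene blocks plus a bridging network C.

    A and B are each a random connected graph (spanning path plus extra
    edges) on the first and second third of the universe; C lives mostly on
    the final third but attaches to genes of both blocks, so A-block and
    B-block genes become mutually reachable only in A ∪ B ∪ C.
    """
    n = spec.n_genes
    if n < 9:
        raise ValueError("overlap trio needs at least 9 genes (three 3-gene blocks)")
    rng = _rng(spec, stream)
    index = GeneIndex(gene_names(n))
    third = n // 3
    block_a = np.arange(0, third)
    block_b = np.arange(third, 2 * third)
    block_c = np.arange(2 * third, n)

    def connected_block(block: np.ndarray, nm: str) -> Network:
        order = rng.permutation(block)
        rows = [order[:-1]]
        cols = [order[1:]]
        # sprinkle extra in-block edges
        iu, ju = np.triu_indices(block.size, k=1)
        extra = rng.random(iu.size) < p_within
        rows.append(block[iu[extra]])
        cols.append(block[ju[extra]])
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        keys = {(min(a, b), max(a, b)) for a, b in zip(r.tolist(), c.tolist())}
        r = np.array([k[0] for k in sorted(keys)])
        c = np.array([k[1] for k in sorted(keys)])
        w = _draw_weights(rng, spec, r.size)
        return _network_from_pairs(r, c, w, index, nm, "trio")

    net_a = connected_block(block_a, "trio_a")
    net_b = connected_block(block_b, "trio_b")

    # C: a path through the C block anchored at one A-block and one B-block gene
    anchor_a = int(rng.choice(block_a))
    anchor_b = int(rng.choice(block_b))
    chain = [anchor_a, *rng.permutation(block_c).tolist(), anchor_b]
    rows = np.array(chain[:-1])
    cols = np.array(chain[1:])
    w = _draw_weights(rng, spec, rows.size)
    net_c = _network_from_pairs(rows, cols, w, index, "trio_c", "trio")
    return net_a, net_b, net_c


def write_fixture_dir(spec: SyntheticSpec, outdir) -> dict[str, Path]:
    """Materialize a file-based fixture tree usable directly by the CLI.

    Layout: ``data/<group>/<name>.txt`` network files plus ``go-terms.txt``.
    Deterministic under the spec seed.
    """
    outdir = Path(outdir)
    annotations = make_annotations(spec)
    nets = [
        make_noise_network(spec, name="noise1", group="noise", stream=2),
        make_noise_network(spec, name="noise2", group="noise", stream=3),
        make_coannotation_network(annotations, spec, name="signal1", group="coann", stream=1),
        *make_overlap_trio(spec),
    ]
    paths: dict[str, Path] = {}
    for net in nets:
        gdir = outdir / "data" / net.group
        gdir.mkdir(parents=True, exist_ok=True)
        p = gdir / f"{net.name}.txt"
        write_network_file(net, p)
        paths[net.name] = p
    query = outdir / "go-terms.txt"
    write_annotation_file(annotations, query)
    paths["go-terms"] = query
    return paths
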