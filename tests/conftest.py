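import numpy as np
import pytest
import scipy.sparse as sp

from netassess.datamodel import AnnotationSet, GeneIndex, Network


def network_from_edges(edges, symbols=None, name="net", group="g"):
    """Build a Network from [(a, b, w), ...]; index from symbols or the edges."""
    if symbols is None:
        seen = {}
        for a, b, _ in edges:
            seen.setdefault(a)
            seen.setdefault(b)
        symbols = list(seen)
    index = GeneIndex(symbols)
    pairs = {}
    for a, b, w in edges:
        key = (a, b) if a < b else (b, a)
        pairs[key] = max(pairs.get(key, 0.0), w)
    return Network.from_edge_dict(name, group, pairs, index)


def random_network(rng, n, p, name="rand", group="g", symbols=None):
    """Erdős–Rényi weighted network on n genes."""
    if symbols is None:
        symbols = [f"g{i:03d}" for i in range(n)]
    index = GeneIndex(symbols)
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < p
    rows, cols = iu[hit], ju[hit]
    w = rng.uniform(0.1, 1.0, size=rows.size)
    mat = sp.coo_matrix(
        (np.r_[w, w], (np.r_[rows, cols], np.r_[cols, rows])), shape=(n, n)
    ).tocsr()
    return Network(name, group, mat, index)


@pytest.fixture
def abc_index():
    return GeneIndex(["a", "b", "c"])


@pytest.fixture
def write_lines(tmp_path):
    def _write(name, lines):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return p

    return _write


@pytest.fixture
def small_annotations():
    return AnnotationSet(
        terms={
            "t1": {"a", "b", "c"},
            "t2": {"b", "c", "d", "e"},
        }
    )
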