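"""Domain types and tab-delimited I/O for association networks and gold standards.

The on-disk dialects are deliberately minimal:

* **Network file** — two or three tab-separated columns per line:
  ``geneA<TAB>geneB[<TAB>weight]``. Missing weights default to 1.0. Tabs must
  not be surrounded by spaces (identifier whitespace is trimmed during
  canonicalization, so stray spaces inside fields are tolerated but never
  required).
* **Gold standard** — one function label per line:
  ``term_id<TAB>gene<TAB>gene...``. Repeated term ids are merged by union.
* **Report** — the fixed ten-column assessment table (see
  :data:`REPORT_COLUMNS`).

Gene identifiers are canonicalized by trimming whitespace and case-folding.
An optional two-column synonym table maps alternate identifiers to canonical
ones; an alternate that maps to more than one distinct canonical identifier
is ambiguous and is dropped entirely, together with every edge touching it.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

#: Column order of the assessment report.
REPORT_COLUMNS = (
    "QUERY",
    "BASELINE-AUC-ROC",
    "SUBJECT-AUC-ROC",
    "%ERR-AUC-ROC",
    "BASELINE-AUC-PR",
    "SUBJECT-AUC-PR",
    "%ERR-AUC-PR",
    "BASELINE-PREC-AT-10-RECALL",
    "SUBJECT-PREC-AT-10-RECALL",
    "%ERR-PREC-AT-10-RECALL",
)

#: Token written for undefined values (e.g. %ERR with a zero baseline).
NA_TOKEN = "NA"

VALID_BRANCHES = frozenset({"bp", "cc", "mf"})


class DataError(ValueError):
    """Malformed input file or unusable resolved inputs."""


def canon(symbol: str) -> str:
    """Canonical identifier form: trimmed and case-folded. Idempotent."""
    return symbol.strip().casefold()


class GeneIndex:
    """Bidirectional mapping between gene identifiers and dense 0-based indices."""

    __slots__ = ("symbols", "lookup")

    def __init__(self, symbols: Iterable[str]):
        self.symbols: list[str] = list(symbols)
        self.lookup: dict[str, int] = {}
        for i, s in enumerate(self.symbols):
            if s in self.lookup:
                raise DataError(f"duplicate gene identifier in index: {s!r}")
            self.lookup[s] = i

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.lookup

    def index(self, symbol: str) -> int:
        return self.lookup[symbol]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneIndex) and self.symbols == other.symbols

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneIndex({len(self)} genes)"


class Network:
    """A named, grouped, symmetric, non-negatively weighted sparse graph.

    The adjacency matrix is stored CSR over a :class:`GeneIndex`; it is
    validated to be exactly symmetric with a zero diagonal and strictly
    positive stored weights.
    """

    def __init__(self, name: str, group: str, matrix, index: GeneIndex):
        m = sp.csr_matrix(matrix, dtype=float)
        m.eliminate_zeros()
        n = len(index)
        if m.shape != (n, n):
            raise DataError(
                f"network {name!r}: matrix shape {m.shape} does not match index size {n}"
            )
        if (m != m.T).nnz != 0:
            raise DataError(f"network {name!r}: matrix is not symmetric")
        if m.diagonal().any():
            raise DataError(f"network {name!r}: self-loops are not allowed")
        if m.nnz and m.data.min() <= 0:
            raise DataError(f"network {name!r}: all stored weights must be > 0")
        self.name = name
        self.group = group
        self.matrix = m
        self.index = index
        self._normalized: "Network | None" = None  # memo used by integration

    @property
    def n_edges(self) -> int:
        return self.matrix.nnz // 2

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield undirected edges once each as (a, b, weight) with a < b."""
        coo = sp.triu(self.matrix, k=1).tocoo()
        syms = self.index.symbols
        for i, j, w in zip(coo.row, coo.col, coo.data):
            a, b = syms[i], syms[j]
            yield (a, b, float(w)) if a < b else (b, a, float(w))

    def edge_dict(self) -> dict[tuple[str, str], float]:
        return {(a, b): w for a, b, w in self.edges()}

    @classmethod
    def from_edge_dict(
        cls,
        name: str,
        group: str,
        pairs: Mapping[tuple[str, str], float],
        index: GeneIndex,
    ) -> "Network":
        return cls(name, group, _matrix_from_pairs(pairs, index), index)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network({self.name!r}, group={self.group!r}, {len(self.index)} genes, {self.n_edges} edges)"


def _matrix_from_pairs(
    pairs: Mapping[tuple[str, str], float], index: GeneIndex
) -> sp.csr_matrix:
    n = len(index)
    if not pairs:
        return sp.csr_matrix((n, n))
    rows, cols, data = [], [], []
    for (a, b), w in pairs.items():
        i, j = index.lookup[a], index.lookup[b]
        rows += (i, j)
        cols += (j, i)
        data += (w, w)
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class AnnotationSet:
    """Mapping from function label to annotated gene set, with optional branch tags."""

    terms: dict[str, set[str]]
    branch: dict[str, str] | None = None

    def term_sizes(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.terms.items()}

    def subset(self, keep: Iterable[str]) -> "AnnotationSet":
        keep = set(keep)
        terms = {t: set(g) for t, g in self.terms.items() if t in keep}
        branch = (
            {t: b for t, b in self.branch.items() if t in keep} if self.branch else None
        )
        return AnnotationSet(terms=terms, branch=branch)


@dataclass
class RunConfig:
    """Configuration of one assessment run."""

    folds: int = 5
    min_annotations: int = 3
    max_annotations: int = 10
    seed: int = 1
    threads: int = 1
    auto_negatives: bool = True
    baseline_selection: tuple[str, ...] = ()
    subject_selection: tuple[str, ...] = ()
    integration: str = "automatic"
    branch: str | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (1 <= self.min_annotations <= self.max_annotations):
            raise ValueError("require 1 <= min_annotations <= max_annotations")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.integration not in ("automatic", "equal"):
            raise ValueError("integration must be 'automatic' or 'equal'")
        if self.branch is not None and self.branch not in VALID_BRANCHES:
            raise ValueError(f"branch must be one of {sorted(VALID_BRANCHES)}")


@dataclass(frozen=True)
class SynonymTable:
    """Alternate → canonical identifier mapping with the ambiguous alternates recorded."""

    mapping: dict[str, str]
    ambiguous: frozenset[str]


# ---------------------------------------------------------------------------
# readers


def read_network_file(
    path,
    index: GeneIndex | None = None,
    name: str | None = None,
    group: str | None = None,
) -> Network:
    """Parse a 2/3-column tab-delimited association network file.

    Two-column rows get weight 1.0.  Duplicate undirected edges collapse to
    the maximum weight; self-loops are dropped with a warning.  When *index*
    is given, rows mentioning unknown identifiers are skipped and counted;
    otherwise the gene index is built from the file in first-appearance order.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if group is None:
        group = "user"

    pairs: dict[tuple[str, str], float] = {}
    order: dict[str, None] = {}
    n_rows = n_self = n_unknown = 0
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise DataError(
                    f"{path}:{ln}: expected 2 or 3 tab-separated fields, got {len(fields)}"
                )
            a, b = canon(fields[0]), canon(fields[1])
            if not a or not b:
                raise DataError(f"{path}:{ln}: empty gene identifier")
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise DataError(
                        f"{path}:{ln}: non-numeric weight {fields[2]!r}"
                    ) from None
                if not math.isfinite(w) or w <= 0:
                    raise DataError(
                        f"{path}:{ln}: weight must be a positive finite number, got {fields[2]!r}"
                    )
            else:
                w = 1.0
            n_rows += 1
            if a == b:
                n_self += 1
                continue
            if index is not None and (a not in index or b not in index):
                n_unknown += 1
                continue
            order.setdefault(a)
            order.setdefault(b)
            key = (a, b) if a < b else (b, a)
            prev = pairs.get(key)
            if prev is None or w > prev:
                pairs[key] = w
    if n_rows == 0:
        raise DataError(f"{path}: empty network file")
    if n_self:
        log.warning("%s: dropped %d self-loop row(s)", path, n_self)
    if n_unknown:
        log.info("%s: skipped %d row(s) with unrecognized identifiers", path, n_unknown)
    if index is None:
        index = GeneIndex(order)
    return Network(name, group, _matrix_from_pairs(pairs, index), index)


def read_annotation_file(path) -> AnnotationSet:
    """Parse a gold-standard file: one ``term<TAB>gene...`` line per term.

    Repeated term ids are merged by union; blank lines are skipped; a line
    with no genes records the term with an empty set and logs a warning.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            term_id = fields[0].strip()
            if not term_id:
                raise DataError(f"{path}:{ln}: empty term identifier")
            genes = {canon(f) for f in fields[1:] if f.strip()}
            if not genes:
                log.warning("%s:%d: term %s lists no genes", path, ln, term_id)
            terms.setdefault(term_id, set()).update(genes)
    return AnnotationSet(terms=terms)


def read_branch_file(path) -> dict[str, str]:
    """Parse a 2-column ``term<TAB>branch`` side file (branch in bp/cc/mf)."""
    path = Path(path)
    branch: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{ln}: expected 2 fields, got {len(fields)}")
            term, b = fields[0].strip(), fields[1].strip().lower()
            if b not in VALID_BRANCHES:
                raise DataError(f"{path}:{ln}: unknown branch {fields[1]!r}")
            branch[term] = b
    return branch


def read_synonym_file(path) -> SynonymTable:
    """Parse a 2-column ``alternate<TAB>canonical`` synonym table.

    Alternates mapping to more than one distinct canonical identifier are
    ambiguous: they are excluded from the mapping and returned in
    ``ambiguous`` so that resolution can drop them entirely.
    """
    path = Path(path)
    seen: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{ln}: expected 2 fields, got {len(fields)}")
            alt, canonical = canon(fields[0]), canon(fields[1])
            if not alt or not canonical:
                raise DataError(f"{path}:{ln}: empty identifier")
            seen.setdefault(alt, set()).add(canonical)
    ambiguous = frozenset(a for a, cs in seen.items() if len(cs) > 1)
    if ambiguous:
        log.warning(
            "synonym table %s: %d ambiguous alternate(s) dropped: %s",
            path,
            len(ambiguous),
            ", ".join(sorted(ambiguous)[:5]),
        )
    mapping = {a: next(iter(cs)) for a, cs in seen.items() if len(cs) == 1}
    return SynonymTable(mapping=mapping, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# resolution


def resolve(
    networks: list[Network],
    annotations: AnnotationSet | None = None,
    synonyms: SynonymTable | str | Path | None = None,
) -> tuple[GeneIndex, list[Network], AnnotationSet]:
    """Resolve networks and annotations onto one shared gene universe.

    The universe is the union of genes appearing in any network after
    applying the synonym table.  Ambiguous alternates are removed entirely
    (their edges are skipped); annotation genes outside the universe are
    dropped.  Edge loss is logged.
    """
    if not networks:
        raise DataError("at least one network is required")
    if isinstance(synonyms, (str, Path)):
        synonyms = read_synonym_file(synonyms)
    mapping = synonyms.mapping if synonyms else {}
    ambiguous = synonyms.ambiguous if synonyms else frozenset()

    def remap(s: str) -> str | None:
        if s in ambiguous:
            return None
        return mapping.get(s, s)

    universe: set[str] = set()
    edge_dicts: list[dict[tuple[str, str], float]] = []
    lost_edges = 0
    for net in networks:
        d: dict[tuple[str, str], float] = {}
        for a, b, w in net.edges():
            ra, rb = remap(a), remap(b)
            if ra is None or rb is None or ra == rb:
                lost_edges += 1
                continue
            key = (ra, rb) if ra < rb else (rb, ra)
            prev = d.get(key)
            if prev is None or w > prev:
                d[key] = w
        edge_dicts.append(d)
        universe.update(s for s in map(remap, net.index.symbols) if s is not None)

    if not universe:
        raise DataError("resolution produced an empty gene universe")
    index = GeneIndex(sorted(universe))
    resolved_nets = [
        Network(net.name, net.group, _matrix_from_pairs(d, index), index)
        for net, d in zip(networks, edge_dicts)
    ]
    if lost_edges:
        log.info("resolution dropped %d edge(s) via ambiguous/merged identifiers", lost_edges)

    if annotations is None:
        annotations = AnnotationSet(terms={})
    res_terms: dict[str, set[str]] = {}
    for term, genes in annotations.terms.items():
        kept = {g for g in (remap(x) for x in genes) if g is not None and g in index}
        res_terms[term] = kept
    res_annotations = AnnotationSet(
        terms=res_terms,
        branch=dict(annotations.branch) if annotations.branch else None,
    )
    log.info(
        "resolved universe: %d genes across %d network(s)", len(index), len(networks)
    )
    return index, resolved_nets, res_annotations


# ---------------------------------------------------------------------------
# writers


def _fmt(value) -> str:
    if value is None:
        return NA_TOKEN
    v = float(value)
    if math.isnan(v):
        return NA_TOKEN
    return format(v, ".9g")


def _fmt_err(value) -> str:
    # %ERR columns use 6-decimal fixed form with trailing zeros trimmed,
    # e.g. 0.101077 and 0.09062
    if value is None:
        return NA_TOKEN
    v = float(value)
    if math.isnan(v):
        return NA_TOKEN
    out = f"{v:.6f}".rstrip("0").rstrip(".")
    return out if out not in ("", "-") else "0"


def write_report(records, path) -> None:
    """Write assessment records as the tab-delimited ten-column report.

    *records* must already be in their final order; metric values are
    printed with nine significant digits, %ERR values with six decimals,
    and undefined values as ``NA``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in records:
            row = (
                r.term_id,
                _fmt(r.baseline.auroc),
                _fmt(r.subject.auroc),
                _fmt_err(r.err_auroc),
                _fmt(r.baseline.aupr),
                _fmt(r.subject.aupr),
                _fmt_err(r.err_aupr),
                _fmt(r.baseline.p10r),
                _fmt(r.subject.p10r),
                _fmt_err(r.err_p10r),
            )
            fh.write("\t".join(row) + "\n")


def read_report(path) -> pd.DataFrame:
    """Re-parse a report written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], dtype={"QUERY": str})
    if tuple(df.columns) != REPORT_COLUMNS:
        raise DataError(f"{path}: unexpected report header {tuple(df.columns)!r}")
    return df


def write_network_file(net: Network, path) -> None:
    """Write a network in the tab-delimited dialect (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w:.9g}\n")


def write_annotation_file(annotations: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(annotations.terms):
            genes = sorted(annotations.terms[term])
            fh.write("\t".join([term, *genes]) + "\n")


def size_distribution(annotations: AnnotationSet) -> Counter:
    return Counter(len(g) for g in annotations.terms.values())
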