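"""The assessment workflow: integrate, cross-validate, difference, report.

For every function label surviving the size filter, the positives are dealt
into K folds (per-term RNG derived from the global seed and the term id, so
fold plans are identical across thread counts, file partitions and the two
rounds).  Each fold withholds its positives, integrates the network set on
the remaining training labels, propagates, ranks every gene outside the
training set, and scores the held-out positives against all non-term genes.
The per-fold AUROC / AUPR / precision-at-10%-recall values are averaged over
evaluated folds; the baseline and subject rounds share fold plans, and their
per-term differentials are reported as %ERR = subject/baseline − 1.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationSet,
    DataError,
    GeneIndex,
    Network,
    RunConfig,
    resolve,
    size_distribution,
)
from .integration import (
    CombinedNetwork,
    combine_automatic,
    combine_equal,
    combine_simultaneous,
)
from .metrics import NAN, compute_fold_metrics
from .propagation import make_bias, propagate, rank_candidates

log = logging.getLogger(__name__)

#: term-size band used for the default simultaneous-weighting collection
SW_SIZE_RANGE = (3, 300)


@dataclass(frozen=True)
class MeanMetrics:
    """Per-term metric means across evaluated folds (NaN = undefined)."""

    auroc: float
    aupr: float
    p10r: float


@dataclass(frozen=True)
class TermAssessment:
    """Baseline vs subject performance for one function label."""

    term_id: str
    term_size: int
    baseline: MeanMetrics
    subject: MeanMetrics
    err_auroc: float
    err_aupr: float
    err_p10r: float


def percent_err(baseline_value: float, subject_value: float) -> float:
    """Relative change subject/baseline − 1; NaN when the baseline is ≤0 or undefined."""
    if baseline_value is None or subject_value is None:
        return NAN
    b, s = float(baseline_value), float(subject_value)
    if not np.isfinite(b) or not np.isfinite(s) or b <= 0:
        return NAN
    return s / b - 1.0


def filter_terms(annotations: AnnotationSet, cfg: RunConfig) -> AnnotationSet:
    """Keep terms whose resolved size is within [min, max]; apply branch filter if set."""
    keep: dict[str, set[str]] = {}
    for term, genes in annotations.terms.items():
        if not (cfg.min_annotations <= len(genes) <= cfg.max_annotations):
            continue
        if (
            cfg.branch is not None
            and annotations.branch
            and annotations.branch.get(term) != cfg.branch
        ):
            continue
        keep[term] = set(genes)
    if not keep:
        dist = dict(sorted(size_distribution(annotations).items()))
        raise DataError(
            f"no terms with {cfg.min_annotations} <= size <= {cfg.max_annotations}; "
            f"size distribution: {dist}"
        )
    return annotations.subset(keep)


def term_seed(seed: int, term_id: str) -> int:
    """Stable 32-bit stream seed derived from (global seed, term id)."""
    digest = hashlib.sha256(f"{seed}\x1f{term_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def make_folds(positives, K: int, seed: int, term_id: str) -> list[list[str]]:
    """Shuffle the positives and deal them round-robin into K subsets.

    Identical for identical (seed, term_id, K) regardless of thread count or
    processing order; subsets may be empty when there are fewer positives
    than folds.
    """
    if K < 2:
        raise ValueError("folds must be >= 2")
    if not positives:
        raise ValueError("cannot make folds from an empty positive set")
    rng = np.random.default_rng(term_seed(seed, term_id))
    order = sorted(positives)
    rng.shuffle(order)
    return [order[k::K] for k in range(K)]


def _combine_for_fold(
    nets: list[Network],
    labels,
    cfg: RunConfig,
    sw_annotations: AnnotationSet,
    sw_combined: CombinedNetwork | None,
) -> CombinedNetwork:
    if cfg.integration == "equal":
        return combine_equal(nets)
    return combine_automatic(nets, labels, sw_annotations, sw_combined=sw_combined)


def _cv_with_folds(
    nets: list[Network],
    positives: set[str],
    folds: list[list[str]],
    cfg: RunConfig,
    sw_annotations: AnnotationSet,
    sw_combined: CombinedNetwork | None,
    index: GeneIndex,
) -> MeanMetrics:
    aurocs, auprs, p10rs = [], [], []
    for held in folds:
        if not held:
            continue
        train = positives.difference(held)
        if not train:
            continue
        labels = make_bias(train, index)
        combined = _combine_for_fold(nets, labels, cfg, sw_annotations, sw_combined)
        scores = propagate(combined, labels)
        ranking = rank_candidates(scores, train, index)
        fm = compute_fold_metrics(ranking, set(held))
        aurocs.append(fm.auroc)
        auprs.append(fm.aupr)
        p10rs.append(fm.prec_at_10_recall)

    def mean(values: list[float]) -> float:
        vals = [v for v in values if np.isfinite(v)]
        return float(np.mean(vals)) if vals else NAN

    return MeanMetrics(auroc=mean(aurocs), aupr=mean(auprs), p10r=mean(p10rs))


def cross_validate_term(
    nets: list[Network],
    positives,
    cfg: RunConfig,
    sw_annotations: AnnotationSet,
    term_id: str,
    sw_combined: CombinedNetwork | None = None,
    folds: list[list[str]] | None = None,
) -> MeanMetrics:
    """K-fold cross validation of one term over one network set."""
    positives = set(positives)
    index = nets[0].index
    if folds is None:
        folds = make_folds(positives, cfg.folds, cfg.seed, term_id)
    return _cv_with_folds(nets, positives, folds, cfg, sw_annotations, sw_combined, index)


def default_sw_annotations(annotations: AnnotationSet) -> AnnotationSet:
    """The run's own gold standard restricted to 3–300-gene terms."""
    lo, hi = SW_SIZE_RANGE
    keep = [t for t, g in annotations.terms.items() if lo <= len(g) <= hi]
    return annotations.subset(keep)


def _sort_records(records: list[TermAssessment]) -> list[TermAssessment]:
    # descending %ERR-AUC-ROC, undefined values last, ties by ascending term id
    def key(r: TermAssessment):
        undefined = not np.isfinite(r.err_auroc)
        return (undefined, -r.err_auroc if not undefined else 0.0, r.term_id)

    return sorted(records, key=key)


def run_parallel(tasks, threads: int):
    """Run (term_id, callable) tasks, serially or across threads.

    Results are independent of *threads* because every task derives its own
    RNG stream.  A failing task is logged and reported as (term_id, None,
    exception) without affecting the others.
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")

    def safe(tid, fn):
        try:
            return tid, fn(), None
        except Exception as exc:  # noqa: BLE001 - per-term isolation is the contract
            log.error("term %s failed: %s", tid, exc)
            return tid, None, exc

    if threads == 1:
        return [safe(tid, fn) for tid, fn in tasks]
    return joblib.Parallel(n_jobs=threads, prefer="threads")(
        joblib.delayed(safe)(tid, fn) for tid, fn in tasks
    )


def assess(
    baseline_nets: list[Network],
    subject_nets: list[Network],
    annotations: AnnotationSet,
    cfg: RunConfig,
    synonyms=None,
    sw_annotations: AnnotationSet | None = None,
) -> list[TermAssessment]:
    """Full differential assessment of subject vs baseline network sets.

    Both selections are resolved against the common universe (union over all
    networks); every surviving term is cross-validated once per round with a
    shared fold plan, and records are sorted by descending %ERR-AUC-ROC.
    """
    if not baseline_nets or not subject_nets:
        raise DataError("baseline and subject selections must both be non-empty")
    t0 = time.perf_counter()

    all_nets: list[Network] = []
    seen: set[str] = set()
    for net in [*baseline_nets, *subject_nets]:
        if net.name not in seen:
            seen.add(net.name)
            all_nets.append(net)
    index, resolved, res_annotations = resolve(all_nets, annotations, synonyms)
    by_name = {net.name: net for net in resolved}
    base = [by_name[n.name] for n in baseline_nets]
    subj = [by_name[n.name] for n in subject_nets]

    seed = cfg.seed
    if not seed:
        seed = int(time.time_ns() % (2**31 - 1)) or 1
        log.warning("no seed specified; using time-based seed %d", seed)

    filtered = filter_terms(res_annotations, cfg)
    log.info("%d term(s) survive the size filter", len(filtered.terms))
    if sw_annotations is None:
        sw_annotations = default_sw_annotations(res_annotations)

    fold_plans = {
        t: make_folds(pos, cfg.folds, seed, t) for t, pos in filtered.terms.items()
    }

    # the simultaneous combination is label-independent: compute it once per
    # round iff some fold will dispatch to it
    sw_base = sw_subj = None
    if cfg.integration == "automatic":
        needs_sw = any(
            len(pos) - len(f) < 5
            for t, pos in filtered.terms.items()
            for f in fold_plans[t]
            if f and len(pos) > len(f)
        )
        if needs_sw and sw_annotations.terms:
            sw_base = combine_simultaneous(base, sw_annotations)
            sw_subj = combine_simultaneous(subj, sw_annotations)

    def task_for(term_id: str):
        positives = filtered.terms[term_id]
        folds = fold_plans[term_id]

        def run() -> TermAssessment:
            b = _cv_with_folds(base, positives, folds, cfg, sw_annotations, sw_base, index)
            s = _cv_with_folds(subj, positives, folds, cfg, sw_annotations, sw_subj, index)
            return TermAssessment(
                term_id=term_id,
                term_size=len(positives),
                baseline=b,
                subject=s,
                err_auroc=percent_err(b.auroc, s.auroc),
                err_aupr=percent_err(b.aupr, s.aupr),
                err_p10r=percent_err(b.p10r, s.p10r),
            )

        return run

    tasks = [(t, task_for(t)) for t in sorted(filtered.terms)]
    results = run_parallel(tasks, cfg.threads)
    records = [rec for _, rec, err in results if err is None and rec is not None]
    failed = [tid for tid, _, err in results if err is not None]
    if failed:
        log.warning("%d term(s) failed and were omitted: %s", len(failed), failed[:10])
    log.info("assessment finished in %.2f s", time.perf_counter() - t0)
    return _sort_records(records)


# ---------------------------------------------------------------------------
# summarization


def summarize(
    records: list[TermAssessment], size_bins: list[tuple[int, int]]
) -> pd.DataFrame:
    """Per-size-bin medians with 95% percentile-interval half-widths.

    For each bin (lo, hi) and each reported metric, the median of the
    defined per-term values and half the spread between the 2.5th and 97.5th
    percentiles are tabulated.  Empty bins are omitted with a warning.
    """
    if not records:
        raise ValueError("no records to summarize")
    metric_of = {
        "baseline_auroc": lambda r: r.baseline.auroc,
        "subject_auroc": lambda r: r.subject.auroc,
        "err_auroc": lambda r: r.err_auroc,
        "baseline_aupr": lambda r: r.baseline.aupr,
        "subject_aupr": lambda r: r.subject.aupr,
        "err_aupr": lambda r: r.err_aupr,
        "baseline_p10r": lambda r: r.baseline.p10r,
        "subject_p10r": lambda r: r.subject.p10r,
        "err_p10r": lambda r: r.err_p10r,
    }
    rows = []
    for lo, hi in size_bins:
        members = [r for r in records if lo <= r.term_size <= hi]
        if not members:
            log.warning("size bin %d-%d is empty; omitted", lo, hi)
            continue
        for name, get in metric_of.items():
            vals = np.array([get(r) for r in members], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            lo_p, hi_p = np.percentile(vals, [2.5, 97.5])
            rows.append(
                {
                    "bin": f"{lo}-{hi}",
                    "metric": name,
                    "median": float(np.median(vals)),
                    "ci95_halfwidth": float((hi_p - lo_p) / 2.0),
                    "n_terms": len(members),
                }
            )
    return pd.DataFrame(rows, columns=["bin", "metric", "median", "ci95_halfwidth", "n_terms"])


def summarize_report_frame(
    df: pd.DataFrame, sizes: dict[str, int], size_bins: list[tuple[int, int]]
) -> pd.DataFrame:
    """Summarize a re-parsed report, with term sizes supplied separately."""
    records = []
    for _, row in df.iterrows():
        term = row["QUERY"]
        if term not in sizes:
            continue
        records.append(
            TermAssessment(
                term_id=term,
                term_size=sizes[term],
                baseline=MeanMetrics(
                    row["BASELINE-AUC-ROC"],
                    row["BASELINE-AUC-PR"],
                    row["BASELINE-PREC-AT-10-RECALL"],
                ),
                subject=MeanMetrics(
                    row["SUBJECT-AUC-ROC"],
                    row["SUBJECT-AUC-PR"],
                    row["SUBJECT-PREC-AT-10-RECALL"],
                ),
                err_auroc=row["%ERR-AUC-ROC"],
                err_aupr=row["%ERR-AUC-PR"],
                err_p10r=row["%ERR-PREC-AT-10-RECALL"],
            )
        )
    if not records:
        raise DataError("no report rows matched the supplied gold standard")
    return summarize(records, size_bins)
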