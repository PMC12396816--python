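"""Model assessment: ranking metrics, substitution accuracy, and model fit.

Mutation placement is scored as an imbalanced binary ranking problem: each
informative site inside the evaluation window is one instance, labeled by
whether it mutated, scored by its predicted substitution probability
``p = 1 - exp(-t* lambda)`` with a per-pair likelihood-optimized branch
length ``t*`` (so scores are comparable across pairs).  Because mutations
are rare, AUROC is complemented by AUPRC and R-precision, whose baseline
for a random classifier is the prevalence ``rho`` = mutated sites / sites.

Model fit is assessed by binning sites on predicted probability and
comparing the observed mutation count per bin with the expected count
(the sum of predicted probabilities), summarized by the histogram-overlap
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from .models import SHMModel, _BASE_INDEX
from .pcp import PcpDataset, mutation_indicators
from .training import optimize_branch_length, substitution_probability

EVAL_WINDOW = (80, 319)  # 0-based, inclusive


@dataclass
class SiteScores:
    """Pooled per-site scores for ranking metrics.

    Arrays are aligned: one entry per informative site inside the
    evaluation window, across all pairs, in (pair, site) order.
    """

    scores: np.ndarray
    labels: np.ndarray
    pcp_index: np.ndarray
    site_index: np.ndarray


@dataclass
class BinnedFit:
    """Observed vs expected mutation counts binned on predicted probability."""

    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class MetricReport:
    auroc: float
    auprc: float
    r_precision: float
    substitution_accuracy: float
    overlap: float
    log_likelihood: float  # mean per-site placement log-likelihood
    prevalence: float
    n_sites: int
    n_mutations: int

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Probability a random mutated site outranks a random unmutated one.

    Computed as the Mann-Whitney U statistic over all positive-negative
    pairs, counting ties as 1/2 — exactly the all-pairs definition.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels, pcp_index=None, site_index=None) -> float:
    """Average precision: mean of precision at each positive's rank.

    Sites are ranked by descending score; ties are broken deterministically
    by (pair index, site index) when provided, else by input order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    if pcp_index is None:
        pcp_index = np.zeros(scores.size, dtype=np.int64)
    if site_index is None:
        site_index = np.arange(scores.size, dtype=np.int64)
    order = np.lexsort((site_index, pcp_index, -scores))
    sorted_labels = labels[order]
    hits = np.cumsum(sorted_labels)
    ranks = np.arange(1, scores.size + 1)
    precision_at_pos = hits[sorted_labels] / ranks[sorted_labels]
    return float(precision_at_pos.sum() / labels.sum())


def r_precision(per_pair: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Micro-averaged R-precision over pairs.

    For each pair with R >= 1 observed mutations, count true mutations
    among its R highest-scored sites (score ties broken by site index);
    the statistic is total hits / total R.  A random ranking scores the
    prevalence rho in expectation.
    """
    hits, total_r = 0, 0
    for scores, labels in per_pair:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        r = int(labels.sum())
        if r == 0:
            continue
        top = np.argsort(-scores, kind="stable")[:r]
        hits += int(labels[top].sum())
        total_r += r
    if total_r == 0:
        raise ValueError("R-precision undefined: every pair has zero mutations")
    return hits / total_r


def substitution_accuracy(csp_rows: np.ndarray, child_bases) -> float:
    """Fraction of mutated sites whose CSP argmax is the observed base.

    ``csp_rows`` has one row over (A,C,G,T) per mutated site; argmax ties
    break alphabetically (A < C < G < T).
    """
    csp_rows = np.atleast_2d(np.asarray(csp_rows, dtype=float))
    if csp_rows.shape[0] == 0:
        raise ValueError("substitution accuracy needs at least one mutated site")
    predicted = np.argmax(csp_rows, axis=1)  # first max = alphabetical tie-break
    truth = np.array([_BASE_INDEX[b] for b in child_bases])
    return float(np.mean(predicted == truth))


# ---------------------------------------------------------------------------
# binned observed/expected fit
# ---------------------------------------------------------------------------

def overlap_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Histogram intersection / average histogram mass, in [0, 1]."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    denom = 0.5 * (observed.sum() + expected.sum())
    if denom == 0:
        return 1.0
    return float(np.minimum(observed, expected).sum() / denom)


def binned_fit(scores, labels, n_bins: int = 20) -> tuple[BinnedFit, float]:
    """Bin sites by predicted probability; compare observed vs expected.

    Bins are equal width in log10(probability) spanning the pooled score
    range.  Per bin, the observed count is the number of mutations and the
    expected count the sum of predicted probabilities; the overlap
    statistic summarizes their agreement.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    logs = np.log10(np.clip(scores, 1e-300, None))
    lo, hi = logs.min(), logs.max()
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(logs, edges) - 1, 0, n_bins - 1)
    observed = np.bincount(idx[labels], minlength=n_bins).astype(float)
    expected = np.bincount(idx, weights=scores, minlength=n_bins)
    fit = BinnedFit(bin_edges=10.0 ** edges, observed=observed, expected=expected)
    return fit, overlap_statistic(observed, expected)


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------

def collect_site_scores(
    model: SHMModel,
    pcps: PcpDataset,
    site_window: tuple[int, int] = EVAL_WINDOW,
    optimize_t: bool = True,
):
    """Scores, labels and CSP rows for all window sites of a dataset.

    Returns (SiteScores, per-pair score/label lists, mutated-site CSP rows,
    mutated-site child bases).  Branch lengths are re-optimized per pair by
    maximum likelihood unless ``optimize_t`` is False (then the stored
    offsets are used).
    """
    lo, hi = site_window
    scores, labels, pcp_idx, site_idx = [], [], [], []
    per_pair = []
    csp_rows, child_bases = [], []
    for j, pcp in enumerate(pcps):
        pred = model.predict_rates(pcp.parent)
        m, mask = mutation_indicators(pcp)
        sites = np.nonzero(mask)[0]
        sites = sites[(sites >= lo) & (sites <= hi)]
        if sites.size == 0:
            continue
        t = (
            optimize_branch_length(model, pcp, rates=pred.rates)
            if optimize_t
            else pcp.branch_length
        )
        p = substitution_probability(pred.rates[sites], t)
        scores.append(p)
        labels.append(m[sites])
        pcp_idx.append(np.full(sites.size, j))
        site_idx.append(sites)
        per_pair.append((p, m[sites]))
        for i in sites[m[sites]]:
            csp_rows.append(pred.csp[i])
            child_bases.append(pcp.child[i])
    if not scores:
        raise ValueError("no informative sites inside the evaluation window")
    pooled = SiteScores(
        scores=np.concatenate(scores),
        labels=np.concatenate(labels),
        pcp_index=np.concatenate(pcp_idx),
        site_index=np.concatenate(site_idx),
    )
    return pooled, per_pair, np.array(csp_rows), child_bases


def evaluate(
    model: SHMModel,
    pcps: PcpDataset,
    site_window: tuple[int, int] = EVAL_WINDOW,
    n_bins: int = 20,
) -> MetricReport:
    """Full metric report on the informative window sites of a dataset."""
    pooled, per_pair, csp_rows, child_bases = collect_site_scores(
        model, pcps, site_window
    )
    s, y = pooled.scores, pooled.labels
    fit, overlap = binned_fit(s, y, n_bins)
    with np.errstate(divide="ignore"):
        ll = np.where(y, np.log(s), np.log1p(-s))
    return MetricReport(
        auroc=auroc(s, y),
        auprc=auprc(s, y, pooled.pcp_index, pooled.site_index),
        r_precision=r_precision(per_pair),
        substitution_accuracy=substitution_accuracy(csp_rows, child_bases),
        overlap=overlap,
        log_likelihood=float(ll.mean()),
        prevalence=float(y.mean()),
        n_sites=int(y.size),
        n_mutations=int(y.sum()),
    )


def write_metric_report(report: MetricReport, path) -> None:
    """Write a report as flat key<TAB>value text."""
    with open(path, "w") as fh:
        for k, v in report.to_dict().items():
            fh.write(f"{k}\t{v}\n")
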