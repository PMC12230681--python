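"""Domain-domain interaction prediction from multi-resource PPI co-occurrence.

Per resource, a candidate domain pair (a, b) is scored by a cosine-style
normalized co-occurrence s_r = n_r(a,b) / sqrt(m_r(a) * m_r(b)), where
n_r counts unordered PPIs carrying the pair across their endpoints and m_r
counts PPIs with the domain on >= 1 endpoint. Resource scores are combined
as a reliability-weighted arithmetic mean, a confidence threshold is
calibrated against ground-truth pairs by maximizing F1, and integer
resource weights are tuned by seeded random search.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    CalibrationResult,
    DDIScoreRecord,
    DomainOccurrence,
    PPIEdgeRecord,
    canonical_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResourceIndex",
    "build_resource_index",
    "resource_pair_score",
    "combined_score",
    "score_all_candidates",
    "calibrate_threshold",
    "assign_confidence",
    "random_weight_search",
    "write_predictions_tsv",
    "write_calibration_curve_tsv",
]


@dataclass
class ResourceIndex:
    """Co-occurrence counts for one PPI resource.

    ``pair_counts[(a, b)]`` (canonical order) is the number of distinct
    unordered PPIs whose endpoints carry the pair; ``domain_counts[d]`` is
    the number of PPIs with d on at least one endpoint. A PPI contributes
    at most 1 to any given count.
    """

    resource: str
    n_edges: int = 0
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    domain_counts: dict[str, int] = field(default_factory=dict)


def build_resource_index(
    edges: Iterable[PPIEdgeRecord],
    domain_occurrences: Iterable[DomainOccurrence],
) -> ResourceIndex:
    """Count domain-pair co-occurrence over one resource's PPI edges.

    Homodimer PPIs contribute to self-pairs (A, A) and to (A, B) for domain
    pairs on the one protein, each counted once.
    """
    domains: dict[str, set[str]] = defaultdict(set)
    for occ in domain_occurrences:
        domains[occ.protein_id].add(occ.domain_id)

    edge_list = list(edges)
    resources = {e.resource for e in edge_list}
    if len(resources) > 1:
        raise ValueError(f"edges span multiple resources: {sorted(resources)}")
    index = ResourceIndex(resource=next(iter(resources)) if resources else "")

    pair_counts: dict[tuple[str, str], int] = defaultdict(int)
    domain_counts: dict[str, int] = defaultdict(int)
    seen_keys = set()
    for edge in edge_list:
        if edge.key in seen_keys:  # defensive: reader already de-duplicates
            continue
        seen_keys.add(edge.key)
        pa, pb = edge.key
        dom_a, dom_b = domains.get(pa, set()), domains.get(pb, set())
        if pa == pb:
            pairs = set(combinations_with_replacement(sorted(dom_a), 2))
        else:
            pairs = {canonical_pair(a, b) for a, b in product(dom_a, dom_b)}
        for pair in pairs:
            pair_counts[pair] += 1
        for d in dom_a | dom_b:
            domain_counts[d] += 1
    index.n_edges = len(seen_keys)
    index.pair_counts = dict(pair_counts)
    index.domain_counts = dict(domain_counts)
    return index


def resource_pair_score(index: ResourceIndex, a: str, b: str) -> float:
    """Cosine co-occurrence score n / sqrt(m_a * m_b), in [0, 1]."""
    pair = canonical_pair(a, b)
    n = index.pair_counts.get(pair, 0)
    if n == 0:
        return 0.0
    m_a = index.domain_counts.get(pair[0], 0)
    m_b = index.domain_counts.get(pair[1], 0)
    if m_a == 0 or m_b == 0:
        return 0.0
    return n / float(np.sqrt(m_a * m_b))


def combined_score(
    weights: Mapping[str, int], per_resource_scores: Mapping[str, float]
) -> float:
    """Weighted arithmetic mean over ALL configured resources.

    A resource without the pair contributes score 0, so breadth of support
    raises the combined score. Invariant under uniform weight scaling.
    """
    if not weights:
        raise ValueError("empty resource weight set")
    missing = set(per_resource_scores) - set(weights)
    if missing:
        raise ValueError(f"weights missing for resources {sorted(missing)}")
    if any(w < 1 for w in weights.values()):
        raise ValueError("resource weights must be >= 1")
    total_w = sum(weights.values())
    return sum(w * per_resource_scores.get(r, 0.0) for r, w in weights.items()) / total_w


def score_all_candidates(
    resource_indexes: Sequence[ResourceIndex],
    weights: Mapping[str, int] | None = None,
) -> list[DDIScoreRecord]:
    """Score every domain pair co-occurring in >= 1 resource.

    Default weights are 1 for every resource. Records are returned in
    canonical pair order with combined score > 0.
    """
    if not resource_indexes:
        raise ValueError("need at least one resource index")
    if weights is None:
        weights = {ix.resource: 1 for ix in resource_indexes}
    by_name = {ix.resource: ix for ix in resource_indexes}
    all_pairs = sorted(set().union(*(ix.pair_counts.keys() for ix in by_name.values())))
    records = []
    for a, b in all_pairs:
        per_resource = {
            name: s for name, ix in by_name.items()
            if (s := resource_pair_score(ix, a, b)) > 0.0
        }
        s_combined = combined_score(weights, per_resource)
        if s_combined > 0.0:
            records.append(DDIScoreRecord(
                domain_a=a, domain_b=b, per_resource=per_resource,
                combined=s_combined,
                n_supporting_resources=len(per_resource),
            ))
    return records


# ---------------------------------------------------------------------------
# Calibration


def _calibrate_scores(
    scores: np.ndarray, is_true: np.ndarray, n_unscored_truth: int = 0
) -> CalibrationResult:
    """Sweep all distinct observed scores as thresholds; maximize F1.

    Ties in F1 break toward the smallest threshold. ``n_unscored_truth``
    adds permanent false negatives (truth pairs never scored).
    """
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    cum_tp = np.cumsum(is_true[order].astype(int))
    total_true = int(cum_tp[-1]) + n_unscored_truth
    if total_true == 0:
        raise ValueError("no scored candidate intersects the ground truth; uncalibratable")
    # last index of each distinct score = inclusive positives at that threshold
    last_idx = np.nonzero(np.diff(s_sorted, append=-np.inf) != 0)[0]
    best = None
    curve = []
    for i in last_idx:
        t = float(s_sorted[i])
        npos = i + 1
        tp = int(cum_tp[i])
        precision = tp / npos
        recall = tp / total_true
        f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
        curve.append((t, precision, recall, f1))
        if best is None or f1 >= best.f1:  # >= prefers smaller t on ties
            best = CalibrationResult(t, precision, recall, f1)
    return CalibrationResult(best.threshold, best.precision, best.recall, best.f1,
                             curve=tuple(curve))


def calibrate_threshold(
    records: Sequence[DDIScoreRecord],
    ground_truth_pairs: Iterable[tuple[str, str]],
    count_unscored_truth: bool = False,
) -> CalibrationResult:
    """Pick the combined-score threshold maximizing F1 against ground truth.

    By default precision/recall are computed over the scored candidate
    universe only; with ``count_unscored_truth`` truth pairs that were never
    scored count as false negatives at every threshold.
    """
    if not records:
        raise ValueError("no score records to calibrate on")
    truth = {canonical_pair(a, b) for a, b in ground_truth_pairs}
    if not truth:
        raise ValueError("empty ground truth")
    scores = np.array([r.combined for r in records], dtype=float)
    is_true = np.array([r.key in truth for r in records], dtype=bool)
    n_unscored = len(truth - {r.key for r in records}) if count_unscored_truth else 0
    return _calibrate_scores(scores, is_true, n_unscored)


def assign_confidence(
    records: Sequence[DDIScoreRecord], threshold: float
) -> list[DDIScoreRecord]:
    """Tier records in place: gold (>= t, >= 2 resources), silver (>= t, 1
    resource), bronze (t/2 <= S < t), below otherwise."""
    for rec in records:
        if rec.combined >= threshold:
            rec.tier = "gold" if rec.n_supporting_resources >= 2 else "silver"
        elif rec.combined >= threshold / 2.0:
            rec.tier = "bronze"
        else:
            rec.tier = "below"
    return list(records)


# ---------------------------------------------------------------------------
# Random weight search


def random_weight_search(
    resource_indexes: Sequence[ResourceIndex],
    ground_truth_pairs: Iterable[tuple[str, str]],
    n_iter: int = 10_000,
    weight_min: int = 1,
    weight_max: int = 100,
    seed: int = 0,
    count_unscored_truth: bool = False,
) -> tuple[dict[str, int], CalibrationResult, list[tuple[dict[str, int], float]]]:
    """Tune integer resource weights by seeded uniform random search.

    Draws ``n_iter`` weight vectors from [weight_min, weight_max] per
    resource (resources in sorted-name order), calibrates a threshold for
    each, and returns the first vector attaining the best F1, its
    calibration, and the per-draw (weights, F1) history.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    names = sorted(ix.resource for ix in resource_indexes)
    by_name = {ix.resource: ix for ix in resource_indexes}
    truth = {canonical_pair(a, b) for a, b in ground_truth_pairs}

    # per-resource scores are weight-independent: precompute the matrix once
    all_pairs = sorted(set().union(*(by_name[n].pair_counts.keys() for n in names)))
    score_matrix = np.array(
        [[resource_pair_score(by_name[n], a, b) for n in names] for a, b in all_pairs],
        dtype=float,
    )
    is_true = np.array([canonical_pair(a, b) in truth for a, b in all_pairs], dtype=bool)
    n_unscored = len(truth - set(all_pairs)) if count_unscored_truth else 0

    rng = np.random.default_rng(seed)
    draws = rng.integers(weight_min, weight_max + 1, size=(n_iter, len(names)))
    best_weights: dict[str, int] | None = None
    best_cal: CalibrationResult | None = None
    history = []
    last_error: Exception | None = None
    for row in draws:
        weights = {name: int(w) for name, w in zip(names, row)}
        combined = score_matrix @ row / row.sum()
        mask = combined > 0.0
        try:
            cal = _calibrate_scores(combined[mask], is_true[mask], n_unscored)
        except ValueError as exc:
            last_error = exc
            continue
        history.append((weights, cal.f1))
        if best_cal is None or cal.f1 > best_cal.f1:
            best_weights, best_cal = weights, cal
    if best_cal is None:
        raise ValueError(f"every weight draw failed to calibrate: {last_error}")
    return best_weights, best_cal, history


# ---------------------------------------------------------------------------
# Output tables


def write_predictions_tsv(
    records: Sequence[DDIScoreRecord], resource_names: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        cols = ["domain_a", "domain_b", *[f"s_{r}" for r in resource_names],
                "combined", "n_supporting_resources", "tier"]
        fh.write("\t".join(cols) + "\n")
        for rec in sorted(records, key=lambda r: (-r.combined, r.key)):
            row = [rec.domain_a, rec.domain_b,
                   *[f"{rec.per_resource.get(r, 0.0):.6g}" for r in resource_names],
                   f"{rec.combined:.6g}", str(rec.n_supporting_resources), rec.tier]
            fh.write("\t".join(row) + "\n")


def write_calibration_curve_tsv(cal: CalibrationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tprecision\trecall\tf1\n")
        for t, p, r, f1 in cal.curve:
            fh.write(f"{t:.6g}\t{p:.6g}\t{r:.6g}\t{f1:.6g}\n")
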