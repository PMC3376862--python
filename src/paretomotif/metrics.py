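"""Site-level evaluation: matching, precision/recall/F and consensus identity.

A predicted site counts as a true site when it overlaps a planted site by
at least ``min_overlap_fraction`` of the shorter site's width (default
50%); matching is greedy by decreasing overlap and one-to-one per
sequence.  Precision is tp over predicted sites, recall tp over true
sites, and F their harmonic mean.  A discovered consensus counts as a
successful identification when its best ungapped-offset identity to the
planted consensus exceeds 70%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import SiteAnnotation, ValidationError


@dataclass(frozen=True)
class MatchResult:
    """Counts and pairing from matching predictions against truth."""

    tp: int
    fp: int
    fn: int
    pairing: tuple[tuple[SiteAnnotation, SiteAnnotation], ...] = ()


def _overlap(a: SiteAnnotation, b: SiteAnnotation) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_sites(predicted: list[SiteAnnotation], truth: list[SiteAnnotation],
                min_overlap_fraction: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of predicted to true sites per sequence.

    A pair is eligible iff its overlap is at least
    ``min_overlap_fraction`` times the shorter site's width; eligible
    pairs are taken in order of decreasing overlap.
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValidationError("min_overlap_fraction must be in (0, 1]")
    pairs: list[tuple[int, int, int]] = []  # (-overlap, pred idx, truth idx)
    for ip, p in enumerate(predicted):
        for it, t in enumerate(truth):
            if p.seq_id != t.seq_id:
                continue
            ov = _overlap(p, t)
            if ov >= min_overlap_fraction * min(p.width, t.width):
                pairs.append((-ov, ip, it))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[SiteAnnotation, SiteAnnotation]] = []
    for _, ip, it in pairs:
        if ip in used_p or it in used_t:
            continue
        used_p.add(ip)
        used_t.add(it)
        matched.append((predicted[ip], truth[it]))
    tp = len(matched)
    return MatchResult(tp, len(predicted) - tp, len(truth) - tp, tuple(matched))


def f_measures(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F score from match counts.

    F is the harmonic mean 2PR / (P + R), defined as 0 when P + R = 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    if tp == fp == fn == 0:
        warnings.warn("no predicted and no true sites; reporting 0/0/0",
                      stacklevel=2)
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def similarity_success(discovered_consensus: str, true_consensus: str,
                       threshold: float = 0.70) -> tuple[float, bool]:
    """Best ungapped identity between two consensi and the success flag.

    The shorter string slides along the longer; identity is the fraction
    of agreeing positions over the overlap (the shorter width) at the best
    offset.  Success requires identity strictly above the threshold.
    """
    if not discovered_consensus or not true_consensus:
        raise ValidationError("consensus strings must be non-empty")
    short, long_ = sorted((discovered_consensus, true_consensus), key=len)
    w = len(short)
    best = 0.0
    for off in range(len(long_) - w + 1):
        agree = sum(a == b for a, b in zip(short, long_[off:off + w]))
        best = max(best, agree / w)
    return best, best > threshold


def assign_motifs(truth_by_motif: dict[str, list[SiteAnnotation]],
                  predicted_by_motif: dict[str, list[SiteAnnotation]],
                  min_overlap_fraction: float = 0.5,
                  ) -> dict[str, tuple[str, MatchResult]]:
    """One-to-one assignment of discovered motifs to planted motifs.

    Builds the small (planted x discovered) F-score matrix and solves the
    linear assignment maximizing total F.  Returns, per planted motif
    label, the assigned discovered label and its match result; planted
    motifs left unassigned (or assigned at F = 0) are absent from the
    result.
    """
    t_labels = list(truth_by_motif)
    p_labels = list(predicted_by_motif)
    if not t_labels or not p_labels:
        return {}
    f_mat = np.zeros((len(t_labels), len(p_labels)))
    results: dict[tuple[int, int], MatchResult] = {}
    for i, tl in enumerate(t_labels):
        for j, pl in enumerate(p_labels):
            res = match_sites(predicted_by_motif[pl], truth_by_motif[tl],
                              min_overlap_fraction)
            results[i, j] = res
            _, _, f_mat[i, j] = f_measures(res.tp, res.fp, res.fn) \
                if res.tp + res.fp + res.fn else (0.0, 0.0, 0.0)
    rows, cols = linear_sum_assignment(f_mat, maximize=True)
    out: dict[str, tuple[str, MatchResult]] = {}
    for i, j in zip(rows, cols):
        if f_mat[i, j] > 0.0:
            out[t_labels[i]] = (p_labels[j], results[i, j])
    return out
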