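"""Tracking evaluation: identity measures (IDF1/IDR/IDP, IDSW) and HOTA.

Identity measures score how well predicted identities cover ground-truth
trajectories under the *best possible* one-to-one trajectory matching:
with IDTP the number of frames in which a ground-truth box and its matched
prediction ID coincide (IOU at least 0.5), and IDFN/IDFP the uncovered
ground-truth/prediction boxes,

    IDF1 = 2*IDTP / (2*IDTP + IDFP + IDFN),
    IDR  = IDTP / (IDTP + IDFN),
    IDP  = IDTP / (IDTP + IDFP).

The identity measures are invariant to a consistent relabeling of predicted
IDs — only the stability of the labeling matters.  IDSW counts the frames
in which a ground-truth trajectory's per-frame matched prediction ID
differs from the ID it was last matched to (gaps ignored).

HOTA averages, over IOU thresholds alpha = 0.05, 0.10, ..., 0.95, the
geometric mean of a detection score and an association score:

    HOTA_a = sqrt(DetA_a * AssA_a),    DetA_a = TP / (TP + FP + FN),
    AssA_a = AssRe_a * AssPr_a / (AssRe_a + AssPr_a - AssRe_a * AssPr_a),

where AssRe/AssPr are the means over true-positive matches c = (g, p) of
TPA(c)/(TPA(c)+FNA(c)) and TPA(c)/(TPA(c)+FPA(c)); TPA counts TPs linking
the same (g, p) pair over the sequence, FNA the remaining detections of g,
FPA the remaining predictions of p.  Per-frame matching at each alpha is
the Hungarian assignment maximizing total IOU among pairs with IOU >=
alpha.  AssA is derived from AssRe and AssPr through the displayed
identity, which therefore holds exactly at every alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Detection, MOTSequence
from .motion import iou

__all__ = ["MetricsReport", "match_frames", "identity_measures", "hota",
           "evaluate", "DEFAULT_ALPHAS"]

DEFAULT_ALPHAS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class MetricsReport:
    """All scores for one (ground truth, prediction) sequence pair."""

    IDSW: int
    IDTP: int
    IDFP: int
    IDFN: int
    IDF1: float
    IDR: float
    IDP: float
    HOTA: float
    DetA: float
    AssA: float
    AssRe: float
    AssPr: float
    alpha_values: Tuple[float, ...] = DEFAULT_ALPHAS
    per_alpha: Dict[float, Dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "IDSW": self.IDSW, "IDTP": self.IDTP, "IDFP": self.IDFP,
            "IDFN": self.IDFN, "IDF1": self.IDF1, "IDR": self.IDR,
            "IDP": self.IDP, "HOTA": self.HOTA, "DetA": self.DetA,
            "AssA": self.AssA, "AssRe": self.AssRe, "AssPr": self.AssPr,
            "alpha_values": list(self.alpha_values),
        }


def _frame_union(gt: MOTSequence, pred: MOTSequence) -> List[int]:
    return sorted(set(gt.frames) | set(pred.frames))


def match_frames(gt: MOTSequence, pred: MOTSequence, alpha: float = 0.5
                 ) -> Dict[int, List[Tuple[Detection, Detection]]]:
    """Per-frame bipartite matching between gt and prediction boxes.

    For each frame, the Hungarian assignment maximizing total IOU over
    pairs with ``IOU >= alpha``; returns frame -> list of (gt, pred) true
    positives.  Unmatched gt boxes are misses, unmatched predictions false
    positives (recoverable from the sequences by set difference).
    """
    out: Dict[int, List[Tuple[Detection, Detection]]] = {}
    for f in _frame_union(gt, pred):
        g = gt.frames.get(f, [])
        p = pred.frames.get(f, [])
        out[f] = []
        if not g or not p:
            continue
        M = np.zeros((len(g), len(p)))
        for i, gd in enumerate(g):
            for j, pd in enumerate(p):
                M[i, j] = iou(gd.box, pd.box)
        rows, cols = linear_sum_assignment(-M)
        for r, c in zip(rows, cols):
            if M[r, c] >= alpha and M[r, c] > 0:
                out[f].append((g[r], p[c]))
    return out


def _overlap_counts(gt: MOTSequence, pred: MOTSequence, alpha: float
                    ) -> Dict[Tuple[int, int], int]:
    """Frames in which gt ID g and pred ID p could be co-located (IOU >=
    alpha), counted per (g, p) pair over the whole sequence."""
    counts: Dict[Tuple[int, int], int] = {}
    for f in _frame_union(gt, pred):
        for gd in gt.frames.get(f, []):
            for pd in pred.frames.get(f, []):
                if iou(gd.box, pd.box) >= alpha:
                    key = (gd.id, pd.id)
                    counts[key] = counts.get(key, 0) + 1
    return counts


def identity_measures(gt: MOTSequence, pred: MOTSequence,
                      alpha: float = 0.5) -> dict:
    """IDTP/IDFP/IDFN, IDF1/IDR/IDP and IDSW for a sequence pair.

    Trajectory-level optimal bipartite matching between gt IDs and
    prediction IDs maximizes the total per-pair co-location count (IOU >=
    ``alpha``); IDSW is counted under independent per-frame matching.
    """
    gt_ids = sorted(gt.ids())
    pr_ids = sorted(pred.ids())
    n_gt = sum(len(v) for v in gt.frames.values())
    n_pr = sum(len(v) for v in pred.frames.values())
    counts = _overlap_counts(gt, pred, alpha)
    idtp = 0
    if gt_ids and pr_ids:
        gain = np.zeros((len(gt_ids), len(pr_ids)))
        gi = {g: i for i, g in enumerate(gt_ids)}
        pi = {p: i for i, p in enumerate(pr_ids)}
        for (g, p), c in counts.items():
            gain[gi[g], pi[p]] = c
        rows, cols = linear_sum_assignment(-gain)
        idtp = int(gain[rows, cols].sum())
    idfn = n_gt - idtp
    idfp = n_pr - idtp
    idf1 = 2 * idtp / (2 * idtp + idfp + idfn) if n_gt + n_pr else 1.0
    idr = idtp / (idtp + idfn) if idtp + idfn else 1.0
    idp = idtp / (idtp + idfp) if idtp + idfp else 1.0

    # IDSW under per-frame matching
    idsw = 0
    last_match: Dict[int, int] = {}
    for f, pairs in sorted(match_frames(gt, pred, alpha).items()):
        for gd, pd in pairs:
            prev = last_match.get(gd.id)
            if prev is not None and prev != pd.id:
                idsw += 1
            last_match[gd.id] = pd.id
    return {"IDTP": idtp, "IDFP": idfp, "IDFN": idfn, "IDF1": idf1,
            "IDR": idr, "IDP": idp, "IDSW": idsw}


def hota(gt: MOTSequence, pred: MOTSequence,
         alphas: Sequence[float] = DEFAULT_ALPHAS) -> dict:
    """HOTA and its components, averaged over the alpha grid.

    Returns HOTA, DetA, AssA, AssRe, AssPr plus the per-alpha breakdown
    under key ``per_alpha``.
    """
    n_gt = sum(len(v) for v in gt.frames.values())
    n_pr = sum(len(v) for v in pred.frames.values())
    gt_count: Dict[int, int] = {}
    pr_count: Dict[int, int] = {}
    for dets in gt.frames.values():
        for d in dets:
            gt_count[d.id] = gt_count.get(d.id, 0) + 1
    for dets in pred.frames.values():
        for d in dets:
            pr_count[d.id] = pr_count.get(d.id, 0) + 1

    per_alpha: Dict[float, Dict[str, float]] = {}
    for a in alphas:
        matches = match_frames(gt, pred, a)
        tp_pairs: List[Tuple[int, int]] = []
        pair_count: Dict[Tuple[int, int], int] = {}
        for pairs in matches.values():
            for gd, pd in pairs:
                key = (gd.id, pd.id)
                tp_pairs.append(key)
                pair_count[key] = pair_count.get(key, 0) + 1
        tp = len(tp_pairs)
        fn = n_gt - tp
        fp = n_pr - tp
        det_a = tp / (tp + fn + fp) if tp + fn + fp else 1.0
        if tp:
            ass_re = sum(pair_count[k] / gt_count[k[0]] for k in tp_pairs) / tp
            ass_pr = sum(pair_count[k] / pr_count[k[1]] for k in tp_pairs) / tp
            denom = ass_re + ass_pr - ass_re * ass_pr
            ass_a = ass_re * ass_pr / denom if denom else 0.0
        else:
            ass_re = ass_pr = ass_a = 0.0 if n_gt + n_pr else 1.0
        per_alpha[float(a)] = {
            "DetA": det_a, "AssA": ass_a, "AssRe": ass_re, "AssPr": ass_pr,
            "HOTA": float(np.sqrt(det_a * ass_a)),
        }
    mean = lambda k: float(np.mean([v[k] for v in per_alpha.values()]))
    return {"HOTA": mean("HOTA"), "DetA": mean("DetA"), "AssA": mean("AssA"),
            "AssRe": mean("AssRe"), "AssPr": mean("AssPr"),
            "per_alpha": per_alpha}


def evaluate(gt: MOTSequence, pred: MOTSequence,
             alphas: Sequence[float] = DEFAULT_ALPHAS) -> MetricsReport:
    """Full scoring of a tracker output against ground truth."""
    idm = identity_measures(gt, pred)
    h = hota(gt, pred, alphas)
    return MetricsReport(
        IDSW=idm["IDSW"], IDTP=idm["IDTP"], IDFP=idm["IDFP"],
        IDFN=idm["IDFN"], IDF1=idm["IDF1"], IDR=idm["IDR"], IDP=idm["IDP"],
        HOTA=h["HOTA"], DetA=h["DetA"], AssA=h["AssA"], AssRe=h["AssRe"],
        AssPr=h["AssPr"], alpha_values=tuple(float(a) for a in alphas),
        per_alpha=h["per_alpha"])
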