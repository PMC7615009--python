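"""Ground-truth comparison of segmentations.

Predicted and reference objects are matched through a bipartite graph with an
edge wherever the Dice overlap of a (ground truth, predicted) pair reaches a
minimum (default 0.15), followed by a maximum-cardinality matching
(Hopcroft–Karp).  Matched pairs are true positives; unmatched ground-truth
objects are false negatives and unmatched predictions false positives — so
over- and under-segmentation of spark clusters are charged correctly (two
true sparks merged into one prediction cost exactly one false negative).

Also here: the agreement score TP/(TP+FP+FN), conversion of bounding boxes
to inscribed ellipses (for comparing bounding-box-only detectors), and a
seeded random-search autofit of detection parameters against reference
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .detect import detect_events
from .io_formats import DetectionParams, LabelMask, LineScanImage

DEFAULT_DICE_MIN = 0.15


@dataclass
class MatchResult:
    """TP/FP/FN bookkeeping of one ground-truth vs prediction comparison."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]]
    dice_per_pair: list[float]

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def dice(obj_a: np.ndarray, obj_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean pixel sets."""
    a = np.asarray(obj_a, dtype=bool)
    b = np.asarray(obj_b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("Dice coefficient is undefined for empty objects")
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def _pair_overlaps(gt: np.ndarray, pred: np.ndarray):
    """Joint label histogram → per-pair Dice for all co-occurring pairs."""
    gt_sizes = np.bincount(gt.ravel())
    pred_sizes = np.bincount(pred.ravel())
    both = (gt > 0) & (pred > 0)
    if not both.any():
        return {}, gt_sizes, pred_sizes
    pairs = gt[both].astype(np.int64) * (pred.max() + 1) + pred[both]
    uniq, counts = np.unique(pairs, return_counts=True)
    out = {}
    base = pred.max() + 1
    for code, inter in zip(uniq, counts):
        g, p = int(code // base), int(code % base)
        out[(g, p)] = 2.0 * inter / (gt_sizes[g] + pred_sizes[p])
    return out, gt_sizes, pred_sizes


def match_events(
    gt: LabelMask, pred: LabelMask, dice_min: float = DEFAULT_DICE_MIN
) -> MatchResult:
    """Match ground-truth and predicted objects by overlap.

    Builds the bipartite graph with edges at Dice ≥ ``dice_min`` and finds a
    maximum matching; ``tp`` is the matching size, ``fn`` the unmatched
    ground-truth objects, ``fp`` the unmatched predictions.  The identities
    ``tp + fn = |GT|`` and ``tp + fp = |P|`` hold for every input.
    """
    if gt.labels.shape != pred.labels.shape:
        raise ValueError("ground-truth and predicted masks must share a shape")
    g_labels = np.unique(gt.labels)
    g_labels = g_labels[g_labels > 0]
    p_labels = np.unique(pred.labels)
    p_labels = p_labels[p_labels > 0]

    overlaps, _, _ = _pair_overlaps(gt.labels, pred.labels)
    edges = {k: v for k, v in overlaps.items() if v >= dice_min}

    graph = nx.Graph()
    gt_nodes = [("gt", int(g)) for g in g_labels]
    pred_nodes = [("pred", int(p)) for p in p_labels]
    graph.add_nodes_from(gt_nodes, bipartite=0)
    graph.add_nodes_from(pred_nodes, bipartite=1)
    for (g, p), d in edges.items():
        graph.add_edge(("gt", g), ("pred", p), dice=d)

    matching = nx.bipartite.maximum_matching(graph, top_nodes=gt_nodes)
    pairs = sorted(
        (g[1], p[1]) for g, p in matching.items() if g[0] == "gt"
    )
    tp = len(pairs)
    fn = len(g_labels) - tp
    fp = len(p_labels) - tp
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        matched_pairs=pairs,
        dice_per_pair=[edges[(g, p)] for g, p in pairs],
    )


def agreement(result: MatchResult) -> float:
    """Agreement score TP / (TP + FP + FN); symmetric in the two roles."""
    total = result.tp + result.fp + result.fn
    if total == 0:
        raise ValueError("agreement is undefined with no objects on either side")
    return result.tp / total


def bbox_to_ellipse(
    bbox_px: tuple[int, int, int, int], image_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of the ellipse inscribed into a half-open pixel bounding
    box ``(t0, t1, x0, x1)``; degenerate extents collapse to a single row,
    column or pixel."""
    t0, t1, x0, x1 = bbox_px
    if not (0 <= t0 < t1 <= image_shape[0] and 0 <= x0 < x1 <= image_shape[1]):
        raise ValueError("bounding box outside the image")
    tc = (t0 + t1 - 1) / 2.0
    xc = (x0 + x1 - 1) / 2.0
    rt = max((t1 - t0) / 2.0, 0.5)
    rx = max((x1 - x0) / 2.0, 0.5)
    tt, xx = np.mgrid[t0:t1, x0:x1]
    inside = ((tt - tc) / rt) ** 2 + ((xx - xc) / rx) ** 2 <= 1.0
    out = np.zeros(image_shape, dtype=bool)
    out[t0:t1, x0:x1] = inside
    return out


# ---------------------------------------------------------------------------
# Parameter autofitting


@dataclass
class AutofitResult:
    params: DetectionParams
    score: float
    n_evaluations: int


def _mean_agreement(
    pairs: list[tuple[LineScanImage, LabelMask]],
    params: DetectionParams,
    dice_min: float,
) -> float:
    scores = []
    for image, ref in pairs:
        pred = detect_events(image, params).mask
        res = match_events(ref, pred, dice_min=dice_min)
        if res.tp + res.fp + res.fn == 0:
            scores.append(1.0)  # both empty: perfect agreement
        else:
            scores.append(agreement(res))
    return float(np.mean(scores))


def autofit(
    pairs: list[tuple[LineScanImage, LabelMask]],
    search_space: dict[str, tuple[float, float]],
    budget: int = 40,
    seed: int = 0,
    initial: DetectionParams | None = None,
    dice_min: float = DEFAULT_DICE_MIN,
) -> AutofitResult:
    """Fit detection parameters to reference annotations.

    Maximises the mean agreement score across ``pairs`` with a seeded random
    search over ``search_space`` (parameter name → (low, high) bounds),
    always evaluating ``initial`` (the defaults) first, followed by a
    coordinate-refinement pass around the best point.  Deterministic given
    seed and budget.
    """
    if not pairs:
        raise ValueError("autofit needs at least one image/reference pair")
    if not search_space:
        raise ValueError("empty search space")
    base = initial if initial is not None else DetectionParams()
    rng = np.random.default_rng(seed)

    def clamp(name, value):
        lo, hi = search_space[name]
        return float(np.clip(value, lo, hi))

    evaluated = 0
    best_params, best_score = base, _mean_agreement(pairs, base, dice_min)
    evaluated += 1

    n_random = max(0, (budget - evaluated) * 2 // 3)
    for _ in range(n_random):
        draw = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in search_space.items()
        }
        cand = base.replace(**draw)
        score = _mean_agreement(pairs, cand, dice_min)
        evaluated += 1
        if score > best_score:
            best_params, best_score = cand, score

    # coordinate refinement around the incumbent
    names = sorted(search_space)
    step_frac = 0.15
    while evaluated < budget:
        improved = False
        for name in names:
            if evaluated >= budget:
                break
            lo, hi = search_space[name]
            span = hi - lo
            current = getattr(best_params, name)
            for delta in (step_frac * span, -step_frac * span):
                if evaluated >= budget:
                    break
                cand = best_params.replace(**{name: clamp(name, current + delta)})
                score = _mean_agreement(pairs, cand, dice_min)
                evaluated += 1
                if score > best_score:
                    best_params, best_score = cand, score
                    improved = True
        if not improved:
            step_frac /= 2.0
            if step_frac < 0.01:
                break
    return AutofitResult(params=best_params, score=best_score, n_evaluations=evaluated)
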