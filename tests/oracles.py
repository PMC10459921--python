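"""Independent brute-force geometric oracles, deliberately written as plain
scalar arithmetic (no shared code with the package kernels)."""

import itertools
import math


def corners(box):
    cx, cy, w, h = box
    return cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2


def oracle_iou(a, b):
    ax0, ay0, ax1, ay1 = corners(a)
    bx0, by0, bx1, by1 = corners(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def oracle_giou(a, b):
    ax0, ay0, ax1, ay1 = corners(a)
    bx0, by0, bx1, by1 = corners(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    hull = (max(ax1, bx1) - min(ax0, bx0)) * (max(ay1, by1) - min(ay0, by0))
    return inter / union - (hull - union) / hull


def oracle_ciou_loss(target, pred):
    """Step-by-step: v (aspect term), a (trade-off), D²/C², assembled last."""
    w1, h1 = target[2], target[3]
    w, h = pred[2], pred[3]
    v = (4.0 / math.pi**2) * (math.atan(w1 / h1) - math.atan(w / h)) ** 2
    iou = oracle_iou(target, pred)
    d2 = (target[0] - pred[0]) ** 2 + (target[1] - pred[1]) ** 2
    tx0, ty0, tx1, ty1 = corners(target)
    px0, py0, px1, py1 = corners(pred)
    cw = max(tx1, px1) - min(tx0, px0)
    ch = max(ty1, py1) - min(ty0, py0)
    c2 = cw**2 + ch**2
    denom = (1.0 - iou) + v
    a = v / denom if denom > 0 else 0.0
    return 1.0 - iou + d2 / c2 + a * v


def oracle_box_loss(target, pred, lam_ciou, lam_l1):
    l1 = sum(abs(t - p) for t, p in zip(target, pred))
    return lam_ciou * oracle_ciou_loss(target, pred) + lam_l1 * l1


def oracle_assignment(cost):
    """Exhaustive minimum-cost injective assignment of rows to columns."""
    n_rows = len(cost)
    n_cols = len(cost[0])
    best = None
    best_total = math.inf
    for perm in itertools.permutations(range(n_cols), n_rows):
        total = sum(cost[i][perm[i]] for i in range(n_rows))
        if total < best_total:
            best_total = total
            best = {i: perm[i] for i in range(n_rows)}
    return best, best_total


def oracle_ap(detections, ground_truth, iou_threshold=0.5):
    """Hand PR-curve AP: detections [(score, image_id, box)], ground_truth
    {image_id: [box, ...]}; greedy best-IoU matching in confidence order."""
    n_gt = sum(len(v) for v in ground_truth.values())
    dets = sorted(detections, key=lambda d: -d[0])
    used = {k: [False] * len(v) for k, v in ground_truth.items()}
    points = []
    tp = fp = 0
    for score, img, box in dets:
        gts = ground_truth.get(img, [])
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            i = oracle_iou(box, g)
            if i > best_iou:
                best_iou, best_j = i, j
        if best_j >= 0 and best_iou >= iou_threshold and not used[img][best_j]:
            used[img][best_j] = True
            tp += 1
        else:
            fp += 1
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_recall = 0.0
    for k, (recall, _) in enumerate(points):
        if recall > prev_recall:
            best_future_precision = max(p for r, p in points[k:])
            ap += (recall - prev_recall) * best_future_precision
            prev_recall = recall
    return ap
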