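"""Independent brute-force oracles used to check the fast implementations.

These deliberately share no code with the package: the DTW oracle enumerates
every monotone warping path recursively, and the AUC oracle counts pairwise
concordance directly.
"""

from __future__ import annotations


def dtw_brute_force(a, b) -> float:
    """Minimal alignment cost by recursive enumeration of all warping paths."""
    n, m = len(a), len(b)

    def cost(x, y):
        return max(x, y) / min(x, y) - 1.0

    def rec(i: int, j: int) -> float:
        here = cost(a[i], b[j])
        if i == n - 1 and j == m - 1:
            return here
        options = []
        if i + 1 < n:
            options.append(rec(i + 1, j))
        if j + 1 < m:
            options.append(rec(i, j + 1))
        if i + 1 < n and j + 1 < m:
            options.append(rec(i + 1, j + 1))
        return here + min(options)

    return rec(0, 0)


def concordance_auc(y_true, y_score) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    pos = [s for s, y in zip(y_score, y_true) if y == 1]
    neg = [s for s, y in zip(y_score, y_true) if y == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def confusion_metrics(y_true, y_score, threshold: float = 0.5) -> dict[str, float]:
    """Hand-tallied confusion-matrix metrics at a threshold."""
    tp = fn = fp = tn = 0
    for y, s in zip(y_true, y_score):
        pred = 1 if s >= threshold else 0
        if y == 1 and pred == 1:
            tp += 1
        elif y == 1:
            fn += 1
        elif pred == 1:
            fp += 1
        else:
            tn += 1
    n = tp + fn + fp + tn
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "acc": (tp + tn) / n,
        "recall": recall,
        "precision": precision,
        "f1": f1,
    }
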