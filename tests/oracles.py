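"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain loops over the defining formulas,
deliberately sharing no code with the package.
"""

import math


def interpolate_oracle(coords, p):
    out = []
    n = len(coords)
    for i in range(n - 1):
        a, b = coords[i], coords[i + 1]
        out.append(list(a))
        for k in range(1, p + 1):
            out.append([((p - k + 1) * a[d] + k * b[d]) / (p + 1)
                        for d in range(3)])
    out.append(list(coords[-1]))
    return out


def homothety_oracle(l, r_max):
    return math.floor(l / 2 - 1) / r_max


def class_weights_oracle(counts):
    biggest = max(counts)
    return [biggest / c for c in counts]


def weighted_ce_oracle(probs, labels, weights):
    total = 0.0
    for x in range(len(probs)):
        for i in range(len(weights)):
            if labels[x][i] == 1:
                total -= weights[i] * math.log(probs[x][i])
    return total


def flip_weight_oracle(dx, dy, dz):
    return 1.0 / (dx + dy + dz + 1)


def fuse_probability_oracle(per_flip_probs, coefficients):
    n_classes = len(per_flip_probs[0])
    best, best_score = None, None
    for i in range(n_classes):
        score = sum(c * row[i] for c, row in zip(coefficients, per_flip_probs))
        if best_score is None or score > best_score + 1e-12:
            best, best_score = i + 1, score
    return best


def fuse_majority_oracle(per_flip_classes, coefficients, per_flip_probs=None,
                         n_classes=6):
    votes = [0.0] * n_classes
    for c, w in zip(per_flip_classes, coefficients):
        votes[c - 1] += w
    top = max(votes)
    tied = [i for i in range(n_classes) if abs(votes[i] - top) <= 1e-12]
    if len(tied) > 1 and per_flip_probs is not None:
        sums = [sum(c * row[i] for c, row in zip(coefficients, per_flip_probs))
                for i in range(n_classes)]
        best = max(sums[i] for i in tied)
        tied = [i for i in tied if abs(sums[i] - best) <= 1e-12]
    return min(tied) + 1


def confusion_oracle(y_true, y_pred, n_classes=6):
    counts = [[0] * n_classes for _ in range(n_classes)]
    for t, p in zip(y_true, y_pred):
        counts[t - 1][p - 1] += 1
    return counts


def metrics_oracle(counts):
    """Accuracy, per-class P/R/F1 and macro metrics from a count matrix."""
    n = len(counts)
    total = sum(sum(row) for row in counts)
    acc = sum(counts[i][i] for i in range(n)) / total
    precision, recall, f1 = [], [], []
    for i in range(n):
        col = sum(counts[j][i] for j in range(n))
        row = sum(counts[i])
        p = counts[i][i] / col if col else 0.0
        r = counts[i][i] / row if row else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    p_m = sum(precision) / n
    r_m = sum(recall) / n
    f1_m = 2 * p_m * r_m / (p_m + r_m) if p_m + r_m else 0.0
    return {"accuracy": acc, "precision": precision, "recall": recall,
            "f1": f1, "macro": (p_m, r_m, f1_m)}
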