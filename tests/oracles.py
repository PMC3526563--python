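"""Independent reference implementations used to check the fast scorers.

These deliberately stay naive: the AUC oracle counts (positive, negative)
pairs, and the weighted oracle evaluates the ROC double sum literally.
"""

from goqa.scoring import classify


def pair_counting_auc(slist, fs_threshold):
    """Fraction of (positive, negative) pairs with the positive ranked
    earlier in the Slist's total order; degenerate labelings follow the
    scorer's conventions (no positives -> 0, no negatives -> 1)."""
    labels = classify(slist, fs_threshold)
    tp = sum(labels)
    tn = len(labels) - tp
    if tp == 0:
        return 0.0
    if tn == 0:
        return 1.0
    wins = sum(
        1
        for i in range(len(labels))
        for j in range(len(labels))
        if labels[i] and not labels[j] and i < j
    )
    return wins / (tp * tn)


def double_loop_yga(slist, fs_threshold):
    """Literal double-sum of the Z-weighted ROC area."""
    labels = classify(slist, fs_threshold)
    tp = sum(labels)
    tn = len(labels) - tp
    if tp == 0:
        return 0.0
    positives = [r.z_score for r, lab in zip(slist.records, labels) if lab]
    if tn == 0:
        return sum(z / tp for z in positives)
    total = 0.0
    for i, (record_i, lab_i) in enumerate(zip(slist.records, labels)):
        if lab_i:
            continue
        n_i = sum(1 for lab in labels[:i] if lab)
        for j in range(n_i):
            total += (1 / tn) * (1 / tp) * positives[j]
    return total
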