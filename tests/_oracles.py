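"""Independent brute-force oracles shared across test modules."""

import numpy as np


def metrics_bruteforce(counts: np.ndarray, c: int) -> tuple[float, ...]:
    """One-vs-rest metrics recomputed formula by formula from raw counts."""
    tp = counts[c, c]
    fn = counts[c].sum() - tp
    fp = counts[:, c].sum() - tp
    tn = counts.sum() - tp - fn - fp
    div = lambda a, b: a / b if b else 0.0
    sens = 100 * div(tp, tp + fn)
    spec = 100 * div(tn, tn + fp)
    acc = 100 * (tp + tn) / counts.sum()
    prec = 100 * div(tp, tp + fp)
    f1 = 100 * div(2 * tp, 2 * tp + fp + fn)
    mcc_den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = 100 * div(tp * tn - fp * fn, mcc_den)
    return sens, spec, acc, prec, f1, mcc
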