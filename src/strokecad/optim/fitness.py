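"""Classification-error fitness shared by both optimizers."""

from __future__ import annotations

import numpy as np

from ..errors import InputError


def fitness_error_rate(predicted, true) -> float:
    """Percentage of misclassified instances:
    100 * (#misclassified / total)."""
    pred = np.asarray(predicted)
    truth = np.asarray(true)
    if pred.shape != truth.shape:
        raise InputError("predicted and true labels must have equal length")
    if pred.size == 0:
        raise InputError("fitness_error_rate requires at least one instance")
    return 100.0 * float(np.count_nonzero(pred != truth)) / pred.size
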