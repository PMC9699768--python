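"""One-vs-rest metric tables from per-epoch confusion diagonals.

The six-class benchmark (class sizes 25/25/24/54/26/24, 178 slices) is
reported through per-epoch counts of correctly classified slices; from
those diagonals the per-class and macro one-vs-rest metrics follow.
"""

from strokecad.evaluation import diagonal_confusion, evaluate_confusion, summary_frame

CLASS_SIZES = [25, 25, 24, 54, 26, 24]
EPOCH_DIAGONALS = {
    "Epoch-500": [23, 24, 24, 52, 24, 22],
    "Epoch-1000": [23, 22, 24, 54, 23, 22],
    "Epoch-1500": [25, 21, 22, 52, 26, 23],
    "Epoch-2000": [25, 20, 23, 54, 26, 23],
}

reports = [
    evaluate_confusion(diagonal_confusion(diag, CLASS_SIZES), epoch_tag=tag)
    for tag, diag in EPOCH_DIAGONALS.items()
]
print(summary_frame(reports).to_string(index=False))
print()
print("sensitivity is exact given only diagonals (it needs just row sums);")
print("column-dependent metrics depend on where the misclassifications land")
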