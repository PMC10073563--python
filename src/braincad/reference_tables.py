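"""Published reference result tables and their arithmetic verification.

The report layouts this package emits mirror a published set of result
tables for the same pipeline: one per-image segmentation table (25
pathological images x 7 metrics) and, for each of three ablation modes,
a per-fold classification table (4 classifiers x 5 folds x 6 metrics) with
its fold-averaged summary.  The numbers are embedded here verbatim —
including their typos — as fixtures, so the evaluation module's metric
identities and averaging rules can be checked against every *derivable*
cell:

* ``AUC = (TPR + TNR) / 2`` for every per-fold row,
* ``F = 2 PPV TPR / (PPV + TPR)`` for every per-fold row,
* column averages of the segmentation table,
* fold means of each per-fold table reproducing the summary table.

Cells that are internally inconsistent in the source (obvious misprints
such as a dropped decimal point, and rounding/truncation artifacts beyond
+/-0.01) are listed in ``KNOWN_DISCREPANCIES`` so the verifier reports them
as known misprints rather than failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import balanced_auc, f_score, round_half_up

__all__ = [
    "SEGMENTATION_TABLE",
    "FOLD_TABLES",
    "SUMMARY_TABLES",
    "KNOWN_DISCREPANCIES",
    "CellCheck",
    "verify_reference_tables",
]

# Per-image segmentation metrics: DSC, PPV, TPR, TNR, F, AUC, accuracy.
SEGMENTATION_COLUMNS = ("DSC", "PPV", "TPR", "TNR", "F", "AUC", "accuracy")
SEGMENTATION_TABLE = np.array([
    [97.85, 99.87, 99.96, 96.70, 99.91, 98.33, 99.84],
    [89.01, 99.85, 99.70, 92.42, 99.77, 96.06, 99.56],
    [83.69, 99.76, 98.56, 94.74, 99.15, 96.65, 98.39],
    [92.66, 99.47, 99.32, 93.55, 99.39, 96.44, 98.88],
    [85.03, 98.28, 98.29, 82.85, 98.53, 90.82, 97.33],
    [87.75, 99.52, 99.68, 85.68, 99.60, 92.68, 99.22],
    [90.69, 98.96, 99.74, 85.84, 99.35, 92.79, 98.79],
    [95.89, 99.65, 99.97, 92.60, 99.81, 96.29, 99.64],
    [91.81, 100.00, 99.64, 99.92, 99.82, 99.78, 99.65],
    [93.75, 100.00, 99.47, 100.00, 99.73, 99.74, 99.49],
    [94.02, 99.96, 99.65, 98.61, 99.80, 99.13, 99.61],
    [95.71, 99.32, 99.21, 95.52, 99.26, 97.36, 98.72],
    [91.81, 99.99, 98.12, 99.87, 99.04, 98.99, 98.28],
    [88.88, 99.62, 98.80, 94.36, 99.21, 96.58, 98.52],
    [93.24, 99.98, 99.20, 99.69, 99.58, 99.44, 99.23],
    [92.27, 99.76, 98.96, 96.94, 99.36, 97.95, 98.82],
    [90.28, 100.00, 99.86, 99.55, 99.92, 99.70, 99.86],
    [91.41, 98.86, 99.60, 87.74, 99.23, 93.67, 98.59],
    [94.94, 99.99, 99.79, 99.33, 99.88, 99.56, 99.78],
    [87.66, 99.99, 99.30, 99.51, 99.64, 99.40, 99.30],
    [94.02, 100.00, 99.35, 99.91, 99.67, 99.63, 99.38],
    [87.04, 100.00, 99.10, 100.00, 99.55, 99.35, 99.13],
    [90.42, 100.00, 99.42, 100.00, 99.71, 99.71, 99.44],
    [97.84, 99.92, 99.97, 96.97, 99.94, 98.47, 99.89],
    [99.27, 100.00, 99.92, 100.00, 99.96, 99.96, 99.92],
])
SEGMENTATION_AVERAGE = {
    "DSC": 91.88, "PPV": 99.71, "TPR": 99.38, "TNR": 95.69,
    "F": 99.55, "AUC": 97.54, "accuracy": 99.17,
}

# Per-fold classification tables, columns TPR, TNR, PPV, F, AUC, accuracy.
# Modes: "raw" = no enhancement/segmentation; "enhanced" = enhancement only;
# "full" = enhancement + segmentation.  Values are verbatim, typos included.
FOLD_COLUMNS = ("TPR", "TNR", "PPV", "F", "AUC", "accuracy")
CLASSIFIER_ORDER = ("SVM", "KNN", "GB", "RF")

FOLD_TABLES: dict[str, dict[str, np.ndarray]] = {
    "raw": {
        "SVM": np.array([
            [100.00, 9111.00, 97.94, 98.96, 95.55, 98.29],
            [100.00, 86.67, 96.94, 98.45, 93.33, 97.45],
            [100.00, 84.44, 96.45, 98.19, 92.22, 97.02],
            [100.00, 86.67, 96.94, 98.45, 93.33, 97.45],
            [100.00, 86.67, 96.94, 98.45, 93.33, 97.45],
        ]),
        "KNN": np.array([
            [96.84, 77.78, 94.84, 95.83, 87.31, 93.19],
            [97.37, 82.22, 95.85, 96.60, 89.79, 94.47],
            [98.42, 75.55, 94.44, 96.38, 86.98, 94.04],
            [97.37, 80.00, 95.36, 96.35, 88.68, 94.04],
            [97.37, 75.55, 94.38, 95.85, 86.46, 93.19],
        ]),
        "GB": np.array([
            [93.68, 93.33, 98.34, 94.97, 93.50, 93.61],
            [98.95, 91.11, 97.92, 98.43, 95.03, 97.44],
            [97.89, 88.89, 97.38, 97.63, 93.39, 96.17],
            [97.89, 97.78, 99.46, 98.67, 97.83, 97.87],
            [98.42, 91.11, 97.90, 98.16, 94.76, 97.02],
        ]),
        "RF": np.array([
            [100.00, 95.55, 98.96, 99.47, 97.77, 99.15],
            [99.47, 95.55, 98.95, 99.21, 97.51, 98.72],
            [100.00, 86.67, 96.64, 98.44, 93.33, 97.44],
            [99.47, 91.11, 97.93, 98.69, 95.29, 97.87],
            [100.00, 97.78, 9947.00, 99.73, 98.89, 99.57],
        ]),
    },
    "enhanced": {
        "SVM": np.array([
            [100.00, 88.89, 97.43, 98.69, 94.44, 97.87],
            [100.00, 91.11, 97.94, 98.96, 95.50, 98.29],
            [100.00, 88.89, 97.43, 98.69, 94.44, 97.87],
            [100.00, 84.44, 96.44, 98.18, 92.22, 97.02],
            [100.00, 84.44, 96.44, 98.18, 92.22, 97.02],
        ]),
        "KNN": np.array([
            [97.37, 75.55, 94.38, 95.85, 86.46, 93.19],
            [96.84, 75.55, 94.36, 95.58, 86.19, 92.76],
            [96.31, 73.33, 93.84, 95.06, 84.82, 91.91],
            [97.89, 75.55, 94.41, 96.12, 86.72, 93.62],
            [95.26, 77.77, 94.70, 95.01, 86.51, 91.91],
        ]),
        "GB": np.array([
            [97.89, 88.89, 97.38, 97.63, 93.39, 96.17],
            [96.84, 95.55, 98.95, 97.88, 96.19, 98.72],
            [96.31, 88.89, 97.41, 96.85, 92.60, 97.02],
            [98.42, 93.33, 98.42, 98.42, 95.87, 97.44],
            [96.31, 97.78, 99.45, 97.85, 97.64, 96.59],
        ]),
        "RF": np.array([
            [100.00, 95.55, 98.96, 99.47, 97.77, 99.15],
            [100.00, 95.55, 98.96, 99.47, 97.77, 99.15],
            [100.00, 93.33, 98.44, 99.21, 96.66, 98.72],
            [100.00, 91.11, 97.94, 98.96, 95.55, 98.29],
            [98.95, 93.33, 98.44, 98.95, 96.14, 97.87],
        ]),
    },
    "full": {
        "SVM": np.array([
            [100.00, 91.11, 97.94, 98.96, 95.55, 98.29],
            [99.47, 86.67, 96.92, 98.33, 93.07, 97.02],
            [100.00, 88.86, 97.43, 98.69, 94.44, 97.87],
            [100.00, 91.11, 97.94, 98.96, 95.55, 98.29],
            [100.00, 91.11, 97.94, 98.96, 95.55, 98.29],
        ]),
        "KNN": np.array([
            [100.00, 93.33, 98.44, 99.21, 99.66, 98.72],
            [100.00, 88.89, 97.43, 98.69, 94.44, 97.87],
            [99.47, 100.00, 100.00, 99.73, 99.73, 99.57],
            [100.00, 91.11, 97.94, 98.96, 95.55, 98.29],
            [99.47, 93.33, 98.43, 98.95, 96.40, 98.29],
        ]),
        "GB": np.array([
            [100.00, 95.55, 98.96, 99.47, 97.77, 99.15],
            [99.47, 95.55, 98.95, 99.21, 97.51, 98.72],
            [99.47, 100.00, 100.00, 99.73, 99.73, 99.57],
            [98.95, 97.78, 9.47, 99.21, 98.36, 98.72],
            [98.95, 97.78, 9.47, 99.21, 98.36, 98.72],
        ]),
        "RF": np.array([
            [100.00, 97.78, 99.47, 99.73, 98.89, 99.57],
            [100.00, 97.78, 99.47, 99.73, 98.89, 99.57],
            [99.47, 100.00, 100.00, 99.73, 99.73, 99.57],
            [100.00, 100.00, 100.00, 100.00, 100.00, 100.00],
            [100.00, 100.00, 100.00, 100.00, 100.00, 100.00],
        ]),
    },
}

# Fold-averaged summaries, columns TPR, TNR, PPV, F, AUC, accuracy.
SUMMARY_TABLES: dict[str, dict[str, list[float]]] = {
    "raw": {
        "SVM": [100.00, 87.11, 97.04, 98.50, 93.55, 97.53],
        "KNN": [97.47, 78.22, 94.97, 96.20, 87.84, 93.78],
        "GB": [97.36, 92.44, 98.20, 97.57, 94.90, 96.42],
        "RF": [99.78, 93.33, 98.45, 99.11, 96.56, 98.55],
    },
    "enhanced": {
        "SVM": [100.00, 87.55, 97.14, 98.54, 93.77, 97.61],
        "KNN": [96.73, 75.55, 94.35, 95.52, 86.14, 92.68],
        "GB": [97.15, 92.88, 98.32, 97.72, 95.02, 97.18],
        "RF": [99.79, 93.77, 98.55, 99.21, 96.78, 98.64],
    },
    "full": {
        "SVM": [99.89, 89.78, 97.63, 98.78, 94.83, 97.95],
        "KNN": [99.78, 93.33, 98.45, 99.11, 97.15, 98.55],
        "GB": [99.37, 97.33, 99.37, 99.36, 98.35, 98.98],
        "RF": [99.89, 99.11, 99.78, 99.84, 99.50, 99.75],
    },
}

# Cells that are misprints or rounding/truncation artifacts in the source
# tables; the verifier reports them as known discrepancies, not failures.
# A float value is the evident correction (used for downstream arithmetic,
# e.g. a dropped decimal point); ``None`` flags the cell without correcting.
KNOWN_DISCREPANCIES: dict[str, float | None] = {
    # dropped decimal points
    "raw:SVM_fold1_TNR": 91.11,      # printed 9111
    "raw:RF_fold5_PPV": 99.47,       # printed 9947
    "full:GB_fold4_PPV": 99.47,      # printed 9.47
    "full:GB_fold5_PPV": 99.47,      # printed 9.47
    # cells inconsistent with the row/column arithmetic beyond +/-0.01
    "raw:GB_fold1_F": None,          # printed 94.97; PPV/TPR give 95.95
    "raw:RF_fold3_F": None,          # printed 98.44; PPV/TPR give 98.29
    "raw:RF_average_PPV": None,      # printed 98.45; corrected folds give 98.39
    "enhanced:SVM_fold2_AUC": None,  # printed 95.5; TPR/TNR give 95.56
    "enhanced:KNN_fold5_F": None,    # printed 95.01; PPV/TPR give 94.98
    "enhanced:GB_fold5_AUC": None,   # printed 97.64; TPR/TNR give 97.05
    "enhanced:GB_average_AUC": None, # printed 95.02; fold mean is 95.14
    "enhanced:RF_fold5_F": None,     # printed 98.95; PPV/TPR give 98.69
    "full:SVM_fold2_F": None,        # printed 98.33; PPV/TPR give 98.18
    "full:KNN_fold1_AUC": None,      # printed 99.66; TPR/TNR give 96.67
    "full:RF_average_accuracy": None, # printed 99.75; fold mean is 99.74
}


@dataclass(frozen=True)
class CellCheck:
    """One verified cell: where, what was recomputed, printed vs derived."""

    table: str
    cell: str
    printed: float
    derived: float
    ok: bool
    known_misprint: bool


def _misprint_corrected(table: str, cell: str, value: float) -> tuple[float, bool]:
    key = f"{table}:{cell}"
    if key in KNOWN_DISCREPANCIES:
        corrected = KNOWN_DISCREPANCIES[key]
        return (value if corrected is None else corrected), True
    return value, False


def verify_reference_tables(tolerance: float = 0.01) -> list[CellCheck]:
    """Recompute every derivable aggregate of the embedded tables through the
    evaluation module and compare with the printed values.

    Returns one :class:`CellCheck` per verified cell.  ``ok`` is true when
    the printed and derived values agree within ``tolerance``; cells listed
    in :data:`KNOWN_DISCREPANCIES` are flagged ``known_misprint`` and never
    counted as failures by callers that honor the flag.
    """
    checks: list[CellCheck] = []

    # segmentation table column averages
    for j, name in enumerate(SEGMENTATION_COLUMNS):
        derived = round_half_up(float(SEGMENTATION_TABLE[:, j].mean()))
        printed = SEGMENTATION_AVERAGE[name]
        printed_c, known = _misprint_corrected("segmentation", f"average_{name}", printed)
        checks.append(CellCheck(
            "segmentation", f"average_{name}", printed, derived,
            abs(derived - printed_c) <= tolerance + 1e-9, known,
        ))

    ti = {name: i for i, name in enumerate(FOLD_COLUMNS)}
    for mode, table in FOLD_TABLES.items():
        for clf, rows in table.items():
            corrected = rows.copy()
            for i, row in enumerate(rows):
                for j, name in enumerate(FOLD_COLUMNS):
                    corrected[i, j], _ = _misprint_corrected(
                        mode, f"{clf}_fold{i + 1}_{name}", row[j]
                    )
            # row identities: AUC and F from TPR/TNR/PPV
            for i, row in enumerate(corrected):
                auc = round_half_up(balanced_auc(row[ti["TPR"]], row[ti["TNR"]]))
                printed = rows[i, ti["AUC"]]
                _, known = _misprint_corrected(mode, f"{clf}_fold{i + 1}_AUC", printed)
                checks.append(CellCheck(
                    mode, f"{clf}_fold{i + 1}_AUC", printed, auc,
                    abs(auc - row[ti["AUC"]]) <= tolerance + 1e-9, known,
                ))
                f = round_half_up(f_score(row[ti["PPV"]], row[ti["TPR"]]))
                printed = rows[i, ti["F"]]
                _, known = _misprint_corrected(mode, f"{clf}_fold{i + 1}_F", printed)
                checks.append(CellCheck(
                    mode, f"{clf}_fold{i + 1}_F", printed, f,
                    abs(f - row[ti["F"]]) <= tolerance + 1e-9, known,
                ))
            # fold averages against the summary table
            for j, name in enumerate(FOLD_COLUMNS):
                derived = round_half_up(float(corrected[:, j].mean()))
                printed = SUMMARY_TABLES[mode][clf][j]
                printed_c, known = _misprint_corrected(
                    mode, f"{clf}_average_{name}", printed
                )
                checks.append(CellCheck(
                    mode, f"{clf}_average_{name}", printed, derived,
                    abs(derived - printed_c) <= tolerance + 1e-9, known,
                ))
    return checks
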