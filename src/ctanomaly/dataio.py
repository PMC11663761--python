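"""Reading cohort artifacts: NIfTI pairs, report JSONL, label CSV, manifest."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_manifest",
    "read_reports",
    "read_labels",
    "load_volume",
    "label_matrix",
]


def read_manifest(cohort_dir: str | Path) -> dict:
    with open(Path(cohort_dir) / "manifest.json") as fh:
        return json.load(fh)


def read_reports(path: str | Path) -> pd.DataFrame:
    """JSONL of {exam_id, patient_id, text}; malformed lines are collected."""
    rows, bad = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError:
                bad += 1
    df = pd.DataFrame(rows, columns=["exam_id", "patient_id", "text"])
    df.attrs["n_malformed"] = bad
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def label_matrix(
    labels: pd.DataFrame,
    organ: str,
    categories: tuple[str, ...],
    column: str = "truth",
) -> tuple[list[str], np.ndarray]:
    """Pivot the long label table into (exam_ids, n_exams x n_categories)."""
    sub = labels[labels["organ"] == organ]
    wide = sub.pivot_table(
        index="exam_id", columns="category", values=column, aggfunc="max"
    )
    exam_ids = sorted(wide.index)
    mat = np.zeros((len(exam_ids), len(categories)), dtype=int)
    for j, cat in enumerate(categories):
        if cat in wide.columns:
            mat[:, j] = wide.loc[exam_ids, cat].fillna(0).astype(int).to_numpy()
    return exam_ids, mat
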