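"""End-to-end convenience pipeline: cohort volumes -> features -> models.

Glues the measurement modules together the way a study analysis would run
them: place four mirrored patch pairs inside each subject's lesion, measure
the pooled IP-NWU and the voxel-wise ratio maps, build the 8-grade histogram
and its 13 features, and assemble the per-subject feature matrix for a
chosen feature set.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .features import assemble_features, build_histogram
from .patches import lesion_patch_specs, measure_ip_nwu
from .volumes import CohortSubject

__all__ = ["subject_features", "cohort_feature_table", "feature_matrix"]


def subject_features(
    subject: CohortSubject,
    feature_set: str = "nwu_clinical_imaging",
    n_pairs: int = 4,
) -> dict[str, float]:
    """Measure one synthetic subject: IP-NWU plus the requested features."""
    specs = lesion_patch_specs(subject.lesion_mask, n_pairs=n_pairs)
    result, maps = measure_ip_nwu(subject.volume, specs)
    hist = build_histogram(maps)
    rec = subject.record
    clinical = {"age": rec.age, "gender": rec.gender, "nihss": rec.nihss}
    fv = assemble_features(hist, result.ip_nwu, clinical=clinical,
                           feature_set=feature_set)
    out = fv.as_dict()
    out["mce"] = float(rec.mce_label)
    return out


def cohort_feature_table(
    subjects: Sequence[CohortSubject],
    feature_set: str = "nwu_clinical_imaging",
    n_pairs: int = 4,
) -> pd.DataFrame:
    """One row per subject: features plus the MCE label column."""
    rows = [subject_features(s, feature_set=feature_set, n_pairs=n_pairs)
            for s in subjects]
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y) with the label column removed."""
    y = table["mce"].to_numpy().astype(int)
    X = table.drop(columns=["mce"]).to_numpy(dtype=np.float64)
    return X, y
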