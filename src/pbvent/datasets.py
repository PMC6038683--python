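"""Bundled reference data.

``load_reference_deltas`` returns the published per-subject peak counts for
a 20-subject cohort (10 periodic-breathing, 10 control) used to validate the
two-group comparison stage without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .features_stats import FeatureVector

__all__ = ["load_reference_deltas", "reference_feature_vectors"]


def load_reference_deltas() -> pd.DataFrame:
    """Reference per-subject peak counts as a DataFrame with columns
    subject_id, label, delta_1..delta_5."""
    with resources.files("pbvent.data").joinpath(
            "reference_cohort_deltas.csv").open() as fh:
        return pd.read_csv(fh)


def reference_feature_vectors() -> list[FeatureVector]:
    """The reference cohort as :class:`FeatureVector` objects."""
    df = load_reference_deltas()
    cols = [c for c in df.columns if c.startswith("delta_")]
    return [
        FeatureVector(subject_id=row["subject_id"],
                      deltas=tuple(int(row[c]) for c in cols),
                      label=row["label"])
        for _, row in df.iterrows()
    ]
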