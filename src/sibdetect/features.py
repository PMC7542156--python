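"""Assembly of the per-window feature table (96 features + metadata).

57 time-domain + 12 frequency-domain features (from the filtered window)
merge with the 27 nonlinear motor-variability features (from the raw
window) into one flat table, one row per window, carrying participant id,
window start time, the binary SIB outcome, and the prompt flag.
"""

from __future__ import annotations

import pandas as pd

from .features_linear import LINEAR_FEATURE_NAMES, linear_features
from .nonlinear import NONLINEAR_FEATURE_NAMES, EmbeddingParams, nonlinear_features
from .preprocess import WindowSet

__all__ = ["ALL_FEATURE_NAMES", "META_COLUMNS", "extract_features"]

ALL_FEATURE_NAMES = tuple(LINEAR_FEATURE_NAMES) + tuple(NONLINEAR_FEATURE_NAMES)
META_COLUMNS = ("participant_id", "start_s", "outcome", "prompt")

assert len(ALL_FEATURE_NAMES) == 96


def extract_features(
    windowset: WindowSet, embedding: EmbeddingParams | None = None
) -> pd.DataFrame:
    """Compute all 96 features for every window.

    Returns a DataFrame whose columns are ``META_COLUMNS`` followed by the
    96 feature names in canonical order.
    """
    rows = []
    for w in windowset:
        row: dict[str, object] = {
            "participant_id": w.participant_id,
            "start_s": w.start_s,
            "outcome": w.outcome,
            "prompt": w.prompt,
        }
        row.update(linear_features(w, windowset.rate_hz))
        row.update(nonlinear_features(w, params=embedding))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[list(META_COLUMNS) + list(ALL_FEATURE_NAMES)]
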