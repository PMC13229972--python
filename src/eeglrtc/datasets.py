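"""Published per-subject scaling-exponent tables shipped as package data.

The study reports, for 13 subjects, DFA scaling exponents under two
embeddings (Isomap, PCA), two DFA approaches (norm-based, mean-based), two
musical stimuli (raga Yaman, raga Puriya Dhanashree) and two conditions
(during music, after/relaxation). These printed values, at the published
2-decimal precision, are the inputs for the paired-comparison and
summary-statistics reproductions.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_subject_alpha", "alpha_column"]

_FILES = {
    "isomap": "isomap_subject_alpha.csv",
    "pca": "pca_subject_alpha.csv",
}


def load_subject_alpha(method: str) -> pd.DataFrame:
    """Per-subject alpha table for one embedding method ("isomap" or "pca").

    Columns are named ``{approach}_{raga}_{condition}`` with approach in
    {norm, mean}, raga in {yaman, pd} and condition in {during, after};
    the index is the subject number (1..13).
    """
    if method not in _FILES:
        raise KeyError(f"method must be one of {sorted(_FILES)}, got {method!r}")
    ref = resources.files("eeglrtc.data").joinpath(_FILES[method])
    with ref.open("r") as fh:
        return pd.read_csv(fh, index_col="subject")


def alpha_column(
    method: str, approach: str, raga: str, condition: str
) -> np.ndarray:
    """One 13-subject alpha vector, e.g. ("isomap", "mean", "yaman", "during")."""
    table = load_subject_alpha(method)
    name = f"{approach}_{raga}_{condition}"
    if name not in table.columns:
        raise KeyError(f"no column {name!r}; available: {list(table.columns)}")
    return table[name].to_numpy()
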