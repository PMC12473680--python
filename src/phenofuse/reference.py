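"""Published reference confusion matrices shipped with the package.

Pixel-count confusion matrices of the three-season regional study the
package's defaults emulate, one per classifier input (each single
sensor and the three-sensor combination).  They serve as fixed inputs
for metric recomputation — ingesting one through
:func:`phenofuse.classify.evaluate_matrix` reproduces the study's
printed overall accuracy and per-class F1 scores.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

REFERENCE_DATASETS = ("landsat", "meteor", "sentinel", "multisensor")


def load_reference_matrix(name: str) -> pd.DataFrame:
    """Load one reference confusion matrix (rows = actual, cols = predicted)."""
    if name not in REFERENCE_DATASETS:
        raise KeyError(f"unknown reference dataset {name!r}; choose from {REFERENCE_DATASETS}")
    path = resources.files("phenofuse.data") / f"confusion_{name}.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, index_col="actual")
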