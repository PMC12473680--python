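"""Quality-layer decoding and cloud-fraction bookkeeping.

Sentinel-2 L2A scenes carry a scene-classification layer (SCL) with
integer codes 0-11; codes 0 (no data), 1 (saturated/defective),
3 (cloud shadow), 8 (medium cloud probability), 9 (high cloud
probability), 10 (haze/cirrus) and 11 (snow) are unusable for NDVI work.
Landsat Collection-2 scenes carry the QA_PIXEL band, where the single
value 21824 denotes a clear land pixel; every other value is masked.
Meteor scenes are delivered as daily composites without a quality layer;
their masks are all-true except for sentinel no-data values.

Scenes are tallied into four masked-fraction bins — <5 % ("cloud-free"),
5-20 % ("low-cloud"), 20-50 % and >50 % — with half-open boundaries on
the left, so that exactly 5 % masked lands in the 5-20 % bin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

#: SCL codes marked unsuitable for analysis.
SENTINEL_INVALID_CODES = frozenset({0, 1, 3, 8, 9, 10, 11})

#: The one QA_PIXEL value denoting a clear land pixel.
LANDSAT_CLEAR_VALUE = 21824

#: Cloud-fraction bin labels, in increasing order of masked fraction.
CLOUD_BINS = ("<5", "5-20", "20-50", ">50")

_BIN_EDGES = (0.05, 0.20, 0.50)


class QualityCodeError(ValueError):
    """A quality layer contained a code outside its documented range."""


@dataclass
class ValidityMask:
    """Boolean usability grid for one scene (True = usable pixel)."""

    valid: np.ndarray
    sensor_id: str
    doy: int | None = None
    year: int | None = None

    def __post_init__(self):
        self.valid = np.asarray(self.valid, bool)

    @property
    def masked_fraction(self) -> float:
        return 1.0 - self.valid.mean() if self.valid.size else 0.0

    def apply(self, grid: np.ndarray) -> np.ndarray:
        """Return ``grid`` with masked pixels replaced by NaN (idempotent)."""
        out = np.asarray(grid, float).copy()
        out[~self.valid] = np.nan
        return out


def sentinel_validity(scl_grid, *, sensor_id="sentinel", doy=None, year=None) -> ValidityMask:
    """Decode a Sentinel SCL grid into a validity mask.

    Raises :class:`QualityCodeError` if any code falls outside 0-11.
    """
    scl = np.asarray(scl_grid)
    bad = scl[(scl < 0) | (scl > 11)]
    if bad.size:
        raise QualityCodeError(f"SCL code {int(bad.flat[0])} outside 0-11")
    valid = ~np.isin(scl, list(SENTINEL_INVALID_CODES))
    return ValidityMask(valid, sensor_id, doy=doy, year=year)


def landsat_validity(qa_grid, *, sensor_id="landsat", doy=None, year=None) -> ValidityMask:
    """Decode a Landsat QA_PIXEL grid: valid iff the value equals 21824."""
    qa = np.asarray(qa_grid)
    if qa.size and qa.min() < 0:
        raise QualityCodeError("QA_PIXEL values must be non-negative")
    return ValidityMask(qa == LANDSAT_CLEAR_VALUE, sensor_id, doy=doy, year=year)


def meteor_validity(ndvi_grid, *, nodata=np.nan, doy=None, year=None) -> ValidityMask:
    """Meteor composites carry no QA layer: valid unless the no-data value."""
    arr = np.asarray(ndvi_grid, float)
    if np.isnan(nodata):
        valid = ~np.isnan(arr)
    else:
        valid = arr != nodata
    return ValidityMask(valid, "meteor", doy=doy, year=year)


def cloud_bin(mask: ValidityMask | float) -> str:
    """Bin a scene by masked fraction: [0,.05), [.05,.20), [.20,.50), [.50,1]."""
    frac = mask.masked_fraction if isinstance(mask, ValidityMask) else float(mask)
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"masked fraction {frac} outside [0, 1]")
    for label, edge in zip(CLOUD_BINS, _BIN_EDGES):
        if frac < edge:
            return label
    return CLOUD_BINS[-1]


@dataclass
class CloudTally:
    """Per-stack count of scenes by masked-fraction bin (a Table-2-style row)."""

    counts: Counter = field(default_factory=Counter)

    def add(self, mask: ValidityMask | float) -> str:
        label = cloud_bin(mask)
        self.counts[label] += 1
        return label

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        return {label: self.counts.get(label, 0) for label in CLOUD_BINS}
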