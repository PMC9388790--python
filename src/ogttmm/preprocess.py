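"""OGTT records and truncation at the post-excursion glucose nadir.

The glycerol model is fit only from drink ingestion (t = 0) to the lowest
glucose sample after the post-drink glucose peak.  Truncating there keeps the
counterregulatory glycerol rebound (pronounced in reactive hypoglycemia) out of
the fitting window, since the model cannot produce glycerol above basal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

#: Blood-draw schedule of the 6-h OGTT protocol, minutes relative to the drink.
PROTOCOL_TIMES = np.array(
    [-20, -10, 0, 10, 20, 30, 45, 60, 75, 90, 105, 120,
     135, 150, 165, 180, 210, 240, 300, 360],
    dtype=float,
)


class NoNadirError(ValueError):
    """Glucose never comes back down after its post-drink peak."""


@dataclass(frozen=True)
class OGTTRecord:
    """One participant's sampled OGTT time series plus basal values.

    times are minutes relative to drink ingestion; glucose in mg/dL, insulin in
    uU/mL, glycerol in umol/L.  ``Gb``/``Ib``/``gb`` are the basal (pre-drink)
    levels of each analyte.  Missing values are NaN, flagged per-analyte.
    """

    participant_id: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    glycerol: np.ndarray
    Gb: float
    Ib: float
    gb: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        for name in ("glucose", "insulin", "glycerol"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} not aligned with times")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"negative {name} values")
            object.__setattr__(self, name, arr)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("Gb", "Ib", "gb"):
            if not getattr(self, name) > 0:
                raise ValueError(f"basal field {name} must be positive")
        object.__setattr__(self, "times", t)

    @property
    def n_post_drink(self) -> int:
        return int(np.sum(self.times >= 0))

    def analyte(self, name: str) -> np.ndarray:
        return {"glucose": self.glucose, "insulin": self.insulin,
                "glycerol": self.glycerol}[name]


def find_glucose_nadir(times, glucose) -> float:
    """Time of the minimum glucose strictly after the post-drink maximum.

    The excursion peak is the (earliest) maximum over t >= 0, unless no
    post-drink sample exceeds the t = 0 value, in which case the peak is taken
    at t = 0 itself (flat/atypical excursion, warned).  Ties in the nadir break
    to the earliest sample.  Raises :class:`NoNadirError` when the peak falls on
    the final sample.
    """
    times = np.asarray(times, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    post = times >= 0
    if not np.any(post):
        raise ValueError("no samples at t >= 0")
    t_post = times[post]
    g_post = glucose[post]
    after_zero = t_post > 0
    if np.any(after_zero) and np.nanmax(g_post[after_zero]) > g_post[0]:
        i_peak = int(np.nanargmax(g_post))
    else:
        i_peak = 0
        warnings.warn(
            "glucose never rises above its t=0 value; excursion peak taken at t=0",
            stacklevel=2,
        )
    if i_peak == t_post.size - 1:
        raise NoNadirError("no nadir: glucose peaks at the final sample")
    tail = g_post[i_peak + 1:]
    i_nadir = i_peak + 1 + int(np.nanargmin(tail))  # argmin -> earliest tie
    return float(t_post[i_nadir])


def truncate_record(record: OGTTRecord, t_nadir: float) -> OGTTRecord:
    """Restrict the record to 0 <= t <= t_nadir; basal fields unchanged.

    Idempotent: re-truncating at the same time is the identity.
    """
    if t_nadir > record.times[-1]:
        raise ValueError("t_nadir beyond the last sample")
    keep = (record.times >= 0) & (record.times <= t_nadir)
    t_post = record.times[(record.times >= 0) & (record.times > 0)]
    if t_post.size and t_nadir < t_post[0]:
        raise ValueError("t_nadir before the first post-drink sample: empty fitting window")
    if np.sum(keep) < 2:
        raise ValueError("truncation leaves an empty fitting window")
    return replace(
        record,
        times=record.times[keep],
        glucose=record.glucose[keep],
        insulin=record.insulin[keep],
        glycerol=record.glycerol[keep],
    )
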