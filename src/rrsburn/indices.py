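"""Hemoglobin and Fluorescence Indices.

The Hemoglobin Index of a wound measurement is its summed hemoglobin signal
coefficients normalized by healthy skin of the same pig on the same day:

    HI_{x,y,z} = (a + b)_{x,y,z} / ( sum_4 (a + b)_{healthy,y,z} / 4 )

with the normalization factor the average of exactly four healthy-skin
measurements.  The Fluorescence Index is the same ratio with the
fluorescence magnitude c in place of (a + b).  Same-pig same-day
normalization cancels laser power, device and animal effects; healthy skin
averages to HI = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .unmixing import SignalCoefficients

__all__ = [
    "Measurement",
    "IndexValue",
    "hemoglobin_index",
    "fluorescence_index",
    "per_wound_index",
    "impute_pod7",
    "HEALTHY_SITES_REQUIRED",
]

HEALTHY_SITES_REQUIRED = 4


@dataclass
class Measurement:
    """One decomposed acquisition keyed by wound (or healthy), pig, day, site."""

    wound: int | str  # wound number, or "healthy"
    pig: int
    pod: int
    site: str
    coefficients: SignalCoefficients

    @property
    def is_healthy(self) -> bool:
        return self.wound == "healthy"


@dataclass
class IndexValue:
    """A normalized index (HI or FI) for one wound measurement."""

    wound: int | str
    pig: int
    pod: int
    kind: str  # "HI" | "FI"
    value: float
    flags: list = field(default_factory=list)


def _check_pairing(wound: Measurement, healthy: list[Measurement]) -> None:
    if len(healthy) != HEALTHY_SITES_REQUIRED:
        raise ValueError(
            f"normalization requires exactly {HEALTHY_SITES_REQUIRED} healthy "
            f"measurements, got {len(healthy)}"
        )
    for h in healthy:
        if h.pig != wound.pig or h.pod != wound.pod:
            raise ValueError(
                "healthy measurement pig/day "
                f"({h.pig}, POD {h.pod}) does not match wound "
                f"({wound.pig}, POD {wound.pod}); cross-pig or cross-day "
                "normalization is forbidden"
            )


def hemoglobin_index(wound: Measurement, healthy: list[Measurement]) -> IndexValue:
    """HI = (a+b)_wound / mean of (a+b) over 4 same-pig same-day healthy sites."""
    _check_pairing(wound, healthy)
    denom = float(np.mean([h.coefficients.hemoglobin_sum for h in healthy]))
    if denom <= 0:
        raise ValueError("healthy hemoglobin normalization factor is not positive")
    return IndexValue(
        wound.wound, wound.pig, wound.pod, "HI",
        wound.coefficients.hemoglobin_sum / denom,
    )


def fluorescence_index(wound: Measurement, healthy: list[Measurement]) -> IndexValue:
    """FI = c_wound / mean of c over 4 same-pig same-day healthy sites."""
    _check_pairing(wound, healthy)
    denom = float(np.mean([h.coefficients.c for h in healthy]))
    if denom <= 0:
        raise ValueError("healthy fluorescence normalization factor is not positive")
    return IndexValue(
        wound.wound, wound.pig, wound.pod, "FI", wound.coefficients.c / denom
    )


def per_wound_index(site_values: list[IndexValue]) -> IndexValue | None:
    """Average the (post-outlier) central-site values into one index per wound.

    Two sites normally survive outlier screening; a single survivor is
    averaged trivially and flagged.  No survivors -> the wound is missing
    for that day (returns None).
    """
    if len(site_values) == 0:
        return None
    if len(site_values) > 2:
        raise ValueError("at most 2 central-site values per wound per day")
    first = site_values[0]
    for v in site_values[1:]:
        if (v.wound, v.pig, v.pod, v.kind) != (first.wound, first.pig, first.pod, first.kind):
            raise ValueError("site values belong to different wound/pig/day/kind")
    flags = ["single-site"] if len(site_values) == 1 else []
    return IndexValue(
        first.wound, first.pig, first.pod, first.kind,
        float(np.mean([v.value for v in site_values])),
        flags=flags,
    )


def impute_pod7(series: dict[int, float]) -> dict[int, float]:
    """Fill a missing POD-7 category mean as the average of POD 3 and POD 14.

    Used only for heatmap aggregation (the study's device malfunctioned on
    POD 7), never for per-day inference.  Returns a new mapping with key 7
    added; both neighbors must be present.
    """
    if 7 in series:
        return dict(series)
    for pod in (3, 14):
        if pod not in series:
            raise ValueError(f"cannot impute POD 7: POD {pod} value missing")
    out = dict(series)
    out[7] = (series[3] + series[14]) / 2.0
    return out
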