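"""Cavalieri stereology and histological area-ratio comparisons.

Volumes are estimated from serial-section profile areas: with sections of
thickness ``t`` µm and every ``k``-th section sampled, the spacing between
sampled sections is ``t·k`` and the Cavalieri estimate is
``V = Σ areas × (t·k)`` (areas in mm², spacing converted to mm, volume in
mm³).  The area-ratio layer compares how a nucleus delineated molecularly
(spatial transcriptomics, ST), cytoarchitectonically (Nissl) and by
connectivity (retrograde tracing) relate within a treatment group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hypothesis_tests import (
    InsufficientDataError,
    TestResult,
    UndefinedStatisticError,
    t_two_sample,
)

__all__ = [
    "SectionSeries",
    "AreaTriplet",
    "cavalieri_volume",
    "compare_group_volumes",
    "ratio_tests",
]


@dataclass(frozen=True)
class SectionSeries:
    """Ordered profile areas (mm²) of one bird's sampled sections."""

    bird_id: str
    group: str
    areas: np.ndarray
    section_thickness: float = 20.0  # µm
    series_step: int = 5  # every k-th section sampled

    def __post_init__(self):
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1 or areas.size == 0:
            raise ValueError("areas must be a non-empty 1-D vector")
        if np.any(areas < 0) or not np.all(np.isfinite(areas)):
            raise ValueError("areas must be finite and non-negative")
        if not self.section_thickness > 0:
            raise ValueError("section thickness must be positive")
        if self.series_step < 1:
            raise ValueError("series step must be >= 1")
        object.__setattr__(self, "areas", areas)

    @property
    def spacing_mm(self) -> float:
        """Distance between consecutive sampled sections, in mm."""
        return self.section_thickness * self.series_step * 1e-3


@dataclass(frozen=True)
class AreaTriplet:
    """Per-bird areas of the same nucleus under three delineations (mm²)."""

    bird_id: str
    st_area: float
    nissl_area: float
    trace_area: float

    def __post_init__(self):
        for name in ("st_area", "nissl_area", "trace_area"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be finite and non-negative")
        if self.trace_area < self.nissl_area:
            warnings.warn(
                f"bird {self.bird_id}: retrogradely defined area smaller than "
                "Nissl-defined area — unusual delineation", stacklevel=2,
            )


def cavalieri_volume(series: SectionSeries) -> float:
    """Cavalieri volume estimate (mm³): cumulated area × section spacing."""
    if np.all(series.areas == 0):
        warnings.warn(
            f"bird {series.bird_id}: all section areas are zero (empty structure)",
            stacklevel=2,
        )
        return 0.0
    return float(series.areas.sum() * series.spacing_mm)


def compare_group_volumes(
    series_list: list[SectionSeries],
    group_a: str = "testosterone",
    group_b: str = "placebo",
) -> tuple[TestResult, dict]:
    """One-sided pooled t test of Cavalieri volumes, group_a > group_b.

    Returns the test result and per-group descriptive summaries
    (mean, SD, n, volumes).
    """
    volumes: dict[str, list[float]] = {group_a: [], group_b: []}
    for s in series_list:
        if s.group in volumes:
            volumes[s.group].append(cavalieri_volume(s))
    for g, vols in volumes.items():
        if len(vols) < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 birds")
    result = t_two_sample(
        np.array(volumes[group_a]), np.array(volumes[group_b]),
        direction="greater", name=f"volume_{group_a}_gt_{group_b}",
    )
    summary = {
        g: {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "n": len(v),
            "volumes_mm3": [float(x) for x in v],
        }
        for g, v in volumes.items()
    }
    return result, summary


def ratio_tests(triplets: list[AreaTriplet], group: str = "") -> list[TestResult]:
    """Compare ST/Nissl against ST/Trace area ratios within one group.

    Because the traced boundary encloses at least the Nissl boundary,
    ST/Nissl is expected to exceed ST/Trace; a one-sided pooled t
    (greater) is used on the two per-bird ratio sets, df = 2(n-1).
    Birds with a zero denominator are excluded with a warning.
    """
    st_nissl, st_trace = [], []
    for t in triplets:
        if t.nissl_area == 0 or t.trace_area == 0:
            warnings.warn(f"bird {t.bird_id}: zero denominator area, excluded", stacklevel=2)
            continue
        st_nissl.append(t.st_area / t.nissl_area)
        st_trace.append(t.st_area / t.trace_area)
    if len(st_nissl) < 2:
        raise InsufficientDataError("need at least 2 birds with valid ratios")
    label = f"_{group}" if group else ""
    name = f"st_nissl_vs_st_trace{label}"
    try:
        result = t_two_sample(
            np.array(st_nissl), np.array(st_trace), direction="greater", name=name
        )
    except UndefinedStatisticError:
        # identical delineations on every bird: no evidence either way
        n = len(st_nissl)
        result = TestResult(
            name=name, statistic=0.0, df=float(2 * (n - 1)), p_value=0.5,
            direction="greater",
        )
    return [result]
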