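"""Soma-size and bouton-density morphometry across song-development stages.

Records carry one measurement each (soma cross-sectional area in µm²,
bouton count per reconstructed axon branch, or branch length in µm) tagged
with bird, day post-implantation (DPI) and a structure label.  Stages are
DPI windows; the default windows follow the standard song-development
timeline: song onset DPI 1–10 and full song DPI 30–42 for bouton
measures, treatment start (DPI 0) vs full song DPI 28–42 for soma size.
Stage effects are tested with a two-way ANOVA using stage and bird as
crossed factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hypothesis_tests import InsufficientDataError, TestResult, two_way_anova

__all__ = [
    "MorphologyRecord",
    "SOMA_STAGE_WINDOWS",
    "BOUTON_STAGE_WINDOWS",
    "bouton_density",
    "stage_summary",
    "stage_change_test",
]

MEASURES = ("soma_area_um2", "bouton_count", "axon_length_um")

# (label, dpi_lo, dpi_hi); windows are half-open [lo, hi+1) on integer days
SOMA_STAGE_WINDOWS = [("treatment_start", 0, 0), ("full_song", 28, 42)]
BOUTON_STAGE_WINDOWS = [("song_onset", 1, 10), ("full_song", 30, 42)]


@dataclass(frozen=True)
class MorphologyRecord:
    bird_id: str
    dpi: int
    structure_id: str
    measure: str
    value: float

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        if self.value < 0 or not np.isfinite(self.value):
            raise ValueError("value must be finite and non-negative")
        if self.measure == "bouton_count" and self.value != int(self.value):
            raise ValueError("bouton_count must be integer-valued")


def bouton_density(records: Sequence[MorphologyRecord]) -> float:
    """Boutons per µm of axon for one branch/session.

    Expects exactly one ``bouton_count`` and one positive
    ``axon_length_um`` record.
    """
    counts = [r.value for r in records if r.measure == "bouton_count"]
    lengths = [r.value for r in records if r.measure == "axon_length_um"]
    if len(counts) != 1 or len(lengths) != 1:
        raise ValueError(
            f"need exactly one bouton_count and one axon_length_um record, "
            f"got {len(counts)} and {len(lengths)}"
        )
    if lengths[0] <= 0:
        raise ValueError("degenerate branch: zero axon length")
    return counts[0] / lengths[0]


def _stage_of(dpi: int, stage_windows) -> str | None:
    # boundary day belongs to the later (higher-DPI) window
    hit = None
    for label, lo, hi in stage_windows:
        if lo <= dpi < hi + 1:
            hit = label
    return hit


def stage_summary(
    records: Sequence[MorphologyRecord],
    stage_windows: Sequence[tuple[str, int, int]],
) -> dict[str, dict[str, dict]]:
    """Descriptive mean ± SD per stage and measure.

    Returns ``{stage: {measure: {mean, sd, n}}}``; stages whose window
    catches no record are omitted with a warning.
    """
    out: dict[str, dict[str, dict]] = {}
    for label, _, _ in stage_windows:
        staged = [r for r in records if _stage_of(r.dpi, stage_windows) == label]
        if not staged:
            warnings.warn(f"stage {label!r}: no records in window, omitted", stacklevel=2)
            continue
        by_measure: dict[str, dict] = {}
        for measure in MEASURES:
            vals = np.array([r.value for r in staged if r.measure == measure])
            if vals.size:
                by_measure[measure] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                }
        out[label] = by_measure
    return out


def stage_change_test(
    records: Sequence[MorphologyRecord],
    measure: str,
    stage_windows: Sequence[tuple[str, int, int]],
) -> TestResult:
    """Stage main effect on a measure, two-way ANOVA with stage and bird.

    For ``bouton_count`` the response is the per-branch density
    (boutons/µm) computed from the paired length record of the same
    bird, structure and DPI.
    """
    if measure == "bouton_count":
        values, stages, birds = [], [], []
        keys = {(r.bird_id, r.structure_id, r.dpi) for r in records}
        for key in sorted(keys):
            sub = [
                r for r in records
                if (r.bird_id, r.structure_id, r.dpi) == key
                and r.measure in ("bouton_count", "axon_length_um")
            ]
            stage = _stage_of(key[2], stage_windows)
            if stage is None or len(sub) < 2:
                continue
            values.append(bouton_density(sub))
            stages.append(stage)
            birds.append(key[0])
    else:
        staged = [
            (r, _stage_of(r.dpi, stage_windows))
            for r in records if r.measure == measure
        ]
        staged = [(r, s) for r, s in staged if s is not None]
        values = [r.value for r, _ in staged]
        stages = [s for _, s in staged]
        birds = [r.bird_id for r, _ in staged]
    if len(set(stages)) < 2 or len(set(birds)) < 2:
        raise InsufficientDataError("need at least 2 stages and 2 birds")
    results = two_way_anova(
        np.array(values), stages, birds, name_a="stage", name_b="bird"
    )
    return results[0]
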