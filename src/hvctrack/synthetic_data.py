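"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators mirror the three experimental read-outs:

* ``gen_tracks`` — longitudinal neuron coordinates: true positions are
  drawn once, uniformly in a 500 µm cube per bird, optionally scaled
  isotropically over time (a scheduled cumulative volume expansion), and
  observed through anisotropic zero-mean Gaussian localisation noise.
  The lateral noise default (0.5 µm) reflects a ~480 nm optical lateral
  resolution; the axial default (2.0 µm) reflects the ~2,000 nm axial
  resolution of 2-photon imaging.  Neurons drop out of sessions at
  random.
* ``gen_sections`` — serial-section area profiles whose Cavalieri
  integral equals a per-bird volume drawn from the group's normal law
  (defaults: treated 0.206 ± 0.028 mm³ n=6, control 0.110 ± 0.036 mm³
  n=4).
* ``gen_morphology`` — stable soma areas (normal, stage-independent)
  plus Poisson bouton counts whose underlying density ramps linearly
  over song development (0.1 → 0.2 boutons/µm).

Every generator is reproducible from its seed and returns a ground-truth
record alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .expansion_model import ExpansionSpec, PointCloud, expand_cloud
from .morphometry import MorphologyRecord
from .tracking_stats import TrackSet
from .volumetry import SectionSeries

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "gen_tracks",
    "gen_sections",
    "gen_morphology",
]


@dataclass(frozen=True)
class NoiseModel:
    """Anisotropic localisation noise: SD in µm, lateral (x, y) vs axial (z)."""

    sigma_xy: float = 0.5
    sigma_z: float = 2.0

    def __post_init__(self):
        if self.sigma_xy < 0 or self.sigma_z < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic longitudinal imaging cohort.

    ``neurons_per_bird`` may be a single count or a (lo, hi) inclusive
    range sampled per bird; the study's per-bird counts ranged from 44
    to 275.  ``true_expansion_schedule`` maps DPI to the *cumulative*
    percent volume expansion in effect at that session (unlisted DPIs
    inherit the last scheduled value; default: no expansion).
    """

    n_birds: int = 5
    neurons_per_bird: int | tuple[int, int] = (44, 275)
    dpis: tuple[int, ...] = (0, 8, 13, 18, 27, 33)
    true_expansion_schedule: tuple[tuple[int, float], ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    dropout_rate: float = 0.1
    side: float = 500.0
    session_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_birds < 1:
            raise ValueError("need at least 1 bird")
        if any(b <= a for a, b in zip(self.dpis, self.dpis[1:])):
            raise ValueError("dpis must be strictly increasing")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        unknown = [d for d, _ in self.true_expansion_schedule if d not in self.dpis]
        if unknown:
            raise ValueError(f"expansion schedule references unknown DPIs: {unknown}")

    def cumulative_p(self, dpi: int) -> float:
        p = 0.0
        for d, sched_p in sorted(self.true_expansion_schedule):
            if d <= dpi:
                p = sched_p
        return p


def gen_tracks(spec: CohortSpec) -> tuple[list[TrackSet], dict]:
    """Simulate a longitudinal imaging cohort.

    Returns the per-bird track sets and a ground-truth dict holding the
    noise-free positions and the expansion schedule, for parameter
    recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    tracksets = []
    truth: dict = {"seed": spec.seed, "schedule": list(spec.true_expansion_schedule), "birds": {}}
    for b in range(spec.n_birds):
        bird_id = f"B{b + 1:02d}"
        if isinstance(spec.neurons_per_bird, tuple):
            lo, hi = spec.neurons_per_bird
            n_neurons = int(rng.integers(lo, hi + 1))
        else:
            n_neurons = int(spec.neurons_per_bird)
        ids = tuple(f"n{i + 1:04d}" for i in range(n_neurons))
        base_xyz = rng.uniform(-spec.side / 2.0, spec.side / 2.0, size=(n_neurons, 3))
        base = PointCloud(ids=ids, xyz=base_xyz, side=spec.side)
        sessions = []
        for dpi in spec.dpis:
            p = spec.cumulative_p(dpi)
            cloud = base
            if p != 0.0:
                cloud = expand_cloud(
                    base, ExpansionSpec(p=p, center_mode="cube_center", allow_shrink=p < 0)
                )
            noise = np.column_stack([
                rng.normal(0.0, spec.noise.sigma_xy, n_neurons),
                rng.normal(0.0, spec.noise.sigma_xy, n_neurons),
                rng.normal(0.0, spec.noise.sigma_z, n_neurons),
            ])
            offset = (
                rng.normal(0.0, spec.session_jitter, 3)
                if spec.session_jitter > 0 else np.zeros(3)
            )
            observed = cloud.xyz + noise + offset
            keep = rng.random(n_neurons) >= spec.dropout_rate
            if keep.sum() < 2:  # a session must remain analysable
                keep[:2] = True
            sess_cloud = PointCloud(
                ids=tuple(i for i, k in zip(ids, keep) if k),
                xyz=observed[keep],
                side=cloud.side,
            )
            sessions.append((dpi, sess_cloud))
        tracksets.append(
            TrackSet(bird_id=bird_id, sessions=tuple(sessions), metadata={"n_neurons": n_neurons})
        )
        truth["birds"][bird_id] = {
            "n_neurons": n_neurons,
            "true_xyz": base_xyz.tolist(),
            "ids": list(ids),
        }
    return tracksets, truth


def _area_profile(n_sections: int) -> np.ndarray:
    """Smooth unimodal (parabolic) profile of unit integral weight."""
    x = (np.arange(n_sections) + 0.5) / n_sections
    prof = x * (1.0 - x)
    return prof / prof.sum()


def gen_sections(
    group_means: dict[str, float] | None = None,
    group_sds: dict[str, float] | None = None,
    ns: dict[str, int] | None = None,
    n_sections: int = 10,
    thickness: float = 20.0,
    step: int = 5,
    seed: int = 0,
) -> tuple[list[SectionSeries], dict]:
    """Simulate serial-section area series for a two-group volumetry study.

    Each bird's target volume is drawn from its group's normal law
    (negative draws are redrawn with a warning) and spread over a smooth
    unimodal profile that integrates exactly to the target under the
    Cavalieri estimator.
    """
    group_means = group_means or {"testosterone": 0.206, "placebo": 0.110}
    group_sds = group_sds or {"testosterone": 0.028, "placebo": 0.036}
    ns = ns or {"testosterone": 6, "placebo": 4}
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group mean volumes must be positive")
    rng = np.random.default_rng(seed)
    spacing_mm = thickness * step * 1e-3
    out, truth = [], {"seed": seed, "birds": {}}
    idx = 0
    for group in group_means:
        for _ in range(ns[group]):
            idx += 1
            bird_id = f"V{idx:02d}"
            vol = rng.normal(group_means[group], group_sds[group])
            while vol <= 0:
                warnings.warn(
                    f"bird {bird_id}: non-positive volume draw, redrawing", stacklevel=2
                )
                vol = rng.normal(group_means[group], group_sds[group])
            areas = _area_profile(n_sections) * vol / spacing_mm
            out.append(
                SectionSeries(
                    bird_id=bird_id, group=group, areas=areas,
                    section_thickness=thickness, series_step=step,
                )
            )
            truth["birds"][bird_id] = {"group": group, "true_volume_mm3": float(vol)}
    return out, truth


def gen_morphology(
    soma_mean: float = 13.4,
    soma_sd: float = 2.0,
    density_start: float = 0.1,
    density_end: float = 0.2,
    dpis: tuple[int, ...] = (0, 5, 10, 20, 30, 42),
    n_cells: int = 120,
    n_branches: int = 16,
    n_birds: int = 5,
    branch_length: float = 100.0,
    seed: int = 0,
) -> tuple[list[MorphologyRecord], dict]:
    """Simulate soma-area and bouton morphology trajectories.

    Soma areas are i.i.d. normal and stage-independent (truncated at
    zero); bouton counts are Poisson with rate = density(dpi) × branch
    length, the density ramping linearly from ``density_start`` at the
    first DPI to ``density_end`` at the last.
    """
    if min(soma_mean, density_start, density_end, branch_length) <= 0 or soma_sd < 0:
        raise ValueError("morphology parameters must be positive (soma_sd >= 0)")
    rng = np.random.default_rng(seed)
    records: list[MorphologyRecord] = []
    span = max(dpis) - min(dpis)
    for b in range(n_birds):
        bird_id = f"M{b + 1:02d}"
        for c in range(n_cells // n_birds):
            cell_id = f"soma{c + 1:03d}"
            for dpi in dpis:
                area = max(0.0, rng.normal(soma_mean, soma_sd))
                records.append(
                    MorphologyRecord(bird_id, dpi, cell_id, "soma_area_um2", area)
                )
    branch_birds = [f"M{(i % min(n_birds, 3)) + 1:02d}" for i in range(n_branches)]
    for i, bird_id in enumerate(branch_birds):
        branch_id = f"branch{i + 1:03d}"
        for dpi in dpis:
            frac = (dpi - min(dpis)) / span if span else 0.0
            density = density_start + (density_end - density_start) * frac
            count = int(rng.poisson(density * branch_length))
            records.append(
                MorphologyRecord(bird_id, dpi, branch_id, "bouton_count", float(count))
            )
            records.append(
                MorphologyRecord(bird_id, dpi, branch_id, "axon_length_um", branch_length)
            )
    truth = {
        "seed": seed,
        "soma_mean": soma_mean, "soma_sd": soma_sd,
        "density_start": density_start, "density_end": density_end,
        "branch_length": branch_length, "dpis": list(dpis),
    }
    return records, truth
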