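"""Geometric null model of isotropic nucleus expansion.

The song-control nucleus is idealised as a cube of side ``L0`` (default
500 µm, i.e. a volume of 0.125 mm³) containing labelled neurons at fixed
positions.  A volume expansion of ``p`` percent is modelled as uniform
linear scaling of every coordinate by ``s = (1 + p/100)**(1/3)`` about a
chosen center.  The model makes two testable predictions for a cloud of
cells riding along with the tissue:

* every cell is displaced by ``(s - 1) * r`` where ``r`` is its distance
  from the scaling center (the *per-point displacement* statistic), and
* every pairwise inter-cell distance grows by the factor ``s``
  (the *pairwise delta* statistic), independent of the center.

Both statistics have closed forms for uniformly distributed points, which
serve as analytic oracles for the Monte Carlo simulation and for the
observed-data comparisons in :mod:`hvctrack.tracking_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "PointCloud",
    "ExpansionSpec",
    "DistanceDeltaSet",
    "DisplacementSummary",
    "UNIT_CUBE_MEAN_RADIUS",
    "UNIT_CUBE_SD_RADIUS",
    "ROBBINS_CONSTANT",
    "scale_factor",
    "cube_volume_mm3",
    "expand_cloud",
    "per_point_displacements",
    "pairwise_delta",
    "simulate_expansion",
    "closed_form_displacement",
    "closed_form_pairwise_delta",
    "estimate_expansion",
]

# E[||U||] and SD[||U||] for U uniform on the unit cube centered at the
# origin; obtained by adaptive quadrature (abs. error < 1e-12).  The SD
# follows from E[||U||^2] = 1/4 exactly.
UNIT_CUBE_MEAN_RADIUS = 0.4802959782275265
UNIT_CUBE_SD_RADIUS = 0.13898119764365024

# Mean distance between two independent uniform points in the unit cube
# (Robbins constant, known in closed form).
ROBBINS_CONSTANT = 0.6617071822671762

CenterMode = Literal["cube_center", "origin_corner", "centroid"]
_CENTER_MODES = ("cube_center", "origin_corner", "centroid")


class DomainError(ValueError):
    """Parameter outside the model's domain (e.g. expansion below -100%)."""


class PairingError(ValueError):
    """Point clouds cannot be matched label-by-label."""


@dataclass(frozen=True)
class PointCloud:
    """Labelled 3-D cell coordinates (µm) inside a nominal bounding cube.

    Parameters
    ----------
    ids
        Unique, hashable point labels; order defines the canonical order
        of all derived vectors.
    xyz
        ``(n, 3)`` float array of coordinates in µm.
    side
        Nominal side length of the bounding cube (µm).
    center
        Coordinates of the cube center (µm).
    """

    ids: tuple
    xyz: np.ndarray
    side: float = 500.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (n, 3), got {xyz.shape}")
        if xyz.shape[0] != len(self.ids):
            raise ValueError("ids and xyz length mismatch")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("point ids must be unique")
        if not self.side > 0:
            raise ValueError("cube side must be positive")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "xyz", xyz)

    def __len__(self) -> int:
        return len(self.ids)

    def sorted_by_id(self) -> "PointCloud":
        order = np.argsort(np.asarray(self.ids, dtype=object))
        return replace(self, ids=tuple(self.ids[i] for i in order), xyz=self.xyz[order])

    def subset(self, keep_ids: Sequence) -> "PointCloud":
        index = {pid: i for i, pid in enumerate(self.ids)}
        rows = [index[pid] for pid in keep_ids]
        return replace(self, ids=tuple(keep_ids), xyz=self.xyz[rows])


@dataclass(frozen=True)
class ExpansionSpec:
    """Volume expansion by ``p`` percent applied as uniform linear scaling.

    ``allow_shrink`` must be set explicitly to model negative ``p``
    (tissue shrinkage); ``p <= -100`` is rejected in any case because it
    implies non-positive volume.
    """

    p: float
    center_mode: CenterMode = "cube_center"
    allow_shrink: bool = False

    def __post_init__(self):
        if self.center_mode not in _CENTER_MODES:
            raise ValueError(
                f"unknown center_mode {self.center_mode!r}; expected one of {_CENTER_MODES}"
            )
        if self.p <= -100:
            raise DomainError(f"expansion p={self.p} implies non-positive volume")
        if self.p < 0 and not self.allow_shrink:
            raise DomainError("negative expansion requires allow_shrink=True")

    @property
    def scale(self) -> float:
        return scale_factor(self.p)


@dataclass(frozen=True)
class DistanceDeltaSet:
    """Element-wise change of matched pairwise distances (µm), D' - D0."""

    deltas: np.ndarray
    label_a: str = "a"
    label_b: str = "b"
    baseline: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self):
        deltas = np.asarray(self.deltas, dtype=float)
        if not np.all(np.isfinite(deltas)):
            raise ValueError("non-finite deltas")
        object.__setattr__(self, "deltas", deltas)
        if self.baseline is not None:
            base = np.asarray(self.baseline, dtype=float)
            if base.shape != deltas.shape:
                raise ValueError("baseline/deltas shape mismatch")
            object.__setattr__(self, "baseline", base)

    @property
    def n_pairs(self) -> int:
        return self.deltas.size

    def mean(self) -> float:
        return float(np.mean(self.deltas))

    def sd(self) -> float:
        return float(np.std(self.deltas, ddof=1)) if self.n_pairs > 1 else 0.0


@dataclass(frozen=True)
class DisplacementSummary:
    """Mean ± SD of a displacement-type statistic over n values."""

    mean: float
    sd: float
    n: int
    statistic_kind: Literal["per_point_displacement", "pairwise_delta"]

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def scale_factor(p: float) -> float:
    """Linear scale factor for a ``p`` percent volume change.

    ``s = (1 + p/100)**(1/3)``; strictly increasing in ``p``.
    """
    if p <= -100:
        raise DomainError(f"p={p} implies non-positive volume")
    return float(np.cbrt(1.0 + p / 100.0))


def cube_volume_mm3(side_um: float) -> float:
    """Volume (mm³) of a cube of side ``side_um`` µm.  500 µm ⇔ 0.125 mm³."""
    if not side_um > 0:
        raise ValueError("side must be positive")
    return (side_um * 1e-3) ** 3


def _resolve_center(cloud: PointCloud, mode: CenterMode) -> np.ndarray:
    center = np.asarray(cloud.center, dtype=float)
    if mode == "cube_center":
        return center
    if mode == "origin_corner":
        return center - cloud.side / 2.0
    if mode == "centroid":
        return cloud.xyz.mean(axis=0)
    raise ValueError(f"unknown center_mode {mode!r}")


def expand_cloud(cloud: PointCloud, spec: ExpansionSpec) -> PointCloud:
    """Scale every point about the configured center by ``spec.scale``.

    Point labels are preserved; the nominal cube side is scaled along so
    the cloud stays inside its (expanded) bounding cube.
    """
    c = _resolve_center(cloud, spec.center_mode)
    s = spec.scale
    new_xyz = c + s * (cloud.xyz - c)
    return replace(cloud, xyz=new_xyz, side=cloud.side * s)


def _match(before: PointCloud, after: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    if set(before.ids) != set(after.ids):
        only_a = sorted(set(before.ids) - set(after.ids), key=str)
        only_b = sorted(set(after.ids) - set(before.ids), key=str)
        raise PairingError(
            f"point id mismatch: only in before={only_a}, only in after={only_b}"
        )
    order = sorted(before.ids, key=str)
    return before.subset(order).xyz, after.subset(order).xyz


def per_point_displacements(before: PointCloud, after: PointCloud) -> np.ndarray:
    """Euclidean displacement (µm) per matched point, ordered by point id.

    This is the center-*dependent* statistic: under uniform scaling the
    displacement of a point equals ``(s - 1)`` times its distance from
    the scaling center.
    """
    a, b = _match(before, after)
    return np.linalg.norm(b - a, axis=1)


def pairwise_delta(before: PointCloud, after: PointCloud) -> DistanceDeltaSet:
    """Change in every pairwise distance, D' - D0, ordered canonically.

    Pairwise distances are invariant to the scaling center, so under pure
    uniform scaling every delta equals ``(s - 1) * D0`` regardless of
    where the expansion is anchored.
    """
    a, b = _match(before, after)
    if a.shape[0] < 2:
        raise PairingError("need at least 2 matched points for pairwise deltas")
    d0 = pdist(a)
    d1 = pdist(b)
    return DistanceDeltaSet(deltas=d1 - d0, label_a="before", label_b="after", baseline=d0)


def simulate_expansion(
    p: float,
    n_points: int = 100,
    side: float = 500.0,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    center_mode: CenterMode = "cube_center",
    allow_shrink: bool = False,
) -> dict[str, DisplacementSummary]:
    """Monte Carlo simulation of the expansion model.

    Each replicate draws ``n_points`` uniform points in a cube of side
    ``side`` centered at the origin, applies the expansion, and records
    per-point displacements and pairwise distance deltas.  Values are
    pooled across replicates.

    Returns a dict with keys ``"per_point_displacement"`` and
    ``"pairwise_delta"``, each a :class:`DisplacementSummary`.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not side > 0:
        raise ValueError("side must be positive")
    spec = ExpansionSpec(p=p, center_mode=center_mode, allow_shrink=allow_shrink)
    rng = np.random.default_rng(seed)

    disp_chunks = []
    delta_chunks = []
    for _ in range(n_reps):
        xyz = rng.uniform(-side / 2.0, side / 2.0, size=(n_points, 3))
        cloud = PointCloud(ids=tuple(range(n_points)), xyz=xyz, side=side)
        expanded = expand_cloud(cloud, spec)
        disp_chunks.append(per_point_displacements(cloud, expanded))
        delta_chunks.append(pairwise_delta(cloud, expanded).deltas)

    disp = np.concatenate(disp_chunks)
    delta = np.concatenate(delta_chunks)
    return {
        "per_point_displacement": DisplacementSummary(
            mean=float(disp.mean()),
            sd=float(disp.std(ddof=1)) if disp.size > 1 else 0.0,
            n=disp.size,
            statistic_kind="per_point_displacement",
        ),
        "pairwise_delta": DisplacementSummary(
            mean=float(delta.mean()),
            sd=float(delta.std(ddof=1)) if delta.size > 1 else 0.0,
            n=delta.size,
            statistic_kind="pairwise_delta",
        ),
    }


def closed_form_displacement(p: float, side: float = 500.0) -> tuple[float, float]:
    """Analytic mean and SD (µm) of per-point displacement under expansion.

    For points uniform in a cube scaled about its center, the displacement
    is ``(s - 1) * ||U|| * side`` with ``U`` uniform on the unit cube, so
    mean and SD scale the unit-cube radius moments.
    """
    if not side > 0:
        raise ValueError("side must be positive")
    excess = scale_factor(p) - 1.0
    return (
        abs(excess) * UNIT_CUBE_MEAN_RADIUS * side,
        abs(excess) * UNIT_CUBE_SD_RADIUS * side,
    )


def closed_form_pairwise_delta(p: float, side: float = 500.0) -> float:
    """Analytic mean pairwise-distance change (µm): (s-1) · R · side.

    ``R`` is the mean distance between two uniform points in the unit cube
    (Robbins constant ≈ 0.6617).
    """
    if not side > 0:
        raise ValueError("side must be positive")
    return (scale_factor(p) - 1.0) * ROBBINS_CONSTANT * side


def estimate_expansion(
    deltas: DistanceDeltaSet | np.ndarray, baseline_distances: np.ndarray | None = None
) -> float:
    """Invert the scaling law: infer the percent volume change from data.

    Under uniform scaling ``mean(D') / mean(D0) = s``, so
    ``p̂ = (ŝ³ − 1) · 100`` with ``ŝ = 1 + mean(deltas)/mean(D0)``.
    """
    if isinstance(deltas, DistanceDeltaSet):
        if baseline_distances is None:
            baseline_distances = deltas.baseline
        deltas = deltas.deltas
    deltas = np.asarray(deltas, dtype=float)
    if baseline_distances is None:
        raise ValueError("baseline distances required")
    base = np.asarray(baseline_distances, dtype=float)
    if deltas.size == 0 or base.size != deltas.size:
        raise ValueError("deltas and baseline must be non-empty and matched")
    mean_base = base.mean()
    if mean_base == 0:
        raise DomainError("degenerate geometry: mean baseline distance is zero")
    s_hat = 1.0 + deltas.mean() / mean_base
    return float((s_hat**3 - 1.0) * 100.0)
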