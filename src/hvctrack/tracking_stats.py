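"""Longitudinal statistics on tracked neuron positions.

Given repeated imaging sessions of the same labelled neurons (indexed by
days post-implantation, DPI), this module quantifies whether the cell
constellation is expanding: pairwise inter-cell distances per session,
their change between sessions, per-day-pair shift summaries, and an OLS
trend of mean shift against time.  Neurons are matched across sessions
by their label; pairs are formed only from neurons present in both
sessions of a comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .expansion_model import DistanceDeltaSet, PointCloud, scale_factor
from .hypothesis_tests import TestResult

__all__ = [
    "TrackSet",
    "ShiftSummary",
    "TrendFit",
    "pairwise_distances",
    "session_distance_changes",
    "shift_summary_per_day",
    "pooled_summary",
    "trend_regression",
    "matched_model_test",
]


class InsufficientOverlapError(ValueError):
    pass


@dataclass(frozen=True)
class TrackSet:
    """All imaging sessions of one bird: ordered (dpi, cloud) pairs."""

    bird_id: str
    sessions: tuple[tuple[int, PointCloud], ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        dpis = [d for d, _ in self.sessions]
        if any(b <= a for a, b in zip(dpis, dpis[1:])):
            raise ValueError(f"DPIs must be strictly increasing, got {dpis}")
        object.__setattr__(self, "sessions", tuple(self.sessions))

    @property
    def dpis(self) -> list[int]:
        return [d for d, _ in self.sessions]

    def cloud(self, dpi: int) -> PointCloud:
        for d, c in self.sessions:
            if d == dpi:
                return c
        raise KeyError(f"bird {self.bird_id}: no session at DPI {dpi}")


@dataclass(frozen=True)
class ShiftSummary:
    bird_id: str
    day_pair: tuple[int, int]
    mean: float
    sd: float
    n_pairs: int

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"R² {self.r_squared} outside [0, 1]")


def pairwise_distances(cloud: PointCloud) -> np.ndarray:
    """All k(k-1)/2 Euclidean distances, in lexicographic id-pair order."""
    if len(cloud) < 2:
        raise InsufficientOverlapError("need at least 2 points")
    return pdist(cloud.sorted_by_id().xyz)


def session_distance_changes(tracks: TrackSet, dpi_a: int, dpi_b: int) -> DistanceDeltaSet:
    """Pairwise-distance deltas between two sessions of one bird.

    Only neurons present in *both* sessions contribute; the number of
    neurons seen in exactly one session is reported as ``n_dropped``.
    """
    cloud_a = tracks.cloud(dpi_a)
    cloud_b = tracks.cloud(dpi_b)
    common = sorted(set(cloud_a.ids) & set(cloud_b.ids), key=str)
    n_dropped = len(set(cloud_a.ids) ^ set(cloud_b.ids))
    if len(common) < 2:
        raise InsufficientOverlapError(
            f"bird {tracks.bird_id}: only {len(common)} neurons shared between "
            f"DPI {dpi_a} and DPI {dpi_b}"
        )
    d0 = pdist(cloud_a.subset(common).xyz)
    d1 = pdist(cloud_b.subset(common).xyz)
    return DistanceDeltaSet(
        deltas=d1 - d0,
        label_a=f"dpi{dpi_a}",
        label_b=f"dpi{dpi_b}",
        baseline=d0,
        n_dropped=n_dropped,
    )


def shift_summary_per_day(
    tracks: TrackSet, reference: str = "consecutive"
) -> list[ShiftSummary]:
    """Mean ± SD of distance deltas for each session pair of one bird.

    ``reference='consecutive'`` compares each session with the previous
    one (the day-to-day shift); ``reference='baseline'`` compares every
    later session against the first (cumulative shift).
    """
    dpis = tracks.dpis
    if len(dpis) < 2:
        raise InsufficientOverlapError("need at least 2 sessions")
    if reference == "consecutive":
        day_pairs = list(zip(dpis, dpis[1:]))
    elif reference == "baseline":
        day_pairs = [(dpis[0], d) for d in dpis[1:]]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    out = []
    for a, b in day_pairs:
        dd = session_distance_changes(tracks, a, b)
        out.append(
            ShiftSummary(
                bird_id=tracks.bird_id, day_pair=(a, b),
                mean=dd.mean(), sd=dd.sd(), n_pairs=dd.n_pairs,
            )
        )
    return out


def pooled_summary(summaries: list[ShiftSummary]) -> ShiftSummary:
    """Descriptive pool of per-day summaries, weighted by pair counts.

    Birds are analysed separately for testing; the pooled value is the
    overall mean shift one would quote descriptively across a cohort.
    """
    if not summaries:
        raise InsufficientOverlapError("no summaries to pool")
    ns = np.array([s.n_pairs for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_total = ns.sum()
    grand = float(np.sum(ns * means) / n_total)
    # pooled variance: within-summary + between-summary spread
    if n_total > 1:
        ss = np.sum((ns - 1) * sds**2) + np.sum(ns * (means - grand) ** 2)
        sd = float(np.sqrt(ss / (n_total - 1)))
    else:
        sd = 0.0
    return ShiftSummary(
        bird_id="pooled", day_pair=(summaries[0].day_pair[0], summaries[-1].day_pair[1]),
        mean=grand, sd=sd, n_pairs=int(n_total),
    )


def matched_model_test(deltas: DistanceDeltaSet, p: float) -> TestResult:
    """Test observed distance changes against a ``p``-percent expansion.

    The model predicts that every baseline pairwise distance grows by
    ``(s - 1)·D0``, so the pair-matched residuals (observed delta minus
    predicted delta) should be centered on zero if the model holds.
    Pairwise residuals sharing a neuron are correlated, which makes the
    naive per-pair t badly anticonservative; the standard error of the
    mean residual is therefore estimated by a leave-one-neuron-out
    jackknife, with df = k - 1 for k neurons.  A positive statistic
    means the constellation changed more than the model predicts.
    """
    resid = deltas.deltas - (scale_factor(p) - 1.0) * (
        deltas.baseline if deltas.baseline is not None else 0.0
    )
    if deltas.baseline is None and p != 0.0:
        raise ValueError("baseline distances required to test a nonzero model")
    n_pairs = resid.size
    k = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    if k * (k - 1) // 2 != n_pairs:
        raise ValueError(f"{n_pairs} residuals is not a complete pair set")
    name = f"matched_vs_{p:g}pct_model"
    # exact model match up to floating point: declare a perfect fit
    ref_scale = float(np.max(np.abs(deltas.baseline))) if deltas.baseline is not None else 1.0
    if np.max(np.abs(resid)) <= 1e-9 * max(1.0, ref_scale):
        return TestResult(name=name, statistic=0.0, df=float(k - 1), p_value=1.0)
    mean = resid.mean()
    per_neuron_sums = squareform(resid).sum(axis=1)
    # leave-one-neuron-out means of the remaining (k-1)(k-2)/2 residuals
    loo = (resid.sum() - per_neuron_sums) / (n_pairs - (k - 1))
    jk_var = (k - 1) / k * np.sum((loo - loo.mean()) ** 2)
    if jk_var == 0.0:
        t_stat = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p_value = 1.0 if t_stat == 0.0 else 0.0
    else:
        t_stat = float(mean / np.sqrt(jk_var))
        p_value = float(2.0 * stats.t.sf(abs(t_stat), k - 1))
    return TestResult(name=name, statistic=t_stat, df=float(k - 1), p_value=p_value)


def trend_regression(summaries: list[ShiftSummary]) -> TrendFit:
    """OLS of per-day-pair mean shift against the (later) session DPI.

    R² of a zero-variance response is 0 by convention (no variance to
    explain).
    """
    if len(summaries) < 3:
        raise InsufficientOverlapError("need at least 3 day points for a trend")
    x = np.array([s.day_pair[1] for s in summaries], dtype=float)
    y = np.array([s.mean for s in summaries], dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.sum(xc**2))
    syy = float(np.sum(yc**2))
    if sxx == 0:
        raise ValueError("all day points identical: slope undefined")
    slope = float(np.sum(xc * yc) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    r2 = 0.0 if syy == 0 else float(min(1.0, slope**2 * sxx / syy))
    return TrendFit(slope=slope, intercept=intercept, r_squared=r2)
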