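"""Model (in)validation by distance of observations from reachable moments.

A candidate stochastic model is confronted with single-cell (or
single-replicate) measurements of one observable species.  For each
measurement y at time t the reachable interval of the species *mean*
[lower(t), upper(t)] is taken from the model's reach sequence, and the
normalized distance is

    d = max(0, lower(t) - y, y - upper(t)) / sqrt(max reachable variance at t)

— zero for any observation inside the reachable mean band, otherwise the
gap in units of the largest standard deviation the model can reach at
that time.  Models whose observations sit many reachable standard
deviations outside their band are unlikely to have generated the data;
the statistic deliberately stops short of a formal test and is reported
per time point (mean and maximum over replicates) for qualitative
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reach_linear import ReachSequence

__all__ = ["Observation", "ValidationScore", "distance_score", "rank_models"]


@dataclass(frozen=True)
class Observation:
    """One measured value of one species at one time."""

    time: float
    species: str
    value: float
    replicate: int = 0


@dataclass
class ValidationScore:
    """Normalized distances of a set of observations from one model."""

    model: str
    species: str
    per_observation: pd.DataFrame  # time, replicate, value, distance
    per_time: pd.DataFrame  # time, mean_distance, max_distance

    @property
    def mean_distance(self) -> float:
        return float(self.per_observation["distance"].mean())

    @property
    def max_distance(self) -> float:
        return float(self.per_observation["distance"].max())


def _bounds_at(seq: ReachSequence, name: str, t: float) -> tuple[float, float]:
    """Interval-hull bounds of one coordinate at time t.

    Times within half a grid step of a grid point snap to it; otherwise
    the bounds of the two neighbouring grid points are linearly
    interpolated (conservatively valid for the reported hulls only).
    """
    times = seq.times
    k = int(np.argmin(np.abs(times - t)))
    gaps = np.diff(times)
    local_gap = 0.0
    if gaps.size:
        adjacent = gaps[max(0, k - 1): k + 1]
        local_gap = float(adjacent.min())
    i = seq.state_index(name)
    if local_gap == 0.0 or abs(times[k] - t) <= local_gap / 2 + 1e-12:
        lo, hi = seq.sets[k].interval_hull()
        return float(lo[i]), float(hi[i])
    if t < times[0] or t > times[-1]:
        raise ValueError(f"observation time {t} outside the reach horizon")
    k0 = int(np.searchsorted(times, t)) - 1
    w = (t - times[k0]) / (times[k0 + 1] - times[k0])
    lo0, hi0 = seq.sets[k0].interval_hull()
    lo1, hi1 = seq.sets[k0 + 1].interval_hull()
    return (
        float((1 - w) * lo0[i] + w * lo1[i]),
        float((1 - w) * hi0[i] + w * hi1[i]),
    )


def distance_score(
    seq: ReachSequence,
    observations: list[Observation],
    species: str,
    model: str = "",
) -> ValidationScore:
    """Score observations of one species against a reach sequence.

    Requires both the mean and the variance coordinate of the species in
    the sequence; raises if the maximal reachable variance at an
    observation time is not positive (the normalization is undefined).
    """
    mean_name = f"mean_{species}"
    var_name = f"var_{species}"
    if mean_name not in seq.state_names or var_name not in seq.state_names:
        raise ValueError(
            f"sequence lacks mean/variance coordinates for species {species!r}"
        )
    rows = []
    for obs in observations:
        if obs.species != species:
            continue
        lo, hi = _bounds_at(seq, mean_name, obs.time)
        _, var_hi = _bounds_at(seq, var_name, obs.time)
        if var_hi <= 0:
            raise ValueError(
                f"nonpositive maximal reachable variance at t={obs.time}"
            )
        gap = max(0.0, lo - obs.value, obs.value - hi)
        rows.append(
            (obs.time, obs.replicate, obs.value, gap / np.sqrt(var_hi))
        )
    per_obs = pd.DataFrame(
        rows, columns=["time", "replicate", "value", "distance"]
    )
    per_time = (
        per_obs.groupby("time")["distance"]
        .agg(mean_distance="mean", max_distance="max")
        .reset_index()
    )
    return ValidationScore(model, species, per_obs, per_time)


def rank_models(
    model_sequences: dict[str, ReachSequence],
    observations: list[Observation],
    species: str,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score several candidate models against the same observations.

    Returns one row per model, ordered by mean normalized distance
    (best-fitting first).  With ``threshold``, models whose maximum
    distance exceeds it at any time are marked unlikely; absent a
    threshold the ranking is purely qualitative, as the distances
    themselves are the result.
    """
    if len(model_sequences) < 2:
        raise ValueError("need at least 2 candidate models to rank")
    rows = []
    for name, seq in model_sequences.items():
        score = distance_score(seq, observations, species, model=name)
        row = {
            "model": name,
            "mean_distance": score.mean_distance,
            "max_distance": score.max_distance,
        }
        if threshold is not None:
            row["unlikely"] = bool(score.max_distance > threshold)
        rows.append((row, score))
    df = pd.DataFrame([r for r, _ in rows]).sort_values(
        "mean_distance", kind="stable", ignore_index=True
    )
    df.attrs["scores"] = {s.model: s for _, s in rows}
    return df
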