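"""Multi-run aggregation: stage/substitution summaries, Welch tests and
contact-frequency maps.

The replication unit is the MD run, not the frame — frames within a run are
strongly autocorrelated, so run-level means are computed first and group
means, standard errors and t-tests operate on those.  Contact frequencies
are pooled frame-weighted across runs (the per-run-average alternative is
available behind a flag), and displayed with inclusive/exclusive category
boundaries: strong for f ≥ 0.10, weak for 0.025 < f < 0.10, none otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RunAggregate",
    "GroupSummary",
    "TTestResult",
    "ContactFrequencyMap",
    "ReplicationError",
    "aggregate_runs",
    "compare_groups",
    "contact_map",
    "categorize_frequency",
    "STRONG_THRESHOLD",
    "WEAK_THRESHOLD",
]

STRONG_THRESHOLD = 0.10   # inclusive
WEAK_THRESHOLD = 0.025    # strict lower bound of "weak"


class ReplicationError(ValueError):
    pass


@dataclass(frozen=True)
class RunAggregate:
    run_id: str
    label: str
    mean: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ReplicationError(f"run {self.run_id} has no frames")
        if not np.isfinite(self.mean):
            raise ReplicationError(f"run {self.run_id} mean is not finite")


@dataclass(frozen=True)
class GroupSummary:
    """Mean of run means with its standard error (SD of run means / √n)."""

    label: str
    n_runs: int
    mean: float
    se: float
    run_means: tuple[float, ...]
    single_run: bool = False


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    stars: str  # "**" p<0.01, "*" p<0.05, "" otherwise


def _run_mean(values) -> tuple[float, int]:
    arr = np.asarray(getattr(values, "values", values), dtype=float)
    if arr.size == 0:
        raise ReplicationError("run has no frames")
    return float(np.nanmean(arr)), int(arr.size)


def aggregate_runs(series_per_run: Mapping[str, Sequence[float]],
                   grouping: Mapping[str, str]) -> list[GroupSummary]:
    """Aggregate per-run frame series into per-group summaries.

    Run-level means are computed first; the group mean and standard error
    are taken over runs.  A single-run group reports SE 0 with a flag.
    Groups appear in first-seen order of ``grouping``.
    """
    runs: dict[str, list[float]] = {}
    for run_id, label in grouping.items():
        if run_id not in series_per_run:
            raise ReplicationError(f"no series for run {run_id!r}")
        mean, _ = _run_mean(series_per_run[run_id])
        runs.setdefault(label, []).append(mean)
    if not runs:
        raise ReplicationError("empty grouping")
    out = []
    for label, means in runs.items():
        arr = np.asarray(means)
        single = arr.size == 1
        se = 0.0 if single else float(np.std(arr, ddof=1) / np.sqrt(arr.size))
        out.append(GroupSummary(label, arr.size, float(arr.mean()), se,
                                tuple(float(m) for m in means), single))
    return out


def compare_groups(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided Welch t-test on run-level means.

    Welch (unequal variance) is used rather than the pooled test.  Exactly
    identical degenerate groups (zero variance, equal means) return
    statistic 0, p = 1.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ReplicationError(
            "need >= 2 run-level means on each side for a t-test")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if xa.mean() == xb.mean():
            stat, p, df = 0.0, 1.0, float(xa.size + xb.size - 2)
        else:
            stat = np.inf if xa.mean() > xb.mean() else -np.inf
            p, df = 0.0, float(xa.size + xb.size - 2)
    else:
        res = sps.ttest_ind(xa, xb, equal_var=False)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return TTestResult(stat, df, p, stars)


def categorize_frequency(f: float) -> str:
    """Display category for a contact frequency.

    ``strong`` for f ≥ 0.10 (boundary inclusive), ``weak`` for
    0.025 < f < 0.10 (strict lower bound), ``none`` otherwise.
    """
    if f >= STRONG_THRESHOLD:
        return "strong"
    if WEAK_THRESHOLD < f < STRONG_THRESHOLD:
        return "weak"
    return "none"


@dataclass
class ContactFrequencyMap:
    """Residue-pair contact frequencies with display categories."""

    frequencies: dict[Hashable, float]
    categories: dict[Hashable, str] = field(default_factory=dict)
    n_frames: int = 0
    pooling: str = "frames"

    def __post_init__(self) -> None:
        for pair, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {pair} outside [0, 1]")
            self.categories.setdefault(pair, categorize_frequency(f))


def contact_map(runs: Sequence[Mapping[Hashable, Sequence[float]]],
                pair_universe: Sequence[Hashable] | None = None,
                pooling: str = "frames") -> ContactFrequencyMap:
    """Contact-frequency map pooled over runs.

    Each run maps a residue-pair key to its per-frame H-bond counts (all
    arrays within a run must share the frame count; a pair absent from a
    run contributes zero bonds for that run's frames).  With
    ``pooling="frames"`` the frequency is (frames with ≥ 1 bond, summed
    over runs) / (total frames); ``pooling="runs"`` averages per-run
    frequencies instead.
    """
    if pooling not in ("frames", "runs"):
        raise ValueError(f"unknown pooling {pooling!r}")
    frame_counts: list[int] = []
    for run in runs:
        lengths = {len(np.asarray(v)) for v in run.values()}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent frame counts in run: {lengths}")
        frame_counts.append(lengths.pop() if lengths else 0)
    total = sum(frame_counts)
    if total == 0:
        raise ValueError("pooled frame count is zero")
    if pair_universe is None:
        seen: list[Hashable] = []
        for run in runs:
            for pair in run:
                if pair not in seen:
                    seen.append(pair)
        pair_universe = seen
    freqs: dict[Hashable, float] = {}
    for pair in pair_universe:
        if pooling == "frames":
            engaged = sum(
                int(np.count_nonzero(np.asarray(run[pair]) >= 1))
                for run in runs if pair in run)
            freqs[pair] = engaged / total
        else:
            per_run = [
                np.count_nonzero(np.asarray(run[pair]) >= 1) / nf
                if pair in run else 0.0
                for run, nf in zip(runs, frame_counts) if nf > 0]
            freqs[pair] = float(np.mean(per_run))
    return ContactFrequencyMap(freqs, n_frames=total, pooling=pooling)
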