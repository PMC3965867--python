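"""Domain data model for the pemphigus joint-modeling pipeline.

The unit of analysis is a subject followed from disease onset (time 0, in
months). Two linked processes are observed per subject:

* a longitudinal biomarker — the serum IgG autoantibody titer measured at
  clinic visits, analysed on the ``ln(1 + titer)`` scale because titers are
  right-skewed and frequently exactly zero;
* a recurrent-event process — successive disease recurrences, represented on
  the gap-time scale ``W_k = T_k - T_{k-1}`` with onset ``T_0 = 0`` and a
  final administratively censored gap at the end of follow-up.

These records are deliberately plain dataclasses: model parameters live in
:mod:`pemjoint.longitudinal`, :mod:`pemjoint.recurrence` and
:mod:`pemjoint.estimation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "LongitudinalObservation",
    "EpisodeRecord",
    "SubjectCovariates",
    "SubjectData",
    "Cohort",
    "Violation",
    "transform_titer",
    "inverse_transform",
    "build_gap_times",
    "validate_cohort",
]

#: slack allowed when checking times against follow-up (months); covers
#: round-trips through text formats where follow-up is reconstructed as a
#: float sum of gap times.
TIME_TOLERANCE = 1e-8


class ValidationError(ValueError):
    """Raised for inputs outside a function's documented domain."""


def transform_titer(titer: float) -> float:
    """Map a raw IgG titer to the analysis scale ``ln(1 + titer)``.

    One is added before taking the natural logarithm because zero titers are
    common and ``ln(0)`` is undefined; the transform is strictly increasing
    and maps 0 to 0.

    Parameters
    ----------
    titer : float
        Raw IgG titer, finite and non-negative.
    """
    if not math.isfinite(titer) or titer < 0:
        raise ValidationError(f"titer must be finite and >= 0, got {titer!r}")
    return math.log1p(titer)


def inverse_transform(y: float) -> float:
    """Invert :func:`transform_titer`: return ``exp(y) - 1``."""
    if not math.isfinite(y) or y < 0:
        raise ValidationError(f"transformed response must be finite and >= 0, got {y!r}")
    return math.expm1(y)


@dataclass(frozen=True)
class LongitudinalObservation:
    """One biomarker measurement: subject, visit time (months), titer.

    ``y`` is always ``ln(1 + titer)``; construct via :meth:`from_titer` to
    guarantee the identity.
    """

    subject_id: Hashable
    t: float
    titer: float
    y: float

    @classmethod
    def from_titer(cls, subject_id: Hashable, t: float, titer: float) -> "LongitudinalObservation":
        if not math.isfinite(t) or t < 0:
            raise ValidationError(f"observation time must be finite and >= 0, got {t!r}")
        return cls(subject_id=subject_id, t=float(t), titer=float(titer), y=transform_titer(titer))


@dataclass(frozen=True)
class EpisodeRecord:
    """One gap time: the recurrent-event outcome unit.

    ``k`` indexes episodes 1..K within a subject; ``delta`` is 1 when the gap
    ends in an observed recurrence and 0 when it ends by censoring (only ever
    the last episode).
    """

    subject_id: Hashable
    k: int
    w: float
    delta: int


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates.

    Indicator coding follows the study convention: ``male`` 1 = male,
    ``single`` 1 = single (0 = married), ``skin_phenotype`` 1 = skin lesions
    (0 = mucosal lesions). ``age`` is years at diagnosis, ``lymphocyte`` the
    baseline laboratory value, ``follow_up`` total follow-up in months.
    """

    age: float
    male: int
    single: int
    skin_phenotype: int
    lymphocyte: float
    follow_up: float


@dataclass
class SubjectData:
    """Covariates plus the subject's observation and episode sequences."""

    subject_id: Hashable
    covariates: SubjectCovariates
    observations: list[LongitudinalObservation] = field(default_factory=list)
    episodes: list[EpisodeRecord] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return sum(e.delta for e in self.episodes)


@dataclass
class Cohort:
    """A list of subjects plus provenance metadata (source file or seed)."""

    subjects: list[SubjectData]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_episodes(self) -> int:
        return sum(len(s.episodes) for s in self.subjects)

    @property
    def n_events(self) -> int:
        return sum(s.n_events for s in self.subjects)


def build_gap_times(
    event_times: Sequence[float],
    follow_up: float,
    subject_id: Hashable = None,
) -> list[EpisodeRecord]:
    """Convert calendar-time recurrences into gap-time episodes.

    ``event_times`` must start at disease onset (``T_0 = 0``) and be strictly
    increasing. Each consecutive pair contributes an event gap
    ``W_k = T_k - T_{k-1}`` with ``delta = 1``; if follow-up extends past the
    last event, a final censored gap ``follow_up - T_K`` with ``delta = 0``
    is appended, so the gaps partition ``[0, follow_up]``.
    """
    times = [float(t) for t in event_times]
    if not times or times[0] != 0.0:
        raise ValidationError("event_times must start at disease onset T_0 = 0")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValidationError(f"event_times must be strictly increasing, got {times}")
    if not math.isfinite(follow_up) or follow_up < times[-1]:
        raise ValidationError(
            f"follow_up ({follow_up!r}) must be finite and >= last event time ({times[-1]!r})"
        )
    episodes = [
        EpisodeRecord(subject_id=subject_id, k=k, w=b - a, delta=1)
        for k, (a, b) in enumerate(zip(times, times[1:]), start=1)
    ]
    if follow_up > times[-1]:
        episodes.append(
            EpisodeRecord(subject_id=subject_id, k=len(episodes) + 1, w=follow_up - times[-1], delta=0)
        )
    return episodes


@dataclass(frozen=True)
class Violation:
    """One broken invariant found by :func:`validate_cohort`."""

    subject_id: Hashable
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.subject_id}] {self.rule}: {self.message}"


def _validate_subject(s: SubjectData) -> Iterable[Violation]:
    cov = s.covariates
    sid = s.subject_id

    for name in ("male", "single", "skin_phenotype"):
        v = getattr(cov, name)
        if v not in (0, 1):
            yield Violation(sid, "indicator_coding", f"{name} must be 0 or 1, got {v!r}")
    if not (math.isfinite(cov.follow_up) and cov.follow_up > 0):
        yield Violation(sid, "follow_up_positive", f"follow_up must be > 0, got {cov.follow_up!r}")

    for o in s.observations:
        if not (math.isfinite(o.t) and o.t >= 0):
            yield Violation(sid, "obs_time_domain", f"time {o.t!r} not finite and >= 0")
        elif o.t > cov.follow_up + TIME_TOLERANCE:
            yield Violation(sid, "obs_within_follow_up", f"time {o.t} exceeds follow-up {cov.follow_up}")
        if not (math.isfinite(o.titer) and o.titer >= 0):
            yield Violation(sid, "titer_domain", f"titer {o.titer!r} not finite and >= 0")
        elif abs(o.y - math.log1p(o.titer)) > 1e-9:
            yield Violation(sid, "titer_transform", f"y={o.y} is not ln(1 + {o.titer})")

    if not s.episodes:
        yield Violation(sid, "episodes_nonempty", "subject has no episodes")
        return
    for i, e in enumerate(s.episodes):
        if e.k != i + 1:
            yield Violation(sid, "episode_indexing", f"episode {i} has index k={e.k}, expected {i + 1}")
        if not (math.isfinite(e.w) and e.w > 0):
            yield Violation(sid, "gap_positive", f"episode {e.k} gap w={e.w!r} must be > 0")
        if e.delta not in (0, 1):
            yield Violation(sid, "delta_coding", f"episode {e.k} delta={e.delta!r} must be 0 or 1")
        elif e.delta == 0 and i != len(s.episodes) - 1:
            yield Violation(sid, "censoring_terminal", f"censored episode {e.k} is not the last episode")
    total = sum(e.w for e in s.episodes)
    if total > cov.follow_up + TIME_TOLERANCE * max(1.0, cov.follow_up):
        yield Violation(sid, "gaps_within_follow_up", f"sum of gaps {total} exceeds follow-up {cov.follow_up}")


def validate_cohort(cohort: Cohort, raise_on_invalid: bool = False) -> list[Violation]:
    """Check every type invariant and return all violations found.

    The check is collect-all rather than fail-fast so a broken synthetic
    cohort reports every problem at once; the input is never mutated. With
    ``raise_on_invalid`` a non-empty report is raised as
    :class:`ValidationError`.
    """
    violations: list[Violation] = []
    if not cohort.subjects:
        violations.append(Violation(None, "cohort_nonempty", "cohort has no subjects"))
    seen: set = set()
    for s in cohort.subjects:
        if s.subject_id in seen:
            violations.append(Violation(s.subject_id, "unique_subject_ids", "duplicate subject_id"))
        seen.add(s.subject_id)
        violations.extend(_validate_subject(s))
    if raise_on_invalid and violations:
        raise ValidationError("; ".join(str(v) for v in violations))
    return violations
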