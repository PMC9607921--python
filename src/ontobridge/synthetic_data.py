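"""Synthetic cohort generator emulating a pilot study's app usage.

The generator stands in for the raw app database: it produces side-effect
and daily-activity records for a pseudonymized cohort with the enrollment
structure of a real pilot — allocated patients, dropouts (with a reason
breakdown), patients who never used the app, and the remaining active
users, of whom only subsets ever report side effects or sync activity data.

Counts are allocated *constructively*, not sampled in expectation: the
configured totals are partitioned across exactly the configured number of
reporting users (each with ≥1 record), then assigned to distinct dates per
user, so a pipeline run reproduces the configured volumes exactly on every
seed.  Randomness (which users report, on which dates, which finding and
severity literals) uses a seeded Mersenne Twister (:mod:`random`).

``STUDY_DEFAULTS`` is the bundled study-scale configuration: 62 allocated,
12 dropouts (7 lack of response / 2 medical / 2 lost to follow-up /
1 personal), 3 never-users, hence 47 users; 234 side-effect records over
34 users and 866 activity records over 38 users, across the
2020-12-22..2022-04-04 window.
"""

from __future__ import annotations

import datetime as _dt
import random
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .conversion import ActivityRecord, AppRecord, PatientLink, SideEffectRecord
from .onto_repository import pct
from .terminology import MappingConfig

__all__ = [
    "DropoutBreakdown",
    "CohortConfig",
    "CohortSummary",
    "GeneratedCohort",
    "STUDY_DEFAULTS",
    "CohortConfigError",
    "generate_cohort",
    "cohort_accounting",
]


class CohortConfigError(ValueError):
    """Infeasible or inconsistent cohort configuration."""


class DropoutBreakdown(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    lack_of_response: int = 0
    medical: int = 0
    lost_to_follow_up: int = 0
    personal: int = 0

    @property
    def total(self) -> int:
        return (
            self.lack_of_response + self.medical + self.lost_to_follow_up + self.personal
        )


class CohortConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    n_allocated: int = 62
    dropouts: DropoutBreakdown = DropoutBreakdown(
        lack_of_response=7, medical=2, lost_to_follow_up=2, personal=1
    )
    n_never_used: int = 3
    n_side_effect_extracts: int = 234
    n_side_effect_users: int = 34
    n_activity_extracts: int = 866
    n_activity_users: int = 38
    start_date: _dt.date = _dt.date(2020, 12, 22)
    end_date: _dt.date = _dt.date(2022, 4, 4)
    seed: int = 20201222

    @property
    def n_users(self) -> int:
        return self.n_allocated - self.dropouts.total - self.n_never_used

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @model_validator(mode="after")
    def _feasible(self) -> "CohortConfig":
        if min(
            self.n_allocated,
            self.n_never_used,
            self.n_side_effect_extracts,
            self.n_side_effect_users,
            self.n_activity_extracts,
            self.n_activity_users,
        ) < 0 or self.dropouts.total < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_users < 0:
            raise ValueError("dropouts + never-users exceed allocated patients")
        if self.end_date < self.start_date:
            raise ValueError("end_date before start_date")
        for label, total, users in (
            ("side-effect", self.n_side_effect_extracts, self.n_side_effect_users),
            ("activity", self.n_activity_extracts, self.n_activity_users),
        ):
            if users > self.n_users:
                raise ValueError(
                    f"{label}: {users} reporting users exceed {self.n_users} app users"
                )
            if total < users:
                raise ValueError(
                    f"{label}: {total} records cannot cover {users} users with >=1 each"
                )
            if users == 0 and total > 0:
                raise ValueError(f"{label}: records configured but zero reporting users")
        if self.n_activity_users:
            per_user_cap = self.n_days
            if self.n_activity_extracts > self.n_activity_users * per_user_cap:
                raise ValueError(
                    "activity records exceed one-per-user-per-day capacity of the window"
                )
        return self


#: Study-scale defaults; running the pipeline on this configuration
#: reproduces the pilot's extract table exactly.
STUDY_DEFAULTS = CohortConfig()


class CohortSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_allocated: int
    dropouts: DropoutBreakdown
    n_never_used: int
    n_users: int
    n_side_effect_records: int
    n_side_effect_reporters: int
    n_activity_records: int
    n_activity_reporters: int


class GeneratedCohort(BaseModel):
    model_config = ConfigDict(frozen=True)

    records: tuple[AppRecord, ...]
    links: tuple[PatientLink, ...]
    summary: CohortSummary


def _partition(total: int, parts: int, cap: int, rng: random.Random) -> list[int]:
    """Split ``total`` into ``parts`` counts, each in [1, cap], exactly."""
    counts = [1] * parts
    remaining = total - parts
    while remaining > 0:
        i = rng.randrange(parts)
        if counts[i] < cap:
            counts[i] += 1
            remaining -= 1
    return counts


_FREE_TEXTS = (
    "se encuentra cansada",
    "molestias leves durante la noche",
    "refiere malestar tras la medicación",
    "sin otros síntomas",
)


def generate_cohort(
    config: CohortConfig,
    mapping: MappingConfig,
    seed: Optional[int] = None,
) -> GeneratedCohort:
    """Generate app records, the patient link table and a cohort summary.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    Dropouts and never-users generate no records and no links — only the
    active users appear in the link table.  Activity has at most one record
    per user per day; side-effect reports also land on distinct days per
    user, with finding and severity literals drawn uniformly from the
    mapping config.
    """
    try:
        config = CohortConfig.model_validate(config.model_dump())
    except ValueError as exc:
        raise CohortConfigError(str(exc)) from exc
    if not mapping.findings or not mapping.severities:
        if config.n_side_effect_extracts > 0:
            raise CohortConfigError(
                "mapping config must provide findings and severities to "
                "sample side-effect records from"
            )
    rng = random.Random(config.seed if seed is None else seed)

    users = [
        (f"XR-{i + 1:04d}", f"ST-{i + 1:04d}") for i in range(config.n_users)
    ]
    links = tuple(PatientLink(app_patient_id=a, study_id=s) for a, s in users)
    app_ids = [a for a, _ in users]

    days = [config.start_date + _dt.timedelta(days=d) for d in range(config.n_days)]
    finding_labels = [b.local_label for b in mapping.findings]
    severity_labels = [b.local_label for b in mapping.severities]

    records: list[AppRecord] = []

    se_users = rng.sample(app_ids, config.n_side_effect_users)
    if se_users:
        se_counts = _partition(
            config.n_side_effect_extracts, len(se_users), len(days), rng
        )
        for uid, k in zip(se_users, se_counts):
            for day in sorted(rng.sample(days, k)):
                records.append(
                    SideEffectRecord(
                        app_patient_id=uid,
                        date=day,
                        finding_label=rng.choice(finding_labels),
                        value_text=(
                            rng.choice(_FREE_TEXTS) if rng.random() < 0.3 else None
                        ),
                        severity_label=rng.choice(severity_labels),
                    )
                )

    act_users = rng.sample(app_ids, config.n_activity_users)
    if act_users:
        act_counts = _partition(
            config.n_activity_extracts, len(act_users), len(days), rng
        )
        for uid, k in zip(act_users, act_counts):
            for day in sorted(rng.sample(days, k)):
                steps = rng.randint(0, 18000)
                records.append(
                    ActivityRecord(
                        app_patient_id=uid,
                        date=day,
                        steps=steps,
                        calories=round(steps * 0.04 + rng.uniform(0, 120), 1),
                        duration=round(steps / 110 + rng.uniform(0, 30), 1),
                    )
                )

    records.sort(
        key=lambda r: (
            r.app_patient_id,
            r.date,
            isinstance(r, ActivityRecord),
        )
    )
    summary = CohortSummary(
        n_allocated=config.n_allocated,
        dropouts=config.dropouts,
        n_never_used=config.n_never_used,
        n_users=config.n_users,
        n_side_effect_records=sum(
            1 for r in records if isinstance(r, SideEffectRecord)
        ),
        n_side_effect_reporters=len(
            {r.app_patient_id for r in records if isinstance(r, SideEffectRecord)}
        ),
        n_activity_records=sum(1 for r in records if isinstance(r, ActivityRecord)),
        n_activity_reporters=len(
            {r.app_patient_id for r in records if isinstance(r, ActivityRecord)}
        ),
    )
    return GeneratedCohort(records=tuple(records), links=links, summary=summary)


def cohort_accounting(summary: CohortSummary) -> dict:
    """Enrollment report: dropout / never-user / user counts with
    percentages of allocated patients (half-up, one decimal)."""
    n = summary.n_allocated
    d = summary.dropouts
    return {
        "allocated": n,
        "dropouts": {"n": d.total, "pct": pct(d.total, n)},
        "dropout_reasons": {
            "lack_of_response": {"n": d.lack_of_response, "pct": pct(d.lack_of_response, d.total)},
            "medical": {"n": d.medical, "pct": pct(d.medical, d.total)},
            "lost_to_follow_up": {"n": d.lost_to_follow_up, "pct": pct(d.lost_to_follow_up, d.total)},
            "personal": {"n": d.personal, "pct": pct(d.personal, d.total)},
        },
        "never_used": {"n": summary.n_never_used, "pct": pct(summary.n_never_used, n)},
        "users": {"n": summary.n_users, "pct": pct(summary.n_users, n)},
    }
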