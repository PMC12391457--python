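"""Demographically structured synthetic cohorts.

A cohort is a list of participants with a diagnostic label (PD / non-PD)
and four protected attributes: sex, race (with a White / Non-White
binarisation), device type and dominant hand.  Default counts mirror a
remote Parkinson's assessment study population of 251 participants
(99 PD, 152 controls; 212 male / 39 female; 201 Windows / 41 Mac /
8 Linux; 176 right- / 75 left-handed) with the race-by-status table
completed so that the small Non-White cells sum consistently.

Every configured one-way margin is reproduced *exactly*: the joint
(race, status) table is laid out deterministically and the remaining
attributes are assigned by a seeded permutation of exact-count lists,
which makes each attribute independent of the others conditional on
the configured margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

SEXES = ("male", "female")
DEVICES = ("Windows", "Mac", "Linux")
HANDS = ("right", "left")
RACES = (
    "White",
    "Black",
    "American-Indian/Alaska-Native",
    "Asian",
    "Native-Hawaiian/Pacific-Islander",
)
LABELS = ("PD", "non-PD")

PD = "PD"
NON_PD = "non-PD"


class CohortConfigError(ValueError):
    """A cohort configuration whose margins are inconsistent."""


@dataclass(frozen=True)
class Participant:
    id: str
    sex: str
    race: str
    device: str
    hand: str
    label: str

    @property
    def race_binary(self) -> str:
        return "White" if self.race == "White" else "Non-White"

    @property
    def is_pd(self) -> bool:
        return self.label == PD


def _default_race_by_status() -> Dict[Tuple[str, str], int]:
    # Default race-by-status cells; chosen so the race, status and total
    # margins are all mutually consistent.
    return {
        ("White", PD): 51,
        ("Black", PD): 33,
        ("American-Indian/Alaska-Native", PD): 12,
        ("Native-Hawaiian/Pacific-Islander", PD): 2,
        ("Asian", PD): 1,
        ("White", NON_PD): 134,
        ("Black", NON_PD): 6,
        ("American-Indian/Alaska-Native", NON_PD): 9,
        ("Native-Hawaiian/Pacific-Islander", NON_PD): 2,
        ("Asian", NON_PD): 1,
    }


@dataclass
class CohortConfig:
    """Marginal counts for a synthetic cohort.

    All margins must sum to ``n_total``; violations raise
    :class:`CohortConfigError` naming the offending margin.
    """

    n_total: int = 251
    n_pd: int = 99
    sex_counts: Dict[str, int] = field(
        default_factory=lambda: {"male": 212, "female": 39}
    )
    device_counts: Dict[str, int] = field(
        default_factory=lambda: {"Windows": 202, "Mac": 41, "Linux": 8}
    )
    hand_counts: Dict[str, int] = field(
        default_factory=lambda: {"right": 176, "left": 75}
    )
    race_by_status: Dict[Tuple[str, str], int] = field(
        default_factory=_default_race_by_status
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 0 or self.n_pd < 0:
            raise CohortConfigError("counts must be non-negative")
        if self.n_pd > self.n_total:
            raise CohortConfigError("n_pd exceeds n_total")
        margins = {
            "sex_counts": sum(self.sex_counts.values()),
            "device_counts": sum(self.device_counts.values()),
            "hand_counts": sum(self.hand_counts.values()),
            "race_by_status": sum(self.race_by_status.values()),
        }
        for name, total in margins.items():
            if total != self.n_total:
                raise CohortConfigError(
                    f"margin {name!r} sums to {total}, expected n_total={self.n_total}"
                )
        for (race, status), c in self.race_by_status.items():
            if c < 0:
                raise CohortConfigError(f"negative count for {(race, status)}")
            if status not in LABELS:
                raise CohortConfigError(f"unknown status {status!r} in race_by_status")
            if race not in RACES:
                raise CohortConfigError(f"unknown race {race!r} in race_by_status")
        pd_total = sum(
            c for (_, status), c in self.race_by_status.items() if status == PD
        )
        if pd_total != self.n_pd:
            raise CohortConfigError(
                f"race_by_status PD cells sum to {pd_total}, expected n_pd={self.n_pd}"
            )
        for counts, allowed, name in (
            (self.sex_counts, SEXES, "sex_counts"),
            (self.device_counts, DEVICES, "device_counts"),
            (self.hand_counts, HANDS, "hand_counts"),
        ):
            for key in counts:
                if key not in allowed:
                    raise CohortConfigError(f"unknown key {key!r} in {name}")


def _exact_count_list(counts: Dict[str, int], order: Tuple[str, ...]) -> List[str]:
    out: List[str] = []
    for value in order:
        out.extend([value] * counts.get(value, 0))
    return out


def generate_cohort(config: CohortConfig | None = None) -> List[Participant]:
    """Generate a cohort reproducing every configured margin exactly.

    Deterministic given ``config.seed``; the same config yields the same
    participant list byte-for-byte.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    race_status: List[Tuple[str, str]] = []
    for status in LABELS:
        for race in RACES:
            race_status.extend(
                [(race, status)] * config.race_by_status.get((race, status), 0)
            )

    sexes = _exact_count_list(config.sex_counts, SEXES)
    devices = _exact_count_list(config.device_counts, DEVICES)
    hands = _exact_count_list(config.hand_counts, HANDS)
    for lst in (sexes, devices, hands):
        rng.shuffle(lst)  # type: ignore[arg-type]

    participants = [
        Participant(
            id=f"P{i:04d}",
            sex=sexes[i],
            race=race_status[i][0],
            device=devices[i],
            hand=hands[i],
            label=race_status[i][1],
        )
        for i in range(config.n_total)
    ]
    return participants


def cohort_to_frame(cohort: List[Participant]) -> pd.DataFrame:
    """Tabulate a cohort with the canonical column order."""
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "sex": [p.sex for p in cohort],
            "race": [p.race for p in cohort],
            "race_binary": [p.race_binary for p in cohort],
            "device": [p.device for p in cohort],
            "hand": [p.hand for p in cohort],
            "label": [p.label for p in cohort],
        }
    )


def frame_to_cohort(frame: pd.DataFrame) -> List[Participant]:
    return [
        Participant(
            id=row.id, sex=row.sex, race=row.race, device=row.device,
            hand=row.hand, label=row.label,
        )
        for row in frame.itertuples()
    ]


def write_cohort_csv(cohort: List[Participant], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> List[Participant]:
    return frame_to_cohort(pd.read_csv(path))
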