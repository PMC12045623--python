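"""Flexible manual-interception task structure.

A trial starts with a peripheral target appearing on a circle of radius
15 cm around the touch point, either static or rotating at a constant
angular velocity (CW negative, CCW positive).  After a randomized delay
the GO cue is given and the subject reaches to intercept the target.
Reach direction is the angle of the reach endpoint, binned into eight
45-degree sectors; together with the five target velocities this yields
a 5 x 8 condition grid.

Angles are degrees throughout, counter-clockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: standard target angular velocities, deg/s (CW negative, CCW positive)
STANDARD_VELOCITIES: tuple[int, ...] = (-240, -120, 0, 120, 240)

#: radius of the circular target path, cm (0.15 a.u. in the network world)
TARGET_RADIUS_CM: float = 15.0
TARGET_RADIUS_AU: float = 0.15

N_SECTORS: int = 8
SECTOR_WIDTH: float = 360.0 / N_SECTORS


@dataclass(frozen=True)
class TrialCondition:
    """Labels and event times of one interception trial.

    Event times are ms from trial start and must be ordered
    ``t_target_on < t_go < t_move_onset < t_touch``.
    """

    target_velocity: float
    initial_target_angle: float
    reach_endpoint_angle: float
    sector: int
    t_target_on: float = 0.0
    t_go: float = 600.0
    t_move_onset: float = 800.0
    t_touch: float = 1100.0

    def __post_init__(self) -> None:
        if not (self.t_target_on < self.t_go < self.t_move_onset < self.t_touch):
            raise ValueError("event times must be ordered TO < GO < MO < Touch")
        if not 1 <= self.sector <= N_SECTORS:
            raise ValueError(f"sector must be 1..{N_SECTORS}, got {self.sector}")

    @property
    def delay(self) -> float:
        """Delay between target onset and GO, ms."""
        return self.t_go - self.t_target_on


@dataclass(frozen=True)
class ConditionGrid:
    """The 5 velocities x 8 reach-direction sectors condition grid."""

    velocities: tuple[float, ...] = STANDARD_VELOCITIES
    n_sectors: int = N_SECTORS

    @property
    def n_cells(self) -> int:
        return len(self.velocities) * self.n_sectors

    def cells(self) -> list[tuple[float, int]]:
        """All (velocity, sector) cells, velocity-major order."""
        return [(v, s) for v in self.velocities for s in range(1, self.n_sectors + 1)]

    def sector_center(self, sector: int) -> float:
        """Center angle of a sector, degrees."""
        if not 1 <= sector <= self.n_sectors:
            raise ValueError(f"sector must be 1..{self.n_sectors}")
        return (sector - 0.5) * (360.0 / self.n_sectors)


def target_angle_at(condition: TrialCondition, t: float) -> float:
    """Angular position of the target at time ``t`` (ms from trial start).

    The target moves on its circular path at constant angular velocity
    from target onset; ``t`` earlier than onset is a domain error.
    """
    if t < condition.t_target_on:
        raise ValueError(f"t={t} precedes target onset at {condition.t_target_on}")
    dt_s = (t - condition.t_target_on) / 1000.0
    return float(np.mod(condition.initial_target_angle + condition.target_velocity * dt_s, 360.0))


def assign_sector(angle: float) -> int:
    """Reach-direction sector (1..8) of an endpoint angle.

    Sectors are half-open 45-degree bins anchored at 0 degrees:
    sector k covers [(k-1)*45, k*45).
    """
    a = np.mod(angle, 360.0)
    if a >= 360.0:  # np.mod(-tiny, 360) can round up to exactly 360
        a = 0.0
    return int(a // SECTOR_WIDTH) + 1


def sector_center(sector: int) -> float:
    return ConditionGrid().sector_center(sector)


def bell_speed_profile(duration: float, displacement: float, n_steps: int = 100) -> np.ndarray:
    """Bell-shaped (minimum-jerk) speed profile of a point-to-point reach.

    Returns the speed sampled at ``n_steps`` uniform sub-intervals
    (midpoint-sampled so the discrete integral matches the displacement
    closely); zero at both endpoints, peak 1.875*displacement/duration
    at mid-movement.

    Parameters
    ----------
    duration : movement time (any unit; speed is displacement/unit time)
    displacement : total path length to cover
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    # minimum-jerk position s(t) = D*(10u^3 - 15u^4 + 6u^5), u = t/T
    u = (np.arange(n_steps) + 0.5) / n_steps
    speed = displacement / duration * 30.0 * u**2 * (1.0 - u) ** 2
    return speed


def make_trial_table(conditions: list[TrialCondition]) -> pd.DataFrame:
    """Tabulate trials, one row per trial (CSV-ready)."""
    return pd.DataFrame(
        {
            "target_velocity": [c.target_velocity for c in conditions],
            "initial_target_angle": [c.initial_target_angle for c in conditions],
            "reach_endpoint_angle": [c.reach_endpoint_angle for c in conditions],
            "sector": [c.sector for c in conditions],
            "t_target_on": [c.t_target_on for c in conditions],
            "t_go": [c.t_go for c in conditions],
            "t_move_onset": [c.t_move_onset for c in conditions],
            "t_touch": [c.t_touch for c in conditions],
        }
    )


def trial_table_conditions(table: pd.DataFrame) -> list[TrialCondition]:
    """Inverse of :func:`make_trial_table`."""
    return [
        TrialCondition(
            target_velocity=row.target_velocity,
            initial_target_angle=row.initial_target_angle,
            reach_endpoint_angle=row.reach_endpoint_angle,
            sector=int(row.sector),
            t_target_on=row.t_target_on,
            t_go=row.t_go,
            t_move_onset=row.t_move_onset,
            t_touch=row.t_touch,
        )
        for row in table.itertuples(index=False)
    ]
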