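"""Stepped-wedge trial structure and randomization.

The phase-one trial divides the study area into sectors of 20-30 households,
combines sectors into 12 groups, and rolls the chimney-stove intervention out
to one group per month over a 12-month wedge, flanked by 6-month pre- and
post-installation observation phases (24 monthly periods in total).  Phase two
is an individually randomized comparison of the biomass-chimney stove against
LPG, stratified by administrative unit (VDC and ward) and by prior trial
participation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StepWedgeDesign",
    "Phase2Assignment",
    "randomize_wedge_order",
    "intervention_indicator",
    "randomize_phase2",
]

TransitionRule = Literal["exclude", "exposed", "drop"]


@dataclass(frozen=True)
class StepWedgeDesign:
    """Cluster/group structure of the stepped-wedge trial.

    Parameters
    ----------
    n_groups
        Number of randomization groups (default 12, one per wedge month).
    sectors_per_group
        Sectors (installation units of 20-30 households) per group.
    pre_months, wedge_months, post_months
        Lengths of the three phases in months; total follow-up is their sum.
    crossover_month
        Mapping group id -> calendar month (1-based) of stove installation.
        Must be a bijection from groups onto the wedge months
        ``pre_months+1 .. pre_months+wedge_months``.  ``None`` denotes an
        all-control schedule (no group ever crosses over), used for null
        simulations.
    transition
        Coding of the installation month itself: ``"exclude"`` (default,
        coded unexposed because installation spans the month), ``"exposed"``,
        or ``"drop"`` (period removed from the panel).
    sector_ordering
        Optional geographic ordering of sector indices used for the
        round-robin striping of sectors onto groups; defaults to the identity
        ordering.
    """

    n_groups: int = 12
    sectors_per_group: int = 4
    pre_months: int = 6
    wedge_months: int = 12
    post_months: int = 6
    crossover_month: Mapping[int, int] | None = None
    transition: TransitionRule = "exclude"
    sector_ordering: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.sectors_per_group < 1:
            raise ValueError("sectors_per_group must be >= 1")
        if min(self.pre_months, self.wedge_months, self.post_months) < 0:
            raise ValueError("phase lengths must be non-negative")
        if self.transition not in ("exclude", "exposed", "drop"):
            raise ValueError(f"unknown transition rule {self.transition!r}")
        if self.crossover_month is not None:
            months = sorted(self.crossover_month.values())
            wedge = list(
                range(self.pre_months + 1, self.pre_months + self.wedge_months + 1)
            )
            if sorted(self.crossover_month) != list(self.groups):
                raise ValueError("crossover_month keys must be exactly the groups")
            if months != wedge:
                raise ValueError(
                    "crossover months must be a bijection onto the wedge months "
                    f"{wedge[0]}..{wedge[-1]}"
                )

    # -- structure -----------------------------------------------------------

    @property
    def n_periods(self) -> int:
        return self.pre_months + self.wedge_months + self.post_months

    @property
    def groups(self) -> range:
        """Group ids, 1-based."""
        return range(1, self.n_groups + 1)

    @property
    def n_sectors(self) -> int:
        return self.n_groups * self.sectors_per_group

    @property
    def sector_ids(self) -> range:
        """Sector ids, 1-based."""
        return range(1, self.n_sectors + 1)

    def group_of_sector(self, sector: int) -> int:
        """Group containing ``sector`` under round-robin striping.

        Sectors are striped across groups in a supplied geographic ordering so
        that each group's sectors are spread over the study area (emulating
        the stratified systematic assignment used in the field).
        """
        if sector not in self.sector_ids:
            raise KeyError(f"unknown sector {sector}")
        ordering = (
            list(self.sector_ordering)
            if self.sector_ordering is not None
            else list(self.sector_ids)
        )
        if sorted(ordering) != list(self.sector_ids):
            raise ValueError("sector_ordering must be a permutation of the sectors")
        position = ordering.index(sector)
        return position % self.n_groups + 1

    def sector_table(self) -> pd.DataFrame:
        """One row per sector with its group label."""
        return pd.DataFrame(
            {
                "sector_id": list(self.sector_ids),
                "group_id": [self.group_of_sector(s) for s in self.sector_ids],
            }
        )

    @classmethod
    def from_wedge_order(
        cls, order: Sequence[int], **kwargs: object
    ) -> "StepWedgeDesign":
        """Build a design from a randomized wedge order.

        ``order[k-1]`` is the group whose stoves are installed in wedge month
        ``k`` (calendar month ``pre_months + k``).
        """
        n_groups = int(kwargs.pop("n_groups", len(order)))
        if sorted(order) != list(range(1, n_groups + 1)):
            raise ValueError("order must be a permutation of the groups")
        pre = int(kwargs.pop("pre_months", 6))
        crossover = {g: pre + k for k, g in enumerate(order, start=1)}
        return cls(
            n_groups=n_groups, pre_months=pre, crossover_month=crossover, **kwargs
        )

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        if payload["crossover_month"] is not None:
            payload["crossover_month"] = {
                int(k): int(v) for k, v in payload["crossover_month"].items()
            }
        if payload["sector_ordering"] is not None:
            payload["sector_ordering"] = [int(s) for s in payload["sector_ordering"]]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "StepWedgeDesign":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass(frozen=True)
class Phase2Assignment:
    """One household's arm in the individually randomized phase-two trial."""

    household_id: str
    stratum: tuple
    prior_participant: bool
    arm: Literal["biomass_chimney", "LPG"]


def randomize_wedge_order(n_groups: int, seed: int) -> list[int]:
    """Draw the wedge order: a uniformly random permutation of the groups.

    Mirrors the field procedure of drawing numbered slips from a hat; the
    group at position ``k`` (0-based ``k-1``) has its stoves installed in
    wedge month ``k``.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    return [int(g) for g in rng.permutation(np.arange(1, n_groups + 1))]


def intervention_indicator(
    design: StepWedgeDesign, group: int, period: int
) -> int | None:
    """Exposure covariate X for one group-period.

    0 before the group's stove installation, 1 strictly after it.  The
    installation month itself is coded per ``design.transition``: unexposed
    (default), exposed, or ``None`` (meaning the period is dropped from the
    panel).  An all-control design (``crossover_month is None``) returns 0
    everywhere.
    """
    if not 1 <= period <= design.n_periods:
        raise ValueError(f"period {period} outside 1..{design.n_periods}")
    if design.crossover_month is None:
        return 0
    if group not in design.crossover_month:
        raise KeyError(f"unknown group {group}")
    cross = design.crossover_month[group]
    if period < cross:
        return 0
    if period > cross:
        return 1
    return {"exclude": 0, "exposed": 1, "drop": None}[design.transition]


def randomize_phase2(
    households: pd.DataFrame, seed: int
) -> list[Phase2Assignment]:
    """Balanced permuted assignment within stratum x prior-participation cells.

    ``households`` needs columns ``household_id``, ``vdc``, ``ward``,
    ``prior_participant``.  Within each (vdc, ward, prior_participant) cell
    the two arms differ in count by at most one.  The result is reproducible
    for a fixed seed and insensitive to the row order of the input: cells are
    processed in sorted key order and households within a cell in sorted id
    order.
    """
    required = {"household_id", "vdc", "ward", "prior_participant"}
    missing = required - set(households.columns)
    if missing:
        raise ValueError(f"households table missing columns: {sorted(missing)}")
    if len(households) == 0:
        raise ValueError("empty household list")
    if households["household_id"].duplicated().any():
        raise ValueError("duplicate household ids")

    rng = np.random.default_rng(seed)
    arms = np.array(["biomass_chimney", "LPG"])
    out: list[Phase2Assignment] = []
    cells = households.groupby(["vdc", "ward", "prior_participant"], sort=True)
    for (vdc, ward, prior), cell in cells:
        ids = sorted(cell["household_id"].astype(str))
        n = len(ids)
        # permuted block: floor(n/2) of each arm plus one random extra if odd
        block = np.repeat(arms, n // 2)
        if n % 2:
            block = np.append(block, rng.choice(arms))
        block = rng.permutation(block)
        out.extend(
            Phase2Assignment(
                household_id=hid,
                stratum=(vdc, ward),
                prior_participant=bool(prior),
                arm=str(arm),
            )
            for hid, arm in zip(ids, block)
        )
    return out


def assignments_to_frame(assignments: Sequence[Phase2Assignment]) -> pd.DataFrame:
    """Export assignments as a table (household_id, vdc, ward, prior, arm)."""
    return pd.DataFrame(
        {
            "household_id": [a.household_id for a in assignments],
            "vdc": [a.stratum[0] for a in assignments],
            "ward": [a.stratum[1] for a in assignments],
            "prior_participant": [a.prior_participant for a in assignments],
            "arm": [a.arm for a in assignments],
        }
    )
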