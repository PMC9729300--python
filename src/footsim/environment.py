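"""Pitch geometry, role-boxes and formation templates.

All coordinates live in a Cartesian frame with the origin at the pitch
centre and the x axis along the pitch length.  Team A defends the goal at
``x = -length/2`` and attacks toward ``+x``; team B is the mirror image.
Role-boxes are axis-aligned rectangles a player's tactical role confines
them to; eleven of them make up a formation.

The shipped rectangle extents are editable defaults (``data/formations.yaml``)
chosen to cover the pitch in the conventional defender/midfielder/forward
bands; the simulator treats them as hard spatial constraints, not
suggestions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PitchConfig",
    "RoleBox",
    "Formation",
    "FormationError",
    "FORMATION_NAMES",
    "build_formation",
    "load_formation_templates",
    "contains_point",
    "clamp_to_pitch",
    "role_box_centre",
]

#: Formation options offered by the simulator.
FORMATION_NAMES = ("3-5-2", "4-4-2", "4-3-3")

GOALKEEPER_ROLE = "G"


class FormationError(ValueError):
    """Raised for unknown formation names or malformed role-box templates."""


@dataclass(frozen=True)
class PitchConfig:
    """Dimensions of the playing field.

    Parameters
    ----------
    length, width : float
        Pitch extents in metres.  Both must be integer multiples of
        ``patch_size`` so the field rasterizes exactly onto the grid used
        for rendering parity with grid-based implementations.
    patch_size : float
        Edge length of one raster patch in metres.  Agents move in
        continuous coordinates; the grid matters only for rasterization.
    goal_width : float
        Width of each goal mouth in metres, centred on ``y = 0``.
    """

    length: float = 110.0
    width: float = 60.0
    patch_size: float = 0.5
    goal_width: float = 7.32

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.patch_size <= 0:
            raise ValueError("pitch dimensions must be positive")
        if self.goal_width <= 0 or self.goal_width > self.width:
            raise ValueError("goal width must be positive and fit on the pitch")
        for extent in (self.length, self.width):
            ratio = extent / self.patch_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    "length and width must be integer multiples of patch_size"
                )

    @property
    def half_length(self) -> float:
        return self.length / 2.0

    @property
    def half_width(self) -> float:
        return self.width / 2.0

    def goal_centre(self, sign: int) -> np.ndarray:
        """Centre of the goal on the ``sign`` side (+1 for +x, -1 for -x)."""
        return np.array([math.copysign(self.half_length, sign), 0.0])


@dataclass(frozen=True)
class RoleBox:
    """Axis-aligned rectangle a player's role confines them to.

    The rectangle is closed: boundary points count as inside, which keeps
    agents from oscillating when they sit exactly on an edge.
    """

    role_label: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    owner: int | None = None

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError("role-box corners must satisfy xmin<=xmax, ymin<=ymax")

    @property
    def centre(self) -> np.ndarray:
        return np.array([(self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0])

    def contains(self, p: Sequence[float]) -> bool:
        return bool(
            self.xmin <= p[0] <= self.xmax and self.ymin <= p[1] <= self.ymax
        )

    def clamp(self, p: Sequence[float]) -> np.ndarray:
        """Nearest point of the (closed) rectangle to ``p``."""
        return np.array(
            [
                min(max(p[0], self.xmin), self.xmax),
                min(max(p[1], self.ymin), self.ymax),
            ]
        )

    def reflected(self) -> "RoleBox":
        """Point reflection through the pitch centre (side A <-> side B)."""
        return RoleBox(
            role_label=self.role_label,
            xmin=-self.xmax,
            ymin=-self.ymax,
            xmax=-self.xmin,
            ymax=-self.ymin,
            owner=self.owner,
        )


@dataclass(frozen=True)
class Formation:
    """Eleven role-boxes arranged for one team."""

    name: str
    role_boxes: tuple[RoleBox, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.role_boxes) != 11:
            raise FormationError(
                f"a formation needs exactly 11 role-boxes, got {len(self.role_boxes)}"
            )
        n_goalkeepers = sum(
            1 for b in self.role_boxes if b.role_label == GOALKEEPER_ROLE
        )
        if n_goalkeepers != 1:
            raise FormationError("a formation needs exactly one goalkeeper role")

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(b.role_label for b in self.role_boxes)


def contains_point(box: RoleBox, p: Sequence[float]) -> bool:
    """True iff ``p`` lies inside or on the boundary of ``box``."""
    return box.contains(p)


def role_box_centre(box: RoleBox) -> np.ndarray:
    """Centroid of the rectangle."""
    return box.centre


def clamp_to_pitch(p: Sequence[float], pitch: PitchConfig) -> np.ndarray:
    """Project ``p`` onto the pitch rectangle (identity for interior points)."""
    return np.array(
        [
            min(max(p[0], -pitch.half_length), pitch.half_length),
            min(max(p[1], -pitch.half_width), pitch.half_width),
        ]
    )


@lru_cache(maxsize=None)
def _default_templates_text() -> str:
    return (
        resources.files("footsim").joinpath("data/formations.yaml").read_text()
    )


def load_formation_templates(text: str | None = None) -> dict[str, list[RoleBox]]:
    """Parse role-box templates from YAML.

    The file maps each formation name to a list of
    ``{role, xmin, ymin, xmax, ymax}`` rectangles for the side defending
    the ``-x`` goal.  With ``text=None`` the packaged defaults are used.
    """
    raw = yaml.safe_load(text if text is not None else _default_templates_text())
    templates: dict[str, list[RoleBox]] = {}
    for name, rows in raw.items():
        boxes = []
        for row in rows:
            try:
                boxes.append(
                    RoleBox(
                        role_label=str(row["role"]),
                        xmin=float(row["xmin"]),
                        ymin=float(row["ymin"]),
                        xmax=float(row["xmax"]),
                        ymax=float(row["ymax"]),
                    )
                )
            except KeyError as exc:  # pragma: no cover - config error path
                raise FormationError(f"role-box template missing field {exc}") from exc
        templates[str(name)] = boxes
    return templates


def build_formation(
    name: str,
    side: str,
    pitch: PitchConfig | None = None,
    templates: Mapping[str, Iterable[RoleBox]] | None = None,
) -> Formation:
    """Instantiate a formation for one side of the pitch.

    Parameters
    ----------
    name : str
        One of :data:`FORMATION_NAMES`.
    side : str
        ``"A"`` (defends the -x goal) or ``"B"`` (defends +x).  Side B's
        boxes are the point reflection of side A's through the pitch centre.
    pitch : PitchConfig, optional
        Used to validate that every box lies within bounds.
    templates : mapping, optional
        Alternative role-box templates; defaults to the packaged YAML.
    """
    if side not in ("A", "B"):
        raise FormationError(f"unknown side {side!r}; expected 'A' or 'B'")
    source = templates if templates is not None else load_formation_templates()
    if name not in source:
        raise FormationError(
            f"unknown formation {name!r}; offered options are {', '.join(FORMATION_NAMES)}"
        )
    boxes = list(source[name])
    if side == "B":
        boxes = [b.reflected() for b in boxes]
    pitch = pitch if pitch is not None else PitchConfig()
    for b in boxes:
        if not (
            -pitch.half_length <= b.xmin
            and b.xmax <= pitch.half_length
            and -pitch.half_width <= b.ymin
            and b.ymax <= pitch.half_width
        ):
            raise FormationError(
                f"role-box {b.role_label} of {name} extends beyond the pitch"
            )
    return Formation(name=name, role_boxes=tuple(boxes))
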