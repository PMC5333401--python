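"""Plate, strip and well bookkeeping for the Phytostrip screening platform.

The physical unit of the platform is a 96-well microtitre plate carrying
12 Phytostrips of 8 gel-filled wells each.  By convention the strips at
either end of a plate (positions 1 and 12) hold solvent controls, leaving
80 assay wells per plate.  Strip and well indices are 1-based throughout
(matching the ``Strip9`` style of the image filenames); pixel coordinates
elsewhere in the package are 0-based.

The imaging robot labels every captured frame as
``[<experiment>_]Plate<id>_Strip<k>_<view>`` with ``view`` one of ``Side``
(root camera) or ``Top`` (overhead shoot camera), e.g.
``PlateA4_Strip9_Side``.  This module parses and composes those names and
does the capacity arithmetic for experiment planning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "VIEWS",
    "PlateLayout",
    "WellAddress",
    "ImagingSchedule",
    "FilenameError",
    "parse_image_name",
    "compose_image_name",
    "assays_per_plate",
    "platform_capacity",
    "total_well_images",
]

#: The two camera positions of the imaging station.
VIEWS = ("Side", "Top")

#: Image-file suffixes stripped before parsing a filename.
_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


class FilenameError(ValueError):
    """Raised when an image filename does not follow the platform convention."""


@dataclass(frozen=True)
class PlateLayout:
    """Layout of one assay plate and the platform it sits on.

    Defaults describe the standard configuration: 54 plates of 12 strips
    with 8 wells each, strips 1 and 12 reserved for controls.
    """

    n_plates: int = 54
    strips_per_plate: int = 12
    wells_per_strip: int = 8
    control_strip_positions: frozenset[int] = field(
        default_factory=lambda: frozenset({1, 12})
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "control_strip_positions", frozenset(self.control_strip_positions)
        )
        if self.n_plates < 0:
            raise ValueError(f"n_plates must be >= 0, got {self.n_plates}")
        if self.strips_per_plate <= 0 or self.wells_per_strip <= 0:
            raise ValueError("strips_per_plate and wells_per_strip must be positive")
        bad = [
            p
            for p in self.control_strip_positions
            if not 1 <= p <= self.strips_per_plate
        ]
        if bad:
            raise ValueError(
                f"control strip positions {sorted(bad)} outside "
                f"[1, {self.strips_per_plate}]"
            )

    @property
    def assay_strips_per_plate(self) -> int:
        return self.strips_per_plate - len(self.control_strip_positions)


@dataclass(frozen=True)
class WellAddress:
    """Address of a strip-level image or an individual well.

    ``well_index`` is optional because the cameras frame a whole strip;
    per-well addresses are produced after cropping.
    """

    plate_id: str
    strip_index: int
    view: str
    well_index: int | None = None
    experiment_tag: str | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.strip_index < 1:
            raise ValueError(f"strip_index must be >= 1, got {self.strip_index}")
        if self.well_index is not None and self.well_index < 1:
            raise ValueError(f"well_index must be >= 1, got {self.well_index}")

    def with_well(self, well_index: int) -> "WellAddress":
        return replace(self, well_index=well_index)


@dataclass(frozen=True)
class ImagingSchedule:
    """Counting model of an imaging campaign.

    ``n_sessions`` counts imaging days including day 0 (the treatment day);
    a 7-day time course imaged daily therefore has 8 sessions.
    """

    n_groups: int
    wells_per_group: int
    views_per_well: int = 2
    n_sessions: int = 1

    def __post_init__(self) -> None:
        for name in ("n_groups", "wells_per_group", "views_per_well", "n_sessions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_NAME_RE = re.compile(
    r"^(?:(?P<exp>.*?)_)?Plate(?P<plate>[A-Za-z0-9]+)_Strip(?P<strip>\d+)_(?P<view>[A-Za-z]+)$"
)


def parse_image_name(name: str, layout: PlateLayout | None = None) -> WellAddress:
    """Parse ``[<experiment>_]Plate<id>_Strip<k>_<view>`` into a :class:`WellAddress`.

    An image-file suffix (``.png`` etc.) is tolerated and stripped.  The
    experiment tag is everything before the first ``Plate`` token.  The view
    token is case-insensitive.  The strip index is validated against
    ``layout`` (default :class:`PlateLayout`).
    """
    if layout is None:
        layout = PlateLayout()
    stem = name
    low = stem.lower()
    for suf in _IMAGE_SUFFIXES:
        if low.endswith(suf):
            stem = stem[: -len(suf)]
            break
    m = _NAME_RE.match(stem)
    if m is None:
        raise FilenameError(
            f"{name!r} does not match '[<experiment>_]Plate<id>_Strip<k>_<view>'"
        )
    view_token = m.group("view")
    view = view_token.capitalize()
    if view not in VIEWS:
        raise FilenameError(f"unknown view token {view_token!r} in {name!r}")
    strip = int(m.group("strip"))
    if not 1 <= strip <= layout.strips_per_plate:
        raise FilenameError(
            f"strip index {strip} in {name!r} outside [1, {layout.strips_per_plate}]"
        )
    return WellAddress(
        plate_id=m.group("plate"),
        strip_index=strip,
        view=view,
        experiment_tag=m.group("exp"),
    )


def compose_image_name(address: WellAddress) -> str:
    """Compose the canonical image name for an address (no file suffix)."""
    prefix = f"{address.experiment_tag}_" if address.experiment_tag else ""
    return f"{prefix}Plate{address.plate_id}_Strip{address.strip_index}_{address.view}"


def assays_per_plate(layout: PlateLayout | None = None) -> int:
    """Number of assay (non-control) wells on one plate.

    The default layout gives 80: (12 − 2 control strips) × 8 wells.
    """
    if layout is None:
        layout = PlateLayout()
    return layout.assay_strips_per_plate * layout.wells_per_strip


def platform_capacity(layout: PlateLayout | None = None) -> int:
    """Total simultaneous assays across the platform: plates × assays/plate."""
    if layout is None:
        layout = PlateLayout()
    return layout.n_plates * assays_per_plate(layout)


def total_well_images(schedule: ImagingSchedule) -> int:
    """Total well images over a campaign: groups × wells × views × sessions."""
    return (
        schedule.n_groups
        * schedule.wells_per_group
        * schedule.views_per_well
        * schedule.n_sessions
    )
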