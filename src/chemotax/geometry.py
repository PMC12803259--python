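"""Coordinate model of the two-chemoattractant microfluidic chemotaxis device.

The device consists of a central cell-loading chamber flanked by two
chemoattractant chambers (fMLP on the left, LTB4 on the right by assay
convention), connected by narrow perpendicular migration channels — ten per
side by default. All coordinates are in microns, origin at the top-left of
the imaged field, x rightward, y downward. Rectangle containment uses
half-open intervals [x0, x1) x [y0, y1) so that region assignment is a
partition of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, DomainError

# Region labels. Every point of the imaged field maps to exactly one.
CENTER = "CENTER"
CHANNEL_LEFT = "CHANNEL_LEFT"
CHANNEL_RIGHT = "CHANNEL_RIGHT"
CHAMBER_LEFT = "CHAMBER_LEFT"
CHAMBER_RIGHT = "CHAMBER_RIGHT"
BACKGROUND = "BACKGROUND"

REGIONS = (CENTER, CHANNEL_LEFT, CHANNEL_RIGHT, CHAMBER_LEFT, CHAMBER_RIGHT,
           BACKGROUND)

#: Regions a cell can physically occupy (everything but BACKGROUND).
DEVICE_REGIONS = REGIONS[:-1]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in microns, half-open on both axes."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def overlaps(self, other: "Rect") -> bool:
        return (self.x0 < other.x1 and other.x0 < self.x1
                and self.y0 < other.y1 and other.y0 < self.y1)


@dataclass(frozen=True)
class Channel:
    """One migration channel: a rectangle tagged with side and index."""

    side: str          # "left" | "right"
    index: int         # 0 .. n_channels-1, top to bottom
    rect: Rect

    @property
    def region(self) -> str:
        return CHANNEL_LEFT if self.side == "left" else CHANNEL_RIGHT


@dataclass(frozen=True)
class DeviceGeometry:
    """Partition of the imaged field into chambers, channels and background."""

    field_width: float        # um
    field_height: float       # um
    center_chamber: Rect
    left_chamber: Rect
    right_chamber: Rect
    channels: tuple[Channel, ...] = field(default_factory=tuple)
    n_channels: int = 10      # per side
    pixel_size: float = 0.65  # um per pixel

    def assign_region(self, x: float, y: float) -> tuple[str, int | None]:
        """Map a point (um) to its (region label, channel index or None).

        Raises DomainError for points outside the field bounds. The half-open
        rectangle convention guarantees every in-field point gets exactly one
        label.
        """
        if not (0 <= x < self.field_width and 0 <= y < self.field_height):
            raise DomainError(
                f"point ({x}, {y}) um lies outside the imaged field "
                f"[0, {self.field_width}) x [0, {self.field_height})")
        if self.center_chamber.contains(x, y):
            return CENTER, None
        if self.left_chamber.contains(x, y):
            return CHAMBER_LEFT, None
        if self.right_chamber.contains(x, y):
            return CHAMBER_RIGHT, None
        for ch in self.channels:
            if ch.rect.contains(x, y):
                return ch.region, ch.index
        return BACKGROUND, None

    def region_of(self, x: float, y: float) -> str:
        return self.assign_region(x, y)[0]

    def in_device(self, x: float, y: float) -> bool:
        """True iff the point is inside a chamber or channel (not background)."""
        try:
            return self.region_of(x, y) != BACKGROUND
        except DomainError:
            return False

    @property
    def image_shape(self) -> tuple[int, int]:
        """(height, width) in pixels of the imaged field."""
        return (int(round(self.field_height / self.pixel_size)),
                int(round(self.field_width / self.pixel_size)))

    def channels_on(self, side: str) -> list[Channel]:
        return [c for c in self.channels if c.side == side]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        rects = {"center_chamber": self.center_chamber,
                 "left_chamber": self.left_chamber,
                 "right_chamber": self.right_chamber}
        for name, r in rects.items():
            if not (0 <= r.x0 < r.x1 <= self.field_width
                    and 0 <= r.y0 < r.y1 <= self.field_height):
                problems.append(f"{name} not contained in field")
        names = list(rects)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if rects[a].overlaps(rects[b]):
                    problems.append(f"{a} overlaps {b}")
        for ch in self.channels:
            r = ch.rect
            tag = f"channel {ch.side}#{ch.index}"
            if not (0 <= r.x0 < r.x1 <= self.field_width
                    and 0 <= r.y0 < r.y1 <= self.field_height):
                problems.append(f"{tag} not contained in field")
            for name, cr in rects.items():
                if r.overlaps(cr):
                    problems.append(f"{tag} overlaps {name}")
            # short ends must abut the center chamber and one side chamber
            if ch.side == "left":
                if r.x1 != self.center_chamber.x0:
                    problems.append(f"{tag} does not abut center chamber")
                if r.x0 != self.left_chamber.x1:
                    problems.append(f"{tag} does not abut left chamber")
            else:
                if r.x0 != self.center_chamber.x1:
                    problems.append(f"{tag} does not abut center chamber")
                if r.x1 != self.right_chamber.x0:
                    problems.append(f"{tag} does not abut right chamber")
        for i, a in enumerate(self.channels):
            for b in self.channels[i + 1:]:
                if a.rect.overlaps(b.rect):
                    problems.append(
                        f"channel {a.side}#{a.index} overlaps "
                        f"channel {b.side}#{b.index}")
        if len(self.channels_on("left")) != self.n_channels:
            problems.append("left channel count != n_channels")
        if len(self.channels_on("right")) != self.n_channels:
            problems.append("right channel count != n_channels")
        return problems


#: Geometry defaults. Channel dimensions are typical for neutrophil
#: migration-channel devices: length must dominate width so migration inside
#: a channel is quasi-one-dimensional.
DEFAULT_GEOMETRY_CONFIG = {
    "n_channels": 10,
    "channel_length_um": 500.0,
    "channel_width_um": 12.0,
    "chamber_width_um": 200.0,
    "field_height_um": 700.0,
    "pixel_size_um": 0.65,
}


def make_default_geometry(config: dict | None = None) -> DeviceGeometry:
    """Build the standard three-chamber device from a configuration dict.

    The field width is derived: two side chambers + two channel banks + the
    central chamber laid out left to right. Channels are evenly spaced
    vertically. Any key absent from ``config`` falls back to
    :data:`DEFAULT_GEOMETRY_CONFIG`.
    """
    cfg = dict(DEFAULT_GEOMETRY_CONFIG)
    if config:
        unknown = set(config) - set(cfg) - {"field_width_um"}
        if unknown:
            raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
        cfg.update(config)

    n = int(cfg["n_channels"])
    clen = float(cfg["channel_length_um"])
    cwid = float(cfg["channel_width_um"])
    chamber_w = float(cfg["chamber_width_um"])
    H = float(cfg["field_height_um"])
    px = float(cfg["pixel_size_um"])

    if n < 1:
        raise ConfigurationError("n_channels must be >= 1")
    for key in ("channel_length_um", "channel_width_um", "chamber_width_um",
                "field_height_um", "pixel_size_um"):
        if float(cfg[key]) <= 0:
            raise ConfigurationError(f"{key} must be positive")

    natural_w = 3 * chamber_w + 2 * clen
    W = float(cfg.get("field_width_um", natural_w))
    if W < natural_w:
        raise ConfigurationError(
            f"field_width_um={W} too small: chambers + channels need "
            f"{natural_w} um")
    if H < n * cwid:
        raise ConfigurationError(
            f"field_height_um={H} too small for {n} channels of width "
            f"{cwid} um")

    # Lay out symmetrically around the field center.
    x_left0 = 0.5 * (W - natural_w)
    left = Rect(x_left0, 0.0, x_left0 + chamber_w, H)
    center = Rect(left.x1 + clen, 0.0, left.x1 + clen + chamber_w, H)
    right = Rect(center.x1 + clen, 0.0, center.x1 + clen + chamber_w, H)

    # Channel centers evenly spaced: y_c(i) = H * (i+1) / (n+1).
    pitch = H / (n + 1)
    if pitch < cwid:
        raise ConfigurationError(
            f"field_height_um={H} gives channel pitch {pitch:.1f} um < "
            f"channel_width_um={cwid}")
    channels = []
    for i in range(n):
        yc = pitch * (i + 1)
        y0, y1 = yc - cwid / 2, yc + cwid / 2
        channels.append(Channel("left", i, Rect(left.x1, y0, center.x0, y1)))
        channels.append(Channel("right", i, Rect(center.x1, y0, right.x0, y1)))

    geom = DeviceGeometry(
        field_width=W, field_height=H, center_chamber=center,
        left_chamber=left, right_chamber=right, channels=tuple(channels),
        n_channels=n, pixel_size=px)
    problems = geom.validate()
    if problems:  # construction should already prevent this
        raise ConfigurationError("; ".join(problems))
    return geom


def geometry_to_dict(geom: DeviceGeometry) -> dict:
    """JSON-serializable representation (round-trips via geometry_from_dict)."""
    def rect(r: Rect) -> list[float]:
        return [r.x0, r.y0, r.x1, r.y1]

    return {
        "field_width_um": geom.field_width,
        "field_height_um": geom.field_height,
        "pixel_size_um": geom.pixel_size,
        "n_channels": geom.n_channels,
        "center_chamber": rect(geom.center_chamber),
        "left_chamber": rect(geom.left_chamber),
        "right_chamber": rect(geom.right_chamber),
        "channels": [{"side": c.side, "index": c.index, "rect": rect(c.rect)}
                     for c in geom.channels],
    }


def geometry_from_dict(d: dict) -> DeviceGeometry:
    def rect(v) -> Rect:
        return Rect(*map(float, v))

    return DeviceGeometry(
        field_width=float(d["field_width_um"]),
        field_height=float(d["field_height_um"]),
        pixel_size=float(d["pixel_size_um"]),
        n_channels=int(d["n_channels"]),
        center_chamber=rect(d["center_chamber"]),
        left_chamber=rect(d["left_chamber"]),
        right_chamber=rect(d["right_chamber"]),
        channels=tuple(Channel(c["side"], int(c["index"]), rect(c["rect"]))
                       for c in d["channels"]),
    )
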