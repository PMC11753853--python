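"""Parameterized trabecular-gap channel geometry with an optional rectangular microcrack.

The model domain is a rectangular channel of length ``L`` (flow direction
``x``), width ``W`` (``y``) and height ``H`` (``z``), representing the fluid
filled gap between two trabecular surfaces.  Bone microdamage is represented
by a rectangular groove (the microcrack) recessed into the bottom wall: it
occupies ``z in [-d, 0]`` and ``x in [x_c - w/2, x_c + w/2]``.

All user-facing lengths are micrometers; conversion to SI meters happens
exactly once, at meshing time (see :mod:`trabflow.meshing`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GeometryError",
    "MicrocrackSpec",
    "GapGeometry",
    "build_geometry",
    "UM_TO_M",
]

#: micrometers per meter, the single unit-conversion constant of the package
UM_TO_M = 1e-6


class GeometryError(ValueError):
    """Raised for impossible channel/crack configurations."""


@dataclass(frozen=True)
class MicrocrackSpec:
    """Rectangular groove in the bottom wall.

    Parameters
    ----------
    depth_um:
        Extent of the groove below the bottom wall (``-z`` direction), μm.
    width_um:
        Extent of the groove along the flow axis ``x``, μm.
    center_x_um:
        Midpoint of the groove along ``x``, μm.  ``None`` means the channel
        midpoint ``L/2``.
    span:
        ``"full_width"`` (groove crosses the whole channel width, the
        default) or ``"centered"`` together with ``span_y_um``.
    """

    depth_um: float = 100.0
    width_um: float = 50.0
    center_x_um: float | None = None
    span: str = "full_width"
    span_y_um: float | None = None

    def __post_init__(self) -> None:
        if self.depth_um < 0 or self.width_um < 0:
            raise GeometryError("crack depth and width must be non-negative")
        if self.span not in ("full_width", "centered"):
            raise GeometryError(f"unknown crack span {self.span!r}")
        if self.span == "centered" and (self.span_y_um is None or self.span_y_um <= 0):
            raise GeometryError("centered crack span requires positive span_y_um")

    @property
    def is_degenerate(self) -> bool:
        """A zero-depth or zero-width groove is equivalent to no crack."""
        return self.depth_um == 0.0 or self.width_um == 0.0


@dataclass(frozen=True)
class GapGeometry:
    """Channel-with-groove domain, all lengths in μm.

    ``dimensionality`` selects a planar x–z section (``"planar_2d"``, which
    ignores ``width_um`` for meshing but keeps it for reporting) or the full
    box (``"full_3d"``).
    """

    length_um: float = 1500.0
    width_um: float = 100.0
    height_um: float = 100.0
    crack: MicrocrackSpec | None = field(default=None)
    dimensionality: str = "planar_2d"

    def __post_init__(self) -> None:
        if self.dimensionality not in ("planar_2d", "full_3d"):
            raise GeometryError(f"unknown dimensionality {self.dimensionality!r}")

    @property
    def dim(self) -> int:
        return 2 if self.dimensionality == "planar_2d" else 3

    @property
    def effective_crack(self) -> MicrocrackSpec | None:
        """The crack with defaults resolved, or ``None`` if absent/degenerate."""
        c = self.crack
        if c is None or c.is_degenerate:
            return None
        if c.center_x_um is None:
            c = replace(c, center_x_um=self.length_um / 2.0)
        return c

    @property
    def crack_x_interval_um(self) -> tuple[float, float] | None:
        c = self.effective_crack
        if c is None:
            return None
        return (c.center_x_um - c.width_um / 2.0, c.center_x_um + c.width_um / 2.0)


def build_geometry(config: GapGeometry) -> GapGeometry:
    """Validate a :class:`GapGeometry`, returning it unchanged.

    Raises
    ------
    GeometryError
        If any dimension is non-positive or the crack does not fit fully
        inside the bottom wall.
    """
    g = config
    for name in ("length_um", "width_um", "height_um"):
        v = getattr(g, name)
        if not v > 0:
            raise GeometryError(f"{name} must be positive, got {v}")
    c = g.effective_crack
    if c is not None:
        if not 0 < c.center_x_um < g.length_um:
            raise GeometryError(
                f"crack center {c.center_x_um} μm outside channel (0, {g.length_um}) μm"
            )
        xl, xr = c.center_x_um - c.width_um / 2, c.center_x_um + c.width_um / 2
        if c.width_um >= g.length_um:
            raise GeometryError(
                f"crack width {c.width_um} μm not smaller than channel length {g.length_um} μm"
            )
        if xl <= 0 or xr >= g.length_um:
            raise GeometryError(
                f"crack x-interval [{xl}, {xr}] μm not interior to (0, {g.length_um}) μm"
            )
        if c.span == "centered":
            if c.span_y_um >= g.width_um:
                raise GeometryError(
                    f"crack span {c.span_y_um} μm not smaller than channel width {g.width_um} μm"
                )
    return g
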