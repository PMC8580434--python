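"""Landmark geometry: image coordinates -> body-frame tentacle vectors.

Landmark coordinates come from video digitisation and use the image
convention (pixels, y increasing downward).  All world angles here are
measured in the standard mathematical sense *after* flipping the y-axis.

Body-frame angles follow the anatomical convention used throughout the
package: 0, 90, 180 and 270 degrees correspond to the ventral, posterior,
dorsal and anterior sides of the animal.  Because static and rotating
trials may be filmed from opposite sides of the arena, a chirality factor
(+1/-1 depending on ``viewing_side``) keeps body angles increasing
ventral -> posterior -> dorsal -> anterior regardless of the camera side:

    body_angle = chirality * (world_angle - ventral_axis_angle) mod 360
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "Point",
    "BodyFrame",
    "TentacleObservation",
    "StimulusOffset",
    "world_angle",
    "build_body_frame",
    "body_angle_of",
    "body_to_world",
    "tentacle_vector",
    "unit_circle_point",
    "chord_distance",
    "wrap_deg",
]

Point = tuple[float, float]

#: chirality applied per camera side; "above" keeps world angles as-is.
CHIRALITY = {"above": 1, "below": -1}


def wrap_deg(angle):
    """Wrap angles (scalar or array) in degrees into [0, 360)."""
    wrapped = np.mod(angle, 360.0)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class BodyFrame:
    """Animal-fixed angular coordinate frame for one video frame."""

    centre: Point
    ventral_axis_angle_world: float  # degrees, world frame (y flipped)
    chirality: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.chirality not in (1, -1):
            raise ValueError("chirality must be +1 or -1")


@dataclass(frozen=True)
class TentacleObservation:
    """One extended tentacle in one frame, as a body-frame vector.

    ``heading_body`` is the pointing direction of the tentacle (base->tip);
    ``positional_angle_body`` is where around the shell margin the tentacle
    is rooted (centre->base).  Both are degrees in [0, 360).
    """

    tentacle_id: str
    frame_index: int
    heading_body: float
    positional_angle_body: float
    length: float

    def angle(self, mode: str = "heading") -> float:
        if mode == "heading":
            return self.heading_body
        if mode == "position":
            return self.positional_angle_body
        raise ValueError(f"unknown angle mode {mode!r}")


@dataclass(frozen=True)
class StimulusOffset:
    """Unit-circle Cartesian offset between two angles."""

    delta_x: float
    delta_y: float
    z: float  # chord length, in [0, 2]


def world_angle(p_from: Point, p_to: Point) -> float:
    """World angle (degrees) of the ray p_from -> p_to in image coordinates.

    The image y-axis points down, so it is negated to obtain standard
    mathematical angles.
    """
    dx = p_to[0] - p_from[0]
    dy = -(p_to[1] - p_from[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("coincident points have no direction")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def build_body_frame(centre: Point, axis_ref: Point,
                     viewing_side: str) -> BodyFrame:
    """Construct the body frame from the centre and ventral-midpoint marks."""
    if viewing_side not in CHIRALITY:
        raise ValueError(f"viewing_side must be one of {sorted(CHIRALITY)}")
    if tuple(centre) == tuple(axis_ref):
        raise DegenerateGeometryError(
            "centre and axis reference landmarks coincide"
        )
    return BodyFrame(
        centre=(float(centre[0]), float(centre[1])),
        ventral_axis_angle_world=world_angle(centre, axis_ref),
        chirality=CHIRALITY[viewing_side],
    )


def body_angle_of(frame: BodyFrame, world_deg: float) -> float:
    """Convert a world angle into the body frame."""
    return wrap_deg(frame.chirality * (world_deg - frame.ventral_axis_angle_world))


def body_to_world(frame: BodyFrame, body_deg: float) -> float:
    """Inverse of :func:`body_angle_of`."""
    return wrap_deg(frame.ventral_axis_angle_world + frame.chirality * body_deg)


def tentacle_vector(base: Point, tip: Point, frame: BodyFrame,
                    tentacle_id: str = "", frame_index: int = 0
                    ) -> TentacleObservation:
    """Turn base/tip landmarks into a body-frame tentacle vector."""
    if tuple(base) == tuple(tip):
        raise DegenerateGeometryError(
            f"tentacle {tentacle_id!r} has zero length (base == tip)"
        )
    length = math.dist(base, tip)
    heading = body_angle_of(frame, world_angle(base, tip))
    positional = body_angle_of(frame, world_angle(frame.centre, base))
    return TentacleObservation(
        tentacle_id=tentacle_id,
        frame_index=frame_index,
        heading_body=heading,
        positional_angle_body=positional,
        length=length,
    )


def unit_circle_point(angle_deg: float) -> Point:
    """Project an angle onto the unit circle: (cos, sin)."""
    rad = math.radians(angle_deg)
    return (math.cos(rad), math.sin(rad))


def chord_distance(angle_a_deg: float, angle_b_deg: float) -> StimulusOffset:
    """Unit-circle chord between two angles: z = 2 |sin((a - b) / 2)|.

    Also reports the absolute differences of the Cartesian components,
    matching how the offset enters the directedness regression.
    """
    ax, ay = unit_circle_point(angle_a_deg)
    bx, by = unit_circle_point(angle_b_deg)
    dx = abs(ax - bx)
    dy = abs(ay - by)
    half = math.radians(angle_a_deg - angle_b_deg) / 2.0
    z = 2.0 * abs(math.sin(half))
    return StimulusOffset(delta_x=dx, delta_y=dy, z=z)
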