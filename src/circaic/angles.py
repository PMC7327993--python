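"""Angle containers, wrapping, and circular summary statistics.

All angles are stored internally in radians on the half-open interval
``[0, 2*pi)``.  Degrees appear only at the I/O boundary (see
:mod:`circaic.io`).
"""

from __future__ import annotations

from typing import Iterable, Iterator, Union

import numpy as np

TWO_PI: float = 2.0 * np.pi


def wrap_angles(x) -> np.ndarray:
    """Reduce angles (radians) into ``[0, 2*pi)`` elementwise.

    ``np.mod`` of a tiny negative value rounds to ``2*pi`` itself; such
    values are mapped back to 0 so the half-open invariant always holds.
    """
    out = np.mod(np.asarray(x, dtype=float), TWO_PI)
    return np.where(out >= TWO_PI, 0.0, out)


class AngleSample:
    """An ordered sample of angles on the circle.

    Parameters
    ----------
    angles : array-like
        One-dimensional collection of angles.
    units : {"rad", "deg"}
        Unit of the *input* values.  Internally everything is stored in
        radians, reduced to ``[0, 2*pi)``.

    Notes
    -----
    The stored array is read-only; derived samples (e.g. rotations) are
    new objects.
    """

    __slots__ = ("angles",)

    def __init__(self, angles: Iterable[float], units: str = "rad") -> None:
        a = np.atleast_1d(np.asarray(angles, dtype=float))
        if a.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if a.size < 1:
            raise ValueError("an AngleSample needs at least one angle")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        if units == "deg":
            a = np.deg2rad(a)
        elif units != "rad":
            raise ValueError(f"unknown units {units!r}; use 'rad' or 'deg'")
        a = wrap_angles(a)
        a.setflags(write=False)
        self.angles = a

    @property
    def n(self) -> int:
        return int(self.angles.size)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[float]:
        return iter(self.angles)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        head = np.array2string(self.angles[:4], precision=4)
        more = "..." if self.n > 4 else ""
        return f"AngleSample(n={self.n}, angles={head}{more})"

    def rotated(self, offset: float) -> "AngleSample":
        """Return a new sample with ``offset`` (radians) added to every angle."""
        return AngleSample(self.angles + offset)


Angles = Union[AngleSample, Iterable[float], np.ndarray]


def as_angle_sample(x: Angles, units: str = "rad") -> AngleSample:
    """Coerce an array-like or :class:`AngleSample` into an :class:`AngleSample`."""
    if isinstance(x, AngleSample):
        return x
    return AngleSample(x, units=units)


# ---------------------------------------------------------------------------
# circular summaries
# ---------------------------------------------------------------------------

def resultant_length(x: Angles) -> float:
    """Mean resultant length ``Rbar`` of a sample.

    ``Rbar = |sum_j exp(i*theta_j)| / n``; 0 for perfectly dispersed data,
    1 when all angles coincide.
    """
    a = as_angle_sample(x).angles
    return float(np.hypot(np.cos(a).sum(), np.sin(a).sum()) / a.size)


def circular_mean(x: Angles) -> float:
    """Mean direction of a sample, in ``[0, 2*pi)``.

    Undefined (returns 0.0) when the resultant vector is numerically null.
    """
    a = as_angle_sample(x).angles
    s, c = np.sin(a).sum(), np.cos(a).sum()
    if np.hypot(c, s) < 1e-12:
        return 0.0
    return float(np.mod(np.arctan2(s, c), TWO_PI))


def axial_mean(x: Angles) -> float:
    """Mean axis orientation, in ``[0, pi)``.

    Computed by the angle-doubling device: the mean direction of
    ``2*theta`` halved.  Appropriate initial guess for axially bimodal
    (modes 180 degrees apart) data.
    """
    a = as_angle_sample(x).angles
    s, c = np.sin(2 * a).sum(), np.cos(2 * a).sum()
    if np.hypot(c, s) < 1e-12:
        return 0.0
    return float(np.mod(0.5 * np.arctan2(s, c), np.pi))


def circular_dist(a: float, b: float) -> float:
    """Smallest absolute angular distance between two directions (radians)."""
    d = np.mod(a - b, TWO_PI)
    return float(min(d, TWO_PI - d))
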