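"""Prosthetic valve design variables: nominal size and vacancy angle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AVAILABLE_SIZES", "ValveDesign", "snap_size"]

#: Nominal self-expanding frame sizes (diameters, mm) on the market.
AVAILABLE_SIZES: tuple[float, ...] = (23.0, 26.0, 29.0, 31.0)


@dataclass(frozen=True)
class ValveDesign:
    """A candidate prosthesis: nominal size plus conduction-sparing vacancy.

    Attributes
    ----------
    size : float
        Nominal device size (diameter), mm.
    theta_deg : float
        Vacancy angle of the cylindrical sector removed from the frame,
        degrees, centered on the conduction-system zone.  0 means a complete
        (unmodified) frame.
    """

    size: float
    theta_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"valve size must be positive, got {self.size}")
        if not (0.0 <= self.theta_deg < 360.0):
            raise ValueError(
                f"vacancy angle must lie in [0, 360) degrees, got {self.theta_deg}"
            )


def snap_size(size: float, available: tuple[float, ...] = AVAILABLE_SIZES) -> float:
    """Snap a continuous size to the nearest available nominal size.

    Ties break toward the smaller device (conservative oversizing).
    """
    sizes = np.asarray(sorted(available), dtype=float)
    dist = np.abs(sizes - size)
    return float(sizes[int(np.argmin(dist))])
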