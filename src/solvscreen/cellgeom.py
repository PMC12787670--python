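"""Unit-cell geometry: volume from lattice parameters.

Angles are accepted in degrees (crystallographic convention).  The volume
follows the metric-tensor expression

    V = abc * sqrt(1 - cos^2(alpha) - cos^2(beta) - cos^2(gamma)
                     + 2 cos(alpha) cos(beta) cos(gamma))

which reduces to ``abc`` for orthogonal cells and to ``abc sin(beta)`` for
monoclinic ones (alpha = gamma = 90 deg).  Standard uncertainties printed
in parentheses are not parsed; inputs are plain numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["UnitCell", "cell_volume"]


@dataclass(frozen=True)
class UnitCell:
    """Lattice parameters: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            angle = getattr(self, name)
            if not 0.0 < angle < 180.0:
                raise ValueError(
                    f"cell angle {name}={angle} must lie in (0, 180) degrees"
                )
        if self._metric_discriminant() <= 0:
            raise ValueError(
                "invalid cell: the three angles admit no positive metric "
                "determinant"
            )

    def _metric_discriminant(self) -> float:
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in cubic angstroms."""
        return self.a * self.b * self.c * math.sqrt(
            self._metric_discriminant()
        )


def cell_volume(
    a: float, b: float, c: float, alpha: float, beta: float, gamma: float
) -> float:
    """Unit-cell volume (cubic angstrom) from lengths (angstrom) and
    angles (degrees)."""
    return UnitCell(a, b, c, alpha, beta, gamma).volume
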