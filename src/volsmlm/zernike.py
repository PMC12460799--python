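"""Real Zernike polynomials on the unit disk, unit-RMS (Noll) normalized.

Wavefront aberrations are described by a small set of named low-order modes
(astigmatism, coma, spherical, trefoil, ...).  Amplitudes are carried in
nm RMS of optical path difference; with the Noll normalization used here the
RMS of ``a * Z_n^m`` over the unit disk is exactly ``a``.

Piston, tip, tilt and defocus are excluded from the correctable set: piston
is invisible, tip/tilt only translate the image, and defocus is the axial
coordinate itself in an astigmatic localization scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODE_INDICES",
    "DEFAULT_CORRECTION_MODES",
    "ZernikeCoeffs",
    "zernike_polynomial",
]

#: Mode label -> (n, m) radial/azimuthal indices (m<0 = sine term).
MODE_INDICES: dict[str, tuple[int, int]] = {
    "astig_oblique": (2, -2),
    "astig_vertical": (2, 2),
    "coma_vertical": (3, -1),
    "coma_horizontal": (3, 1),
    "trefoil_vertical": (3, -3),
    "trefoil_horizontal": (3, 3),
    "spherical": (4, 0),
    "astig2_oblique": (4, -2),
    "astig2_vertical": (4, 2),
}

#: The seven modes corrected by default, in correction order: astigmatism
#: (vertical, oblique), coma (vertical, horizontal), first-order spherical,
#: trefoil (vertical, horizontal).
DEFAULT_CORRECTION_MODES: tuple[str, ...] = (
    "astig_vertical",
    "astig_oblique",
    "coma_vertical",
    "coma_horizontal",
    "spherical",
    "trefoil_vertical",
    "trefoil_horizontal",
)


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^{|m|}(rho)."""
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_polynomial(mode: str, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the unit-RMS Zernike polynomial for a named mode.

    Parameters
    ----------
    mode
        One of the labels in :data:`MODE_INDICES`.
    rho, theta
        Polar pupil coordinates; ``rho`` in [0, 1].
    """
    try:
        n, m = MODE_INDICES[mode]
    except KeyError as exc:
        raise KeyError(f"unknown Zernike mode {mode!r}") from exc
    m_abs = abs(m)
    r = _radial(n, m_abs, rho)
    if m == 0:
        return math.sqrt(n + 1) * r
    norm = math.sqrt(2 * (n + 1))
    if m > 0:
        return norm * r * np.cos(m_abs * theta)
    return norm * r * np.sin(m_abs * theta)


@dataclass
class ZernikeCoeffs:
    """Modal wavefront description; amplitudes in nm RMS per mode.

    Modes absent from ``coefficients`` are zero.  Arithmetic helpers return
    new objects; instances are treated as immutable by the rest of the code.
    """

    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mode, amp in self.coefficients.items():
            if mode not in MODE_INDICES:
                raise KeyError(f"unknown Zernike mode {mode!r}")
            if not np.isfinite(amp):
                raise ValueError(f"non-finite amplitude for mode {mode!r}")

    def get(self, mode: str) -> float:
        return float(self.coefficients.get(mode, 0.0))

    def with_mode(self, mode: str, amplitude_nm: float) -> "ZernikeCoeffs":
        new = dict(self.coefficients)
        new[mode] = float(amplitude_nm)
        return ZernikeCoeffs(new)

    def add(self, other: "ZernikeCoeffs") -> "ZernikeCoeffs":
        new = dict(self.coefficients)
        for mode, amp in other.coefficients.items():
            new[mode] = new.get(mode, 0.0) + amp
        return ZernikeCoeffs(new)

    def total_rms_nm(self, modes: "list[str] | None" = None) -> float:
        """Root-sum-square amplitude over ``modes`` (all modes if None)."""
        if modes is None:
            modes = list(self.coefficients)
        return float(np.sqrt(sum(self.get(m) ** 2 for m in modes)))

    def wavefront_nm(self, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Sum the modal expansion on a pupil grid; nm of optical path."""
        w = np.zeros_like(rho)
        for mode, amp in self.coefficients.items():
            if amp != 0.0:
                w = w + amp * zernike_polynomial(mode, rho, theta)
        return w
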