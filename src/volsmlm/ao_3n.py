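"""Sensorless modal adaptive optics: the 3N correction algorithm.

Each Zernike mode is probed at three coefficients (+α, 0, −α) around the
current correction, an image-quality merit factor is measured for each, a
parabola is fitted through the three samples and the correction jumps to its
extremum.  The merit factor is the inverse of the maximum pixel intensity of
a point-source image (lower is better), which is well suited to single
point-source objects: any aberration spreads the PSF and lowers its peak.

The sweep over all modes is repeated for a small number of iterations
(typically 2–3) with a probe amplitude α = 60 nm RMS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .zernike import DEFAULT_CORRECTION_MODES, ZernikeCoeffs

__all__ = [
    "MeritEvaluation",
    "CorrectionState",
    "evaluate_merit",
    "parabola_vertex",
    "run_3n",
]

logger = logging.getLogger(__name__)


@dataclass
class MeritEvaluation:
    """One mode probe: merits at (−α, 0, +α) and the fitted optimum."""

    mode: str
    sampled_coeffs: tuple[float, float, float]
    merits: tuple[float, float, float]
    alpha_opt_nm: float
    convex: bool = True


@dataclass
class CorrectionState:
    """Accumulated correction plus the per-probe log."""

    correction: ZernikeCoeffs
    log: list[MeritEvaluation] = field(default_factory=list)
    initial_merit: float = float("nan")
    final_merit: float = float("nan")


def evaluate_merit(image: np.ndarray, baseline: float = 0.0) -> float:
    """Inverse of the maximum pixel intensity (after baseline subtraction).

    Lower is better.  ``baseline`` defaults to 0 (raw maxima); subtracting
    the camera baseline makes the merit reflect signal rather than offset.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    peak = float(image.max()) - baseline
    if peak <= 0:
        raise ValueError("merit undefined: no signal above baseline")
    return 1.0 / peak


def parabola_vertex(
    merits: tuple[float, float, float], alpha_nm: float
) -> tuple[float, bool]:
    """Vertex of the parabola through merits sampled at (−α, 0, +α).

    Returns ``(alpha_opt_nm, convex)``.  For positive curvature the vertex

        α_opt = α (m− − m+) / (2 (m− − 2 m0 + m+))

    is clamped to [−α, +α].  Non-convex or flat triplets fall back to the
    best sampled coefficient and are flagged ``convex=False``.
    """
    if alpha_nm <= 0:
        raise ValueError("alpha_nm must be > 0")
    m_minus, m_0, m_plus = merits
    if not np.all(np.isfinite(merits)):
        raise ValueError("non-finite merit values")
    curvature = m_minus - 2.0 * m_0 + m_plus
    if curvature > 0:
        alpha_opt = alpha_nm * (m_minus - m_plus) / (2.0 * curvature)
        return float(np.clip(alpha_opt, -alpha_nm, alpha_nm)), True
    best = int(np.argmin(merits))
    return float((-alpha_nm, 0.0, alpha_nm)[best]), False


def run_3n(
    system: Callable[[ZernikeCoeffs], np.ndarray],
    modes: Sequence[str] = DEFAULT_CORRECTION_MODES,
    alpha_nm: float = 60.0,
    iterations: int = 3,
    initial: ZernikeCoeffs | None = None,
    *,
    baseline: float = 0.0,
    n_average: int = 1,
) -> CorrectionState:
    """Run the 3N sensorless correction loop.

    Parameters
    ----------
    system
        Callable mapping a correction :class:`ZernikeCoeffs` to a point
        source image (e.g. a simulated or measured bead frame).
    modes
        Ordered mode labels to correct; default is the seven first
        aberration modes (astigmatism V/O, coma V/H, spherical, trefoil V/H).
    alpha_nm
        Probe amplitude α in nm RMS (default 60).
    iterations
        Full sweeps over the mode list (typically 2–3).
    n_average
        Frames averaged per merit evaluation (for noisy systems).
    """
    if not modes:
        raise ValueError("modes must be non-empty")
    state = CorrectionState(correction=initial if initial is not None else ZernikeCoeffs())

    def merit_of(coeffs: ZernikeCoeffs) -> float:
        vals = [evaluate_merit(system(coeffs), baseline) for _ in range(n_average)]
        return float(np.mean(vals))

    state.initial_merit = merit_of(state.correction)
    for _ in range(iterations):
        for mode in modes:
            base = state.correction.get(mode)
            probes = (base - alpha_nm, base, base + alpha_nm)
            merits = tuple(
                merit_of(state.correction.with_mode(mode, c)) for c in probes
            )
            alpha_opt, convex = parabola_vertex(merits, alpha_nm)
            if not convex:
                logger.warning(
                    "non-convex merit triplet for mode %s; taking best sample", mode
                )
            state.correction = state.correction.with_mode(mode, base + alpha_opt)
            state.log.append(
                MeritEvaluation(
                    mode=mode,
                    sampled_coeffs=probes,
                    merits=merits,
                    alpha_opt_nm=alpha_opt,
                    convex=convex,
                )
            )
    state.final_merit = merit_of(state.correction)
    return state
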