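"""UV/IR/DOS spectral summaries and line broadening.

Excitation line lists are reduced to a wavelength-of-maximum-absorption
summary (the highest-oscillator-strength line) plus the adsorption-induced
shift against a reference spectrum; stick spectra are broadened into
smooth curves for DOS/IR-style presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import GqdError
from .records import ExcitationLine
from .units import HC_EV_NM

DOS_BROADENING_EV = 0.3      # presentation default, Gaussian FWHM
IR_BROADENING_CM1 = 8.0      # presentation default, Lorentzian FWHM
GRID_POINTS = 1000


def eex_from_lambda(lambda_nm: float) -> float:
    """Exciton energy in eV from a wavelength in nm (E = hc/lambda)."""
    if lambda_nm <= 0:
        raise GqdError(f"wavelength must be positive, got {lambda_nm}")
    return HC_EV_NM / lambda_nm


@dataclass(frozen=True)
class UVSummary:
    """Per-species UV summary: peaks ranked by oscillator strength."""

    label: str
    peaks: tuple[ExcitationLine, ...]
    lambda_max: float
    shift_vs_reference: Optional[float] = None  # nm; positive = red shift


def uv_summary(
    label: str,
    excitations: Sequence[ExcitationLine],
    reference: Optional[UVSummary] = None,
) -> UVSummary:
    """Summarize an excitation list; lambda_max is the strongest line.

    With a reference (the bare sensor), the shift is complex lambda_max
    minus sensor lambda_max, so a red shift is positive.
    """
    if not excitations:
        raise GqdError(f"{label}: cannot summarize an empty excitation list")
    peaks = tuple(sorted(excitations, key=lambda ln: ln.f_osc, reverse=True))
    lam = peaks[0].lambda_nm
    shift = None if reference is None else lam - reference.lambda_max
    return UVSummary(label=label, peaks=peaks, lambda_max=lam, shift_vs_reference=shift)


@dataclass(frozen=True)
class SpectrumCurve:
    """A broadened spectrum on a strictly increasing grid."""

    grid: np.ndarray
    intensity: np.ndarray
    broadening_width: float
    kernel: Literal["gaussian", "lorentzian"]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise GqdError("spectrum grid must be strictly increasing")


def broaden(
    lines: Sequence[tuple[float, float]],
    width: float,
    kernel: Literal["gaussian", "lorentzian"] = "gaussian",
    grid: Optional[np.ndarray] = None,
    n_points: int = GRID_POINTS,
) -> SpectrumCurve:
    """Convolve a stick spectrum with unit-area kernels of FWHM ``width``.

    Each line contributes its intensity times a normalized kernel, so the
    integral of the curve over a wide grid approaches the summed stick
    intensities. With no explicit grid, one spanning all lines plus a
    5-FWHM margin is built.
    """
    if width <= 0:
        raise GqdError(f"broadening width must be positive, got {width}")
    if grid is None:
        if lines:
            lo = min(p for p, _ in lines) - 5 * width
            hi = max(p for p, _ in lines) + 5 * width
        else:
            lo, hi = 0.0, 1.0
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)
    intensity = np.zeros_like(grid)
    if kernel == "gaussian":
        sigma = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        for pos, amp in lines:
            intensity += amp * np.exp(-0.5 * ((grid - pos) / sigma) ** 2) / (
                sigma * math.sqrt(2.0 * math.pi)
            )
    elif kernel == "lorentzian":
        gamma = width / 2.0
        for pos, amp in lines:
            intensity += amp * (gamma / math.pi) / ((grid - pos) ** 2 + gamma**2)
    else:
        raise GqdError(f"unknown kernel {kernel!r}")
    return SpectrumCurve(grid=grid, intensity=intensity, broadening_width=width, kernel=kernel)


def dos_gap(occupied_levels: Sequence[float], virtual_levels: Sequence[float]) -> float:
    """Gap between the highest occupied and lowest virtual level (eV).

    Equals the frontier gap when only the HOMO/LUMO are supplied.
    Overlapping level sets are floored at zero with a warning.
    """
    if not len(occupied_levels) or not len(virtual_levels):
        raise GqdError("dos_gap requires non-empty occupied and virtual level lists")
    gap = min(virtual_levels) - max(occupied_levels)
    if gap < 0:
        warnings.warn(
            f"occupied and virtual levels overlap (raw gap {gap:.3f} eV); flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return gap
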