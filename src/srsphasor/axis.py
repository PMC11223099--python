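"""Wavenumber-axis construction for hyperspectral SRS acquisition.

A hyperspectral stimulated Raman scattering (SRS) stack is acquired by holding
the Stokes beam fixed and retuning the pump laser in equal *wavelength* steps
between frames.  The probed Raman shift of a frame is

    shift(lambda_pump) = 1e7 / lambda_pump - 1e7 / lambda_stokes   [cm^-1]

with wavelengths in nm, so the resulting wavenumber grid is slightly
non-uniform in cm^-1 even though the retune grid is uniform in nm.
:func:`build_wavenumber_axis` reproduces that acquisition geometry exactly:
frames are acquired from the high-shift end (shortest pump wavelength)
downward, and the axis is stored in ascending wavenumber order with the
acquisition order recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateAxisError, InvalidParameterError

__all__ = ["WavenumberAxis", "build_wavenumber_axis", "raman_shift", "pump_wavelength"]

#: tolerance (cm^-1) for checking that axis values sit on the pump retune grid
GRID_TOL_CM1 = 0.05


def raman_shift(pump_nm: float | np.ndarray, stokes_nm: float) -> float | np.ndarray:
    """Raman shift (cm^-1) probed by a pump/Stokes wavelength pair (nm)."""
    return 1e7 / np.asarray(pump_nm, dtype=float) - 1e7 / stokes_nm


def pump_wavelength(shift_cm1: float | np.ndarray, stokes_nm: float) -> float | np.ndarray:
    """Pump wavelength (nm) needed to probe a Raman shift against a Stokes beam."""
    return 1e7 / (1e7 / stokes_nm + np.asarray(shift_cm1, dtype=float))


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered Raman-shift axis of a hyperspectral stack.

    Parameters
    ----------
    values : ndarray
        Raman shifts in cm^-1, strictly ascending, all within [0, 5000].
    stokes_wavelength : float or None
        Stokes wavelength in nm.  ``None`` for axes of unknown provenance
        (e.g. two hand-picked imaging frequencies); the retune-grid
        consistency check is then skipped.
    retune_step : float or None
        Pump retune increment in nm between consecutive frames.
    acquisition_order : str
        ``"descending"`` when frames were acquired high-shift first (the
        pump retunes toward longer wavelengths), else ``"ascending"``.
    """

    values: np.ndarray
    stokes_wavelength: float | None = None
    retune_step: float | None = None
    acquisition_order: str = "ascending"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise DegenerateAxisError("axis needs at least 2 wavenumber values")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("axis values must be finite")
        if np.any(values < 0) or np.any(values > 5000):
            raise InvalidParameterError("axis values must lie within [0, 5000] cm^-1")
        if not np.all(np.diff(values) > 0):
            raise InvalidParameterError("axis values must be strictly ascending")
        if self.acquisition_order not in ("ascending", "descending"):
            raise InvalidParameterError(
                f"acquisition_order must be 'ascending' or 'descending', "
                f"got {self.acquisition_order!r}"
            )
        if self.stokes_wavelength is not None and self.retune_step is not None:
            self._check_retune_grid()

    def _check_retune_grid(self):
        """Each value must match shift(lambda) for a lambda on the retune grid."""
        lam = pump_wavelength(self.values, self.stokes_wavelength)
        steps = (lam - lam.min()) / self.retune_step
        on_grid = raman_shift(
            lam.min() + np.round(steps) * self.retune_step, self.stokes_wavelength
        )
        err = np.abs(on_grid - self.values)
        if np.any(err > GRID_TOL_CM1):
            raise InvalidParameterError(
                f"axis values deviate from the pump retune grid by up to "
                f"{err.max():.3g} cm^-1 (tolerance {GRID_TOL_CM1})"
            )

    @property
    def n_channels(self) -> int:
        return int(self.values.size)

    @property
    def pump_wavelengths(self) -> np.ndarray:
        """Pump wavelengths (nm) in *acquisition* order."""
        if self.stokes_wavelength is None:
            raise InvalidParameterError("axis has no Stokes wavelength recorded")
        vals = self.values[::-1] if self.acquisition_order == "descending" else self.values
        return pump_wavelength(vals, self.stokes_wavelength)

    def index_of(self, shift_cm1: float, tol: float = 5.0) -> int:
        """Index of the channel nearest ``shift_cm1``; error beyond ``tol`` cm^-1."""
        from .errors import AxisMismatchError

        idx = int(np.argmin(np.abs(self.values - shift_cm1)))
        if abs(self.values[idx] - shift_cm1) > tol:
            raise AxisMismatchError(
                f"no channel within {tol} cm^-1 of {shift_cm1} cm^-1 "
                f"(nearest is {self.values[idx]:.1f})"
            )
        return idx


def build_wavenumber_axis(
    stokes_nm: float,
    shift_start: float,
    shift_end: float,
    retune_step_nm: float,
) -> WavenumberAxis:
    """Build the wavenumber axis of a pump-retuned hyperspectral acquisition.

    The pump starts at the wavelength probing ``shift_end`` (the high-shift
    end of the window) and steps toward longer wavelengths in increments of
    ``retune_step_nm``, taking one frame per step, up to and including the
    last step that does not pass ``shift_start``.  The frame count is
    therefore ``floor(|delta lambda| / step) + 1``.

    Parameters
    ----------
    stokes_nm : float
        Stokes wavelength in nm (e.g. 1031.4).
    shift_start, shift_end : float
        Raman-shift window in cm^-1 (e.g. 2800 and 3050).
    retune_step_nm : float
        Pump retune increment in nm (e.g. 0.4).

    Returns
    -------
    WavenumberAxis
        Values ascending in cm^-1, ``acquisition_order="descending"``.
    """
    if not np.isfinite(stokes_nm) or stokes_nm <= 0:
        raise InvalidParameterError(f"stokes_nm must be positive, got {stokes_nm}")
    if not np.isfinite(retune_step_nm) or retune_step_nm <= 0:
        raise InvalidParameterError(f"retune_step_nm must be positive, got {retune_step_nm}")
    if not (np.isfinite(shift_start) and np.isfinite(shift_end)):
        raise InvalidParameterError("shift window must be finite")
    if shift_start == shift_end:
        raise DegenerateAxisError("shift_start == shift_end gives an empty window")

    lo, hi = sorted((float(shift_start), float(shift_end)))
    lam_first = pump_wavelength(hi, stokes_nm)   # shortest pump wavelength
    lam_last = pump_wavelength(lo, stokes_nm)    # longest pump wavelength
    # 1e-9 nm guard so an exactly-on-grid endpoint is included despite rounding
    n = int(np.floor((lam_last - lam_first) / retune_step_nm + 1e-9)) + 1
    if n < 2:
        raise DegenerateAxisError(
            f"window [{lo}, {hi}] cm^-1 spans fewer than 2 frames at "
            f"{retune_step_nm} nm retune"
        )
    pump = lam_first + retune_step_nm * np.arange(n)
    shifts = raman_shift(pump, stokes_nm)        # descending
    return WavenumberAxis(
        values=shifts[::-1].copy(),
        stokes_wavelength=float(stokes_nm),
        retune_step=float(retune_step_nm),
        acquisition_order="descending",
    )
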