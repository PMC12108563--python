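"""Wear-rate estimation from gravimetric joint-simulator series.

Implements the ISO-14243-2-style bookkeeping used for cyclic wear tests of
joint prostheses: the net mass loss after n cycles, W_n, is the measured
specimen loss corrected by the soak-control mass change, and the average
wear rate is the slope of the linear model W_n = a*n + b fitted by ordinary
least squares.  Mass rates convert to volumetric rates through the bearing
material's density.

The cyclic test kinematics (rotation amplitude, anterior/posterior and
medial/lateral translations, load, total cycle count) are carried as scenario
metadata only — no tribological wear model is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WearSeries",
    "WearResult",
    "net_mass_loss",
    "wear_rate",
    "mass_to_volume",
    "compression_load_split",
    "WEAR_SCENARIO",
    "UHMWPE_DENSITY_MG_MM3",
    "TI6AL4V_DENSITY_MG_MM3",
]

#: UHMWPE density in mg/mm^3 (bearing-grade polyethylene; configurable).
UHMWPE_DENSITY_MG_MM3 = 0.93
#: Ti-6Al-4V density in mg/mm^3.
TI6AL4V_DENSITY_MG_MM3 = 4.43

#: Cyclic-test scenario constants (metadata, not simulated): a 12 deg
#: condylar rotation combined with 8.5 mm anterior/posterior and 0.7 mm
#: medial/lateral translation under a constant 20 N chewing load, run for
#: 5 million cycles and read out gravimetrically every 500,000 cycles.
WEAR_SCENARIO = dict(
    rotation_deg=12.0,
    translation_ap_mm=8.5,
    translation_ml_mm=0.7,
    load_N=20.0,
    total_cycles=5_000_000,
    readout_step_cycles=500_000,
)


@dataclass
class WearSeries:
    """Cumulative gravimetric readings at increasing cycle counts.

    ``specimen_loss`` is the measured cumulative mass loss of the specimen
    (mg, loss positive); ``soak_change`` is the apparent mass loss of the
    unloaded soak control (mg, loss positive — a fluid-absorption *gain*
    therefore enters as a negative value).
    """

    cycles: np.ndarray
    specimen_loss: np.ndarray
    soak_change: np.ndarray = None

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.specimen_loss = np.asarray(self.specimen_loss, dtype=float)
        if self.soak_change is None:
            self.soak_change = np.zeros_like(self.cycles)
        self.soak_change = np.asarray(self.soak_change, dtype=float)
        if not (len(self.cycles) == len(self.specimen_loss)
                == len(self.soak_change)):
            raise ValueError("series columns must have equal length")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycle counts must be strictly increasing")


@dataclass
class WearResult:
    """Average wear rate and derived quantities."""

    rate_mg_per_Mc: float          # slope a, mg per 10^6 cycles
    intercept_mg: float            # constant b
    volumetric_mm3_per_Mc: float   # rate / density; nan when density unset
    interval_rates_mg_per_Mc: np.ndarray = field(default=None)
    interval_cycles: np.ndarray = field(default=None)
    density_mg_mm3: float = None


def net_mass_loss(series: WearSeries) -> np.ndarray:
    """Net loss W_n = specimen loss corrected by the soak control.

    The soak-control *gain* is added: with loss-positive sign convention,
    W_n = specimen_loss - soak_change.
    """
    return series.specimen_loss - series.soak_change


def wear_rate(W: np.ndarray, cycles: np.ndarray,
              density_mg_mm3: float | None = None) -> WearResult:
    """Fit W_n = a*n + b by ordinary least squares.

    Returns the slope rescaled to mg per 10^6 cycles, the intercept b (mg),
    the volumetric rate if a density is given, and per-interval secant rates
    for step-wise plotting.
    """
    W = np.asarray(W, dtype=float)
    n = np.asarray(cycles, dtype=float)
    if len(W) != len(n):
        raise ValueError("W and cycles must have equal length")
    if len(n) < 2:
        raise ValueError("at least 2 points required")
    if np.ptp(n) == 0:
        raise ValueError("all cycle counts identical; regression impossible")
    # centred OLS for numerical stability at n ~ 10^6
    nm, Wm = n.mean(), W.mean()
    a = float(np.sum((n - nm) * (W - Wm)) / np.sum((n - nm) ** 2))
    b = float(Wm - a * nm)
    rate = a * 1e6
    dW = np.diff(W)
    dn = np.diff(n)
    vol = rate / density_mg_mm3 if density_mg_mm3 else float("nan")
    return WearResult(rate_mg_per_Mc=rate, intercept_mg=b,
                      volumetric_mm3_per_Mc=vol,
                      interval_rates_mg_per_Mc=dW / dn * 1e6,
                      interval_cycles=n[1:],
                      density_mg_mm3=density_mg_mm3)


def mass_to_volume(rate_mg_per_Mc: float, density_mg_mm3: float) -> float:
    """Convert a mass wear rate (mg/10^6 cycles) to mm^3/10^6 cycles."""
    if density_mg_mm3 <= 0:
        raise ValueError("density must be positive")
    return rate_mg_per_Mc / density_mg_mm3


def compression_load_split(total_N: float,
                           ipsilateral_fraction: float = 0.7):
    """Split a compression load between the treated and the opposite side.

    Returns ``(ipsilateral_N, contralateral_N)``; the default 70/30 split
    places most of the load on the side of the defect.
    """
    f = float(ipsilateral_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"ipsilateral fraction must be in [0, 1], got {f}")
    return total_N * f, total_N * (1.0 - f)
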