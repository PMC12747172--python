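"""Optical density conversion and modified Beer-Lambert inversion.

Conventions
-----------
* OD change is the natural log of the ratio of intensity to its temporal
  mean, ``od(t) = -ln(I(t) / mean_t(I))`` (Homer convention); the choice
  of reference only shifts the baseline.
* Extinction coefficients are shipped as a documented constant table in
  cm^-1 mM^-1 (compiled Gratzer/Prahl values at 760 and 850 nm) and can
  be overridden.
* Concentration outputs are in uM; source-detector separations from the
  montage are in mm and converted to cm internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nirsqc.signal_io import Recording

#: extinction coefficients [cm^-1 mM^-1]: wavelength -> (eps_HbO, eps_HbR)
DEFAULT_EXTINCTION = {
    760.0: (0.5864, 1.5485),
    850.0: (1.0580, 0.6913),
}

DEFAULT_DPF = 6.0

# Coefficients of the general wavelength/age DPF equation
# (cubic in wavelength, power law in age).
_DPF_A = 223.3
_DPF_B = 0.05624
_DPF_G = 0.8493
_DPF_C3 = -5.723e-7
_DPF_C2 = 1.245e-3
_DPF_C1 = -0.9025


@dataclass
class ODSeries:
    """Dimensionless optical-density change, shape (time, channel, 2)."""

    od: np.ndarray

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValueError("OD series contains non-finite values")


@dataclass
class HbSeries:
    """Oxy/deoxyhemoglobin concentration change in uM, shape (time, channel)."""

    hbo: np.ndarray
    hbr: np.ndarray

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share a shape")


@dataclass
class MbllParams:
    """Per-channel geometry and optics for the modified Beer-Lambert law.

    Attributes
    ----------
    extinction : ndarray, shape (2, 2)
        Rows are wavelengths, columns (eps_HbO, eps_HbR), in cm^-1 mM^-1.
    dpf : ndarray, shape (2,)
        Differential pathlength factor per wavelength.
    separation_cm : ndarray, shape (n_channels,)
        Source-detector separation in cm.
    """

    extinction: np.ndarray
    dpf: np.ndarray
    separation_cm: np.ndarray

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.dpf = np.atleast_1d(np.asarray(self.dpf, dtype=float))
        if self.dpf.size == 1:
            self.dpf = np.repeat(self.dpf, 2)
        self.separation_cm = np.atleast_1d(np.asarray(self.separation_cm, dtype=float))
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if np.any(self.dpf <= 0) or np.any(self.separation_cm <= 0):
            raise ValueError("dpf and separation must be positive")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")

    @classmethod
    def for_recording(
        cls,
        rec: Recording,
        extinction_table: dict[float, tuple[float, float]] | None = None,
        dpf: float | str | None = None,
    ) -> "MbllParams":
        """Build parameters from a recording's wavelengths, montage and age.

        ``dpf`` may be a scalar, ``"age"`` (use the age-dependent formula,
        falling back to the default 6 when age is unknown), or None
        (default 6).
        """
        table = extinction_table or DEFAULT_EXTINCTION
        ext = np.array([_lookup_extinction(table, wl) for wl in rec.wavelengths])
        if dpf == "age":
            dpf_vec = np.array([dpf_for_age(rec.age, wl) for wl in rec.wavelengths])
        elif dpf is None:
            dpf_vec = np.array([DEFAULT_DPF, DEFAULT_DPF])
        else:
            dpf_vec = np.array([float(dpf), float(dpf)])
        if rec.montage:
            sep = np.array([g.separation_mm for g in rec.montage]) / 10.0
        else:
            sep = np.full(rec.n_channels, 3.0)
        return cls(extinction=ext, dpf=dpf_vec, separation_cm=sep)


def _lookup_extinction(table, wavelength, tol_nm: float = 25.0):
    best = min(table, key=lambda wl: abs(wl - wavelength))
    if abs(best - wavelength) > tol_nm:
        raise ValueError(
            f"no extinction entry within {tol_nm} nm of {wavelength} nm"
        )
    return table[best]


def intensity_to_od(intensity: np.ndarray) -> ODSeries:
    """Convert strictly positive intensity to OD change.

    ``od(t) = -ln(I(t) / mean_t(I))`` per (channel, wavelength) column.
    """
    intensity = np.asarray(intensity, dtype=float)
    nonpos = ~(intensity > 0)
    if np.any(nonpos):
        idx = tuple(int(i) for i in np.argwhere(nonpos)[0])
        raise ValueError(
            f"nonpositive intensity at (sample, channel, wavelength) = {idx}"
        )
    mean = intensity.mean(axis=0, keepdims=True)
    return ODSeries(od=-np.log(intensity / mean))


def mbll(od: ODSeries, params: MbllParams) -> HbSeries:
    """Invert the modified Beer-Lambert law channel by channel.

    Solves, for each channel and time point, the 2x2 system

        dOD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * dpf(lambda)

    for (dHbO, dHbR); output in uM.
    """
    x = od.od
    n_t, n_ch, _ = x.shape
    sep = params.separation_cm
    if sep.size == 1:
        sep = np.repeat(sep, n_ch)
    if sep.size != n_ch:
        raise ValueError("separation vector does not match channel count")
    hbo = np.empty((n_t, n_ch))
    hbr = np.empty((n_t, n_ch))
    for ch in range(n_ch):
        # system matrix in mM: row per wavelength
        m = params.extinction * (params.dpf * sep[ch])[:, None]
        inv = np.linalg.inv(m)
        conc = x[:, ch, :] @ inv.T  # (time, 2) in mM
        hbo[:, ch] = conc[:, 0] * 1e3
        hbr[:, ch] = conc[:, 1] * 1e3
    return HbSeries(hbo=hbo, hbr=hbr)


def forward_mbll(hbo_um: np.ndarray, hbr_um: np.ndarray, params: MbllParams) -> np.ndarray:
    """Forward model: concentrations in uM -> OD change (time, channel, 2).

    The exact inverse of :func:`mbll`; used by the simulator and in
    round-trip testing.
    """
    hbo_um = np.atleast_2d(np.asarray(hbo_um, dtype=float))
    hbr_um = np.atleast_2d(np.asarray(hbr_um, dtype=float))
    n_t, n_ch = hbo_um.shape
    sep = params.separation_cm
    if sep.size == 1:
        sep = np.repeat(sep, n_ch)
    od = np.empty((n_t, n_ch, 2))
    conc_mm = np.stack([hbo_um, hbr_um], axis=-1) * 1e-3
    for ch in range(n_ch):
        m = params.extinction * (params.dpf * sep[ch])[:, None]
        od[:, ch, :] = conc_mm[:, ch, :] @ m.T
    return od


def dpf_for_age(age: float | None, wavelength: float) -> float:
    """Differential pathlength factor.

    Without an age the fixed default of 6 is used. With an age, the
    general DPF(wavelength, age) equation (power law in age plus a cubic
    wavelength correction) is evaluated.
    """
    if age is None:
        return DEFAULT_DPF
    if not (0 < age < 120):
        raise ValueError(f"age out of range (0, 120): {age}")
    lam = float(wavelength)
    return (
        _DPF_A
        + _DPF_B * age ** _DPF_G
        + _DPF_C3 * lam**3
        + _DPF_C2 * lam**2
        + _DPF_C1 * lam
    )


def recording_to_hb(
    rec: Recording,
    extinction_table: dict[float, tuple[float, float]] | None = None,
    dpf: float | str | None = None,
) -> HbSeries:
    """Intensity -> OD -> hemoglobin concentration changes for a recording."""
    od = intensity_to_od(rec.intensity)
    params = MbllParams.for_recording(rec, extinction_table=extinction_table, dpf=dpf)
    return mbll(od, params)
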