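"""Spectral component models: Mössbauer doublets and powder EPR.

Zero-field 57Fe Mössbauer spectra of [2Fe-2S] clusters are quadrupole
doublets: two Lorentzian absorption lines of full width Γ centered at
δ ± ΔE_Q/2, where δ is the isomer shift and ΔE_Q the quadrupole
splitting (both mm/s on the Doppler velocity axis).  Spectra are stored
transmission-style — dips below a zero baseline, so the absorption
minima sit at the line centers — and fitted by least squares with
per-parameter uncertainties.

Continuous-wave X-band EPR spectra of frozen solutions are powder
patterns: the resonance field of a molecule at angle θ between its
symmetry axis and the magnetic field follows hν = g(θ) μB B with
g(θ)² = g∥² cos²θ + g⊥² sin²θ for an axial g tensor.  Orientation
averaging over a sin θ-weighted grid, convolution with a Gaussian
lineshape in the field domain, and differentiation give the familiar
first-derivative spectrum, with edge features at the fields of g∥ and
g⊥ (the g⊥ edge dominant).  Multi-component spectra are weighted sums;
component weights are defined as double-integral (spin-count) fractions
and can be re-fit from a measured spectrum with g values held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math
import warnings

import numpy as np
from scipy.optimize import nnls
import lmfit

__all__ = [
    "MossbauerDoublet",
    "MossbauerFit",
    "EprComponent",
    "Spectrum1D",
    "simulate_mossbauer",
    "fit_mossbauer",
    "simulate_epr_powder",
    "fit_epr_weights",
    "MHZ_PER_GAUSS",
    "FIELD_MT_PER_GHZ",
]

#: hν = g μB B  =>  B[mT] = 71.4477 ν[GHz] / g
FIELD_MT_PER_GHZ = 71.4477

MHZ_PER_GAUSS = 2.8025  # unused in the g-only model, kept for unit sanity


@dataclass(frozen=True)
class MossbauerDoublet:
    """Lorentzian quadrupole doublet parameters (velocity axis, mm/s)."""

    isomer_shift: float                 # δ, mm/s
    quadrupole_splitting: float         # ΔE_Q, mm/s
    linewidth: float = 0.24             # Γ, FWHM mm/s (typical experimental minimum)
    amplitude: float = 1.0              # total absorption area, a.u.
    asymmetry: float = 1.0              # area(low-velocity line) / area(high)

    def __post_init__(self):
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if self.quadrupole_splitting < 0:
            raise ValueError("quadrupole splitting must be >= 0")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry ratio must be > 0")

    @property
    def line_centers(self) -> tuple[float, float]:
        h = self.quadrupole_splitting / 2.0
        return (self.isomer_shift - h, self.isomer_shift + h)


@dataclass(frozen=True)
class Spectrum1D:
    """A 1-D spectrum: strictly increasing axis + ordinate, with metadata."""

    axis: np.ndarray
    ordinate: np.ndarray
    axis_unit: str = ""
    frequency_ghz: float | None = None   # microwave frequency for EPR
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        ax = np.asarray(self.axis, float)
        y = np.asarray(self.ordinate, float)
        if ax.ndim != 1 or ax.shape != y.shape:
            raise ValueError("axis and ordinate must be 1-D and equally long")
        if np.any(np.diff(ax) <= 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "axis", ax)
        object.__setattr__(self, "ordinate", y)

    def write(self, path) -> None:
        header = f"# axis_unit: {self.axis_unit}\n"
        if self.frequency_ghz is not None:
            header += f"# frequency_ghz: {self.frequency_ghz}\n"
        with open(path, "w") as fh:
            fh.write(header)
            for x, y in zip(self.axis, self.ordinate):
                fh.write(f"{x:.6g}\t{y:.8g}\n")

    @classmethod
    def read(cls, path, axis_unit: str = "") -> "Spectrum1D":
        freq = None
        xs, ys = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "axis_unit:" in line:
                        axis_unit = line.split("axis_unit:")[1].strip()
                    elif "frequency_ghz:" in line:
                        freq = float(line.split("frequency_ghz:")[1])
                    continue
                a, b = line.split()
                xs.append(float(a))
                ys.append(float(b))
        return cls(np.array(xs), np.array(ys), axis_unit=axis_unit, frequency_ghz=freq)


def _lorentzian(x: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    hw = fwhm / 2.0
    return (area / math.pi) * hw / ((x - center) ** 2 + hw ** 2)


def simulate_mossbauer(d: MossbauerDoublet, axis: np.ndarray) -> Spectrum1D:
    """Transmission-style doublet: dips of total area ``amplitude`` at δ ± ΔE_Q/2."""
    axis = np.asarray(axis, float)
    lo, hi = d.line_centers
    if lo < axis[0] or hi > axis[-1]:
        warnings.warn("velocity grid does not span both line centers", stacklevel=2)
    a_low = d.amplitude * d.asymmetry / (1.0 + d.asymmetry)
    a_high = d.amplitude / (1.0 + d.asymmetry)
    y = _lorentzian(axis, lo, d.linewidth, a_low) + _lorentzian(axis, hi, d.linewidth, a_high)
    return Spectrum1D(axis, -y, axis_unit="mm/s")


@dataclass(frozen=True)
class MossbauerFit:
    params: MossbauerDoublet
    stderr: dict[str, float | None]
    converged: bool
    residual_norm: float
    reduced_chi2: float


def _doublet_model(x, isomer_shift, quadrupole_splitting, linewidth, amplitude, asymmetry):
    lo = isomer_shift - quadrupole_splitting / 2.0
    hi = isomer_shift + quadrupole_splitting / 2.0
    a_low = amplitude * asymmetry / (1.0 + asymmetry)
    a_high = amplitude / (1.0 + asymmetry)
    return -(_lorentzian(x, lo, linewidth, a_low) + _lorentzian(x, hi, linewidth, a_high))


def fit_mossbauer(
    spec: Spectrum1D,
    init: MossbauerDoublet,
    vary_asymmetry: bool = True,
) -> MossbauerFit:
    """Least-squares doublet fit; non-convergence is flagged, never raised."""
    model = lmfit.Model(_doublet_model)
    p = model.make_params(
        isomer_shift=init.isomer_shift,
        quadrupole_splitting=init.quadrupole_splitting,
        linewidth=init.linewidth,
        amplitude=init.amplitude,
        asymmetry=init.asymmetry,
    )
    p["quadrupole_splitting"].min = 0.0
    p["linewidth"].min = 1e-4
    p["amplitude"].min = 0.0
    p["asymmetry"].min = 1e-3
    p["asymmetry"].vary = vary_asymmetry
    try:
        res = model.fit(spec.ordinate, p, x=spec.axis)
        fitted = MossbauerDoublet(
            isomer_shift=res.params["isomer_shift"].value,
            quadrupole_splitting=res.params["quadrupole_splitting"].value,
            linewidth=res.params["linewidth"].value,
            amplitude=res.params["amplitude"].value,
            asymmetry=res.params["asymmetry"].value,
        )
        stderr = {k: (res.params[k].stderr if res.params[k].vary else None) for k in res.params}
        resid = float(np.linalg.norm(res.residual))
        return MossbauerFit(fitted, stderr, bool(res.success), resid,
                            float(res.redchi) if res.redchi is not None else float("nan"))
    except Exception:
        resid = float(np.linalg.norm(
            spec.ordinate - _doublet_model(spec.axis, init.isomer_shift,
                                           init.quadrupole_splitting, init.linewidth,
                                           init.amplitude, init.asymmetry)))
        return MossbauerFit(init, {}, False, resid, float("nan"))


@dataclass(frozen=True)
class EprComponent:
    """One component of a CW powder EPR spectrum (axial or isotropic)."""

    kind: str                       # "axial" or "isotropic"
    g_parallel: float | None = None
    g_perp: float | None = None
    g_iso: float | None = None
    linewidth_g: float = 10.0       # gauss (peak-to-peak convolution width)
    weight: float = 1.0             # double-integral fraction

    def __post_init__(self):
        if self.kind not in ("axial", "isotropic"):
            raise ValueError("kind must be 'axial' or 'isotropic'")
        gs = ((self.g_parallel, self.g_perp) if self.kind == "axial" else (self.g_iso,))
        for g in gs:
            if g is None:
                raise ValueError(f"{self.kind} component missing a g value")
            if not 1.5 < g < 2.5:
                raise ValueError(f"g value {g} outside the plausible (1.5, 2.5) window")
        if self.linewidth_g <= 0:
            raise ValueError("linewidth must be > 0")

    def g_at(self, theta: np.ndarray) -> np.ndarray:
        if self.kind == "isotropic":
            return np.full_like(theta, self.g_iso)
        return np.sqrt(self.g_parallel ** 2 * np.cos(theta) ** 2
                       + self.g_perp ** 2 * np.sin(theta) ** 2)


def _component_absorption(c: EprComponent, frequency_ghz: float, field_mt: np.ndarray,
                          n_theta: int = 1800) -> np.ndarray:
    """Unit-area absorption envelope of one component on the field grid (mT)."""
    theta = (np.arange(n_theta) + 0.5) * (math.pi / 2.0) / n_theta
    wts = np.sin(theta)
    b_res = FIELD_MT_PER_GHZ * frequency_ghz / c.g_at(theta)
    lo, hi = field_mt[0], field_mt[-1]
    if np.min(b_res) < lo or np.max(b_res) > hi:
        warnings.warn(
            f"field grid misses part of the {c.kind} component resonance "
            f"({np.min(b_res):.1f}-{np.max(b_res):.1f} mT)", stacklevel=3)
    hist, edges = np.histogram(b_res, bins=len(field_mt), range=(lo, hi), weights=wts)
    db = edges[1] - edges[0]
    stick = hist / (wts.sum() * db)     # unit-area stick envelope
    # Gaussian convolution in the field domain; linewidth given in gauss
    sigma_mt = (c.linewidth_g * 0.1) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    k = np.arange(-int(6 * sigma_mt / db) - 1, int(6 * sigma_mt / db) + 2) * db
    kern = np.exp(-0.5 * (k / sigma_mt) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(stick, kern, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return np.interp(field_mt, centers, smooth)


def simulate_epr_powder(
    components: list[EprComponent],
    frequency_ghz: float,
    field_mt: np.ndarray,
    n_theta: int = 1800,
) -> Spectrum1D:
    """First-derivative CW powder spectrum of a weighted component mixture.

    Component weights must sum to 1 (within 1e-6) and scale the
    double-integral (absorption area) of each component.
    """
    field_mt = np.asarray(field_mt, float)
    total_w = sum(c.weight for c in components)
    if abs(total_w - 1.0) > 1e-6:
        raise ValueError(f"component weights sum to {total_w}, expected 1")
    absorption = np.zeros_like(field_mt)
    for c in components:
        absorption += c.weight * _component_absorption(c, frequency_ghz, field_mt, n_theta)
    deriv = np.gradient(absorption, field_mt)
    return Spectrum1D(field_mt, deriv, axis_unit="mT", frequency_ghz=frequency_ghz)


def fit_epr_weights(
    spec: Spectrum1D,
    components_fixed_g: list[EprComponent],
    frequency_ghz: float | None = None,
    n_theta: int = 1800,
) -> np.ndarray:
    """Re-fit component weights with g values and linewidths held fixed.

    Non-negative least squares on the component first-derivative basis,
    followed by normalization to sum 1 (the global scale is absorbed).
    Identical components make the design degenerate and raise an error.
    """
    if frequency_ghz is None:
        frequency_ghz = spec.frequency_ghz
    if frequency_ghz is None:
        raise ValueError("microwave frequency required (not present in spectrum metadata)")
    if len(components_fixed_g) == 0:
        raise ValueError("need at least one component")
    basis = []
    for c in components_fixed_g:
        absorption = _component_absorption(c, frequency_ghz, spec.axis, n_theta)
        basis.append(np.gradient(absorption, spec.axis))
    A = np.stack(basis, axis=1)
    if len(components_fixed_g) > 1:
        s = np.linalg.svd(A / np.linalg.norm(A, axis=0, keepdims=True), compute_uv=False)
        if s[-1] < 1e-8:
            raise ValueError("degenerate design: components are indistinguishable")
    w, _ = nnls(A, spec.ordinate)
    if w.sum() <= 0:
        raise ValueError("all fitted weights are zero; spectrum does not match the basis")
    return w / w.sum()
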