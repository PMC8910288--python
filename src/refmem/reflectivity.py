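"""Specular neutron reflectivity of slab stacks (Abeles method).

The reflectivity R(Q) of a stack of homogeneous slabs is computed by the
Parratt/Abeles recursion over interface reflection amplitudes, with Gaussian
interfacial roughness included through Nevot-Croce damping factors
exp(-2 k_n k_{n+1} sigma^2).  Instrument resolution is applied by Gaussian
smearing in Q with a FWHM-defined dQ/Q, using fixed-order Gauss-Legendre
quadrature and re-evaluating the model beyond the data range rather than
truncating the kernel.

Q is the momentum transfer 4 pi sin(theta) / lambda in Å⁻¹; below the critical
edge set by the fronting/backing SLD difference the reflectivity is unity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

from .components import SolventContrast
from .slab import SlabStack

__all__ = [
    "InstrumentModel",
    "ReflectivityCurve",
    "abeles",
    "abeles_profile",
    "smear",
    "apply_scale_background",
    "D17_QGRID",
    "INTER_QGRID",
]

#: default log-spaced momentum-transfer grids for the two instrument geometries
D17_QGRID = np.logspace(np.log10(0.01), np.log10(0.25), 250)
INTER_QGRID = np.logspace(np.log10(0.009), np.log10(0.3), 250)

# FWHM of a unit-variance Gaussian
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class InstrumentModel:
    """Resolution, scale and background of a reflectometer configuration.

    ``dq_over_q`` is the FWHM relative Q resolution; per-point resolutions can
    be supplied instead when a dataset carries a dQ column.  ``background`` is
    an additive constant on R and ``scale`` a multiplicative factor, applied
    after smearing.
    """

    name: str = "generic"
    dq_over_q: float = 0.05
    background: float = 0.0
    scale: float = 1.0
    fit_background: bool = False

    def __post_init__(self) -> None:
        if self.dq_over_q <= 0:
            raise ValueError("dq_over_q must be > 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


#: D17-style configuration (variable wavelength resolution, subtracted background)
D17 = InstrumentModel("D17", dq_over_q=0.05, background=1e-6)
#: INTER-style configuration (4% angular resolution, background fitted)
INTER = InstrumentModel("INTER", dq_over_q=0.04, background=2e-6, fit_background=True)


@dataclass
class ReflectivityCurve:
    """A reflectivity curve: momentum transfer Q (Å⁻¹) and reflectivity R."""

    q: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.q.shape != self.r.shape:
            raise ValueError("Q and R must have the same shape")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be strictly increasing")


def _abeles_kernel(
    q: np.ndarray,
    slds: np.ndarray,
    thickness: np.ndarray,
    roughness: np.ndarray,
) -> np.ndarray:
    """Parratt recursion with Nevot-Croce roughness; SLDs in 1e-6 Å⁻²."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    slds = np.asarray(slds, dtype=complex) * 1e-6
    thickness = np.asarray(thickness, dtype=float)
    roughness = np.asarray(roughness, dtype=float)
    n_int = len(slds) - 1
    if len(thickness) != n_int - 1 or len(roughness) != n_int:
        raise ValueError("inconsistent profile array lengths")
    if np.any(thickness < 0) or np.any(roughness < 0):
        raise ValueError("thicknesses and roughnesses must be >= 0")

    kz0_sq = (q / 2.0) ** 2
    # principal square root: non-negative imaginary part below the edge
    k = np.sqrt(kz0_sq[:, None] - 4.0 * np.pi * (slds[None, :] - slds[0]))

    # recursion from the backing interface towards the fronting
    rtot = np.zeros_like(q, dtype=complex)
    for j in range(n_int - 1, -1, -1):
        kj, kj1 = k[:, j], k[:, j + 1]
        rj = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * roughness[j] ** 2)
        if j == n_int - 1:
            rtot = rj
        else:
            beta = np.exp(2j * kj1 * thickness[j])
            rtot = (rj + rtot * beta) / (1.0 + rj * rtot * beta)
    return np.abs(rtot) ** 2


def _microslice_profile(slds, thickness, roughness, dz: float = 0.5):
    """Resolve rough interfaces into thin sharp slabs via the erf profile."""
    slds = np.asarray(slds, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    # absolute interface positions, first interface at z = 0
    zi = np.concatenate([[0.0], np.cumsum(thickness)])
    pad = 4.0 * max(float(np.max(roughness)), 1.0)
    z = np.arange(zi[0] - pad, zi[-1] + pad + dz, dz)
    prof = np.full_like(z, slds[0])
    for j, z0 in enumerate(zi):
        sig = max(roughness[j], 1e-3)
        step = 0.5 * (1.0 + erf((z - z0) / (np.sqrt(2.0) * sig)))
        prof = prof + (slds[j + 1] - slds[j]) * step
    sub_sld = np.concatenate([[slds[0]], 0.5 * (prof[1:] + prof[:-1]), [slds[-1]]])
    sub_thick = np.full(len(sub_sld) - 2, dz)
    sub_rough = np.zeros(len(sub_sld) - 1)
    return sub_sld, sub_thick, sub_rough


def abeles_profile(
    q,
    slds,
    thickness,
    roughness,
    microslice: bool | None = None,
) -> np.ndarray:
    """Reflectivity from raw profile arrays (fronting/backing included in slds).

    Nevot-Croce factors are the default roughness treatment.  When an
    interface roughness exceeds half the thickness of an adjacent layer the
    approximation degrades; a warning is issued and, with ``microslice=True``,
    the continuous erf profile is sliced into thin sharp sub-layers instead.
    """
    thickness = np.asarray(thickness, dtype=float)
    roughness = np.asarray(roughness, dtype=float)
    if np.any(thickness < 0) or np.any(roughness < 0):
        raise ValueError("thicknesses and roughnesses must be >= 0")
    if len(thickness):
        adjacent = np.minimum(
            np.concatenate([[np.inf], thickness]),
            np.concatenate([thickness, [np.inf]]),
        )
        rough_vs_layer = roughness > adjacent / 2.0
        if np.any(rough_vs_layer):
            if microslice is None:
                warnings.warn(
                    "interfacial roughness exceeds half an adjacent layer "
                    "thickness; Nevot-Croce is inaccurate here (pass "
                    "microslice=True for a sliced-profile calculation)",
                    stacklevel=2,
                )
            if microslice:
                s, t, r = _microslice_profile(slds, thickness, roughness)
                return _abeles_kernel(q, s, t, r)
    return _abeles_kernel(q, slds, thickness, roughness)


def abeles(
    stack: SlabStack,
    q,
    contrast: SolventContrast | None = None,
    microslice: bool | None = None,
) -> ReflectivityCurve:
    """Unsmeared specular reflectivity of a slab stack at one solvent contrast."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Q values must be > 0")
    slds, thickness, roughness = stack.profile(contrast)
    r = abeles_profile(q, slds, thickness, roughness, microslice=microslice)
    return ReflectivityCurve(q, r)


def _gauss_quadrature(n_points: int):
    x, w = leggauss(n_points)
    # map nodes to [-3.5, 3.5] standard deviations and weight by the Gaussian
    half = 3.5
    x = x * half
    w = w * half * np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
    return x, w / w.sum()


def smear(
    model: Callable[[np.ndarray], np.ndarray] | ReflectivityCurve,
    q=None,
    instrument: InstrumentModel | None = None,
    dq_over_q: float | None = None,
    n_points: int = 17,
) -> ReflectivityCurve:
    """Gaussian resolution smearing with FWHM-defined dQ/Q.

    ``model`` is preferably a callable R(Q): the smeared value at each Q is a
    fixed-order quadrature over a Gaussian of sigma = (dQ/Q) Q / 2.355, with
    the model re-evaluated at nodes beyond the data range.  A sampled
    :class:`ReflectivityCurve` is also accepted; it is then log-interpolated
    and extended by its end values, which is only adequate well inside the
    measured range.
    """
    if dq_over_q is None:
        if instrument is None:
            raise ValueError("need an InstrumentModel or dq_over_q")
        dq_over_q = instrument.dq_over_q
    if dq_over_q <= 0:
        raise ValueError("dq_over_q must be > 0")

    if isinstance(model, ReflectivityCurve):
        curve = model
        if q is None:
            q = curve.q
        logr = np.log(np.clip(curve.r, 1e-300, None))

        def model_fn(qq):
            return np.exp(np.interp(qq, curve.q, logr))

    else:
        model_fn = model
        if q is None:
            raise ValueError("q grid required when smearing a callable")

    q = np.asarray(q, dtype=float)
    x, w = _gauss_quadrature(n_points)
    sigma = dq_over_q * q / _FWHM
    nodes = q[:, None] + sigma[:, None] * x[None, :]
    nodes = np.clip(nodes, 1e-6, None)
    vals = model_fn(nodes.ravel()).reshape(nodes.shape)
    return ReflectivityCurve(q, vals @ w)


def apply_scale_background(
    curve: ReflectivityCurve, scale: float = 1.0, background: float = 0.0
) -> ReflectivityCurve:
    """R' = scale * R + background."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return ReflectivityCurve(curve.q, scale * curve.r + background)
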