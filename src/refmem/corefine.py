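"""Simultaneous refinement of one slab model against multiple contrasts.

The central object is a :class:`StackModel`: a slab stack turned into a named
parameter set (layer thicknesses, solvent fractions, intrinsic SLDs, per-
dataset scale and background) that is evaluated against several reflectivity
datasets at once.  Structural parameters — thickness, solvent fraction,
roughness — are shared across contrasts by construction, since one physical
structure underlies all of them; only the solvent SLD and any isotope-
sensitive intrinsic SLDs differ between datasets.  Where a layer's intrinsic
SLD legitimately varies with contrast (labile-hydrogen exchange in protein-
containing layers), the per-contrast offsets of the template are preserved
and a single scalar shifts the whole series, so the contrast pattern stays
consistent with proton exchange.

Fitting minimizes the global chi-squared

    chi2 = sum_datasets sum_points ((R_model - R_obs) / dR)^2

with a seeded global stage (differential evolution) followed by a bounded
local least-squares polish; parameter uncertainties come from the local-stage
covariance scaled by sqrt(chi2/dof), and can be propagated to derived
quantities by the delta method or Monte-Carlo resampling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import lmfit
import numpy as np

from .components import STANDARD_CONTRASTS, SolventContrast
from .dataset import ReflectivityDataset
from .reflectivity import InstrumentModel, abeles_profile, smear
from .slab import Layer, SlabStack

__all__ = [
    "StackModel",
    "FitResult",
    "chi_squared",
    "fit",
    "propagate_uncertainty",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20220223


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


class StackModel:
    """A slab stack parameterized for multi-contrast co-refinement.

    Parameters are created for every layer of the template stack:

    * ``tau_<layer>``   thickness (Å)
    * ``phi_<group>``   solvent fraction; all chain-region layers (roles
      ``chains`` and ``mid``) share one ``phi_chains`` parameter, matching
      the constraint that the chain-region solvent content is kept constant,
      heads and protein layers get their own
    * ``rho_<layer>``   intrinsic SLD in the first contrast (1e-6 Å⁻²); for
      layers with a per-contrast SLD series the template's offsets ride on
      top of this scalar
    * ``sigma_<layer>`` roughness (Å)
    * ``scale_<contrast>``, ``background_<contrast>`` per dataset

    All parameters start fixed at template values; free selected ones with
    :meth:`set_free` before fitting.
    """

    def __init__(
        self,
        stack: SlabStack,
        instrument: InstrumentModel,
        contrasts: Sequence[SolventContrast] = STANDARD_CONTRASTS,
        exchange_completeness: float = 1.0,
    ):
        self.stack = stack.copy()
        self.instrument = instrument
        self.contrasts = {c.name: c for c in contrasts}
        self.exchange_completeness = exchange_completeness

        self._layers = self.stack.all_layers()
        self._slugs = []
        counts: dict[str, int] = {}
        for lay in self._layers:
            s = _slug(lay.name)
            counts[s] = counts.get(s, 0) + 1
            self._slugs.append(s if counts[s] == 1 else f"{s}_{counts[s]}")

        first = next(iter(self.contrasts.values()))
        # per-contrast intrinsic-SLD offsets relative to the first contrast
        self._rho_offsets: dict[str, np.ndarray] = {}
        self._phi_param: list[str] = []
        self._base: dict[str, float] = {}
        for lay, slug in zip(self._layers, self._slugs):
            base = lay.intrinsic_sld(first, self.exchange_completeness)
            self._base[f"rho_{slug}"] = base
            self._rho_offsets[slug] = np.array(
                [
                    lay.intrinsic_sld(c, self.exchange_completeness) - base
                    for c in self.contrasts.values()
                ]
            )
            if lay.role in ("chains", "mid"):
                phi_name = "phi_chains"
            else:
                phi_name = f"phi_{slug}"
            self._phi_param.append(phi_name)

        self.params = lmfit.Parameters()
        for lay, slug in zip(self._layers, self._slugs):
            self.params.add(f"tau_{slug}", value=lay.thickness, vary=False, min=0.0)
            self.params.add(f"rho_{slug}", value=self._base[f"rho_{slug}"], vary=False)
            self.params.add(f"sigma_{slug}", value=lay.roughness, vary=False, min=0.0)
        seen = set()
        for lay, phi_name in zip(self._layers, self._phi_param):
            if phi_name in seen:
                continue
            seen.add(phi_name)
            phi = lay.solvent_fraction
            if isinstance(phi, Mapping):
                phi = float(np.mean(list(phi.values())))
            self.params.add(phi_name, value=phi, vary=False, min=0.0, max=1.0)
        for cname in self.contrasts:
            self.params.add(
                f"scale_{_slug(cname)}", value=instrument.scale, vary=False, min=1e-3
            )
            self.params.add(
                f"background_{_slug(cname)}",
                value=instrument.background,
                vary=False,
                min=0.0,
            )

    # ------------------------------------------------------------------
    def set_free(self, spec: Mapping[str, tuple[float, float]]):
        """Free parameters with (min, max) bounds; start at the bounds midpoint.

        Starting at the midpoint keeps the refinement honest: the optimizer is
        handed the prior range, not the answer.
        """
        for name, (lo, hi) in spec.items():
            p = self.params[name]
            p.set(min=lo, max=hi, value=0.5 * (lo + hi), vary=True)
        return self

    def free_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.vary]

    # ------------------------------------------------------------------
    def _profile_arrays(self, values: Mapping[str, float], contrast_index: int,
                        contrast: SolventContrast):
        rho_s = contrast.sld
        slds = [self.stack.fronting.sld()]
        thick, rough = [], []
        for lay, slug, phi_name in zip(self._layers, self._slugs, self._phi_param):
            rho_in = values[f"rho_{slug}"] + self._rho_offsets[slug][contrast_index]
            phi = values[phi_name]
            slds.append((1.0 - phi) * rho_in + phi * rho_s)
            thick.append(values[f"tau_{slug}"])
            rough.append(values[f"sigma_{slug}"])
        slds.append(rho_s)
        rough.append(self.stack.backing_roughness)
        return np.array(slds), np.array(thick), np.array(rough)

    def reflectivity(
        self, values: Mapping[str, float], dataset: ReflectivityDataset
    ) -> np.ndarray:
        """Smeared, scaled model reflectivity on a dataset's Q grid."""
        cnames = list(self.contrasts)
        ci = cnames.index(dataset.contrast)
        contrast = self.contrasts[dataset.contrast]
        slds, thick, rough = self._profile_arrays(values, ci, contrast)

        def raw(qq):
            return abeles_profile(qq, slds, thick, rough, microslice=False)

        smeared = smear(raw, dataset.q, instrument=self.instrument)
        s = values[f"scale_{_slug(dataset.contrast)}"]
        b = values[f"background_{_slug(dataset.contrast)}"]
        return s * smeared.r + b

    def residuals(self, params, datasets: Sequence[ReflectivityDataset]) -> np.ndarray:
        values = params.valuesdict() if hasattr(params, "valuesdict") else dict(params)
        out = []
        for ds in datasets:
            out.append((self.reflectivity(values, ds) - ds.r) / ds.dr)
        return np.concatenate(out)

    def stack_with(self, params) -> SlabStack:
        """A copy of the template stack carrying the fitted parameter values."""
        values = params.valuesdict() if hasattr(params, "valuesdict") else dict(params)
        out = self.stack.copy()
        layers = out.all_layers()
        cnames = list(self.contrasts)
        for lay, slug, phi_name in zip(layers, self._slugs, self._phi_param):
            lay.thickness = values[f"tau_{slug}"]
            lay.roughness = values[f"sigma_{slug}"]
            lay.solvent_fraction = values[phi_name]
            offsets = self._rho_offsets[slug]
            if np.any(offsets != 0):
                lay.sld = {
                    cn: values[f"rho_{slug}"] + off
                    for cn, off in zip(cnames, offsets)
                }
            else:
                lay.sld = values[f"rho_{slug}"]
            lay.composition = None
        return out


@dataclass
class FitResult:
    """Best-fit parameters, uncertainties and fit diagnostics."""

    params: lmfit.Parameters
    chisqr: float
    redchi: float
    ndata: int
    nvarys: int
    per_dataset_chisqr: dict[str, float]
    residual: np.ndarray
    covar: np.ndarray | None
    var_names: list[str]
    success: bool
    nfev: int
    seed: int
    message: str = ""

    @property
    def values(self) -> dict[str, float]:
        return {k: float(p.value) for k, p in self.params.items()}

    @property
    def stderr(self) -> dict[str, float]:
        return {
            k: (float(p.stderr) if p.stderr is not None else float("nan"))
            for k, p in self.params.items()
            if p.vary
        }


def chi_squared(
    model: StackModel, params, datasets: Sequence[ReflectivityDataset]
) -> float:
    """Global chi-squared over all datasets (exact weighted sum of squares)."""
    for ds in datasets:
        if np.any(ds.dr <= 0):
            raise ValueError("all dR must be > 0")
    res = model.residuals(params, datasets)
    return float(res @ res)


def fit(
    model: StackModel,
    datasets: Sequence[ReflectivityDataset],
    seed: int = DEFAULT_SEED,
    global_stage: bool = False,
    de_maxiter: int = 60,
    de_popsize: int = 12,
) -> FitResult:
    """Co-refine the model against the datasets; deterministic per seed.

    The optional global stage runs seeded differential evolution inside the
    parameter bounds before the bounded trust-region least-squares polish.
    Non-convergence is reported in the result flags rather than raised.
    """
    if not datasets:
        raise ValueError("no datasets given")
    if not model.free_names():
        raise ValueError("no free parameters; call set_free first")

    params = model.params
    start_chi2 = chi_squared(model, params, datasets)

    def residual(p):
        return model.residuals(p, datasets)

    nfev = 0
    if global_stage:
        mini = lmfit.Minimizer(residual, params)
        budget = de_maxiter * de_popsize * max(len(model.free_names()), 1)
        de = mini.minimize(
            method="differential_evolution",
            seed=seed,
            max_nfev=budget,
            popsize=de_popsize,
            tol=1e-6,
            polish=False,
            init="sobol",
        )
        params = de.params
        nfev += de.nfev

    mini = lmfit.Minimizer(residual, params)
    out = mini.minimize(method="least_squares")
    nfev += out.nfev

    per_ds = {}
    values = out.params.valuesdict()
    for ds in datasets:
        r = (model.reflectivity(values, ds) - ds.r) / ds.dr
        per_ds[ds.contrast or "?"] = float(r @ r)
    chisqr = float(sum(per_ds.values()))

    success = bool(out.success) and chisqr <= start_chi2 + 1e-9
    # keep the better point if the optimizer somehow worsened things
    result_params = out.params if chisqr <= start_chi2 + 1e-9 else model.params

    return FitResult(
        params=result_params,
        chisqr=chisqr,
        redchi=float(out.redchi),
        ndata=int(out.ndata),
        nvarys=int(out.nvarys),
        per_dataset_chisqr=per_ds,
        residual=np.asarray(out.residual),
        covar=getattr(out, "covar", None),
        var_names=list(out.var_names),
        success=success,
        nfev=nfev,
        seed=seed,
        message=str(getattr(out, "message", "")),
    )


def _covariance(result: FitResult) -> np.ndarray:
    if result.covar is not None and np.all(np.isfinite(result.covar)):
        return np.asarray(result.covar)
    warnings.warn(
        "covariance unavailable or singular; using independent per-parameter "
        "uncertainties",
        stacklevel=3,
    )
    err = np.array(
        [
            result.params[n].stderr if result.params[n].stderr else 0.0
            for n in result.var_names
        ]
    )
    return np.diag(err**2)


def propagate_uncertainty(
    result: FitResult,
    derived: Callable[[dict[str, float]], float],
    method: str = "delta",
    n_mc: int = 10_000,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float]:
    """Propagate fitted-parameter uncertainties to a derived quantity.

    ``derived`` maps a {parameter-name: value} dict to a scalar.  The delta
    method uses a first-order expansion around the best fit with the fit
    covariance; the Monte-Carlo method resamples parameters from a normal
    approximation (seeded, reproducible) and reports mean and standard
    deviation.  Returns (value, sigma).
    """
    best = result.values
    value = float(derived(best))
    cov = _covariance(result)
    names = result.var_names
    x0 = np.array([best[n] for n in names])

    if method == "delta":
        grad = np.zeros(len(names))
        for i, n in enumerate(names):
            sig = np.sqrt(max(cov[i, i], 0.0))
            h = sig * 1e-3 if sig > 0 else max(abs(x0[i]), 1.0) * 1e-6
            up, dn = dict(best), dict(best)
            up[n] = x0[i] + h
            dn[n] = x0[i] - h
            grad[i] = (derived(up) - derived(dn)) / (2.0 * h)
        var = float(grad @ cov @ grad)
        return value, float(np.sqrt(max(var, 0.0)))

    if method == "mc":
        rng = np.random.default_rng(seed)
        # jitter guards against numerically semi-definite covariances
        jitter = 1e-12 * np.trace(cov) / max(len(names), 1)
        draws = rng.multivariate_normal(
            x0, cov + jitter * np.eye(len(names)), size=n_mc, method="cholesky"
        )
        samples = np.empty(n_mc)
        for k in range(n_mc):
            d = dict(best)
            d.update(zip(names, draws[k]))
            samples[k] = derived(d)
        return float(np.mean(samples)), float(np.std(samples, ddof=1))

    raise ValueError(f"unknown method {method!r}; use 'delta' or 'mc'")
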