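"""Synthetic multi-contrast reflectivity data from published fixture structures.

The study's seven membrane systems are shipped as a registry of fixtures, each
a slab stack whose per-layer parameters (thickness, intrinsic SLD per
contrast, solvent fraction, roughness) equal the central values of the
corresponding published results table.  Simulating the four standard solvent
contrasts (D2O, CM4, CMSi, H2O) from a fixture, with realistic counting noise
and instrument resolution, produces datasets on which every downstream stage
(co-refinement, derived quantities, reporting) can be exercised without any
measured data.

Fixture ids follow ``T<n>_lipid`` / ``T<n>_protein`` for the bilayer before
and after enzyme addition; ``fixtures()`` lists the registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import CONTRAST_ORDER, STANDARD_CONTRASTS, SolventContrast
from .dataset import ReflectivityDataset
from .reflectivity import (
    D17,
    D17_QGRID,
    INTER,
    INTER_QGRID,
    InstrumentModel,
    abeles_profile,
    smear,
)
from .slab import Layer, SlabStack, default_oxide

__all__ = [
    "Fixture",
    "NoiseModel",
    "fixture_stack",
    "fixture_ids",
    "simulate_dataset",
    "simulate_experiment",
    "recovery_bounds",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian counting-noise model: dR = relative_error * R_model."""

    relative_error: float = 0.03
    background: float = 1e-6

    def __post_init__(self) -> None:
        if self.relative_error <= 0:
            raise ValueError("relative_error must be > 0")


@dataclass
class Fixture:
    """A registered table structure with its instrument configuration."""

    id: str
    stack: SlabStack
    instrument: InstrumentModel
    qgrid: np.ndarray
    contrasts: tuple[SolventContrast, ...] = STANDARD_CONTRASTS
    description: str = ""


def _vec(d2o, cm4, cmsi, h2o) -> dict[str, float]:
    return dict(zip(CONTRAST_ORDER, (d2o, cm4, cmsi, h2o)))


def _lay(name, tau, rho, phi, sigma, role, leaflet=None, err=None) -> Layer:
    return Layer(
        name,
        tau,
        sigma,
        phi,
        sld=rho,
        role=role,
        leaflet=leaflet,
    )


_PROT_RHO = _vec(3.0, 2.6, 2.2, 1.8)


def _stack(layers) -> SlabStack:
    return SlabStack(oxide=default_oxide(), layers=list(layers))


# Layer rows: (name, tau, rho, phi, sigma, role, leaflet, (dtau, drho, dphi))
# The final tuple holds the published fitting uncertainties (most sensitive
# contrast) used by parameter-recovery tests; None marks values the source
# table does not print.
_TABLES: dict[str, dict] = {
    "T1_lipid": dict(
        instrument="INTER",
        description="chain-deuterated PC with 10 mol% cardiolipin, bilayer only",
        layers=[
            ("inner heads", 11, 2.0, 0.54, 3, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 16, 5.4, 0.19, 4, "chains", "inner", (1, 0.1, 0.03)),
            ("outer chains", 16, 4.6, 0.19, 2, "chains", "outer", (1, 0.1, 0.03)),
            ("outer heads", 9, 2.1, 0.51, 7, "heads", "outer", (1, 0.2, 0.05)),
        ],
    ),
    "T1_protein": dict(
        instrument="INTER",
        description="chain-deuterated PC/cardiolipin after human-enzyme addition",
        layers=[
            ("inner heads", 10, 2.0, 0.54, 3, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 15, 5.4, 0.21, 4, "chains", "inner", (1, 0.1, 0.03)),
            ("outer chains + protein", 15, _vec(4.0, 3.8, 3.7, 3.5), 0.21, 4, "chains", "outer", (1, 0.1, 0.03)),
            ("outer heads + protein", 8, _vec(2.5, 2.3, 2.1, 1.9), 0.44, 4, "heads", "outer", (1, 0.5, 0.05)),
            ("protein layer 1", 43, _PROT_RHO, 0.84, 5, "protein", None, (5, 0.2, 0.03)),
            ("protein layer 2", 60, _PROT_RHO, 0.95, 5, "protein", None, (15, 0.2, None)),
        ],
    ),
    "T2_lipid": dict(
        instrument="D17",
        description="hydrogenous PC with 10 mol% cardiolipin, bilayer only",
        layers=[
            ("inner heads", 8, 2.0, 0.43, 3, "heads", "inner", (1, 0.2, 0.08)),
            ("inner chains", 15, -0.27, 0.10, 3, "chains", "inner", (1, 0.1, 0.02)),
            ("outer chains", 15, -0.27, 0.10, 3, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads", 9, 2.1, 0.59, 6, "heads", "outer", (1, 0.2, 0.08)),
        ],
    ),
    "T2_protein": dict(
        instrument="D17",
        description="hydrogenous PC/cardiolipin after bacterial-enzyme addition",
        layers=[
            ("inner heads", 9, 2.0, 0.50, 4, "heads", "inner", (1, 0.2, 0.08)),
            ("inner chains", 15, -0.27, 0.19, 4, "chains", "inner", (1, 0.1, 0.02)),
            ("outer chains + protein", 15, _vec(0.0025, -0.035, -0.063, 0.11), 0.19, 5, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads + protein", 9, 2.1, 0.50, 3, "heads", "outer", (1, 0.5, 0.05)),
            ("protein layer 1", 46, _PROT_RHO, 0.72, 3, "protein", None, (5, 0.2, 0.02)),
            ("protein layer 2", 55, _PROT_RHO, 0.93, 3, "protein", None, (15, 0.2, None)),
        ],
    ),
    "T3_lipid": dict(
        instrument="INTER",
        description="chain-deuterated PC/cardiolipin with a central ubiquinone layer",
        layers=[
            ("inner heads", 10, 2.0, 0.58, 3, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 13, 5.4, 0.09, 2, "chains", "inner", (1, 0.2, 0.02)),
            ("ubiquinone + chains", 4, 2.7, 0.09, 1, "mid", None, (1, 0.2, 0.02)),
            ("outer chains", 13, 4.4, 0.09, 4, "chains", "outer", (1, 0.2, 0.02)),
            ("outer heads", 9, 2.1, 0.47, 5, "heads", "outer", (1, 0.2, 0.05)),
        ],
    ),
    "T3_protein": dict(
        instrument="INTER",
        description="deuterated PC/cardiolipin/ubiquinone after human-enzyme addition",
        layers=[
            ("inner heads", 11, 2.0, 0.48, 3, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 13, 5.4, 0.11, 3, "chains", "inner", (1, 0.2, 0.02)),
            ("ubiquinone + chains", 4, 2.7, 0.11, 2, "mid", None, (1, 0.2, 0.02)),
            ("outer chains + protein", 13, _vec(4.0, 3.9, 3.8, 4.0), 0.11, 2, "chains", "outer", (1, 0.2, 0.02)),
            ("outer heads + protein", 8, _vec(2.5, 2.3, 2.1, 2.0), 0.40, 3, "heads", "outer", (1, 0.5, 0.05)),
            ("protein layer 1", 36, _PROT_RHO, 0.70, 4, "protein", None, (5, 0.2, 0.02)),
            ("protein layer 2", 60, _PROT_RHO, 0.95, 4, "protein", None, (15, 0.2, None)),
        ],
    ),
    "T4_lipid": dict(
        instrument="INTER",
        description="hydrogenous PC/cardiolipin with a central ubiquinone layer",
        layers=[
            ("inner heads", 10, 2.0, 0.51, 3, "heads", "inner", (1, 0.2, 0.08)),
            ("inner chains", 14, -0.27, 0.02, 3, "chains", "inner", (1, 0.1, 0.02)),
            ("ubiquinone + chains", 4, 0.12, 0.02, 1, "mid", None, (1, 0.12, 0.02)),
            ("outer chains", 14, -0.27, 0.02, 3, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads", 8, 2.1, 0.45, 4, "heads", "outer", (1, 0.2, 0.10)),
        ],
    ),
    "T4_protein": dict(
        instrument="INTER",
        description="hydrogenous PC/cardiolipin/ubiquinone after bacterial-enzyme addition",
        layers=[
            ("inner heads", 10, 2.0, 0.56, 3, "heads", "inner", (1, 0.2, 0.08)),
            ("inner chains", 13, -0.27, 0.10, 2, "chains", "inner", (1, 0.1, 0.02)),
            ("ubiquinone + chains", 4, 0.12, 0.10, 1, "mid", None, (1, 0.12, 0.02)),
            ("outer chains + protein", 13, _vec(0.057, 0.017, -0.023, -0.063), 0.10, 2, "chains", "outer", (1, 0.2, 0.02)),
            ("outer heads + protein", 7, _vec(2.3, 2.2, 2.1, 2.1), 0.50, 4, "heads", "outer", (1, 0.2, 0.05)),
            ("protein layer 1", 39, _PROT_RHO, 0.81, 5, "protein", None, (5, 0.2, 0.03)),
            ("protein layer 2", 73, _PROT_RHO, 0.95, 5, "protein", None, (15, 0.2, None)),
        ],
    ),
    "T5_lipid": dict(
        instrument="D17",
        description="yeast polar-lipid extract bilayer",
        layers=[
            ("inner heads", 9, _vec(3.0, 2.8, 2.6, 2.4), 0.45, 4, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 14, -0.22, 0.02, 4, "chains", "inner", (1, 0.1, 0.02)),
            ("outer chains", 14, -0.22, 0.02, 3, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads", 8, _vec(3.0, 2.8, 2.6, 2.4), 0.42, 3, "heads", "outer", (1, 0.2, 0.05)),
        ],
    ),
    "T5_protein": dict(
        instrument="D17",
        description="yeast extract bilayer after human-enzyme addition",
        layers=[
            ("inner heads", 9, _vec(3.0, 2.8, 2.6, 2.4), 0.54, 4, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 14, -0.22, 0.15, 4, "chains", "inner", (1, 0.1, 0.02)),
            ("outer chains + protein", 14, _vec(0.10, 0.06, 0.02, -0.02), 0.15, 4, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads + protein", 8, _vec(3.0, 2.8, 2.5, 2.3), 0.50, 3, "heads", "outer", (1, 0.2, 0.05)),
            ("protein layer 1", 35, _PROT_RHO, 0.70, 3, "protein", None, (5, 0.2, 0.02)),
            ("protein layer 2", 60, _PROT_RHO, 0.95, 3, "protein", None, (15, 0.2, None)),
        ],
    ),
    "T6_lipid": dict(
        instrument="D17",
        description="yeast extract bilayer with a central ubiquinone layer",
        layers=[
            ("inner heads", 9, _vec(3.0, 2.8, 2.6, 2.4), 0.46, 3, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 13, -0.22, 0.02, 4, "chains", "inner", (1, 0.1, 0.02)),
            ("ubiquinone layer", 4, 0.19, 0.02, 1, "mid", None, (1, 0.1, 0.02)),
            ("outer chains", 13, -0.22, 0.02, 1, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads", 9, _vec(3.0, 2.8, 2.6, 2.4), 0.49, 3, "heads", "outer", (1, 0.2, 0.05)),
        ],
    ),
    "T6_protein": dict(
        instrument="D17",
        description="yeast extract/ubiquinone bilayer after human-enzyme addition",
        layers=[
            ("inner heads", 9, _vec(3.0, 2.8, 2.6, 2.4), 0.53, 5, "heads", "inner", (1, 0.2, 0.05)),
            ("inner chains", 13, -0.22, 0.10, 4, "chains", "inner", (1, 0.1, 0.02)),
            ("ubiquinone layer", 4, 0.19, 0.10, 1, "mid", None, (1, 0.1, 0.02)),
            ("outer chains + protein", 13, _vec(0.10, 0.06, 0.02, -0.02), 0.10, 1, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads + protein", 8, _vec(3.0, 2.8, 2.5, 2.3), 0.50, 4, "heads", "outer", (1, 0.2, 0.05)),
            ("protein layer 1", 40, _PROT_RHO, 0.70, 6, "protein", None, (5, 0.2, 0.03)),
            ("protein layer 2", 60, _PROT_RHO, 0.95, 6, "protein", None, (15, 0.2, None)),
        ],
    ),
    "T7_lipid": dict(
        instrument="D17",
        description="bacterial-mimic PC/PE/PG/cardiolipin bilayer",
        layers=[
            ("inner heads", 9, _vec(2.9, 2.7, 2.6, 2.4), 0.56, 4, "heads", "inner", (1, 0.2, 0.08)),
            ("inner chains", 16, -0.27, 0.09, 6, "chains", "inner", (1, 0.1, 0.02)),
            ("outer chains", 16, -0.27, 0.09, 3, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads", 9, _vec(2.9, 2.7, 2.6, 2.4), 0.56, 6, "heads", "outer", (1, 0.2, 0.08)),
        ],
    ),
    "T7_protein": dict(
        instrument="D17",
        description="bacterial-mimic bilayer after bacterial-enzyme addition",
        layers=[
            ("inner heads", 9, _vec(2.9, 2.7, 2.6, 2.4), 0.60, 5, "heads", "inner", (1, 0.2, 0.08)),
            ("inner chains", 16, -0.27, 0.16, 6, "chains", "inner", (1, 0.1, 0.02)),
            ("outer chains + protein", 15, _vec(0.55, 0.45, 0.35, 0.11), 0.16, 4, "chains", "outer", (1, 0.1, 0.02)),
            ("outer heads + protein", 8, _vec(2.9, 2.7, 2.5, 2.3), 0.62, 5, "heads", "outer", (1, 0.2, 0.05)),
            ("protein layer 1", 40, _PROT_RHO, 0.63, 5, "protein", None, (5, 0.2, 0.02)),
            ("protein layer 2", 55, _PROT_RHO, 0.93, 5, "protein", None, (15, 0.2, None)),
        ],
    ),
}


def fixture_ids() -> list[str]:
    return sorted(_TABLES)


def fixture_stack(fixture_id: str) -> Fixture:
    """Build the registered fixture; unknown ids raise with the registry listed."""
    try:
        entry = _TABLES[fixture_id]
    except KeyError:
        raise KeyError(
            f"unknown fixture {fixture_id!r}; registered: {', '.join(fixture_ids())}"
        ) from None
    layers = [_lay(*row) for row in entry["layers"]]
    instrument = INTER if entry["instrument"] == "INTER" else D17
    qgrid = INTER_QGRID if entry["instrument"] == "INTER" else D17_QGRID
    return Fixture(
        id=fixture_id,
        stack=_stack(layers),
        instrument=instrument,
        qgrid=qgrid.copy(),
        description=entry["description"],
    )


def model_reflectivity(
    fixture: Fixture, contrast: SolventContrast, q: np.ndarray | None = None
) -> np.ndarray:
    """Noise-free forward model: smeared reflectivity x scale + background."""
    q = fixture.qgrid if q is None else np.asarray(q, dtype=float)
    slds, thick, rough = fixture.stack.profile(contrast)

    # fixtures knowingly pair a thin central layer with comparable roughness;
    # Nevot-Croce is used consistently in simulation and refinement
    def raw(qq):
        return abeles_profile(qq, slds, thick, rough, microslice=False)

    smeared = smear(raw, q, instrument=fixture.instrument)
    return fixture.instrument.scale * smeared.r + fixture.instrument.background


def simulate_dataset(
    fixture: Fixture,
    contrast: SolventContrast | str,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> ReflectivityDataset:
    """One noisy reflectivity dataset at a single solvent contrast.

    R_obs = model + Gaussian noise with sigma = relative_error * model; the
    dR column stores that sigma.  Deterministic for a given seed.
    """
    if isinstance(contrast, str):
        contrast = SolventContrast.from_name(contrast)
    if contrast.name not in {c.name for c in fixture.contrasts}:
        raise ValueError(f"contrast {contrast.name!r} not part of fixture {fixture.id}")
    noise = noise or NoiseModel(background=fixture.instrument.background)
    r_model = model_reflectivity(fixture, contrast)
    dr = noise.relative_error * r_model
    rng = np.random.default_rng(seed)
    r_obs = r_model + rng.normal(0.0, 1.0, size=r_model.shape) * dr
    dq = fixture.instrument.dq_over_q * fixture.qgrid
    return ReflectivityDataset(
        q=fixture.qgrid.copy(),
        r=r_obs,
        dr=dr,
        dq=dq,
        contrast=contrast.name,
        instrument=fixture.instrument.name,
        meta={"fixture": fixture.id, "seed": seed,
              "relative_error": noise.relative_error},
    )


def simulate_experiment(
    fixture: Fixture, seed: int = 0, noise: NoiseModel | None = None
) -> list[ReflectivityDataset]:
    """The four-contrast experiment: one dataset per standard contrast.

    All four datasets share the same structure; their noise streams derive
    from ``seed`` plus fixed per-contrast offsets 0..3 so realizations are
    reproducible yet independent.
    """
    return [
        simulate_dataset(fixture, contrast, noise=noise, seed=seed + offset)
        for offset, contrast in enumerate(fixture.contrasts)
    ]


def _rho_bounds(template_value: float) -> tuple[float, float]:
    # prior band encoding the deuteration scheme of the layer material, not
    # its refined value: hydrogenous chains, mixed central layer, or
    # chain-deuterated material
    if template_value < 1.0:
        return (-0.6, 1.5)
    if template_value < 3.5:
        return (0.0, 5.0)
    return (3.5, 7.0)


def recovery_bounds(fixture: Fixture) -> dict[str, tuple[float, float]]:
    """Generic free-parameter bounds for refitting a simulated fixture.

    Mirrors the refinement strategy of the study: layer thicknesses and
    solvent fractions free everywhere, intrinsic SLDs free in the chain
    region (where deuteration contrast carries the information), headgroup
    and protein SLDs fixed at their composition-derived values, roughnesses
    held at the characterized values.  Bounds are role-based physical
    ranges; optimizers start from their midpoints.
    """
    import re as _re

    bounds: dict[str, tuple[float, float]] = {}
    counts: dict[str, int] = {}
    for lay in fixture.stack.layers:
        slug = _re.sub(r"[^a-z0-9]+", "_", lay.name.lower()).strip("_")
        counts[slug] = counts.get(slug, 0) + 1
        if counts[slug] > 1:
            slug = f"{slug}_{counts[slug]}"
        if lay.role == "heads":
            bounds[f"tau_{slug}"] = (5.0, 15.0)
            bounds[f"phi_{slug}"] = (0.2, 0.8)
        elif lay.role == "chains":
            bounds[f"tau_{slug}"] = (8.0, 22.0)
            rho = lay.sld if not isinstance(lay.sld, dict) else lay.sld["D2O"]
            bounds[f"rho_{slug}"] = _rho_bounds(float(rho))
        elif lay.role == "mid":
            # the thin central layer enters the reflectivity essentially
            # through the product of thickness and SLD contrast; its SLD is
            # therefore refined at the characterized nominal thickness
            rho = lay.sld if not isinstance(lay.sld, dict) else lay.sld["D2O"]
            bounds[f"rho_{slug}"] = _rho_bounds(float(rho))
        elif lay.role == "protein" and counts.get("protein_layer", 1) == 1:
            bounds[f"tau_{slug}"] = (25.0, 60.0)
            bounds[f"phi_{slug}"] = (0.5, 0.95)
    if any(lay.role in ("chains", "mid") for lay in fixture.stack.layers):
        bounds["phi_chains"] = (0.0, 0.4)
    return bounds


def fixture_uncertainties(fixture_id: str) -> dict[str, float]:
    """Published fitting uncertainties keyed by co-refinement parameter name.

    Thickness/SLD/solvent-fraction intervals from the source tables; the
    shared chain-region solvent fraction takes the chain layers' interval.
    """
    from .corefine import _slug

    entry = _TABLES[fixture_id]
    out: dict[str, float] = {}
    counts: dict[str, int] = {}
    for row in entry["layers"]:
        name, role = row[0], row[5]
        dtau, drho, dphi = row[7]
        slug = _slug(name)
        counts[slug] = counts.get(slug, 0) + 1
        if counts[slug] > 1:
            slug = f"{slug}_{counts[slug]}"
        if dtau is not None:
            out[f"tau_{slug}"] = float(dtau)
        if drho is not None:
            out[f"rho_{slug}"] = float(drho)
        if dphi is not None:
            if role in ("chains", "mid"):
                out["phi_chains"] = float(dphi)
            else:
                out[f"phi_{slug}"] = float(dphi)
    return out


def recovery_model(fixture: Fixture):
    """A :class:`~refmem.corefine.StackModel` configured for refitting.

    Frees the parameters of :func:`recovery_bounds` and, when the
    characterized structure has equal leaflet chain thicknesses (as all the
    registered lipid-only structures do), ties the outer chain thickness to
    the inner so a single parameter describes both leaflets.
    """
    from .corefine import StackModel, _slug

    model = StackModel(fixture.stack, fixture.instrument)
    bounds = recovery_bounds(fixture)
    chains = fixture.stack.find("chains")
    tie = (
        len(chains) == 2
        and chains[0].thickness == chains[1].thickness
        and not fixture.stack.find("protein")
    )
    if tie:
        slug_in, slug_out = (_slug(c.name) for c in chains)
        bounds.pop(f"tau_{slug_out}", None)
        model.set_free(bounds)
        model.params[f"tau_{slug_out}"].set(expr=f"tau_{slug_in}")
    else:
        model.set_free(bounds)
    return model
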