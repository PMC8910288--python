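"""Structural quantities derived from a (fitted) membrane stack.

Coverage, total bilayer thickness, per-component compositions, absolute
protein penetration, adsorbed amount and protein:lipid ratio — the numbers a
reflectometry table reports alongside the raw layer parameters.  All
percentages are volume percent; thicknesses are Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .components import ScatteringComponent
from .slab import Layer, SlabStack, area_per_lipid

__all__ = [
    "DerivedQuantities",
    "coverage",
    "total_thickness",
    "total_composition",
    "absolute_protein_fraction",
    "adsorbed_amount",
    "derive",
]


def _phi(layer: Layer) -> float:
    phi = layer.solvent_fraction
    if isinstance(phi, Mapping):
        return float(sum(phi.values()) / len(phi))
    return float(phi)


def _chain_region(stack: SlabStack) -> list[Layer]:
    return [lay for lay in stack.layers if lay.role in ("chains", "mid")]


def coverage(stack: SlabStack) -> float:
    """Bilayer coverage: 100 minus the chain-region solvent vol%.

    The solvent fraction is thickness-averaged over the chain layers
    (including a central ubiquinone layer, which shares the chain region).
    """
    chains = _chain_region(stack)
    if not chains:
        raise ValueError("stack has no chain layers")
    total = sum(lay.thickness for lay in chains)
    phi = sum(lay.thickness * _phi(lay) for lay in chains) / total
    return 100.0 * (1.0 - phi)


def total_thickness(stack: SlabStack) -> float:
    """Total bilayer thickness: heads + chains (+ central layer), Å.

    Oxide and adsorbed protein layers are excluded.  An empty stack has zero
    thickness.
    """
    return stack.total_thickness


def _component_matches(key, component) -> bool:
    if isinstance(key, ScatteringComponent):
        key = key.name
    if isinstance(component, ScatteringComponent):
        component = component.name
    return str(key) == str(component)


def total_composition(stack: SlabStack, component) -> float:
    """Total vol% of a component over the chain region.

    Weighted by layer thickness and material (non-solvent) volume, i.e. by
    the actual volume of material each layer contributes:

        100 * sum_i tau_i (1 - phi_i) f_i / sum_i tau_i (1 - phi_i)

    Returns 0 with a warning when the component appears nowhere.
    """
    chains = _chain_region(stack)
    if not chains:
        raise ValueError("stack has no chain layers")
    num = den = 0.0
    found = False
    for lay in chains:
        w = lay.thickness * (1.0 - _phi(lay))
        den += w
        if lay.composition is None:
            continue
        for key, frac in lay.composition.items():
            if _component_matches(key, component):
                num += w * frac
                found = True
    if not found:
        warnings.warn(f"component {component!r} not present in any chain layer")
        return 0.0
    return 100.0 * num / den


def absolute_protein_fraction(rel_fraction: float, solvent_fraction: float) -> float:
    """Convert protein vol% relative to the lipids into vol% of the whole layer.

    Both inputs in percent: result = rel * (100 - solvent) / 100.
    """
    if not 0.0 <= rel_fraction <= 100.0 or not 0.0 <= solvent_fraction <= 100.0:
        raise ValueError("fractions must be in [0, 100]")
    return rel_fraction * (100.0 - solvent_fraction) / 100.0


def adsorbed_amount(
    layers: SlabStack | Iterable[tuple[float, float]],
    protein_volume: float,
    protein: ScatteringComponent | str = "protein",
) -> float:
    """Adsorbed protein amount in molecules/µm².

    Sums tau * phi_protein / V_protein over protein-bearing layers, where
    phi_protein is the protein fraction of the whole layer, and converts from
    Å⁻² to µm⁻² (x 1e8).  ``layers`` is either a stack whose compositions
    reference the protein component, or explicit (thickness, protein volume
    fraction of the whole layer) pairs.
    """
    if protein_volume <= 0:
        raise ValueError("protein volume must be > 0")
    if isinstance(layers, SlabStack):
        pairs = []
        for lay in layers.layers:
            if lay.composition is None:
                continue
            f = sum(
                frac
                for key, frac in lay.composition.items()
                if _component_matches(key, protein)
            )
            if f > 0:
                pairs.append((lay.thickness, f * (1.0 - _phi(lay))))
        layers = pairs
    total = sum(tau * f for tau, f in layers)
    return total * 1e8 / protein_volume


@dataclass
class DerivedQuantities:
    """The derived-quantity block of a results table."""

    coverage: float  # vol%
    total_thickness: float  # Å
    compositions: dict[str, float]  # component -> vol% of chain region
    area_per_lipid: dict[str, float]  # leaflet -> Å² (hydrated chain layer)
    adsorbed: float | None = None  # molecules/µm²
    protein_lipid_ratio: float | None = None  # N in 1:N


def derive(
    stack: SlabStack,
    components: Iterable[str] = (),
    protein: ScatteringComponent | None = None,
) -> DerivedQuantities:
    """Compute the standard derived-quantity set from a stack.

    ``components`` names species whose total chain-region vol% should be
    reported; ``protein`` (with its molecular volume) enables the adsorbed
    amount and the outer-leaflet protein:lipid ratio.
    """
    comps = {c: total_composition(stack, c) for c in components}
    apl = {}
    for leaflet in ("inner", "outer"):
        try:
            apl[leaflet] = area_per_lipid(stack, leaflet, region="chains")
        except (ValueError, KeyError):
            pass
    adsorbed = ratio = None
    if protein is not None:
        adsorbed = adsorbed_amount(stack, protein.volume, protein)
        outer = stack.find("chains", "outer")
        if outer and outer[0].composition is not None:
            lay = outer[0]
            f_prot = sum(
                frac
                for key, frac in lay.composition.items()
                if _component_matches(key, protein)
            )
            lipid_frac = 1.0 - f_prot
            v_lipid = None
            try:
                v_lipid = area_per_lipid(stack, "outer", region="chains")
            except ValueError:
                pass
            if f_prot > 0:
                # per unit area: lipid count / protein count in the outer leaflet
                prot_per_area = lay.thickness * (1.0 - _phi(lay)) * f_prot / protein.volume
                from .components import get_component

                # mean chain volume per lipid from the layer composition
                vols, weights = [], []
                for key, frac in lay.composition.items():
                    if _component_matches(key, protein):
                        continue
                    comp = key if isinstance(key, ScatteringComponent) else get_component(str(key))
                    vols.append(comp.volume)
                    weights.append(frac)
                if vols and prot_per_area > 0:
                    wsum = sum(weights)
                    mol_weights = [w / v for w, v in zip(weights, vols)]
                    msum = sum(mol_weights)
                    v_mean = sum(
                        (mw / msum) * v for mw, v in zip(mol_weights, vols)
                    )
                    lip_per_area = (
                        lay.thickness * (1.0 - _phi(lay)) * lipid_frac / v_mean
                    )
                    ratio = lip_per_area / prot_per_area
    return DerivedQuantities(
        coverage=coverage(stack),
        total_thickness=total_thickness(stack),
        compositions=comps,
        area_per_lipid=apl,
        adsorbed=adsorbed,
        protein_lipid_ratio=ratio,
    )
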