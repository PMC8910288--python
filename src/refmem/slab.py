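"""Layered slab models of supported lipid membranes.

A supported bilayer at the Si/water interface is represented as a
:class:`SlabStack`: silicon fronting, a thin native-oxide layer, then an
ordered list of layers running from the substrate towards the solution.  Each
:class:`Layer` carries a thickness, an interfacial roughness against its
predecessor, a solvent volume fraction, and either a fixed intrinsic
(solvent-free) SLD per contrast or a composition in terms of registered
molecular components.  The mixed SLD of a layer at a solvent contrast is the
volume-fraction-weighted sum

    rho_layer = (1 - phi) * sum_i f_i rho_i(contrast)  +  phi * rho_solvent

which is the composition rule the whole analysis rests on.

:func:`build_bilayer` assembles the four-layer (heads/chains/chains/heads) and
five-layer (with a thin central ubiquinone-rich slab) membrane models from a
:class:`BilayerSpec`; :func:`add_protein` decorates a stack with penetrating
and adsorbed protein; :func:`apply_area_constraint` enforces equal area per
lipid in the headgroup and chain sublayers of a lipid-only leaflet.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .components import (
    ScatteringComponent,
    SolventContrast,
    get_component,
    mol_to_vol,
    vol_to_mol,
)

__all__ = [
    "Layer",
    "SlabStack",
    "BilayerSpec",
    "LIPID_CLASSES",
    "layer_sld",
    "build_bilayer",
    "add_protein",
    "apply_area_constraint",
    "area_per_lipid",
]

#: lipid class -> (head fragment, hydrogenous chain fragment, chain-deuterated fragment)
LIPID_CLASSES: dict[str, tuple[str, str, str | None]] = {
    "popc": ("popc_heads", "popc_chains", "d63popc_chains"),
    "tocl": ("tocl_heads", "tocl_chains", None),
    "pope": ("pope_heads", "pope_chains", None),
    "popg": ("popg_heads", "popg_chains", None),
    "pops": ("pops_heads", "pops_chains", None),
    "popi": ("popi_heads", "popi_chains", None),
}


def _as_component(c) -> ScatteringComponent:
    return c if isinstance(c, ScatteringComponent) else get_component(str(c))


@dataclass
class Layer:
    """One slab of the interfacial structure.

    ``sld`` is the intrinsic (solvent-free) SLD in 1e-6 Å⁻², either a scalar
    (contrast-independent) or a mapping contrast-name -> value.  Alternatively
    a ``composition`` {component -> volume fraction of the non-solvent part}
    may be given, from which the intrinsic SLD is computed per contrast
    (components with labile hydrogens then pick up solvent isotope exchange).
    ``solvent_fraction`` may likewise be contrast-dependent.
    """

    name: str
    thickness: float
    roughness: float = 0.0
    solvent_fraction: float | Mapping[str, float] = 0.0
    sld: float | Mapping[str, float] | None = None
    composition: Mapping[object, float] | None = None
    role: str = "layer"
    leaflet: str | None = None

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"layer {self.name!r}: thickness must be >= 0")
        if self.roughness < 0:
            raise ValueError(f"layer {self.name!r}: roughness must be >= 0")
        for phi in self._phi_values():
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"layer {self.name!r}: solvent fraction outside [0, 1]")
        if self.composition is not None:
            fracs = list(self.composition.values())
            if any(f < 0 for f in fracs):
                raise ValueError(f"layer {self.name!r}: negative composition fraction")
            if abs(sum(fracs) - 1.0) > 1e-6:
                raise ValueError(
                    f"layer {self.name!r}: composition fractions sum to "
                    f"{sum(fracs)}, expected 1"
                )
        if self.sld is None and self.composition is None:
            raise ValueError(f"layer {self.name!r}: needs sld or composition")

    def _phi_values(self):
        if isinstance(self.solvent_fraction, Mapping):
            return list(self.solvent_fraction.values())
        return [self.solvent_fraction]

    def solvent_fraction_at(self, contrast: SolventContrast) -> float:
        if isinstance(self.solvent_fraction, Mapping):
            return self.solvent_fraction[contrast.name]
        return self.solvent_fraction

    def intrinsic_sld(
        self, contrast: SolventContrast, exchange_completeness: float = 1.0
    ) -> float:
        """Solvent-free SLD of the layer material at a contrast."""
        if self.composition is not None:
            return sum(
                frac
                * _as_component(comp).sld(contrast.d2o_fraction, exchange_completeness)
                for comp, frac in self.composition.items()
            )
        if isinstance(self.sld, Mapping):
            return self.sld[contrast.name]
        return float(self.sld)

    def mixed_sld(
        self, contrast: SolventContrast, exchange_completeness: float = 1.0
    ) -> float:
        """Full layer SLD including the solvent contribution."""
        phi = self.solvent_fraction_at(contrast)
        return (1.0 - phi) * self.intrinsic_sld(
            contrast, exchange_completeness
        ) + phi * contrast.sld


def layer_sld(layer: Layer, contrast: SolventContrast) -> float:
    """Volume-fraction-weighted SLD of a layer including its solvent term."""
    return layer.mixed_sld(contrast)


@dataclass
class SlabStack:
    """Silicon fronting | oxide | ordered membrane layers | aqueous backing."""

    fronting: ScatteringComponent = field(
        default_factory=lambda: get_component("silicon")
    )
    oxide: Layer | None = None
    layers: list[Layer] = field(default_factory=list)
    backing: SolventContrast | None = None
    #: roughness of the outermost interface against the bulk solvent, Å
    backing_roughness: float = 3.0

    def all_layers(self) -> list[Layer]:
        return ([self.oxide] if self.oxide is not None else []) + list(self.layers)

    def profile(self, contrast: SolventContrast | None = None):
        """(slds, thicknesses, roughnesses) arrays for the optical calculation.

        ``slds`` has length n_layers + 2 (fronting and backing included),
        ``thicknesses`` length n_layers, ``roughnesses`` length n_layers + 1
        (one per interface, attached to the preceding layer's top surface).
        """
        contrast = contrast or self.backing
        if contrast is None:
            raise ValueError("no solvent contrast given and stack has no backing")
        inner = self.all_layers()
        slds = (
            [self.fronting.sld()]
            + [lay.mixed_sld(contrast) for lay in inner]
            + [contrast.sld]
        )
        thick = [lay.thickness for lay in inner]
        # one roughness per interface: each layer's value applies to the
        # interface with its predecessor; the solvent interface has its own
        rough = [lay.roughness for lay in inner] + [
            self.backing_roughness if inner else 0.0
        ]
        return slds, thick, rough

    def find(self, role: str, leaflet: str | None = None) -> list[Layer]:
        return [
            lay
            for lay in self.layers
            if lay.role == role and (leaflet is None or lay.leaflet == leaflet)
        ]

    @property
    def bilayer_layers(self) -> list[Layer]:
        """Layers belonging to the membrane proper (heads, chains, mid)."""
        return [lay for lay in self.layers if lay.role in ("heads", "chains", "mid")]

    @property
    def total_thickness(self) -> float:
        return sum(lay.thickness for lay in self.bilayer_layers)

    def copy(self) -> "SlabStack":
        return copy.deepcopy(self)


def default_oxide(thickness: float = 12.0, solvent_fraction: float = 0.10,
                  roughness: float = 3.0) -> Layer:
    """Native SiO2 layer with a standard hydration."""
    return Layer(
        "oxide",
        thickness,
        roughness,
        solvent_fraction,
        composition={"silica": 1.0},
        role="oxide",
    )


@dataclass
class BilayerSpec:
    """Composition-parameterized description of a supported membrane.

    Leaflet compositions are volume fractions of the *chain* volume per lipid
    class and must each sum to 1.  ``q10_fraction`` is the ubiquinone volume
    fraction of the thin central layer; a positive value selects the
    five-layer model.  Chain thicknesses are per-leaflet chain-equivalent
    values: in the five-layer model the chain volume residing in the central
    layer is subtracted from the two chain slabs, so total chain volume is
    conserved between the 4- and 5-layer parameterizations.
    """

    inner_lipids: Mapping[str, float]
    outer_lipids: Mapping[str, float]
    deuterated_pc: bool = False
    q10_fraction: float = 0.0
    q10_thickness: float = 4.0
    force_four_layer: bool = False
    force_five_layer: bool = False
    head_thickness: tuple[float, float] = (10.0, 9.0)
    chain_thickness: tuple[float, float] = (16.0, 16.0)
    head_solvent: tuple[float, float] = (0.54, 0.51)
    chain_solvent: float = 0.19
    roughness: float = 3.0
    # protein decoration
    protein: ScatteringComponent | None = None
    penetration_outer_chains: float = 0.0  # vol fraction relative to the lipids
    penetration_outer_heads: float | None = None
    penetration_inner: float = 0.0  # must stay 0; the model forbids it
    surface_layers: Sequence[tuple[float, float]] = ()  # (thickness, solvent phi)

    def __post_init__(self) -> None:
        for side, comp in (("inner", self.inner_lipids), ("outer", self.outer_lipids)):
            if abs(sum(comp.values()) - 1.0) > 1e-6:
                raise ValueError(f"{side} leaflet composition must sum to 1")
            for cls in comp:
                if cls not in LIPID_CLASSES:
                    raise KeyError(f"unknown lipid class {cls!r}")
        if not 0.0 <= self.q10_fraction <= 1.0:
            raise ValueError("q10_fraction must be in [0, 1]")
        if not 0.0 <= self.penetration_outer_chains <= 1.0:
            raise ValueError("penetration fraction must be in [0, 1]")

    def chain_fragment(self, lipid_class: str) -> str:
        head, chain_h, chain_d = LIPID_CLASSES[lipid_class]
        if self.deuterated_pc and chain_d is not None:
            return chain_d
        return chain_h

    def head_fragment(self, lipid_class: str) -> str:
        return LIPID_CLASSES[lipid_class][0]

    def chain_composition(self, leaflet: str) -> dict[str, float]:
        comp = self.inner_lipids if leaflet == "inner" else self.outer_lipids
        return {self.chain_fragment(cls): f for cls, f in comp.items()}

    def head_composition(self, leaflet: str) -> dict[str, float]:
        """Head-volume fractions implied by the chain-volume fractions."""
        comp = self.inner_lipids if leaflet == "inner" else self.outer_lipids
        chain_vols = {
            cls: get_component(self.chain_fragment(cls)).volume for cls in comp
        }
        head_vols = {cls: get_component(self.head_fragment(cls)).volume for cls in comp}
        mol = vol_to_mol(dict(comp), chain_vols)
        by_class = mol_to_vol(mol, head_vols)
        return {self.head_fragment(cls): f for cls, f in by_class.items()}


def build_bilayer(spec: BilayerSpec, oxide: Layer | None = None) -> SlabStack:
    """Assemble the 4- or 5-layer membrane stack from a composition spec."""
    if spec.q10_fraction > 0 and spec.force_four_layer:
        raise ValueError("cannot force a four-layer model with q10_fraction > 0")
    five_layer = spec.q10_fraction > 0 or spec.force_five_layer

    tau_h_in, tau_h_out = spec.head_thickness
    tau_c_in, tau_c_out = spec.chain_thickness
    sigma = spec.roughness

    layers: list[Layer] = [
        Layer(
            "inner heads",
            tau_h_in,
            sigma,
            spec.head_solvent[0],
            composition=spec.head_composition("inner"),
            role="heads",
            leaflet="inner",
        )
    ]

    if five_layer:
        f_q = spec.q10_fraction
        tau_mid = spec.q10_thickness
        # chain volume relocated into the central layer, split between leaflets
        relocated = (1.0 - f_q) * tau_mid / 2.0
        tau_c_in_eff = tau_c_in - relocated
        tau_c_out_eff = tau_c_out - relocated
        if tau_c_in_eff < 0 or tau_c_out_eff < 0:
            raise ValueError("central layer thicker than available chain volume")
        mid_chains = {}
        for leaflet in ("inner", "outer"):
            for frag, f in spec.chain_composition(leaflet).items():
                mid_chains[frag] = mid_chains.get(frag, 0.0) + 0.5 * f
        mid_comp = {"q10": f_q}
        for frag, f in mid_chains.items():
            mid_comp[frag] = mid_comp.get(frag, 0.0) + (1.0 - f_q) * f
        layers += [
            Layer(
                "inner chains",
                tau_c_in_eff,
                sigma,
                spec.chain_solvent,
                composition=spec.chain_composition("inner"),
                role="chains",
                leaflet="inner",
            ),
            Layer(
                "ubiquinone + chains",
                tau_mid,
                sigma,
                spec.chain_solvent,
                composition=mid_comp,
                role="mid",
            ),
            Layer(
                "outer chains",
                tau_c_out_eff,
                sigma,
                spec.chain_solvent,
                composition=spec.chain_composition("outer"),
                role="chains",
                leaflet="outer",
            ),
        ]
    else:
        layers += [
            Layer(
                "inner chains",
                tau_c_in,
                sigma,
                spec.chain_solvent,
                composition=spec.chain_composition("inner"),
                role="chains",
                leaflet="inner",
            ),
            Layer(
                "outer chains",
                tau_c_out,
                sigma,
                spec.chain_solvent,
                composition=spec.chain_composition("outer"),
                role="chains",
                leaflet="outer",
            ),
        ]

    layers.append(
        Layer(
            "outer heads",
            tau_h_out,
            sigma,
            spec.head_solvent[1],
            composition=spec.head_composition("outer"),
            role="heads",
            leaflet="outer",
        )
    )

    return SlabStack(
        fronting=get_component("silicon"),
        oxide=oxide if oxide is not None else default_oxide(),
        layers=layers,
    )


def _mix_in_protein(layer: Layer, protein: ScatteringComponent, p: float) -> Layer:
    """Replace a fraction p (relative to the lipids) of a layer's material."""
    comp = {k: (1.0 - p) * f for k, f in layer.composition.items()}
    comp[protein] = comp.get(protein, 0.0) + p
    return replace(layer, composition=comp)


def add_protein(stack: SlabStack, spec: BilayerSpec) -> SlabStack:
    """Decorate a lipid stack with penetrating and surface-adsorbed protein.

    The outer-chain and outer-head layers receive a protein volume fraction
    relative to the lipids; the inner leaflet is never modified (penetration
    into it is outside the model and raises).  Surface protein layers are
    appended with the stated thickness and solvent fraction.
    """
    if spec.penetration_inner != 0:
        raise ValueError("the model forbids protein penetration into the inner leaflet")
    if spec.protein is None and (
        spec.penetration_outer_chains > 0 or spec.surface_layers
    ):
        raise ValueError("spec.protein required to add protein layers")
    out = stack.copy()
    if spec.penetration_outer_chains == 0 and not spec.surface_layers:
        return out

    protein = spec.protein
    p_chain = spec.penetration_outer_chains
    p_head = (
        spec.penetration_outer_heads
        if spec.penetration_outer_heads is not None
        else p_chain
    )
    for i, lay in enumerate(out.layers):
        if lay.leaflet != "outer" or lay.composition is None:
            continue
        if lay.role == "chains" and p_chain > 0:
            out.layers[i] = _mix_in_protein(lay, protein, p_chain)
        elif lay.role == "heads" and p_head > 0:
            out.layers[i] = _mix_in_protein(lay, protein, p_head)
    for j, (tau, phi) in enumerate(spec.surface_layers, start=1):
        out.layers.append(
            Layer(
                f"protein layer {j}",
                tau,
                3.0,
                phi,
                composition={protein: 1.0},
                role="protein",
            )
        )
    return out


def _leaflet_per_lipid_volumes(stack: SlabStack, leaflet: str):
    chains = stack.find("chains", leaflet)
    heads = stack.find("heads", leaflet)
    if not chains or not heads:
        raise ValueError(f"stack has no complete {leaflet!r} leaflet")
    chain_lay, head_lay = chains[0], heads[0]
    for lay in (chain_lay, head_lay):
        if lay.composition is None:
            raise ValueError("area constraint needs composition-defined layers")
        for comp in lay.composition:
            name = comp.name if isinstance(comp, ScatteringComponent) else str(comp)
            if "head" not in name and "chain" not in name:
                raise ValueError(
                    f"leaflet {leaflet!r} contains non-lipid component {name!r}; "
                    "the area constraint applies to lipid-only leaflets"
                )
    chain_vols = {c: _as_component(c).volume for c in chain_lay.composition}
    head_vols = {c: _as_component(c).volume for c in head_lay.composition}
    mol = vol_to_mol(dict(chain_lay.composition), chain_vols)
    v_chain = sum(x * chain_vols[c] for c, x in mol.items())
    # head volume per lipid follows the same mole fractions
    by_head = {}
    for c, x in mol.items():
        head_name = str(c).replace("_chains", "_heads").replace("d63popc", "popc")
        by_head[head_name] = x
    v_head = sum(x * get_component(h).volume for h, x in by_head.items())
    return chain_lay, head_lay, v_chain, v_head


def area_per_lipid(stack: SlabStack, leaflet: str, region: str = "chains") -> float:
    """Area per lipid molecule (Å²) in the hydrated chain or head sublayer."""
    chain_lay, head_lay, v_chain, v_head = _leaflet_per_lipid_volumes(stack, leaflet)
    lay, v = (chain_lay, v_chain) if region == "chains" else (head_lay, v_head)
    phi = lay.solvent_fraction if not isinstance(lay.solvent_fraction, Mapping) else (
        list(lay.solvent_fraction.values())[0]
    )
    return v / (lay.thickness * (1.0 - phi))


def apply_area_constraint(stack: SlabStack, leaflet: str) -> SlabStack:
    """Set the head-layer hydration so head and chain areas per lipid agree.

    Solves V_head / (tau_head (1 - phi_head)) = V_chain / (tau_chain (1 - phi_chain))
    for phi_head; raises if the required value falls outside [0, 1].
    """
    out = stack.copy()
    chain_lay, head_lay, v_chain, v_head = _leaflet_per_lipid_volumes(out, leaflet)
    phi_c = chain_lay.solvent_fraction
    if isinstance(phi_c, Mapping):
        phi_c = list(phi_c.values())[0]
    phi_head = 1.0 - (v_head / v_chain) * chain_lay.thickness * (
        1.0 - phi_c
    ) / head_lay.thickness
    if not -1e-9 <= phi_head <= 1.0 + 1e-9:
        raise ValueError(
            f"area constraint infeasible for {leaflet!r} leaflet: "
            f"required head solvent fraction {phi_head:.3f} outside [0, 1]"
        )
    head_lay.solvent_fraction = min(max(phi_head, 0.0), 1.0)
    return out
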