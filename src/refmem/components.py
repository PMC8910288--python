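"""Scattering length densities of membrane components under H/D contrast variation.

Everything a slab model needs to know about a molecular species is collected in
a :class:`ScatteringComponent`: its partial molecular volume, its bound coherent
scattering length, and how many of its hydrogens exchange with the solvent.
From these the scattering length density (SLD) at any D2O/H2O mixture follows.

Unit conventions, used throughout the package:

* scattering lengths in fm,
* volumes in Å³,
* SLDs in 1e-6 Å⁻² (so ``sld = 10 * b_fm / volume_A3``),
* solvent composition as D2O volume fraction in [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "ScatteringComponent",
    "SolventContrast",
    "STANDARD_CONTRASTS",
    "CONTRAST_ORDER",
    "scattering_length",
    "parse_formula",
    "sld_from_formula",
    "solvent_sld",
    "match_point",
    "protein_volume",
    "protein_sld",
    "protein_component",
    "mol_to_vol",
    "vol_to_mol",
    "get_component",
    "component_registry",
    "residue_table",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d+\.?\d*|\.\d+)?")


def _load_elements() -> dict[str, float]:
    table = {}
    text = resources.files("refmem.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, b = line.split("\t")
        table[sym] = float(b)
    return table


#: bound coherent scattering lengths, fm (Sears compilation)
B_COH: dict[str, float] = _load_elements()

#: scattering-length gain when a labile H is replaced by D, fm
B_EXCHANGE = B_COH["D"] - B_COH["H"]


def scattering_length(formula: Mapping[str, float] | str) -> float:
    """Total bound coherent scattering length of a formula, in fm."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    b = 0.0
    for element, count in formula.items():
        if element not in B_COH:
            raise KeyError(
                f"no tabulated coherent scattering length for element {element!r}"
            )
        b += B_COH[element] * count
    return b


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-style formula such as ``C32H64`` or ``C32H4.15D59.85``.

    Fractional counts are allowed so that partial isotopic incorporation can be
    expressed directly in the formula.
    """
    out: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        element = m.group(1)
        count = float(m.group(2)) if m.group(2) else 1.0
        out[element] = out.get(element, 0.0) + count
    if pos != len(formula) or not out:
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


@dataclass(frozen=True)
class ScatteringComponent:
    """A molecular species with volume, scattering length and labile hydrogens.

    Parameters
    ----------
    name : str
    volume : float
        Partial molecular volume, Å³.
    b_coh : float
        Total bound coherent scattering length in fully protiated solvent, fm.
    n_labile : float, default 0
        Number of solvent-exchangeable hydrogens. May be fractional for
        composite species.
    formula : dict, optional
        Element->count map the scattering length was derived from, if known.
    """

    name: str
    volume: float
    b_coh: float
    n_labile: float = 0.0
    formula: Mapping[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"component {self.name!r}: volume must be > 0")
        if self.formula is not None:
            n_h = self.formula.get("H", 0.0) + self.formula.get("D", 0.0)
            if self.n_labile > n_h + 1e-9:
                raise ValueError(
                    f"component {self.name!r}: n_labile exceeds hydrogen count"
                )

    def b_at(self, d2o_fraction: float = 0.0, exchange_completeness: float = 1.0) -> float:
        """Scattering length (fm) with labile H partially exchanged for D."""
        return self.b_coh + self.n_labile * d2o_fraction * exchange_completeness * B_EXCHANGE

    def sld(self, d2o_fraction: float = 0.0, exchange_completeness: float = 1.0) -> float:
        """SLD (1e-6 Å⁻²) in a solvent of the given D2O volume fraction."""
        return 10.0 * self.b_at(d2o_fraction, exchange_completeness) / self.volume

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: Mapping[str, float] | str,
        volume: float,
        n_labile: float = 0.0,
    ) -> "ScatteringComponent":
        if isinstance(formula, str):
            formula = parse_formula(formula)
        return cls(name, volume, scattering_length(formula), n_labile, dict(formula))


def sld_from_formula(formula: Mapping[str, float] | str, volume: float) -> float:
    """SLD (1e-6 Å⁻²) of a molecule given its formula and volume (Å³)."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return 10.0 * scattering_length(formula) / volume


# Pure-water endpoints.  Equal molecular volumes of 30.0 Å³ are used for H2O
# and D2O, the convention that reproduces the standard match points.
WATER_H = ScatteringComponent.from_formula("water", "H2O", 30.0, n_labile=2)
WATER_D = ScatteringComponent.from_formula("heavy_water", "D2O", 30.0)

SLD_H2O = WATER_H.sld()
SLD_D2O = WATER_D.sld()


def solvent_sld(d2o_fraction: float) -> float:
    """SLD of a D2O/H2O mixture, linear in the D2O volume fraction."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    return SLD_H2O + d2o_fraction * (SLD_D2O - SLD_H2O)


def match_point(target_sld: float) -> float:
    """D2O volume fraction whose mixture SLD equals ``target_sld``.

    Inverse of :func:`solvent_sld`; raises for targets outside the attainable
    [SLD(H2O), SLD(D2O)] band.
    """
    lo, hi = min(SLD_H2O, SLD_D2O), max(SLD_H2O, SLD_D2O)
    if not lo <= target_sld <= hi:
        raise ValueError(
            f"target SLD {target_sld} outside attainable range [{lo:.3f}, {hi:.3f}]"
        )
    return (target_sld - SLD_H2O) / (SLD_D2O - SLD_H2O)


@dataclass(frozen=True)
class SolventContrast:
    """A D2O/H2O mixture identified by name with its D2O volume fraction."""

    name: str
    d2o_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("d2o_fraction must be in [0, 1]")

    @property
    def sld(self) -> float:
        return solvent_sld(self.d2o_fraction)

    @classmethod
    def from_name(cls, name: str) -> "SolventContrast":
        key = name.strip().lower()
        for c in STANDARD_CONTRASTS:
            if c.name.lower() == key:
                return c
        raise KeyError(
            f"unknown contrast {name!r}; standard contrasts are "
            + ", ".join(c.name for c in STANDARD_CONTRASTS)
        )


#: the four buffer contrasts of the measurement protocol: pure D2O, the
#: 66 vol% mixture matched to 4e-6 Å⁻² (CM4), the 38 vol% silicon-matched
#: mixture (CMSi) and pure H2O.
STANDARD_CONTRASTS: tuple[SolventContrast, ...] = (
    SolventContrast("D2O", 1.0),
    SolventContrast("CM4", 0.66),
    SolventContrast("CMSi", 0.38),
    SolventContrast("H2O", 0.0),
)

CONTRAST_ORDER: tuple[str, ...] = tuple(c.name for c in STANDARD_CONTRASTS)


# ---------------------------------------------------------------------------
# proteins

def residue_table(volume_set: str = "zamyatnin1984") -> dict[str, ScatteringComponent]:
    """Per-residue components for the requested published volume set."""
    text = resources.files("refmem.data").joinpath("residues.tsv").read_text()
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    col = {"zamyatnin1984": 4, "jacrot1976": 5}.get(volume_set)
    if col is None:
        raise KeyError(
            f"unknown residue volume set {volume_set!r}; "
            "available: zamyatnin1984, jacrot1976"
        )
    table = {}
    for code, name, formula, n_labile, *vols in rows:
        table[code] = ScatteringComponent.from_formula(
            name, formula, float(vols[col - 4]), n_labile=float(n_labile)
        )
    return table


def _residue_counts(sequence_or_counts) -> dict[str, float]:
    if isinstance(sequence_or_counts, Mapping):
        counts = dict(sequence_or_counts)
    else:
        counts = {}
        for code in str(sequence_or_counts).strip().upper():
            if code.isspace():
                continue
            counts[code] = counts.get(code, 0) + 1
    if not counts:
        raise ValueError("empty residue composition")
    return counts


def protein_volume(sequence, volume_set: str = "zamyatnin1984") -> float:
    """Molecular volume (Å³) of a protein as the sum of its residue volumes."""
    table = residue_table(volume_set)
    counts = _residue_counts(sequence)
    total = 0.0
    for code, n in counts.items():
        if code not in table:
            raise KeyError(f"unknown residue code {code!r}")
        total += n * table[code].volume
    return total


def protein_component(
    sequence, name: str = "protein", volume_set: str = "zamyatnin1984"
) -> ScatteringComponent:
    """Aggregate a residue composition (or sequence) into one component.

    The component carries the summed volume, the scattering length in H2O, and
    the total labile-hydrogen count, so its SLD at any contrast follows from
    :meth:`ScatteringComponent.sld`.
    """
    table = residue_table(volume_set)
    counts = _residue_counts(sequence)
    volume = b = n_lab = 0.0
    for code, n in counts.items():
        if code not in table:
            raise KeyError(f"unknown residue code {code!r}")
        res = table[code]
        volume += n * res.volume
        b += n * res.b_coh
        n_lab += n * res.n_labile
    return ScatteringComponent(name, volume, b, n_lab)


def protein_sld(
    sequence,
    d2o_fraction: float,
    exchange_completeness: float = 1.0,
    volume_set: str = "zamyatnin1984",
) -> float:
    """Protein SLD (1e-6 Å⁻²) at a solvent contrast.

    Labile hydrogens take the solvent's isotopic composition: their scattering
    length is interpolated between H and D by
    ``d2o_fraction * exchange_completeness``.  With full exchange the SLD is
    exactly linear in the solvent D2O fraction.
    """
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError("d2o_fraction must be in [0, 1]")
    return protein_component(sequence, volume_set=volume_set).sld(
        d2o_fraction, exchange_completeness
    )


# ---------------------------------------------------------------------------
# composition bookkeeping

def mol_to_vol(
    mol_fractions: Mapping[str, float], volumes: Mapping[str, float]
) -> dict[str, float]:
    """Convert mole fractions to volume fractions, phi_i ∝ x_i V_i."""
    if any(x < 0 for x in mol_fractions.values()):
        raise ValueError("mole fractions must be non-negative")
    total = sum(mol_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mole fractions must sum to 1, got {total}")
    weighted = {k: x * volumes[k] for k, x in mol_fractions.items()}
    norm = sum(weighted.values())
    return {k: v / norm for k, v in weighted.items()}


def vol_to_mol(
    vol_fractions: Mapping[str, float], volumes: Mapping[str, float]
) -> dict[str, float]:
    """Inverse of :func:`mol_to_vol`: x_i ∝ phi_i / V_i."""
    if any(p < 0 for p in vol_fractions.values()):
        raise ValueError("volume fractions must be non-negative")
    weighted = {k: p / volumes[k] for k, p in vol_fractions.items()}
    norm = sum(weighted.values())
    return {k: v / norm for k, v in weighted.items()}


# ---------------------------------------------------------------------------
# component registry (lipid fragments, solvents, substrate materials)

def component_registry() -> dict[str, ScatteringComponent]:
    """All components from the shipped table, keyed by name."""
    text = resources.files("refmem.data").joinpath("lipids.tsv").read_text()
    registry = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, formula, volume, n_labile, _note = line.split("\t")
        registry[name] = ScatteringComponent.from_formula(
            name, formula, float(volume), n_labile=float(n_labile)
        )
    return registry


_REGISTRY: dict[str, ScatteringComponent] | None = None


def get_component(name: str) -> ScatteringComponent:
    """Look up a shipped component by name (see ``data/lipids.tsv``)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = component_registry()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown component {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
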