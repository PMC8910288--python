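# Methods

`refmem` analyses specular neutron reflectometry (NR) from solid-supported
lipid membranes with a composition-parameterized slab model refined
simultaneously against several solvent contrasts. This note records the model,
its assumptions, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Scattering length densities and contrast variation

Every molecular species is a `ScatteringComponent` with a partial molecular
volume V (Å³), a total bound coherent scattering length b (fm, Sears values
shipped as static data) and a count of solvent-exchangeable (labile)
hydrogens. SLDs are reported in 1e-6 Å⁻² as ρ = 10·b/V. Solvent mixtures are
linear in the D2O volume fraction between the pure-water endpoints, both taken
at V = 30.0 Å³; this convention reproduces the standard match points (38 vol%
D2O matches silicon at ≈2.07, 66 vol% gives 4.0). Labile hydrogens on proteins
and headgroups take the solvent's isotopic composition; the
`exchange_completeness` parameter (default 1.0, i.e. full exchange weighted by
the solvent D fraction) is exposed because exchange kinetics in buried sites
can be incomplete.

Residue-level protein properties use peptide-bond-form formulas with labile-H
counts for pH-7 protonation states and a selectable published residue-volume
set (`zamyatnin1984` canonical, `jacrot1976` alternate). Protein volumes are
strict sums over residues.

The shipped `hs_dhodh_d29_synthetic.fasta` is a **synthetic stand-in**
sequence: a constructed 366-residue surrogate whose composition reproduces the
documented aggregate properties of the truncated human enzyme construct
(molecular volume ≈ 49165 Å³; SLD series ≈ 3.0/2.6/2.2/1.8 across
D2O/CM4/CMSi/H2O). It exists so the pipeline is runnable and testable without
external sequence retrieval; it is not the natural sequence, and tests using
it validate the residue tables and exchange model, not database access.

### Component volumes

The published appendix volumes underlying the original tables are not
redistributable here, so the package ships one self-consistent literature set:
PO chain fragments at 946 Å³ (fluid phase, ~25-30 °C), the phosphocholine
headgroup (with glycerol and carbonyls) at 331 Å³, four-chain cardiolipin
chains at 2.32 × the PC chain volume (the ratio implied by 10 mol% ↔
20.5 vol%), and ubiquinone-10 at 1478 Å³ from its mass density. With these
values the composition-built leaflets reproduce the published intrinsic SLDs
within the printed uncertainties. The chain-deuterated PC carries 95% D
incorporation at its 63 labelled positions, expressed as fractional counts in
the formula table; this is the deuteration level consistent with the
characterized SLD of the custom-synthesized lipid (perdeuteration would give
≈6.8 rather than the observed ≈6.3 × 1e-6 Å⁻²).

## Slab models

A membrane is a stack: silicon fronting, a native-oxide layer (default 12 Å,
10% hydrated, held fixed), the bilayer layers, and the aqueous backing. Each
layer has thickness τ, interfacial roughness σ against its predecessor,
solvent fraction φ, and either a fixed intrinsic SLD per contrast or a
composition from which per-contrast SLDs follow. The mixed SLD is the
volume-fraction-weighted sum of component SLDs plus the solvent term — the
identity that lets contrast variation decompose layer compositions.

`build_bilayer` produces the four-layer model (inner heads, inner chains,
outer chains, outer heads) or, when ubiquinone is present, the five-layer
model with a thin central ubiquinone+chains layer. Chain thicknesses in the
spec are per-leaflet chain-equivalents: the chain material relocated into the
central layer is subtracted from the leaflet slabs, so total chain volume is
conserved between the two parameterizations. Protein decorates a stack by
penetrating the outer chains/heads at a volume fraction relative to the lipids
(converted to absolute via 1−φ) and by appended surface layers; penetration
into the inner leaflet is outside the model and raises. The area-per-lipid
constraint (equal hydrated area in head and chain sublayers of a lipid-only
leaflet) is solved for the head hydration in closed form. With the shipped
volumes the outer-leaflet head hydration lands inside the printed interval;
the inner leaflet comes out a few volume percent high, consistent with
interfacial water at the substrate that the ideal constraint does not model —
the test tolerances state this explicitly.

## Reflectivity

The forward model is the Parratt/Abeles interface recursion with Nevot-Croce
roughness factors exp(−2 k_n k_{n+1} σ²), complex wavevectors via the
principal square root (non-negative imaginary part below the critical edge).
When σ exceeds half an adjacent layer thickness the code warns and offers a
micro-sliced erf-profile calculation; the table-derived fixtures knowingly
pair a 4 Å central layer with comparable roughness, and both simulation and
refinement use Nevot-Croce consistently so the approximation cancels in
recovery tests. Resolution smearing is Gaussian with FWHM-defined dQ/Q
(instrument presets: 5% for the monochromatic-geometry preset, 4% for the
time-of-flight preset), evaluated by 17-point Gauss-Legendre quadrature over
±3.5σ with model re-evaluation beyond the data range. Scale and additive
background apply after smearing. Default Q grids are 250 log-spaced points
over 0.01-0.25 or 0.009-0.3 Å⁻¹.

Correctness is established against closed-form Fresnel reflectivity, total
reflection below the critical edge, Kiessig fringe spacing 2π/τ, optical
reciprocity, and an independent direct solution of the one-dimensional wave
equation (a linear boundary-value solver sharing no algorithm with the
recursion), to better than 1e-6 relative on randomized stacks.

## Co-refinement

One structural parameter set serves all contrasts: thicknesses, solvent
fractions and roughnesses are shared by construction; the chain-region layers
share a single solvent-fraction parameter (the constraint that chain-region
solvent is constant across contrasts); only scale and background exist per
dataset. Layers whose intrinsic SLD legitimately varies with contrast
(proton exchange) keep their per-contrast offsets, rigidly shifted by one
scalar, so the fitted series stays consistent with exchange.

χ² is the exact weighted sum of squared residuals over all datasets. The
optimizer is an optional seeded global stage (differential evolution, Sobol
initialization, no polish) followed by a bounded trust-region least-squares
polish; results are deterministic per seed (default 20220223). Parameter
uncertainties come from the local-stage covariance scaled by √(χ²/dof);
per-contrast χ² values are reported as sensitivity diagnostics. Derived
quantities get uncertainties by the first-order delta method, or by seeded
Monte-Carlo parameter resampling when requested or when the covariance is
unusable.

### Refitting convention for the thin central layer

For a layer much thinner than 2π/Q_max, thickness and SLD contrast enter the
reflectivity at leading order only through their product, so jointly freeing
both leaves a flat ridge: with 3% noise the refitted central-layer SLD then
scatters several times wider than its published interval. The package's
recovery convention therefore quotes the central-layer SLD at the
characterized nominal thickness (4 Å, fixed), matching how thin-interlayer
compositions are quoted in practice, and ties the two leaflet chain
thicknesses to a single parameter wherever the characterized structure is
symmetric (as all the registered lipid-only structures are). All other
thicknesses, the solvent fractions and the chain-region SLDs stay free, with
role-based physical bounds (e.g. hydrogenous vs chain-deuterated SLD bands)
and optimizer starts at bounds midpoints — the refit is handed the prior
range, never the answer.

## Synthetic data

Fixtures encode the published per-layer central values (and printed
uncertainty intervals) of the seven membrane systems, before and after enzyme
addition. Simulated datasets are the smeared, scaled model plus additive
background with Gaussian noise of 3% relative standard deviation (a typical
counting precision for these instruments; the sources print no counting
statistics), with dR set to that σ. The four contrasts use seed offsets 0-3
from the experiment seed, giving reproducible yet independent noise streams.

What passing recovery tests show: the full pipeline — simulation, smearing,
co-refinement, uncertainty reporting — is self-consistent and unbiased at
realistic noise, with every free parameter landing inside the published
interval in ≥90% of 20 replicates per system. What they do not show:
robustness to real-data pathologies (non-Gaussian backgrounds, imperfect
substrates, transient extra layers such as a floating second bilayer, scale
drifts between contrasts), which the flat-noise generator deliberately omits.

## Derived quantities

Coverage is 100 minus the thickness-averaged chain-region solvent vol%; total
thickness sums heads, chains and the central layer (never oxide or adsorbed
protein); component totals are thickness-and-material-volume weighted means;
absolute penetration is rel·(100−φ)/100. The adsorbed amount implements the
bookkeeping sum Σ τ·φ_protein·10⁸/V_protein (molecules/µm²) and the
protein:lipid ratio uses the outer-leaflet chain volume per lipid; these are
tested at the formula level (hand value, zero, linearity) only, because the
corresponding literature figure cannot be reconciled with the printed layer
parameters by volume bookkeeping. A_wet, the area per lipid in a hydrated
sublayer, is defined here as V_lipid/(τ·(1−φ)) — the definition is a package
choice, stated because the symbol is otherwise undefined in common usage.

## Problem sizes

Default grids are 250 points per contrast (1000 points per four-contrast
experiment). Recovery tests run 20 replicates per system with the local
refinement stage; the acceptance script runs one seeded four-contrast
simulation and a global+local refinement.

## Known limitations

- No incoherent/absorption cross-sections, X-ray SLDs, or polarized
  reflectivity; no lateral heterogeneity.
- Per-contrast solvent fractions (printed in some footnotes) are supported in
  the data model but fixtures carry the shared central values.
- The Nevot-Croce treatment is approximate for σ > τ/2; the micro-slicing
  fallback is available but not the default.
- The inner-leaflet area-per-lipid constraint reproduces the printed head
  hydration only to within a few volume percent (see above).
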