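# Molecular components used to build membrane slab models.
# Formulas may carry fractional counts (isotopic incorporation, e.g. the
# chain-deuterated PC synthesized with 95% D at the 63 labelled positions).
# Volumes in Å³ from the component-volume literature for fluid-phase PO-chain
# lipids near 25-30 °C; chain fragments exclude the ester carbonyls (counted
# with the headgroup/backbone).
# name	formula	volume	n_labile	note
water	H2O	30.0	2	pure H2O, 25 C
heavy_water	D2O	30.0	0	pure D2O, same molecular volume
silicon	Si	20.02	0	crystalline Si, 8 atoms per a=5.431 A cell
silica	SiO2	45.4	0	amorphous native oxide
popc_heads	C10H18NO8P	331.0	0	phosphocholine + glycerol + carbonyls
popc_chains	C32H64	946.0	0	palmitoyl + oleoyl hydrocarbon
d63popc_chains	C32H4.15D59.85	946.0	0	chain-deuterated PC, 95% D at 63 positions
tocl_heads	C13H10O17P2Na2	530.0	1	cardiolipin triglycerol/bisphosphate + carbonyls, Na salt
tocl_chains	C68H132	2194.7	0	four oleoyl chains (2.32x popc_chains)
pope_heads	C7H12NO8P	252.0	3	phosphoethanolamine + glycerol + carbonyls
pope_chains	C32H64	946.0	0	same PO chains as POPC
popg_heads	C6H10NaO10P	257.0	2	phosphoglycerol + glycerol + carbonyls, Na salt
popg_chains	C32H64	946.0	0	same PO chains as POPC
pops_heads	C7H11NNaO10P	244.0	3	phosphoserine + glycerol + carbonyls, Na salt
pops_chains	C32H64	946.0	0	same PO chains as POPC
popi_heads	C9H15O13P	306.0	5	phosphoinositol + glycerol + carbonyls
popi_chains	C32H64	946.0	0	same PO chains as POPC
q10	C59H90O4	1478.0	0	ubiquinone-10, V from density 0.97 g/cm3
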