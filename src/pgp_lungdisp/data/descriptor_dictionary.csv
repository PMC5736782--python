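name,unit,description
cLogD7.4,dimensionless,Calculated octanol/water distribution coefficient (log10) at pH 7.4
cLogP,dimensionless,Calculated octanol/water partition coefficient (log10) of the neutral species
abraham_acidity,dimensionless,Abraham solvation descriptor A: overall hydrogen-bond acidity
abraham_basicity,dimensionless,Abraham solvation descriptor B: overall hydrogen-bond basicity
hbd,count,Number of hydrogen-bond donor groups
hba,count,Number of hydrogen-bond acceptor groups
hb_total,count,Total hydrogen-bonding groups (hbd + hba)
rotatable_bonds,count,Number of rotatable bonds (molecular flexibility)
abraham_volume,dimensionless,Abraham descriptor V: McGowan characteristic volume (cm^3 mol^-1 / 100)
abraham_polarizability,dimensionless,Abraham descriptor S: dipolarity/polarizability
psa,angstrom^2,Topological polar surface area
mw,g/mol,Molecular weight
abraham_mri,dimensionless,Abraham descriptor E: excess molar refraction
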