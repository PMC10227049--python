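# HPLC column registry: substrate (0 = amylose, 1 = cellulose), connection
# (0 = immobilized, 1 = coated), packing material size (um), and the
# descriptor 5-vector [TPSA, RPSA, RASA, MEDC, MATS] of the chiral
# stationary phase, computed with chirsep.chem_graphs.compute_descriptors
# on the methyl-capped glucopyranose monomer unit of each CSP polymer.
# These values are editable configuration, not measured truth.
columns:
  ADH:   # amylose tris(3,5-dimethylphenylcarbamate), coated
    substrate_code: 0
    connection_code: 1
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2140, 0.7882, 11.8472, -0.1938]
  ODH:   # cellulose tris(3,5-dimethylphenylcarbamate), coated
    substrate_code: 1
    connection_code: 1
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2140, 0.7882, 11.8472, -0.1938]
  OJH:   # cellulose tris(4-methylbenzoate), coated
    substrate_code: 1
    connection_code: 1
    packing_size: 5.0
    csp_descriptors: [106.59, 0.1792, 0.8223, 13.1913, -0.1555]
  ASH:   # amylose tris((S)-alpha-methylbenzylcarbamate), coated
    substrate_code: 0
    connection_code: 1
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2140, 0.7882, 11.4769, -0.1938]
  IA:    # amylose tris(3,5-dimethylphenylcarbamate), immobilized
    substrate_code: 0
    connection_code: 0
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2140, 0.7882, 11.8472, -0.1938]
  IB:    # cellulose tris(3,5-dimethylphenylcarbamate), immobilized
    substrate_code: 1
    connection_code: 0
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2140, 0.7882, 11.8472, -0.1938]
  IC:    # cellulose tris(3,5-dichlorophenylcarbamate), immobilized
    substrate_code: 1
    connection_code: 0
    packing_size: 5.0
    csp_descriptors: [142.68, 0.1970, 0.8089, 9.5916, -0.0243]
  ID:    # amylose tris(3-chlorophenylcarbamate), immobilized
    substrate_code: 0
    connection_code: 0
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2198, 0.7840, 9.5916, -0.0350]
  IG:    # amylose tris(3-chloro-4-methylphenylcarbamate), immobilized
    substrate_code: 0
    connection_code: 0
    packing_size: 5.0
    csp_descriptors: [142.68, 0.2052, 0.7990, 10.3910, -0.0332]
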