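# Default side-compound (cofactor) list for metabolic graph construction.
# One KEGG compound ID per line.  Removal is opt-in: pass this set to
# build_graph(..., side_compounds=default_side_compounds()).
C00001  # H2O
C00002  # ATP
C00003  # NAD+
C00004  # NADH
C00005  # NADPH
C00006  # NADP+
C00008  # ADP
C00009  # Orthophosphate
C00010  # Coenzyme A
C00011  # CO2
C00013  # Diphosphate
C00014  # Ammonia
C00080  # H+
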