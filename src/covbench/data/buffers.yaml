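# Het-group codes treated as buffer / crystallization agents rather than
# cofactors in the curation proximity rule.  Editable config; codes follow
# the PDB chemical-component dictionary.
buffer_names:
  - GOL   # glycerol
  - EDO   # ethylene glycol
  - PEG   # di(hydroxyethyl)ether
  - PGE   # triethylene glycol
  - PG4   # tetraethylene glycol
  - MPD   # 2-methyl-2,4-pentanediol
  - DMS   # dimethyl sulfoxide
  - ACT   # acetate
  - ACY   # acetic acid
  - FMT   # formate
  - CIT   # citrate
  - TRS   # tris buffer
  - EPE   # HEPES
  - MES   # MES buffer
  - BME   # beta-mercaptoethanol
  - DTT   # dithiothreitol
  - IMD   # imidazole
  - NO3   # nitrate
  - SO4   # sulfate
  - PO4   # phosphate
  - CL    # chloride
  - BR    # bromide
  - IOD   # iodide
  - NH4   # ammonium
  - AZI   # azide
  - BCT   # bicarbonate
  - CO3   # carbonate
  - FLC   # citrate anion
  - TLA   # tartrate
  - MLI   # malonate
  - UNX   # unknown atom/ion
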