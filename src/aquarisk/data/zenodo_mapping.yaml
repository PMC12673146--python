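# Best-effort column-mapping template for the published Maziba catchment
# monitoring dataset (Zenodo, DOI 10.5281/zenodo.15465720).  The deposit is
# not redistributed here; download it and, if its column headers differ,
# edit the aliases below before loading it with
# `aquarisk.io.read_monitoring_table(path, mapping=load_zenodo_mapping())`.
layout: wide
station: Station
date: Date
columns:
  "Temperature": WT
  "DO": DO
  "pH": PH
  "Turbidity": TURB
  "EC": EC
  "TDS": TDS
  "TSS": TSS
  "Chl-a": CHL_A
  "TH": TH
  "Na": NA
  "K": K
  "Cl": CL
  "SO4": SO4
  "NH4-N": NH4_N
  "NO2-N": NO2_N
  "NO3-N": NO3_N
  "SRP": SRP
  "TP": TP
  "TN": TN
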