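parameters:
- code: DO
  name: Dissolved oxygen
  units: mg/L
  wawqi_standard: 6.0
  wawqi_ideal: 14.6
  cpi_standard: 8.0
  in_wawqi: true
  in_cpi: true
  do_like: true
- code: PH
  name: pH
  units: ''
  wawqi_standard: 8.5
  wawqi_ideal: 7.0
  cpi_standard: 8.5
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: TURB
  name: Turbidity
  units: NTU
  wawqi_standard: 25.0
  wawqi_ideal: 0.0
  cpi_standard: 25.0
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: EC
  name: Electrical conductivity
  units: uS/cm
  wawqi_standard: 2500.0
  wawqi_ideal: 0.0
  cpi_standard: 2500.0
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: NH4_N
  name: Ammonium nitrogen
  units: mg/L
  wawqi_standard: 0.2
  wawqi_ideal: 0.0
  cpi_standard: 0.2
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: NO2_N
  name: Nitrite nitrogen
  units: mg/L
  wawqi_standard: 3.0
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: true
  in_cpi: false
  do_like: false
- code: NO3_N
  name: Nitrate nitrogen
  units: mg/L
  wawqi_standard: 13.29
  wawqi_ideal: 0.0
  cpi_standard: 13.29
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: SRP
  name: Soluble reactive phosphorus
  units: mg/L
  wawqi_standard: 2.2
  wawqi_ideal: 0.0
  cpi_standard: 2.2
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: CL
  name: Chloride
  units: mg/L
  wawqi_standard: 250.0
  wawqi_ideal: 0.0
  cpi_standard: 120.0
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: NA
  name: Sodium
  units: mg/L
  wawqi_standard: 200.0
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: true
  in_cpi: false
  do_like: false
- code: SO4
  name: Sulphate
  units: mg/L
  wawqi_standard: 400.0
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: true
  in_cpi: false
  do_like: false
- code: TH
  name: Total hardness
  units: mg/L
  wawqi_standard: 200.0
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: true
  in_cpi: false
  do_like: false
- code: WT
  name: Water temperature
  units: degC
  wawqi_standard: 25.0
  wawqi_ideal: 0.0
  cpi_standard: 27.0
  in_wawqi: true
  in_cpi: true
  do_like: false
- code: TDS
  name: Total dissolved solids
  units: mg/L
  wawqi_standard: null
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: false
  in_cpi: false
  do_like: false
- code: TSS
  name: Total suspended solids
  units: mg/L
  wawqi_standard: null
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: false
  in_cpi: false
  do_like: false
- code: TP
  name: Total phosphorus
  units: mg/L
  wawqi_standard: null
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: false
  in_cpi: false
  do_like: false
- code: TN
  name: Total nitrogen
  units: mg/L
  wawqi_standard: null
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: false
  in_cpi: false
  do_like: false
- code: K
  name: Potassium
  units: mg/L
  wawqi_standard: null
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: false
  in_cpi: false
  do_like: false
- code: CHL_A
  name: Chlorophyll a
  units: ug/L
  wawqi_standard: null
  wawqi_ideal: 0.0
  cpi_standard: null
  in_wawqi: false
  in_cpi: false
  do_like: false
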