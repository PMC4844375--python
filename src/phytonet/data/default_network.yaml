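variables:
- name: AmaxL
  unit: µmol CO2 m-2 s-1
  module_hint: gas_exchange
- name: gs
  unit: mol H2O m-2 s-1
  module_hint: gas_exchange
- name: E
  unit: mmol H2O m-2 s-1
  module_hint: gas_exchange
- name: Rd
  unit: µmol CO2 m-2 s-1
  module_hint: gas_exchange
- name: Pr
  unit: µmol CO2 m-2 s-1
  module_hint: gas_exchange
- name: Ci
  unit: µmol mol-1
  module_hint: gas_exchange
- name: FvFm
  unit: dimensionless
  module_hint: photochemical
- name: dF_Fm
  unit: dimensionless
  module_hint: photochemical
- name: NPQ
  unit: dimensionless
  module_hint: photochemical
- name: ETR
  unit: µmol m-2 s-1
  module_hint: photochemical
modules:
  gas_exchange:
  - - AmaxL
    - Ci
  - - AmaxL
    - E
  - - AmaxL
    - Pr
  - - AmaxL
    - Rd
  - - AmaxL
    - gs
  - - Ci
    - Pr
  - - Ci
    - Rd
  - - Ci
    - gs
  - - E
    - gs
  photochemical:
  - - ETR
    - FvFm
  - - ETR
    - NPQ
  - - ETR
    - dF_Fm
  - - FvFm
    - NPQ
  - - FvFm
    - dF_Fm
  - - NPQ
    - dF_Fm
linking:
- - AmaxL
  - ETR
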