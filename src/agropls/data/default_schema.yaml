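# Default explanatory-variable schema: 34 variables describing each farm and its
# study barley field -- farm description, landscape context, farm- and field-level
# management practices (history 2009-2011 and current year 2012), and soil parameters.
# valid_range pools the two study regions; region_standardized variables are
# median-centred within region before analysis.
variables:
  - {name: TST,        label: "Time since transition to organic farming",      level: farm_description, kind: continuous, unit: "year",      valid_range: [0, 26]}
  - {name: Size,       label: "Farm size",                                     level: farm_description, kind: continuous, unit: "ha",        valid_range: [11, 700]}
  - {name: LHI,        label: "Landscape heterogeneity index (1 km radius)",   level: landscape,        kind: index,      unit: "",          valid_range: [-4, 4]}
  - {name: Leys,       label: "Proportion of rotational leys",                 level: farm_management,  kind: percentage, unit: "%",         valid_range: [0, 87]}
  - {name: Grains,     label: "Proportion of cereal crops",                    level: farm_management,  kind: percentage, unit: "%",         valid_range: [6, 95]}
  - {name: Ocrops,     label: "Proportion of other crops",                     level: farm_management,  kind: percentage, unit: "%",         valid_range: [0, 56]}
  - {name: PP,         label: "Presence of pasture",                           level: farm_management,  kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: OFert-area, label: "Area receiving organic fertilizers",            level: farm_management,  kind: continuous, unit: "ha",        valid_range: [0, 380]}
  - {name: AOFert,     label: "Amount of organic fertilizers",                 level: farm_management,  kind: continuous, unit: "t/ha",      valid_range: [0, 70]}
  - {name: LDI,        label: "Livestock density index",                       level: farm_management,  kind: index,      unit: "",          valid_range: [0, 3.3]}
  - {name: SRM,        label: "Straw and residue management (farm)",           level: farm_management,  kind: ordinal,    unit: "",          valid_range: [1, 3]}
  - {name: Freq-OFe,   label: "Frequency of organic fertilizer use 2009-2011", level: field_history,    kind: continuous, unit: "1/year",    valid_range: [0, 1]}
  - {name: OFe-AT,     label: "Organic fertilizer application technique",      level: field_history,    kind: ordinal,    unit: "",          valid_range: [0, 2]}
  - {name: Min-N,      label: "Mineral N applied, 3-year average",             level: field_history,    kind: continuous, unit: "kg/ha",     valid_range: [0, 175]}
  - {name: Min-PK,     label: "Mineral PK applied",                            level: field_history,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: PEST,       label: "Pesticide applied 2009-2011",                   level: field_history,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: STR-M,      label: "Straw and residue management (field)",          level: field_history,    kind: ordinal,    unit: "",          valid_range: [0, 2]}
  - {name: Org-N12,    label: "N from organic fertilizers in 2012",            level: field_current,    kind: continuous, unit: "kg/ha",     valid_range: [0, 167]}
  - {name: OFe-AT12,   label: "Organic fertilizer application technique 2012", level: field_current,    kind: ordinal,    unit: "",          valid_range: [0, 2]}
  - {name: Min-N12,    label: "Mineral N applied in 2012",                     level: field_current,    kind: continuous, unit: "kg/ha",     valid_range: [0, 175]}
  - {name: SMR-L12,    label: "Straw left on field before sowing 2012",        level: field_current,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: StdSd,      label: "Sowing date (day of year)",                     level: field_current,    kind: continuous, unit: "DOY",       valid_range: [84, 145], region_standardized: true}
  - {name: Seed,       label: "Seed rate sown",                                level: field_current,    kind: continuous, unit: "1/m2",      valid_range: [100, 220]}
  - {name: PC-pea,     label: "Pea as preceding crop",                         level: field_current,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: PC-leys,    label: "Leys as preceding crop",                        level: field_current,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: PC-cereal,  label: "Cereal as preceding crop",                      level: field_current,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: PEST-12,    label: "Pesticide applied in 2012",                     level: field_current,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: US-12,      label: "Barley undersown with grass/clover",            level: field_current,    kind: dummy,      unit: "",          valid_range: [0, 1]}
  - {name: Weed,       label: "Percentage weed cover (mean of 3 assessments)", level: field_current,    kind: percentage, unit: "%",         valid_range: [0, 60]}
  - {name: SMN1,       label: "Soil mineral N before fertilization",           level: soil,             kind: continuous, unit: "kg/ha",     valid_range: [12, 57]}
  - {name: pH,         label: "Soil pH",                                       level: soil,             kind: continuous, unit: "",          valid_range: [5.6, 8.0]}
  - {name: Tot-C,      label: "Total soil carbon",                             level: soil,             kind: percentage, unit: "%",         valid_range: [1.1, 12.0]}
  - {name: Tot-N,      label: "Total soil nitrogen",                           level: soil,             kind: percentage, unit: "%",         valid_range: [0.1, 1.0]}
  - {name: Clay,       label: "Soil clay content",                             level: soil,             kind: percentage, unit: "%",         valid_range: [4, 66], region_standardized: true}
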