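# Default aggregation rules: one rule per non-soil schema variable (29 rules).
# Raw answer names follow the questionnaire topics; where the original
# question-by-question mapping is not public the rule documents the assumption
# made (e.g. preceding-crop dummies all read the same categorical answer).
rules:
  - target: TST
    inputs: [years_since_transition]
    method: identity
  - target: Size
    inputs: [farm_area_ha]
    method: identity
  - target: LHI
    inputs: [prop_seminatural, prop_field_border]
    method: index_formula
  - target: Leys
    inputs: [ley_area_ha, farm_area_ha]
    method: proportion
    parameters: {scale: 100}
  - target: Grains
    inputs: [cereal_area_ha, farm_area_ha]
    method: proportion
    parameters: {scale: 100}
  - target: Ocrops
    inputs: [other_crop_area_ha, farm_area_ha]
    method: proportion
    parameters: {scale: 100}
  - target: PP
    inputs: [has_pasture]
    method: dummy
    parameters: {true_values: [1, "yes", true]}
  - target: OFert-area
    inputs: [ofert_area_ha]
    method: identity
  - target: AOFert
    inputs: [ofert_amount_t_ha]
    method: identity
  - target: LDI
    inputs: [livestock_units, utilized_area_ha]
    method: proportion
    parameters: {scale: 1}
  - target: SRM
    inputs: [straw_management_farm]
    method: ordinal_scale
    parameters:
      mapping: {removed: 1, sometimes_incorporated: 2, always_incorporated: 3}
  - target: Freq-OFe
    inputs: [n_ofe_2009, n_ofe_2010, n_ofe_2011]
    method: count_over_years
    parameters: {years: 3}
  - target: OFe-AT
    inputs: [ofe_technique_hist]
    method: ordinal_scale
    parameters:
      mapping: {none: 0, broadcast_or_mulched: 1, broadcast_and_mulched: 2}
  - target: Min-N
    inputs: [min_n_2009, min_n_2010, min_n_2011]
    method: mean_over_assessments
  - target: Min-PK
    inputs: [min_pk_used]
    method: dummy
    parameters: {true_values: [1, "yes", true]}
  - target: PEST
    inputs: [pesticide_used_hist]
    method: dummy
    parameters: {true_values: [1, "yes", true]}
  - target: STR-M
    inputs: [straw_management_field]
    method: ordinal_scale
    parameters:
      mapping: {none: 0, incorporated_or_mulched: 1, incorporated_and_mulched: 2}
  - target: Org-N12
    inputs: [org_n_2012]
    method: identity
  - target: OFe-AT12
    inputs: [ofe_technique_2012]
    method: ordinal_scale
    parameters:
      mapping: {none: 0, broadcast_or_mulched: 1, broadcast_and_mulched: 2}
  - target: Min-N12
    inputs: [min_n_2012]
    method: identity
  - target: SMR-L12
    inputs: [straw_left_2012]
    method: dummy
    parameters: {true_values: [1, "yes", true]}
  - target: StdSd
    inputs: [sowing_doy_2012]
    method: identity
  - target: Seed
    inputs: [seed_rate_2012]
    method: identity
  - target: PC-pea
    inputs: [preceding_crop]
    method: dummy
    parameters: {true_values: [pea]}
  - target: PC-leys
    inputs: [preceding_crop]
    method: dummy
    parameters: {true_values: [leys]}
  - target: PC-cereal
    inputs: [preceding_crop]
    method: dummy
    parameters: {true_values: [cereal]}
  - target: PEST-12
    inputs: [pesticide_used_2012]
    method: dummy
    parameters: {true_values: [1, "yes", true]}
  - target: US-12
    inputs: [undersown_2012]
    method: dummy
    parameters: {true_values: [1, "yes", true]}
  - target: Weed
    inputs: [weed_cover_jul18, weed_cover_jul25, weed_cover_aug02]
    method: mean_over_assessments
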