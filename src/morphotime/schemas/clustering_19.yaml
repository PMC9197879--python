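# The 19-of-27 feature selection used for mature clustering (duplicated
# basket measurements collapsed into the single weighted score).  The
# membership is PROVISIONAL — the published selection is not enumerated in
# the accompanying text — and this file is meant to be edited.
name: clustering_19
features:
  - {name: dendrite_length, compartment: dendrite, units: um}
  - {name: axon_length, compartment: axon, units: um}
  - {name: axon_sholl_10, compartment: axon, units: count}
  - {name: axon_sholl_50, compartment: axon, units: count}
  - {name: axon_sholl_100, compartment: axon, units: count}
  - {name: axon_sholl_150, compartment: axon, units: count}
  - {name: axon_sholl_200, compartment: axon, units: count}
  - {name: axon_mean_branch_level, compartment: axon, units: level}
  - {name: axon_straightness, compartment: axon, units: ratio}
  - {name: soma_volume, compartment: soma, units: um3}
  - {name: filopodia_count, compartment: dendrite, units: count}
  - {name: dendrite_ml_height, compartment: dendrite, units: um}
  - {name: axon_ml_height, compartment: axon, units: um}
  - {name: axon_span, compartment: axon, units: um}
  - {name: collateral_up_count, compartment: axon, units: count}
  - {name: collateral_down_count, compartment: axon, units: count}
  - {name: weighted_basket_score, compartment: axon, units: score}
  - {name: primary_dendrites, compartment: dendrite, units: count}
  - {name: relative_ml_position, compartment: location, units: ratio}
clustering_subset:
  - dendrite_length
  - axon_length
  - axon_sholl_10
  - axon_sholl_50
  - axon_sholl_100
  - axon_sholl_150
  - axon_sholl_200
  - axon_mean_branch_level
  - axon_straightness
  - soma_volume
  - filopodia_count
  - dendrite_ml_height
  - axon_ml_height
  - axon_span
  - collateral_up_count
  - collateral_down_count
  - weighted_basket_score
  - primary_dendrites
  - relative_ml_position
groups:
  axonal_core:
    - axon_length
    - axon_span
    - axon_ml_height
    - axon_straightness
    - weighted_basket_score
    - axon_mean_branch_level
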