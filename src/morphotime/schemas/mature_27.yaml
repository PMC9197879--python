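# Mature molecular-layer interneuron repertoire: 27 features over the
# dendrites, axon, soma and location of a fully reconstructed cell.
# The clustering_subset below is the 19-feature selection used for
# clustering; it is PROVISIONAL (the published subset membership is not
# enumerated in the accompanying text) and is meant to be edited.
name: mature_27
features:
  - {name: dendrite_length, compartment: dendrite, units: um}
  - {name: axon_length, compartment: axon, units: um}
  - {name: axon_sholl_10, compartment: axon, units: count}
  - {name: axon_sholl_50, compartment: axon, units: count}
  - {name: axon_sholl_100, compartment: axon, units: count}
  - {name: axon_sholl_150, compartment: axon, units: count}
  - {name: axon_sholl_200, compartment: axon, units: count}
  - {name: axon_mean_branch_level, compartment: axon, units: level}
  - {name: axon_max_branch_level, compartment: axon, units: level}
  - {name: axon_straightness, compartment: axon, units: ratio}
  - {name: soma_volume, compartment: soma, units: um3}
  - {name: filopodia_count, compartment: dendrite, units: count}
  - {name: filopodia_density, compartment: dendrite, units: per_um}
  - {name: dendrite_ml_height, compartment: dendrite, units: um}
  - {name: axon_ml_height, compartment: axon, units: um}
  - {name: axon_span, compartment: axon, units: um}
  - {name: axon_z_depth, compartment: axon, units: um}
  - {name: collateral_up_count, compartment: axon, units: count}
  - {name: collateral_up_length, compartment: axon, units: um}
  - {name: collateral_up_percent, compartment: axon, units: percent}
  - {name: collateral_down_count, compartment: axon, units: count}
  - {name: collateral_down_length, compartment: axon, units: um}
  - {name: collateral_down_percent, compartment: axon, units: percent}
  - {name: weighted_basket_score, compartment: axon, units: score}
  - {name: axon_carrying_dendrite, compartment: axon, units: flag}
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
    - axon_max_branch_level
  dendritic:
    - dendrite_length
    - filopodia_count
    - filopodia_density
    - dendrite_ml_height
    - primary_dendrites
  location:
    - relative_ml_position
  soma:
    - soma_volume
  basket:
    - weighted_basket_score
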