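# Developmental repertoire: 28 features describing the axon, soma and
# location of partially mature cells (dendrites are too immature to score
# beyond the primary-dendrite count).  The soma volume is the ellipsoid
# approximation from the three slice-mode calliper diameters.  The exact
# published membership is not enumerated in the accompanying text; the two
# terminal/branch-point counts complete the set and the file is meant to be
# edited.
name: developmental_28
features:
  - {name: axon_length, compartment: axon, units: um}
  - {name: axon_sholl_10, compartment: axon, units: count}
  - {name: axon_sholl_50, compartment: axon, units: count}
  - {name: axon_sholl_100, compartment: axon, units: count}
  - {name: axon_sholl_150, compartment: axon, units: count}
  - {name: axon_sholl_200, compartment: axon, units: count}
  - {name: axon_mean_branch_level, compartment: axon, units: level}
  - {name: axon_max_branch_level, compartment: axon, units: level}
  - {name: axon_straightness, compartment: axon, units: ratio}
  - {name: axon_ml_height, compartment: axon, units: um}
  - {name: axon_span, compartment: axon, units: um}
  - {name: axon_z_depth, compartment: axon, units: um}
  - {name: collateral_up_count, compartment: axon, units: count}
  - {name: collateral_up_length, compartment: axon, units: um}
  - {name: collateral_up_percent, compartment: axon, units: percent}
  - {name: collateral_down_count, compartment: axon, units: count}
  - {name: collateral_down_length, compartment: axon, units: um}
  - {name: collateral_down_percent, compartment: axon, units: percent}
  - {name: pcl_reaching_branches, compartment: axon, units: count}
  - {name: soma_x_diameter, compartment: soma, units: um}
  - {name: soma_y_diameter, compartment: soma, units: um}
  - {name: soma_z_diameter, compartment: soma, units: um}
  - {name: soma_volume, compartment: soma, units: um3}
  - {name: soma_height, compartment: location, units: um}
  - {name: relative_ml_position, compartment: location, units: ratio}
  - {name: primary_dendrites, compartment: dendrite, units: count}
  - {name: axon_terminal_count, compartment: axon, units: count}
  - {name: axon_branch_point_count, compartment: axon, units: count}
clustering_subset:
  - axon_length
  - axon_sholl_10
  - axon_sholl_50
  - axon_sholl_100
  - axon_sholl_150
  - axon_sholl_200
  - axon_mean_branch_level
  - axon_max_branch_level
  - axon_straightness
  - axon_ml_height
  - axon_span
  - axon_z_depth
  - collateral_up_count
  - collateral_up_length
  - collateral_up_percent
  - collateral_down_count
  - collateral_down_length
  - collateral_down_percent
  - pcl_reaching_branches
  - soma_x_diameter
  - soma_y_diameter
  - soma_z_diameter
  - soma_volume
  - soma_height
  - relative_ml_position
  - primary_dendrites
  - axon_terminal_count
  - axon_branch_point_count
groups:
  axonal:
    - axon_length
    - axon_span
    - axon_ml_height
    - axon_straightness
    - axon_sholl_100
    - axon_max_branch_level
  soma:
    - soma_x_diameter
    - soma_y_diameter
    - soma_z_diameter
    - soma_volume
  location:
    - soma_height
    - relative_ml_position
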