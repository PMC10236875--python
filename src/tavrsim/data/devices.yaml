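# Self-expanding THV frame catalog, version 1.
#
# Geometry (frame heights, inflow/waist/outflow profile) follows published
# device dimensions; the radial-force parameters are modelling configuration
# chosen to reproduce qualitative chronic-outward-force behaviour (plateau at
# small diameters, linear decay to zero at the local free diameter). None of
# these constants are clinically measured quantities.
#
# profile: [height along frame from inflow edge (mm), unloaded diameter (mm)]
# plateau_n_per_mm: chronic outward force plateau, N per mm of frame height
# knee_fraction: diameter fraction of the local free diameter at which the
#   force leaves the plateau and starts its linear decay to zero.
catalog_version: 1
devices:
  EvolutPRO-23:
    size: 23
    frame_height: 45.0
    crimped_diameter: 6.0
    has_pericardial_wrap: true
    profile: [[0.0, 23.0], [10.0, 23.0], [22.0, 20.0], [34.0, 24.0], [45.0, 34.0]]
    plateau_n_per_mm: 45.0
    knee_fraction: 0.7
  EvolutPRO-26:
    size: 26
    frame_height: 45.0
    crimped_diameter: 6.0
    has_pericardial_wrap: true
    profile: [[0.0, 26.0], [10.0, 26.0], [22.0, 22.0], [34.0, 26.0], [45.0, 34.0]]
    plateau_n_per_mm: 52.0
    knee_fraction: 0.7
  EvolutPRO-29:
    size: 29
    frame_height: 45.0
    crimped_diameter: 6.0
    has_pericardial_wrap: true
    profile: [[0.0, 29.0], [10.0, 29.0], [22.0, 24.0], [34.0, 28.0], [45.0, 34.0]]
    plateau_n_per_mm: 60.0
    knee_fraction: 0.7
  EvolutR-34:
    size: 34
    frame_height: 50.0
    crimped_diameter: 6.0
    has_pericardial_wrap: false
    profile: [[0.0, 34.0], [11.0, 34.0], [25.0, 27.0], [38.0, 32.0], [50.0, 38.0]]
    plateau_n_per_mm: 70.0
    knee_fraction: 0.7
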