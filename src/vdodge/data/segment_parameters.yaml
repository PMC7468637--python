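# Segment inertial parameters for the whole-body center-of-mass model.
#
# mass_fraction: fraction of whole-body mass per segment instance
# com_fraction:  COM position along the segment from the proximal landmark
# count:         2 for bilateral segments represented by midline landmarks
#
# Standard adult dispersion values (Winter-style); user-overridable.  The
# trunk entry includes head and neck; the forearm entries include the
# hand (the distal landmark is the hand centroid); the foot is a point
# mass at the ankle (feet stay planted, so this only offsets the COM by a
# constant).
trunk:
  mass_fraction: 0.578
  com_fraction: 0.66
  proximal: hip
  distal: shoulder
  count: 1
thigh:
  mass_fraction: 0.100
  com_fraction: 0.433
  proximal: hip
  distal: knee
  count: 2
shank:
  mass_fraction: 0.0465
  com_fraction: 0.433
  proximal: knee
  distal: ankle_c
  count: 2
foot:
  mass_fraction: 0.0145
  com_fraction: 0.5
  proximal: ankle_c
  distal: ankle_c
  count: 2
upper_arm:
  mass_fraction: 0.028
  com_fraction: 0.436
  proximal: shoulder
  distal: elbow
  count: 2
forearm_hand_l:
  mass_fraction: 0.022
  com_fraction: 0.682
  proximal: elbow
  distal: hand_l
  count: 1
forearm_hand_r:
  mass_fraction: 0.022
  com_fraction: 0.682
  proximal: elbow
  distal: hand_r
  count: 1
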