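- id: location_km
  name: Location (distance to the victim, km)
  direction: minimize
  scale_kind: continuous
  rank: 9
- id: age
  name: Age (years)
  direction: minimize
  scale_kind: continuous
  rank: 10
- id: access_healthcare
  name: Access to healthcare
  direction: minimize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 6
  level_labels: [very bad, bad, good, very good]
- id: airways
  name: Airways and oxygenation
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 1
  level_labels: [unhurt, small, medium, severe]
- id: consciousness
  name: State of consciousness
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 2
  level_labels: [unhurt, small, medium, severe]
- id: pulse
  name: Pulse
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 3
  level_labels: [unhurt, small, medium, severe]
- id: trauma
  name: Trauma
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 4
  level_labels: [unhurt, small, medium, severe]
- id: health_history
  name: Victim's health history
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 5
  level_labels: [unhurt, small, medium, severe]
- id: access_location
  name: Access to the victim's location
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 7
  level_labels: [none, low, medium, high]
- id: social_commotion
  name: Social commotion
  direction: maximize
  scale_kind: ordinal
  scale_min: 1
  scale_max: 4
  n_levels: 4
  rank: 8
  level_labels: [none, low, medium, high]
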