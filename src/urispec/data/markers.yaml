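# Default healthy/pathological marker definitions for a urinalysis panel.
# Cut-offs follow the clinical reference ranges; pH [5, 7.5] and specific
# gravity [1.002, 1.04] are literature reference ranges.  Directions are
# clinically conventional (elevated value = pathological); set
# caption_rule: true on a marker to use the literal "pathological iff
# value <= cutoff" convention instead.
bilirubin:
  scale: ordinal
  cutoff: 1.0
  ordinal_levels: [neg, 1+, 2+, 3+]
  pathological_levels: [1+, 2+, 3+]
  direction: high_is_pathological
erythrocytes:
  scale: quantitative
  cutoff: 25.0
  direction: high_is_pathological
ketones:
  scale: ordinal
  cutoff: 1.0
  ordinal_levels: [neg, 1+, 2+, 3+]
  pathological_levels: [1+, 2+, 3+]
  direction: high_is_pathological
leukocytes:
  scale: quantitative
  cutoff: 10.0
  direction: high_is_pathological
nitrite:
  scale: ordinal
  cutoff: 0.5
  ordinal_levels: [neg, pos]
  pathological_levels: [pos]
  direction: high_is_pathological
protein:
  scale: quantitative
  cutoff: 150.0
  direction: high_is_pathological
urobilinogen:
  scale: ordinal
  cutoff: 1.0
  ordinal_levels: [neg, 1+, 2+, 3+]
  pathological_levels: [1+, 2+, 3+]
  direction: high_is_pathological
glucose:
  scale: quantitative
  cutoff: 15.0
  direction: high_is_pathological
ph:
  scale: quantitative
  range_bounds: [5.0, 7.5]
  direction: range
  source: literature
specific_gravity:
  scale: quantitative
  range_bounds: [1.002, 1.04]
  direction: range
  source: literature
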