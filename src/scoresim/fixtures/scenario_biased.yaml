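# Field-motivated category weights for the generic simulation card:
# burning and bracken are pushed towards their negative categories, positive
# indicator species towards their top category.
name: biased
weights:
  pos_species_number: [0.5, 0.2, 0.2, 0.1]
  pos_species_cover: [0.5, 0.2, 0.2, 0.1]
  neg_species_cover: [0.3, 0.4, 0.2, 0.1]
  veg_structure: [0.2, 0.3, 0.3, 0.2]
  bracken_cover: [0.05, 0.15, 0.3, 0.5]
  bryophyte_cover: [0.65, 0.15, 0.1, 0.1]
  drainage: [0.4, 0.4, 0.1, 0.1]
  grazing: [0.25, 0.5, 0.15, 0.1]
  bare_soil: [0.3, 0.3, 0.4]
  burning: [0.05, 0.2, 0.3, 0.45]
  supplementary_feeding: [0.25, 0.55, 0.1, 0.1]
  damaging_activities: [0.2, 0.5, 0.2, 0.1]
rules: []
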