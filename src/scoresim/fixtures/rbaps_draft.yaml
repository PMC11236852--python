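id: rbaps_draft
name: RBAPS draft peatland scorecard
nominal_max: 100
declared_point_loss: 120
indicators:
  - id: pos_species_number
    name: Positive indicator species - number
    group: vegetation
    method: site-wide presence/absence (9 species from a list of 13)
    categories:
      - {label: "9 or more species", description: "at least 9 positive indicator species recorded", points: 15}
      - {label: "6-8 species", description: "6 to 8 positive indicator species recorded", points: 8, provenance: reconstructed}
      - {label: "3-5 species", description: "3 to 5 positive indicator species recorded", points: 3, provenance: reconstructed}
      - {label: "fewer than 3 species", description: "fewer than 3 positive indicator species recorded", points: 0}
  - id: pos_species_cover
    name: Positive indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 50%", description: "> 50% combined cover of positive indicator species", points: 15}
      - {label: "26-50%", description: "26-50% combined cover", points: 8, provenance: reconstructed}
      - {label: "11-25%", description: "11-25% combined cover", points: 3, provenance: reconstructed}
      - {label: "10% or less", description: "<= 10% combined cover", points: 0}
  - id: neg_species_number
    name: Negative indicator species - number
    group: vegetation
    method: site-wide presence/absence (negative indicators and invasives, any)
    categories:
      - {label: "none", description: "no negative indicator or invasive species recorded", points: 10}
      - {label: "one species", description: "a single negative indicator or invasive species recorded", points: -10, provenance: reconstructed}
      - {label: "two or three species", description: "two or three species recorded", points: -25, provenance: reconstructed}
      - {label: "more than three", description: "more than three species recorded", points: -40, provenance: reconstructed}
  - id: neg_species_cover
    name: Negative indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "absent", description: "no negative indicator species present", points: 10}
      - {label: "under 5%", description: "< 5% of site", points: 0, provenance: reconstructed}
      - {label: "5-25%", description: "5-25% of site", points: -10, provenance: reconstructed}
      - {label: "over 25%", description: "> 25% of site", points: -25, provenance: reconstructed}
  - id: drainage
    name: Drainage
    group: hydrology
    method: site-wide visual assessment of active drains
    categories:
      - {label: "no active drains", description: "no functioning artificial drainage", points: 15}
      - {label: "old vegetated drains", description: "historic drains, revegetated and non-functioning", points: 0, provenance: reconstructed}
      - {label: "localised active drains", description: "functioning drains affecting part of the site", points: -10, provenance: reconstructed}
      - {label: "extensive active drains", description: "functioning drains across the site", points: -20, provenance: reconstructed}
  - id: wet_features
    name: Wet features
    group: hydrology
    method: site-wide visual assessment of natural wet features
    provenance: reconstructed
    categories:
      - {label: "intact", description: "natural wet features present and intact", points: 5, provenance: reconstructed}
      - {label: "mostly intact", description: "wet features present with minor damage", points: 3, provenance: reconstructed}
      - {label: "degraded", description: "wet features present but degraded", points: 2, provenance: reconstructed}
      - {label: "absent", description: "no natural wet features remain", points: 0, provenance: reconstructed}
  - id: grazing
    name: Grazing
    group: site_management
    method: site-wide visual estimate (expert opinion)
    categories:
      - {label: "optimal", description: "grazing level appropriate to the habitat", points: 10}
      - {label: "slightly inappropriate", description: "slight over- or under-grazing", points: 5, provenance: reconstructed}
      - {label: "moderately inappropriate", description: "clear over- or under-grazing impacts", points: 0, provenance: reconstructed}
      - {label: "severely inappropriate", description: "severe over- or under-grazing impacts", points: -5, provenance: reconstructed}
  - id: bare_soil
    name: Bare soil
    group: site_management
    method: site-wide visual estimate
    categories:
      - {label: "none", description: "no bare soil beyond natural features", points: 3}
      - {label: "up to 5%", description: "<= 5% bare soil", points: 0, provenance: reconstructed}
      - {label: "over 5%", description: "> 5% bare soil", points: -1.5}
  - id: burning
    name: Burning
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none required or evident", description: "no burning required or evident", points: 10}
      - {label: "old evidence", description: "evidence of past burning", points: 0, provenance: reconstructed}
      - {label: "recent localised", description: "recent burning over part of the site", points: -10, provenance: reconstructed}
      - {label: "extensive recent", description: "extensive recent burning", points: -25, provenance: reconstructed}
  - id: supplementary_feeding
    name: Supplementary feeding
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "low", description: "little or no supplementary feeding", points: 7}
      - {label: "moderate", description: "regular feeding, limited damage", points: 2, provenance: reconstructed}
      - {label: "high", description: "frequent feeding, localised damage", points: 0, provenance: reconstructed}
      - {label: "severe", description: "widespread feeding damage", points: -3.5, provenance: reconstructed}
aliases:
  positive_species_number: pos_species_number
  positive_species_cover: pos_species_cover
  negative_species_number: neg_species_number
  negative_species_cover: neg_species_cover
  drainage: drainage
  wet_features: wet_features
  grazing: grazing
  bare_soil: bare_soil
  burning: burning
  supplementary_feeding: supplementary_feeding
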