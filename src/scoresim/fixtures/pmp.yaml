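id: pmp
name: Pearl Mussel Project peatland scorecard
nominal_max: 100
declared_point_loss: 180
indicators:
  - id: pos_species_number
    name: Positive indicator species - number
    group: vegetation
    method: site-wide presence/absence (9 species from a list of 16)
    categories:
      - {label: "9 or more species", description: "at least 9 positive indicator species recorded", points: 10}
      - {label: "6-8 species", description: "6 to 8 positive indicator species recorded", points: 6, provenance: reconstructed}
      - {label: "3-5 species", description: "3 to 5 positive indicator species recorded", points: 2, provenance: reconstructed}
      - {label: "fewer than 3 species", description: "fewer than 3 positive indicator species recorded", points: 0}
  - id: neg_species_number
    name: Negative indicator species - number
    group: vegetation
    method: site-wide presence/absence (invasives, any)
    categories:
      - {label: "none", description: "no invasive species recorded", points: 5}
      - {label: "one species", description: "a single invasive species recorded", points: 0, provenance: reconstructed}
      - {label: "two species", description: "two invasive species recorded", points: -10, provenance: reconstructed}
      - {label: "three or more", description: "three or more invasive species recorded", points: -20, provenance: reconstructed}
  - id: neg_species_cover
    name: Negative indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "absent", description: "no negative indicator species present", points: 5}
      - {label: "under 1%", description: "< 1% of site", points: -5, provenance: reconstructed}
      - {label: "1-5%", description: "1-5% of site", points: -15, provenance: reconstructed}
      - {label: "over 5%", description: "> 5% of site", points: -30, provenance: reconstructed}
  - id: veg_structure
    name: Vegetation structure
    group: vegetation
    method: site-wide visual assessment (expert opinion)
    categories:
      - {label: "varied", description: "varied sward heights, mixed-age heather, defined bryophyte layer", points: 15}
      - {label: "partially varied", description: "some structural variation", points: 5, provenance: reconstructed}
      - {label: "mostly uniform", description: "limited structural variation", points: -11.16, provenance: reconstructed}
      - {label: "uniform", description: "uniform vegetation height and composition", points: -15, provenance: reconstructed}
  - id: bryophyte_cover
    name: Bryophyte cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 30%", description: "> 30% bryophyte cover", points: 20}
      - {label: "20-30%", description: "20-30% bryophyte cover", points: 5, provenance: reconstructed}
      - {label: "6-20%", description: "6-20% bryophyte cover", points: -5, provenance: reconstructed}
      - {label: "0-5%", description: "0-5% bryophyte cover", points: -10, provenance: reconstructed}
  - id: drainage
    name: Drainage
    group: hydrology
    method: site-wide visual assessment of active drains
    categories:
      - {label: "no active drains", description: "no functioning artificial drainage", points: 15}
      - {label: "old vegetated drains", description: "historic drains, revegetated and non-functioning", points: 5, provenance: reconstructed}
      - {label: "localised active drains", description: "functioning drains affecting part of the site", points: -10, provenance: reconstructed}
      - {label: "widespread active drains", description: "functioning drains over much of the site", points: -20, provenance: reconstructed}
      - {label: "extensive recent drainage", description: "extensive, recently maintained drainage network", points: -30}
  - id: watercourse_contribution
    name: Contribution to watercourses
    group: hydrology
    method: visual assessment of watercourses (presence/absence of wet features)
    categories:
      - {label: "intact wet features", description: "wet features present and intact", points: 15}
      - {label: "partially intact", description: "wet features present but locally damaged", points: 5, provenance: reconstructed}
      - {label: "degraded", description: "wet features degraded", points: 0, provenance: reconstructed}
      - {label: "absent or destroyed", description: "wet features absent or destroyed", points: -15, provenance: reconstructed}
  - id: bare_soil
    name: Bare soil
    group: site_management
    method: site-wide visual estimate
    categories:
      - {label: "none", description: "no bare soil beyond natural features", points: 2}
      - {label: "up to 10%", description: "<= 10% bare soil", points: 0, provenance: reconstructed}
      - {label: "over 10%", description: "> 10% bare soil", points: -2}
  - id: burning
    name: Burning
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "no evidence", description: "no evidence of burning", points: 5}
      - {label: "old evidence", description: "evidence of past burning", points: -10, provenance: reconstructed}
      - {label: "recent localised", description: "recent burning over part of the site", points: -20, provenance: reconstructed}
      - {label: "extensive recent", description: "extensive recent burning", points: -30, provenance: reconstructed}
  - id: turbary
    name: Turbary (peat extraction)
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "no cutting for over 2 years", description: "no cutting within the last 2 years", points: 3}
      - {label: "recent hand cutting", description: "hand cutting within the last 2 years", points: 0, provenance: reconstructed}
      - {label: "active extraction", description: "active or mechanical extraction", points: -15, provenance: reconstructed}
  - id: supplementary_feeding
    name: Supplementary feeding
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "no damage", description: "no feeding damage", points: 2}
      - {label: "localised damage", description: "poaching and enrichment around feeders", points: 0, provenance: reconstructed}
      - {label: "widespread damage", description: "widespread feeding damage", points: -8, provenance: reconstructed}
  - id: damaging_activities
    name: Damaging activities
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no damaging activities evident", points: 3}
      - {label: "low", description: "minor, localised damage", points: 0, provenance: reconstructed}
      - {label: "moderate", description: "clear damage over part of the site", points: -2, provenance: reconstructed}
      - {label: "high", description: "widespread damage", points: -5, provenance: reconstructed}
aliases:
  positive_species_number: pos_species_number
  negative_species_number: neg_species_number
  negative_species_cover: neg_species_cover
  vegetation_structure: veg_structure
  bryophyte_cover: bryophyte_cover
  drainage: drainage
  watercourse_contribution: watercourse_contribution
  bare_soil: bare_soil
  burning: burning
  turbary: turbary
  supplementary_feeding: supplementary_feeding
  damaging_activities: damaging_activities
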