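id: bff
name: Blackstairs Farming Futures heathland scorecard
nominal_max: 100
declared_point_loss: 125
indicators:
  - id: pos_species_number
    name: Positive indicator species - number
    group: vegetation
    method: site-wide presence/absence (10 species from a list of 22)
    categories:
      - {label: "10 or more species", description: "at least 10 positive indicator species recorded", points: 20}
      - {label: "7-9 species", description: "7 to 9 positive indicator species recorded", points: 10, provenance: reconstructed}
      - {label: "4-6 species", description: "4 to 6 positive indicator species recorded", points: 5, provenance: reconstructed}
      - {label: "fewer than 4 species", description: "fewer than 4 positive indicator species recorded", points: 0}
  - id: pos_species_cover
    name: Positive indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 50%", description: "> 50% combined cover of positive indicator species", points: 20}
      - {label: "26-50%", description: "26-50% combined cover", points: 8, provenance: reconstructed}
      - {label: "11-25%", description: "11-25% combined cover", points: 4, provenance: reconstructed}
      - {label: "10% or less", description: "<= 10% combined cover", points: 0}
  - id: neg_species_cover
    name: Negative indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "absent", description: "no negative indicator species present", points: 5}
      - {label: "under 5%", description: "< 5% of site", points: -2, provenance: reconstructed}
      - {label: "5-25%", description: "5-25% of site", points: -12, provenance: reconstructed}
      - {label: "over 25%", description: "> 25% of site", points: -25, provenance: reconstructed}
  - id: veg_structure
    name: Vegetation structure
    group: vegetation
    method: site-wide visual assessment (expert opinion)
    categories:
      - {label: "varied", description: "varied sward heights, mixed-age heather, open grass and sedge patches, defined bryophyte layer", points: 10}
      - {label: "partially varied", description: "some structural variation but dominated by one stand type", points: 5, provenance: reconstructed}
      - {label: "uniform", description: "uniform vegetation height and composition (over- or under-grazing)", points: 0}
  - id: bracken_cover
    name: Bracken cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "under 10%", description: "< 10% bracken cover", points: 5}
      - {label: "10-25%", description: "10-25% bracken cover", points: 0, provenance: reconstructed}
      - {label: "26-50%", description: "26-50% bracken cover", points: -15, provenance: reconstructed}
      - {label: "over 50%", description: "> 50% bracken cover", points: -30, provenance: reconstructed}
  - id: scrub_cover
    name: Scrub cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "under 10%", description: "< 10% scrub cover", points: 5}
      - {label: "10-25%", description: "10-25% scrub cover", points: 0, provenance: reconstructed}
      - {label: "26-50%", description: "26-50% scrub cover", points: -10, provenance: reconstructed}
      - {label: "over 50%", description: "> 50% scrub cover", points: -20, provenance: reconstructed}
  - id: bryophyte_cover
    name: Bryophyte cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 25%", description: "> 25% bryophyte cover", points: 5}
      - {label: "10-25%", description: "10-25% bryophyte cover", points: 4, provenance: reconstructed}
      - {label: "under 10%", description: "< 10% bryophyte cover", points: 0}
  - id: drainage
    name: Drainage
    group: hydrology
    method: site-wide visual assessment of active drains
    categories:
      - {label: "no active drains", description: "no functioning artificial drainage", points: 15}
      - {label: "old vegetated drains", description: "historic drains, revegetated and non-functioning", points: 0, provenance: reconstructed}
      - {label: "localised active drains", description: "functioning drains affecting part of the site", points: -10, provenance: reconstructed}
      - {label: "extensive active drains", description: "functioning drains across the site", points: -15, provenance: reconstructed}
  - id: grazing
    name: Grazing
    group: site_management
    method: site-wide visual estimate (expert opinion)
    categories:
      - {label: "optimal", description: "grazing level appropriate to the habitat", points: 5}
      - {label: "slightly inappropriate", description: "slight over- or under-grazing", points: 0, provenance: reconstructed}
      - {label: "moderately inappropriate", description: "clear over- or under-grazing impacts", points: -1, provenance: reconstructed}
      - {label: "severely inappropriate", description: "severe over- or under-grazing impacts", points: -3, provenance: reconstructed}
  - id: bare_soil
    name: Bare soil
    group: site_management
    method: site-wide visual estimate
    categories:
      - {label: "none", description: "no bare soil beyond natural features", points: 2}
      - {label: "up to 5%", description: "<= 5% bare soil", points: 0, provenance: reconstructed}
      - {label: "over 5%", description: "> 5% bare soil", points: -2}
  - id: burning
    name: Burning
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none or controlled", description: "no burning, or controlled burning only", points: 5}
      - {label: "limited old evidence", description: "limited evidence of past uncontrolled burning", points: -3.28, provenance: reconstructed}
      - {label: "recent localised", description: "recent uncontrolled burning over part of the site", points: -10, provenance: reconstructed}
      - {label: "extensive recent", description: "extensive recent uncontrolled burning", points: -25, provenance: reconstructed}
  - id: damaging_activities
    name: Damaging activities
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no damaging activities evident", points: 3}
      - {label: "low", description: "minor, localised damage", points: 0}
      - {label: "moderate", description: "clear damage over part of the site", points: -2, provenance: reconstructed}
      - {label: "high", description: "widespread damage", points: -5, provenance: reconstructed}
aliases:
  positive_species_number: pos_species_number
  positive_species_cover: pos_species_cover
  negative_species_cover: neg_species_cover
  vegetation_structure: veg_structure
  bracken_cover: bracken_cover
  scrub_cover: scrub_cover
  bryophyte_cover: bryophyte_cover
  drainage: drainage
  grazing: grazing
  bare_soil: bare_soil
  burning: burning
  damaging_activities: damaging_activities
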