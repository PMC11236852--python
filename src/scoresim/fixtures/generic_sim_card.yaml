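id: generic_sim_card
name: Generic simulation scorecard
nominal_max: 100
indicators:
  - id: pos_species_number
    name: Positive indicator species - number
    group: vegetation
    method: site-wide presence/absence
    categories:
      - {label: "high", description: "full complement of positive indicator species", points: 15}
      - {label: "moderate", description: "most positive indicator species present", points: 8}
      - {label: "low", description: "few positive indicator species present", points: 4}
      - {label: "very low", description: "positive indicator species largely absent", points: 0}
  - id: pos_species_cover
    name: Positive indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 50%", description: "> 50% combined cover", points: 15}
      - {label: "26-50%", description: "26-50% combined cover", points: 8}
      - {label: "11-25%", description: "11-25% combined cover", points: 4}
      - {label: "10% or less", description: "<= 10% combined cover", points: 0}
  - id: neg_species_cover
    name: Negative indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "absent", description: "no negative indicator species present", points: 5}
      - {label: "under 5%", description: "< 5% of site", points: 0}
      - {label: "5-25%", description: "5-25% of site", points: -10}
      - {label: "over 25%", description: "> 25% of site", points: -20}
  - id: veg_structure
    name: Vegetation structure
    group: vegetation
    method: site-wide visual assessment (expert opinion)
    categories:
      - {label: "varied", description: "varied sward heights, mixed-age heather", points: 15}
      - {label: "partially varied", description: "some structural variation", points: 10.8}
      - {label: "mostly uniform", description: "limited structural variation", points: -5}
      - {label: "uniform", description: "uniform vegetation height and composition", points: -10}
  - id: bracken_cover
    name: Bracken cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "under 10%", description: "< 10% bracken cover", points: 5}
      - {label: "10-25%", description: "10-25% bracken cover", points: 0}
      - {label: "26-50%", description: "26-50% bracken cover", points: -15}
      - {label: "over 50%", description: "> 50% bracken cover", points: -35}
  - id: bryophyte_cover
    name: Bryophyte cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 25%", description: "> 25% bryophyte cover", points: 5}
      - {label: "10-25%", description: "10-25% bryophyte cover", points: 4}
      - {label: "5-10%", description: "5-10% bryophyte cover", points: 3}
      - {label: "under 5%", description: "< 5% bryophyte cover", points: 0}
  - id: drainage
    name: Drainage
    group: hydrology
    method: site-wide visual assessment of active drains
    categories:
      - {label: "no active drains", description: "no functioning artificial drainage", points: 15}
      - {label: "old vegetated drains", description: "historic drains, non-functioning", points: 0}
      - {label: "localised active drains", description: "functioning drains affecting part of the site", points: -10}
      - {label: "extensive active drains", description: "functioning drains across the site", points: -20}
  - id: grazing
    name: Grazing
    group: site_management
    method: site-wide visual estimate (expert opinion)
    categories:
      - {label: "optimal", description: "grazing level appropriate to the habitat", points: 5}
      - {label: "slightly inappropriate", description: "slight over- or under-grazing", points: 0}
      - {label: "moderately inappropriate", description: "clear over- or under-grazing impacts", points: -2}
      - {label: "severely inappropriate", description: "severe over- or under-grazing impacts", points: -5}
  - id: bare_soil
    name: Bare soil
    group: site_management
    method: site-wide visual estimate
    categories:
      - {label: "none", description: "no bare soil beyond natural features", points: 2}
      - {label: "up to 5%", description: "<= 5% bare soil", points: 0}
      - {label: "over 5%", description: "> 5% bare soil", points: -2}
  - id: burning
    name: Burning
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none or controlled", description: "no burning, or controlled burning only", points: 8}
      - {label: "limited old evidence", description: "limited evidence of past burning", points: 0}
      - {label: "recent localised", description: "recent burning over part of the site", points: -10}
      - {label: "extensive recent", description: "extensive recent burning", points: -25}
  - id: supplementary_feeding
    name: Supplementary feeding
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no supplementary feeding", points: 4}
      - {label: "no damage", description: "feeding present but no damage", points: 0}
      - {label: "localised damage", description: "poaching and enrichment around feeders", points: -1}
      - {label: "widespread damage", description: "widespread feeding damage", points: -4}
  - id: damaging_activities
    name: Damaging activities
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no damaging activities evident", points: 6}
      - {label: "low", description: "minor, localised damage", points: 0}
      - {label: "moderate", description: "clear damage over part of the site", points: -4}
      - {label: "high", description: "widespread damage", points: -10}
aliases:
  positive_species_number: pos_species_number
  positive_species_cover: pos_species_cover
  negative_species_cover: neg_species_cover
  vegetation_structure: veg_structure
  bracken_cover: bracken_cover
  bryophyte_cover: bryophyte_cover
  drainage: drainage
  grazing: grazing
  bare_soil: bare_soil
  burning: burning
  supplementary_feeding: supplementary_feeding
  damaging_activities: damaging_activities
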