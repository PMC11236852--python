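id: test_card
name: Prototype landscape-aware scorecard (Test)
nominal_max: 500
declared_point_loss: 565
indicators:
  - id: pos_species_number
    name: Positive indicator species - number
    group: vegetation
    method: presence/absence at monitoring stops (9 species from a list of 22)
    categories:
      - {label: "9 or more species", description: "at least 9 positive indicator species recorded", points: 90}
      - {label: "6-8 species", description: "6 to 8 positive indicator species recorded", points: 60, provenance: reconstructed}
      - {label: "3-5 species", description: "3 to 5 positive indicator species recorded", points: 30, provenance: reconstructed}
      - {label: "fewer than 3 species", description: "fewer than 3 positive indicator species recorded", points: 0}
  - id: veg_structure
    name: Vegetation structure
    group: vegetation
    method: visual assessment (expert opinion)
    categories:
      - {label: "varied", description: "varied sward heights, mixed-age heather, defined bryophyte layer", points: 90}
      - {label: "partially varied", description: "some structural variation", points: 30, provenance: reconstructed}
      - {label: "mostly uniform", description: "limited structural variation", points: -30, provenance: reconstructed}
      - {label: "uniform", description: "uniform vegetation height and composition", points: -80, provenance: reconstructed}
  - id: scrub_cover
    name: Scrub cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "under 5%", description: "< 5% scrub cover", points: 40}
      - {label: "5-25%", description: "5-25% scrub cover", points: 0, provenance: reconstructed}
      - {label: "26-50%", description: "26-50% scrub cover", points: -50, provenance: reconstructed}
      - {label: "over 50%", description: "> 50% scrub cover", points: -100, provenance: reconstructed}
  - id: bryophyte_cover
    name: Bryophyte cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "over 25%", description: "> 25% bryophyte cover", points: 50}
      - {label: "10-25%", description: "10-25% bryophyte cover", points: 20, provenance: reconstructed}
      - {label: "under 10%", description: "< 10% bryophyte cover", points: -20, provenance: reconstructed}
      - {label: "near absent", description: "bryophyte layer effectively absent", points: -50, provenance: reconstructed}
  - id: drainage
    name: Drainage
    group: hydrology
    method: site-wide visual assessment of active drains
    categories:
      - {label: "no active drains", description: "no functioning artificial drainage", points: 60}
      - {label: "old vegetated drains", description: "historic drains, revegetated and non-functioning", points: 20, provenance: reconstructed}
      - {label: "localised active drains", description: "functioning drains affecting part of the site", points: -20, provenance: reconstructed}
      - {label: "extensive active drains", description: "functioning drains across the site", points: -60, provenance: reconstructed}
  - id: bare_soil
    name: Bare soil
    group: site_management
    method: site-wide visual estimate
    categories:
      - {label: "none", description: "no bare soil beyond natural features", points: 10}
      - {label: "up to 5%", description: "<= 5% bare soil", points: 0, provenance: reconstructed}
      - {label: "over 5%", description: "> 5% bare soil", points: -10, provenance: reconstructed}
  - id: burning
    name: Burning
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none or controlled", description: "no burning, or controlled burning only", points: 40}
      - {label: "limited old evidence", description: "limited evidence of past uncontrolled burning", points: 0, provenance: reconstructed}
      - {label: "recent localised", description: "recent uncontrolled burning over part of the site", points: -60, provenance: reconstructed}
      - {label: "extensive recent", description: "extensive recent uncontrolled burning", points: -125, provenance: reconstructed}
  - id: damaging_activities
    name: Damaging activities
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no damaging activities evident", points: 20}
      - {label: "low", description: "minor, localised damage", points: 0, provenance: reconstructed}
      - {label: "moderate", description: "clear damage over part of the site", points: -20, provenance: reconstructed}
      - {label: "high", description: "widespread damage", points: -40, provenance: reconstructed}
  - id: landscape_features
    name: Landscape features
    group: site_management
    method: assessment of landscape context at monitoring stops
    provenance: reconstructed
    categories:
      - {label: "intact", description: "landscape features intact and connected", points: 60, provenance: reconstructed}
      - {label: "partially intact", description: "some landscape features degraded", points: 30, provenance: reconstructed}
      - {label: "degraded", description: "landscape features largely degraded", points: 0, provenance: reconstructed}
      - {label: "severely degraded", description: "landscape features lost or severely damaged", points: -50, provenance: reconstructed}
  - id: adjacent_habitat
    name: Adjacent habitat condition
    group: site_management
    method: assessment of surrounding habitat at monitoring stops
    provenance: reconstructed
    categories:
      - {label: "favourable", description: "adjacent semi-natural habitat in good condition", points: 40, provenance: reconstructed}
      - {label: "intermediate", description: "adjacent habitat partially degraded", points: 20, provenance: reconstructed}
      - {label: "poor", description: "adjacent habitat degraded", points: 0, provenance: reconstructed}
      - {label: "hostile", description: "intensive or damaging adjacent land use", points: -50, provenance: reconstructed}
aliases:
  positive_species_number: pos_species_number
  vegetation_structure: veg_structure
  scrub_cover: scrub_cover
  bryophyte_cover: bryophyte_cover
  drainage: drainage
  bare_soil: bare_soil
  burning: burning
  damaging_activities: damaging_activities
  landscape_features: landscape_features
  adjacent_habitat: adjacent_habitat
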