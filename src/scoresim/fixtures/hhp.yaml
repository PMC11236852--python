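id: hhp
name: Hen Harrier Project peatland scorecard
nominal_max: 100
declared_point_loss: 190
indicators:
  - id: neg_species_number
    name: Negative indicator species - number
    group: vegetation
    method: site-wide presence/absence (invasives, any)
    categories:
      - {label: "none", description: "no invasive species recorded", points: 3}
      - {label: "one species", description: "a single invasive species recorded", points: 0, provenance: reconstructed}
      - {label: "two species", description: "two invasive species recorded", points: -6, provenance: reconstructed}
      - {label: "three or more", description: "three or more invasive species recorded", points: -15, provenance: reconstructed}
  - id: neg_species_cover
    name: Negative indicator species - cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "absent", description: "no negative indicator species present", points: 3}
      - {label: "under 5%", description: "< 5% of site", points: -8, provenance: reconstructed}
      - {label: "5-25%", description: "5-25% of site", points: -18, provenance: reconstructed}
      - {label: "over 25%", description: "> 25% of site", points: -25, provenance: reconstructed}
  - id: veg_structure
    name: Vegetation structure
    group: vegetation
    method: site-wide visual assessment (expert opinion)
    categories:
      - {label: "varied", description: "varied sward heights, mixed-age heather, defined bryophyte layer", points: 40}
      - {label: "partially varied", description: "some structural variation", points: 10, provenance: reconstructed}
      - {label: "mostly uniform", description: "limited structural variation", points: -10.28, provenance: reconstructed}
      - {label: "uniform", description: "uniform vegetation height and composition", points: -20, provenance: reconstructed}
  - id: bracken_cover
    name: Bracken cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "under 10%", description: "< 10% bracken cover", points: 8}
      - {label: "10-25%", description: "10-25% bracken cover", points: -15, provenance: reconstructed}
      - {label: "26-50%", description: "26-50% bracken cover", points: -30, provenance: reconstructed}
      - {label: "over 50%", description: "> 50% bracken cover", points: -40, provenance: reconstructed}
  - id: scrub_cover
    name: Scrub cover
    group: vegetation
    method: site-wide visual estimate
    categories:
      - {label: "absent or small natural areas", description: "absent, or small areas of natural scrub only", points: 6}
      - {label: "localised encroachment", description: "scrub encroaching locally", points: -2, provenance: reconstructed}
      - {label: "widespread encroachment", description: "scrub encroaching across the site", points: -12, provenance: reconstructed}
      - {label: "dominant", description: "scrub dominant over much of the site", points: -20, provenance: reconstructed}
  - id: drainage
    name: Drainage
    group: hydrology
    method: site-wide visual assessment of active drains
    categories:
      - {label: "no active drains", description: "no functioning artificial drainage", points: 15}
      - {label: "old vegetated drains", description: "historic drains, largely non-functioning", points: -5, provenance: reconstructed}
      - {label: "localised active drains", description: "functioning drains affecting part of the site", points: -15, provenance: reconstructed}
      - {label: "extensive active drains", description: "functioning drains across the site", points: -20, provenance: reconstructed}
  - id: watercourse_impact
    name: Impact on watercourse
    group: hydrology
    method: visual assessment of watercourses (livestock access)
    categories:
      - {label: "no impact", description: "no livestock access or bank damage", points: 5}
      - {label: "minor access", description: "limited livestock access", points: 0, provenance: reconstructed}
      - {label: "regular access", description: "regular livestock access, localised poaching", points: -4, provenance: reconstructed}
      - {label: "severe damage", description: "heavy poaching and bank erosion", points: -10, provenance: reconstructed}
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
      - {label: "none required or evident", description: "no burning required or evident", points: 6}
      - {label: "old evidence", description: "evidence of past burning", points: -5, provenance: reconstructed}
      - {label: "recent localised", description: "recent burning over part of the site", points: -15, provenance: reconstructed}
      - {label: "extensive recent", description: "extensive recent burning", points: -25, provenance: reconstructed}
  - id: turbary
    name: Turbary (peat extraction)
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none or limited hand cutting", description: "none, or < 5% of site hand cut", points: 4}
      - {label: "historic cutting", description: "historic cutting, revegetating", points: 0, provenance: reconstructed}
      - {label: "recent hand cutting", description: "recent hand cutting beyond threshold", points: -1, provenance: reconstructed}
      - {label: "mechanical cutting", description: "active mechanical extraction", points: -5, provenance: reconstructed}
  - id: supplementary_feeding
    name: Supplementary feeding
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no supplementary feeding", points: 4}
      - {label: "no damage", description: "feeding present but no damage", points: 1, provenance: reconstructed}
      - {label: "localised damage", description: "poaching and enrichment around feeders", points: 0, provenance: reconstructed}
      - {label: "widespread damage", description: "widespread feeding damage", points: -3, provenance: reconstructed}
  - id: damaging_activities
    name: Damaging activities
    group: site_management
    method: site-wide visual assessment
    categories:
      - {label: "none", description: "no damaging activities evident", points: 4}
      - {label: "low", description: "minor, localised damage", points: 0, provenance: reconstructed}
      - {label: "moderate", description: "clear damage over part of the site", points: -1, provenance: reconstructed}
      - {label: "high", description: "widespread damage", points: -5, provenance: reconstructed}
aliases:
  negative_species_number: neg_species_number
  negative_species_cover: neg_species_cover
  vegetation_structure: veg_structure
  bracken_cover: bracken_cover
  scrub_cover: scrub_cover
  drainage: drainage
  watercourse_impact: watercourse_impact
  bare_soil: bare_soil
  burning: burning
  turbary: turbary
  supplementary_feeding: supplementary_feeding
  damaging_activities: damaging_activities
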