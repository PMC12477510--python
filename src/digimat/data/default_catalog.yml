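# Default indicator catalog for the digital-maturity-in-health index:
# 14 country-level indicators grouped into 7 subcomponents.  The catalog is
# configuration — swap this file to assess a different indicator set.
#
# raw_range declares natural bounds used by the fixed-bounds normalization
# strategy; indicators without natural bounds omit it and must be normalized
# min-max over the analysis set.
subcomponents:
  - infrastructure
  - workforce
  - leadership-and-governance
  - strategy-and-investment
  - legislation-policy-and-compliance
  - gender-diversity
  - consumer-readiness

indicators:
  - id: mobile_3g_coverage
    label: Proportion of population covered by at least a 3G mobile network
    subcomponent: infrastructure
    direction: higher
    raw_range: [0, 100]
  - id: egov_online_services
    label: Government online services index
    subcomponent: infrastructure
    direction: higher
    raw_range: [0, 1]
  - id: electricity_access
    label: Proportion of population with access to electricity
    subcomponent: infrastructure
    direction: higher
    raw_range: [0, 100]
  - id: ict_skill_training
    label: ICT skill training in the education system
    subcomponent: workforce
    direction: higher
    raw_range: [1, 7]
  - id: govtech_maturity
    label: GovTech Maturity Index
    subcomponent: leadership-and-governance
    direction: higher
    raw_range: [0, 1]
  - id: emerging_tech_investment
    label: Investment in emerging technologies
    subcomponent: strategy-and-investment
    direction: higher
    raw_range: [1, 7]
  - id: software_spend_gdp
    label: Computer software expenditure as a percentage of GDP
    subcomponent: strategy-and-investment
    direction: higher
  - id: ict_regulatory_environment
    label: ICT regulatory environment
    subcomponent: legislation-policy-and-compliance
    direction: higher
    raw_range: [0, 100]
  - id: emerging_tech_regulation
    label: Regulation of emerging technologies
    subcomponent: legislation-policy-and-compliance
    direction: higher
    raw_range: [1, 7]
  - id: privacy_protection_law
    label: Privacy protection in law
    subcomponent: legislation-policy-and-compliance
    direction: higher
  - id: cybersecurity_index
    label: Global cybersecurity index
    subcomponent: legislation-policy-and-compliance
    direction: higher
    raw_range: [0, 100]
  - id: gender_gap_social_media
    label: Gender gap ratio in social media use (1 = parity)
    subcomponent: gender-diversity
    direction: higher
    raw_range: [0, 1]
  - id: gender_gap_mobile_ownership
    label: Gender gap ratio for mobile phone ownership (1 = parity)
    subcomponent: gender-diversity
    direction: higher
    raw_range: [0, 1]
  - id: mobile_phone_ownership
    label: Proportion of population that owns a mobile phone
    subcomponent: consumer-readiness
    direction: higher
    raw_range: [0, 100]

region_aliases:
  AFRO: African
  AFR: African
  AMRO: Americas
  AMR: Americas
  PAHO: Americas
  SEARO: South-East Asia
  SEAR: South-East Asia
  EURO: European
  EUR: European
  EMRO: Eastern Mediterranean
  EMR: Eastern Mediterranean
  WPRO: Western Pacific
  WPR: Western Pacific
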