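# Evaluation framework for a community long-term ageing health-care system:
# five dimensions, twenty criteria. Display order follows list order.
dimensions:
  - code: D1
    name: Workforce
  - code: D2
    name: Source of Funding
  - code: D3
    name: Application of Technology
  - code: D4
    name: Service Nature and Health-Care System
  - code: D5
    name: Norms
criteria:
  - code: C11
    name: Workforce matching platform
    dimension: D1
  - code: C12
    name: Specialization level
    dimension: D1
  - code: C13
    name: Workforce supply capacity
    dimension: D1
  - code: C14
    name: Labour service flexibility
    dimension: D1
  - code: C21
    name: Government subsidies
    dimension: D2
  - code: C22
    name: Stable pension
    dimension: D2
  - code: C23
    name: Social insurance
    dimension: D2
  - code: C24
    name: Commercial insurance
    dimension: D2
  - code: C25
    name: Public welfare invested donation
    dimension: D2
  - code: C31
    name: Smart physiological monitoring facility
    dimension: D3
  - code: C32
    name: Intelligent case care system
    dimension: D3
  - code: C33
    name: Living-environment monitoring system
    dimension: D3
  - code: C41
    name: Residential services
    dimension: D4
  - code: C42
    name: Case care services
    dimension: D4
  - code: C43
    name: Integration of health
    dimension: D4
  - code: C44
    name: Health promotion
    dimension: D4
  - code: C51
    name: Institutional setting standards
    dimension: D5
  - code: C52
    name: Operational specification
    dimension: D5
  - code: C53
    name: Financial specification
    dimension: D5
  - code: C54
    name: Enterprise resource input specification
    dimension: D5
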