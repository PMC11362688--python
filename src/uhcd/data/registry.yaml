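# Default indicator registry: 24 tracer indicators in 13 tracer areas and
# 5 tracer domains.  Orientation "adverse_incidence" marks indicators stored
# as incidences (low = good) that are complemented (100 - x) before
# aggregation.  The equity subset lists the 14 household-survey indicators
# used for subgroup-disaggregated analysis.
domains:
  - key: rmnch
    name: Reproductive, maternal, newborn and child health
    areas:
      - key: pregnancy_delivery_care
        name: Pregnancy and delivery care
        indicators:
          - id: anc4
            name: Mothers with at least four antenatal care visits (%)
          - id: pnc_skilled
            name: Mothers receiving skilled postnatal care within 2 days of delivery (%)
          - id: sba
            name: Live births attended by skilled health personnel (%)
          - id: institutional_delivery
            name: Births occurring in health facilities (%)
      - key: family_planning
        name: Family planning
        indicators:
          - id: modern_contraception
            name: Married women aged 15-49 using modern contraception (%)
      - key: full_immunization
        name: Full immunization
        indicators:
          - id: full_immunization
            name: Children 12-23 months fully immunized (BCG, measles, 3x polio, 3x DPT) (%)
  - key: infectious
    name: Infectious diseases
    areas:
      - key: wash
        name: Water, sanitation and hygiene
        indicators:
          - id: sanitation
            name: Population using an improved sanitation facility (%)
          - id: drinking_water
            name: Population using an improved drinking-water source (%)
      - key: tb_treatment
        name: Effective treatment of tuberculosis
        indicators:
          - id: tb_success
            name: Treatment success rate for new pulmonary smear-positive TB cases (%)
  - key: ncd
    name: Noncommunicable diseases
    areas:
      - key: cvd_prevention
        name: Prevention of cardiovascular diseases
        indicators:
          - id: normal_bp
            name: Adults 18+ with blood pressure below 140/90 mmHg (%)
      - key: diabetes_prevention
        name: Prevention of diabetes
        indicators:
          - id: normal_glucose
            name: Adults 18+ with blood glucose at or below 140 mg/dL (%)
      - key: tobacco_control
        name: Tobacco control and tobacco use
        indicators:
          - id: non_smoking
            name: Adults 15+ not smoking tobacco (%)
      - key: cancer_screening
        name: Cancer detection and treatment
        indicators:
          - id: cervical_screening
            name: Women ever screened for cervical cancer (%)
          - id: breast_screening
            name: Women ever screened for breast cancer (%)
  - key: capacity
    name: Service capacity and access
    areas:
      - key: facility_access
        name: Health facility access
        indicators:
          - id: facility_24x7
            name: Functioning facilities providing round-the-clock care per IPHS norms (%)
      - key: infrastructure
        name: Health infrastructure
        indicators:
          - id: beds
            name: Beds available as a share of the IPHS norm (%)
      - key: essential_medicines
        name: Essential medicines
        indicators:
          - id: medicines
            name: Essential medicines (IPHS list) available in PHCs and CHCs (%)
      - key: workforce
        name: Health workforce
        indicators:
          - id: doctors
            name: Doctors available as a share of the IPHS norm (%)
          - id: paramedics
            name: Paramedical staff available as a share of the IPHS norm (%)
      - key: mch_training
        name: Health personnel with maternal and child health training
        indicators:
          - id: sba_training
            name: Health personnel trained in skilled birth attendance in past 5 years (%)
          - id: emoc_training
            name: Health personnel trained in basic emergency obstetric care in past 5 years (%)
  - key: frp
    name: Financial risk protection
    areas:
      - key: insurance
        name: Health insurance coverage
        indicators:
          - id: insurance
            name: Population covered by a health insurance scheme (%)
      - key: catastrophic_protection
        name: Protection from catastrophic health expenditure
        indicators:
          - id: catastrophic_expenditure
            name: Population experiencing catastrophic health expenditure (%)
            orientation: adverse_incidence
      - key: impoverishment_protection
        name: Protection from impoverishment
        indicators:
          - id: impoverishment
            name: Population impoverished by health expenses (%)
            orientation: adverse_incidence

# 14 household-survey-derived indicators with subgroup disaggregation:
# all RMNCH (6), WASH (2), all NCD (5), health insurance (1).
equity_subset:
  - anc4
  - pnc_skilled
  - sba
  - institutional_delivery
  - modern_contraception
  - full_immunization
  - sanitation
  - drinking_water
  - normal_bp
  - normal_glucose
  - non_smoking
  - cervical_screening
  - breast_screening
  - insurance
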