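# Default value sets shipped with phenoval.
# Editable stand-in code lists: a myocarditis/pericarditis diagnosis family,
# a cardiac-workup supporting-evidence panel, and COVID-19 vaccine CVX codes.
# Override with your curated lists via `phenoval ... --valuesets <file>`.
valuesets:
  - name: myopericarditis-diagnosis
    role: target_diagnosis
    description: >
      ICD-10-CM myocarditis/pericarditis family. Prefix entries match whole
      code families (e.g. I40 matches I40.0, I40.1, ...).
    entries:
      - {system: "http://hl7.org/fhir/sid/icd-10-cm", code: "I40", prefix: true}
      - {system: "http://hl7.org/fhir/sid/icd-10-cm", code: "I41"}
      - {system: "http://hl7.org/fhir/sid/icd-10-cm", code: "I51.4"}
      - {system: "http://hl7.org/fhir/sid/icd-10-cm", code: "I30", prefix: true}
      - {system: "http://hl7.org/fhir/sid/icd-10-cm", code: "I31.9"}
      - {system: "http://hl7.org/fhir/sid/icd-10-cm", code: "I32"}
  - name: cardiac-workup
    role: supporting_evidence
    description: >
      LOINC cardiac-injury workup panel; presence of a result near the index
      diagnosis counts as supporting evidence.
    entries:
      - {system: "http://loinc.org", code: "6598-7"}    # Troponin T
      - {system: "http://loinc.org", code: "10839-9"}   # Troponin I
      - {system: "http://loinc.org", code: "42757-5"}   # Troponin I, high sensitivity
      - {system: "http://loinc.org", code: "49563-0"}   # Troponin T, high sensitivity
      - {system: "http://loinc.org", code: "30934-4"}   # BNP
      - {system: "http://loinc.org", code: "33762-6"}   # NT-proBNP
      - {system: "http://loinc.org", code: "2157-6"}    # Creatine kinase
  - name: covid19-vaccines
    role: exposure_vaccine
    description: CVX codes for US-authorized COVID-19 vaccines and boosters.
    entries:
      - {system: "http://hl7.org/fhir/sid/cvx", code: "207"}  # Moderna
      - {system: "http://hl7.org/fhir/sid/cvx", code: "208"}  # Pfizer-BioNTech
      - {system: "http://hl7.org/fhir/sid/cvx", code: "211"}  # Novavax
      - {system: "http://hl7.org/fhir/sid/cvx", code: "212"}  # Janssen
      - {system: "http://hl7.org/fhir/sid/cvx", code: "213"}  # Unspecified COVID-19
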