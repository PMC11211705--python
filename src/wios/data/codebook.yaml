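# Default codebook: subevent codes per impact area, contributing factors,
# and policy/management responses.  Keywords are matched case-folded on
# token boundaries against summary text; `default_when_unmatched` marks the
# code assigned when no other code of the theme matched for the topic.
themes:
  area_of_impact:
    codes:
      - code: infections
        label: Infections
        topics: [infections_deaths]
        keywords: ["tested positive"]
      - code: deaths
        label: Deaths
        topics: [infections_deaths]
        keywords: ["succumbed"]
      - code: infections_and_deaths
        label: Infections and deaths
        topics: [infections_deaths]
        keywords: ["infections and deaths"]
      - code: exam_postponement
        label: Exam postponement
        topics: [education]
        keywords: ["postponed examinations"]
      - code: clinical_training_suspension
        label: Suspension of clinical training
        topics: [education]
        keywords: ["clinical placements"]
      - code: inperson_classes_suspension
        label: Suspension of in-person classes
        topics: [education]
        keywords: ["classroom teaching"]
      - code: celebrations_suspension
        label: Suspension of in-person celebrations
        topics: [education]
        keywords: ["graduation ceremony"]
      - code: visa_issues
        label: Visa issues (study and work)
        topics: [education]
        keywords: ["student visa"]
      - code: other_disruptions
        label: Other disruptions
        topics: [education]
        keywords: ["curriculum disruption"]
      - code: first_dose
        label: First dose
        topics: [vaccination]
        keywords: ["first dose"]
      - code: second_dose
        label: Second dose or fully vaccinated
        topics: [vaccination]
        keywords: ["fully vaccinated"]
      - code: booster_dose
        label: Booster dose
        topics: [vaccination]
        keywords: ["booster"]
      - code: unspecified
        label: Unspecified
        topics: [vaccination]
        keywords: []
        default_when_unmatched: true
      - code: demonstration
        label: Demonstration, picket, or protest
        topics: [industrial_action]
        keywords: ["picket", "demonstration", "protest"]
      - code: sit_down_walkout
        label: Sit-down or walkout
        topics: [industrial_action]
        keywords: ["walkout", "sit-down"]
      - code: strike
        label: Strike
        topics: [industrial_action]
        keywords: ["strike"]
      - code: anxiety
        label: Anxiety
        topics: [mental_health]
        keywords: ["anxiety"]
      - code: burnout
        label: Burnout
        topics: [mental_health]
        keywords: ["burnout"]
      - code: depression
        label: Depression
        topics: [mental_health]
        keywords: ["depression"]
      - code: exhaustion
        label: Exhaustion, overwork, and fatigue
        topics: [mental_health]
        keywords: ["exhaustion", "overwork", "fatigue"]
      - code: sleep_issues
        label: Sleep issues
        topics: [mental_health]
        keywords: ["insomnia"]
      - code: stress
        label: Stress
        topics: [mental_health]
        keywords: ["stress"]
      - code: suicide
        label: Suicide
        topics: [mental_health]
        keywords: ["suicide"]
      - code: trauma
        label: Trauma, PTSD, and secondary traumatic stress
        topics: [mental_health]
        keywords: ["trauma", "ptsd"]
  contributing_factor:
    codes:
      - code: remuneration
        label: Remuneration and compensation
        keywords: ["unpaid wages", "hazard pay"]
      - code: ppe_shortage
        label: Lack of adequate PPE
        keywords: ["protective equipment"]
      - code: workload
        label: Excessive workload
        keywords: ["excessive workload"]
      - code: staff_shortage
        label: Staff shortages
        keywords: ["understaffed wards"]
      - code: occupational_risk
        label: Occupational risks
        keywords: ["occupational hazards"]
      - code: vaccine_safety_concern
        label: Vaccine safety concerns
        keywords: ["side effects"]
  response:
    codes:
      - code: students_support
        label: Students supporting service provision
        keywords: ["final-year deployment"]
      - code: personnel_affairs
        label: Personnel affairs
        keywords: ["salary increment"]
      - code: technology
        label: Technology
        keywords: ["telehealth"]
      - code: disciplinary_action
        label: Disciplinary action
        keywords: ["sanctions"]
      - code: mandates
        label: Mandates
        keywords: ["compliance mandate"]
      - code: supply_strategy
        label: Supply strategies
        keywords: ["priority shipments"]
      - code: therapy_support
        label: Therapeutic support
        keywords: ["counseling"]
      - code: uptake_campaign
        label: Vaccine uptake campaign
        keywords: ["promotion campaign"]
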