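# Major depression guideline knowledge base (the Emily case).
# CBT is the mandatory core of the plan; the antidepressant component is
# optional with a selective serotonin reuptake inhibitor (SSRI) as its
# listed alternative, so a patient who declines medication outright can
# still reach agreement on CBT alone.
condition: major_depression
recommended_plan: [cbt, antidepressant]
interventions:
  cbt:
    rationale: >-
      A talking therapy that helps individuals manage problems by changing the way
      they think and behave.
    optional: false
    alternatives: []
    support:
      - {id: cbt_s1, text: "Most commonly used to treat anxiety and depression."}
      - {id: cbt_s2, text: "Can also be effective for other mental and physical health issues."}
    against:
      - {id: cbt_a1, text: "Requires sustained commitment, with regular sessions and homework."}
  antidepressant:
    rationale: >-
      Medication to manage the symptoms of depression.
    optional: true
    alternatives: [ssri]
    support:
      - {id: antidep_s1, text: "Most people with moderate or severe depression benefit from antidepressants."}
      - {id: antidep_s2, text: "A modern selective serotonin reuptake inhibitor can be prescribed, which is generally well tolerated and considered a safe option."}
    against:
      - {id: antidep_a1, text: "Side effects can include nausea, headaches, dry mouth, fatigue, sleep problems, and sexual issues."}
  ssri:
    rationale: >-
      A modern antidepressant that is as effective as older antidepressants but
      tends to have fewer side effects.
    optional: true
    alternatives: []
    support:
      - {id: ssri_s1, text: "As effective as older antidepressants but tend to have fewer side effects."}
      - {id: ssri_s2, text: "Side effects usually improve over time."}
    against:
      - {id: ssri_a1, text: "Can cause nausea, headaches, dry mouth, fatigue, sleep problems, and sexual issues."}
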