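# Atrial fibrillation guideline knowledge base (the David case).
# Argument texts are verbatim from the case's guideline comparison table;
# weights default to 1.0 (the source ranks no argument above another).
condition: atrial_fibrillation
recommended_plan: [cardiac_angiography, surgical_ablation]
interventions:
  cardiac_angiography:
    rationale: >-
      The type, duration, and frequency of atrial fibrillation can be determined,
      while the presence of potential cardiovascular problems can be assessed.
    optional: false
    alternatives: [cardiac_ultrasound]
    support:
      - {id: angio_s1, text: "Provides detailed information about the structure of the heart."}
      - {id: angio_s2, text: "Make an accurate diagnosis."}
      - {id: angio_s3, text: "Helps to plan surgical procedures."}
      - {id: angio_s4, text: "Improves the success rate of surgery and reduces the risk."}
    against:
      - {id: angio_a1, text: "Invasive surgery."}
      - {id: angio_a2, text: "There are potential complications, such as vascular damage, infection, and contrast agent toxicity to the kidney."}
      - {id: angio_a3, text: "Slight pain (which was aggravated by David's last experience)."}
      - {id: angio_a4, text: "Vascular injury."}
      - {id: angio_a5, text: "Infection."}
      - {id: angio_a6, text: "Contrast agent toxicity."}
  surgical_ablation:
    rationale: >-
      Interventional therapy to target and eliminate abnormal atrial conduction tissue.
    optional: false
    alternatives: []
    support:
      - {id: ablation_s1, text: "Effectively restoring normal heart rhythm."}
      - {id: ablation_s2, text: "Eliminates arrhythmia symptoms."}
      - {id: ablation_s3, text: "Improves the quality of life."}
    against:
      - {id: ablation_a1, text: "Invasive surgery."}
      - {id: ablation_a2, text: "There is a risk of bleeding, blood clots, and infection."}
      - {id: ablation_a3, text: "It may cause pain."}
      - {id: ablation_a4, text: "Bleeding and infection."}
  cardiac_ultrasound:
    rationale: >-
      To assess heart structure and function using noninvasive ultrasound imaging.
    optional: false
    alternatives: []
    support:
      - {id: ultra_s1, text: "Noninvasive procedures."}
      - {id: ultra_s2, text: "Provides real-time imaging of the heart."}
      - {id: ultra_s3, text: "Helps assess heart function."}
      - {id: ultra_s4, text: "Assists in the development of treatment plans."}
    against:
      - {id: ultra_a1, text: "Limited ability to visualize certain structures."}
      - {id: ultra_a2, text: "It takes expertise to explain it accurately."}
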