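# Default two-level evaluation indicator system for traditional-medicine
# emergency-health policies: 10 main indicators, 44 binary sub-indicators.
# The disclosure indicator (X10) declares no sub-indicators and is scored
# as a single implicit binary variable.
name: "TCM emergency policy evaluation system"
version: "1.0"
mains:
  - id: X1
    label: "Policy Nature"
    source_note: "Modified from an article by Estrada"
    subs:
      - {id: "X1:1", label: "Forecast"}
      - {id: "X1:2", label: "Supervise"}
      - {id: "X1:3", label: "Guide"}
      - {id: "X1:4", label: "Describe"}
  - id: X2
    label: "Policy Time"
    source_note: "Modified from the article by Lan Yafei, Han Haizhi"
    subs:
      - {id: "X2:1", label: "Long-term (> 5 years)"}
      - {id: "X2:2", label: "Mid-term (3 ~ 5 years)"}
      - {id: "X2:3", label: "Short-term (< 3 years)"}
  - id: X3
    label: "Policy Release Agency"
    source_note: "By authors modifying based on Policy Document information"
    subs:
      - {id: "X3:1", label: "the State Council"}
      - {id: "X3:2", label: "National Health Commission of the People's Republic of China"}
      - {id: "X3:3", label: "National Administration of Traditional Chinese Medicine"}
  - id: X4
    label: "Policy Function"
    source_note: "By authors based on the results from content analysis"
    subs:
      - {id: "X4:1", label: "Institution-Building"}
      - {id: "X4:2", label: "Medical Treatment"}
      - {id: "X4:3", label: "Resource Sharing"}
      - {id: "X4:4", label: "Personnel Training"}
      - {id: "X4:5", label: "Expert Organizations"}
      - {id: "X4:6", label: "Clinical Study"}
      - {id: "X4:7", label: "Emergency Plan"}
      - {id: "X4:8", label: "Advantages of TCM"}
      - {id: "X4:9", label: "Informatization"}
      - {id: "X4:10", label: "Responsibility Implementation"}
      - {id: "X4:11", label: "Epidemic Prevention Propaganda"}
      - {id: "X4:12", label: "Hospital Infection Prevention and Control"}
  - id: X5
    label: "Guarantees Measures"
    source_note: "By authors based on the results from content analysis"
    subs:
      - {id: "X5:1", label: "Personnel Guarantee"}
      - {id: "X5:2", label: "Technical Guarantee"}
      - {id: "X5:3", label: "Organizational Guarantee"}
      - {id: "X5:4", label: "Funding Guarantee"}
      - {id: "X5:5", label: "System"}
      - {id: "X5:6", label: "Law"}
      - {id: "X5:7", label: "R&D Guarantee"}
      - {id: "X5:8", label: "Emergency Supplies"}
  - id: X6
    label: "Policy Perspective"
    source_note: "Modified from the article by Zhang Yong'an and Qie Hai-tuo"
    subs:
      - {id: "X6:1", label: "Macro-level"}
      - {id: "X6:2", label: "Micro-level"}
  - id: X7
    label: "Policy Evaluation"
    source_note: "Modified from the article by Zhang Yong'an and Qie Hai-tuo"
    subs:
      - {id: "X7:1", label: "Clear objectives"}
      - {id: "X7:2", label: "Clear authority and responsibility"}
      - {id: "X7:3", label: "Detailed planning"}
      - {id: "X7:4", label: "Scientific program"}
  - id: X8
    label: "Policy Receptors"
    source_note: "Modified from the article by Zhang Yong'an and Qie Hai-tuo"
    subs:
      - {id: "X8:1", label: "Government Department"}
      - {id: "X8:2", label: "Healthcare institution"}
      - {id: "X8:3", label: "Enterprise"}
      - {id: "X8:4", label: "Social Force"}
  - id: X9
    label: "Policy Instrument"
    source_note: "Modified from an article by Jinfu Wang and Qingyun Yang"
    subs:
      - {id: "X9:1", label: "Motivational type"}
      - {id: "X9:2", label: "Compulsory type"}
      - {id: "X9:3", label: "Service oriented"}
      - {id: "X9:4", label: "Market oriented"}
  - id: X10
    label: "Policy Disclosure"
    source_note: "Modified from the article by Zhang Yong'an and Qie Hai-tuo"
    subs: []
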