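variable,label,score
X1:1,Forecast,0.54
X1:2,Supervise,0.54
X1:3,Guide,1.00
X1:4,Describe,1.00
X2:1,Long-term (> 5 years),0.31
X2:2,Mid-term (3 ~ 5 years),0.08
X2:3,Short-term (< 3 years),0.62
X3:1,the State Council,0.23
X3:2,National Health Commission of the People's Republic of China,0.15
X3:3,National Administration of Traditional Chinese Medicine,0.92
X4:1,Institution-Building,0.85
X4:2,Medical Treatment,1.00
X4:3,Resource Sharing,0.46
X4:4,Personnel Training,0.46
X4:5,Expert Organizations,0.54
X4:6,Clinical Study,0.31
X4:7,Emergency Plan,0.69
X4:8,Advantages of TCM,0.46
X4:9,Informatization,0.31
X4:10,Responsibility Implementation,0.38
X4:11,Epidemic Prevention Propaganda,0.46
X4:12,Hospital Infection Prevention and Control,0.23
X5:1,Personnel Guarantee,0.85
X5:2,Technical Guarantee,0.85
X5:3,Organizational Guarantee,0.62
X5:4,Funding Guarantee,0.23
X5:5,System,0.54
X5:6,Law,0.15
X5:7,R&D Guarantee,0.15
X5:8,Emergency Supplies,0.69
X6:1,Macro-level,0.62
X6:2,Micro-level,0.77
X7:1,Clear objectives,1.00
X7:2,Clear authority and responsibility,0.62
X7:3,Detailed planning,0.69
X7:4,Scientific program,1.00
X8:1,Government Department,0.85
X8:2,Healthcare institution,0.77
X8:3,Enterprise,0.08
X8:4,Social Force,0.31
X9:1,Motivational type,0.77
X9:2,Compulsory type,0.54
X9:3,Service oriented,0.31
X9:4,Market oriented,0.08
X10,Policy Disclosure,1.00
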