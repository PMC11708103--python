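pid,title,release_date,agencies
P1,"Notice from the State Administration of Traditional Chinese Medicine on Maximizing the Role of Traditional Chinese Medicine in Disease Prevention and Disaster Relief",2003-07-29,"National Administration of Traditional Chinese Medicine"
P2,"Notice on Maximizing the Role of Traditional Chinese Medicine in Health Emergency Response Work",2009-04-24,"Ministry of Health P.R.China; National Administration of Traditional Chinese Medicine"
P3,"Notice from the General Office of the Ministry of Health and the Office of the State Administration of Traditional Chinese Medicine on Further Utilizing Traditional Chinese Medicine in the Prevention and Control of H1N1 Influenza (Swine Flu)",2010-01-28,"Ministry of Health P.R.China; National Administration of Traditional Chinese Medicine"
P4,"Notice from the State Administration of Traditional Chinese Medicine on Issuing the Clinical Research System Construction Plan (Trial) for Traditional Chinese Medicine Prevention and Treatment of Infectious Diseases",2010-11-01,"National Administration of Traditional Chinese Medicine"
P5,"Notice on Fully Utilizing Traditional Chinese Medicine in Flood Disaster Disease Prevention and Control",2016-07-25,"National Administration of Traditional Chinese Medicine"
P6,"Notice on Strengthening Information Technology Support for Traditional Chinese Medicine Prevention and Control Work in the COVID-19 Pandemic",2020-02-08,"National Administration of Traditional Chinese Medicine"
P7,"Notice on Establishing and Improving the Mechanism for Collaboration between Traditional Chinese Medicine and Western Medicine in the Prevention and Control of Infectious Diseases such as COVID-19",2020-02-12,"National Health Commission of the People's Republic of China; National Administration of Traditional Chinese Medicine"
P8,"Notice on Issuing the Trial Guidelines for Traditional Chinese Medicine Rehabilitation during the Recovery Phase of COVID-19",2020-02-22,"National Health Commission of the People's Republic of China; National Administration of Traditional Chinese Medicine"
P9,"Notice from the Office of the State Administration of Traditional Chinese Medicine on Carrying Out Various Tasks of Traditional Chinese Medicine in the Normalized Prevention and Control of COVID-19",2020-05-15,"National Administration of Traditional Chinese Medicine"
P10,"Notice on Further Strengthening the Prevention and Control of COVID-19 in Traditional Chinese Medical Institutions",2020-06-19,"National Administration of Traditional Chinese Medicine"
P11,"Notice on Implementing Traditional Chinese Medicine Measures for the Prevention and Control of COVID-19 during the Winter and Spring Seasons",2020-12-14,"National Administration of Traditional Chinese Medicine"
P12,"Guidelines (Trial) for the Construction and Management of National Traditional Chinese Medicine Emergency Medical Teams",2021-06-15,"National Administration of Traditional Chinese Medicine"
P13,"Notice on Further Leveraging the Unique Advantages of Traditional Chinese Medicine in the Medical Treatment of COVID-19 Infections",2023-01-02,"Joint Prevention and Control Mechanism of the State Council"
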