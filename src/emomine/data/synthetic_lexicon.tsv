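term	concept	item
cancer	cancer	cancer_keyword
malignant tumor	cancer	cancer_keyword
암	cancer	cancer_keyword
tumor	cancer	cancer_keyword
hope	hope	HG
hopeful	hope	HG
희망	hope	HG
gratitude	gratitude	HG
thankful	gratitude	HG
감사	gratitude	HG
anxiety	anxiety	FAO
anxious	anxiety	FAO
불안	anxiety	FAO
worry	anxiety	FAO
overwhelmed	overwhelmed	FAO
막막	overwhelmed	FAO
fear	anxiety	FAO
depression	depression	SDLG
depressed	depression	SDLG
우울	depression	SDLG
loneliness	loneliness	SDLG
lonely	loneliness	SDLG
외로움	loneliness	SDLG
guilt	guilt	SDLG
죄책감	guilt	SDLG
sad	depression	SDLG
anger	anger	AD
angry	anger	AD
분노	anger	AD
denial	denial	AD
부정	denial	AD
male	male	male
man	male	male
남자	male	male
female	female	female
woman	female	female
여자	female	female
under ten	age_under_10	age_under_10
child	age_under_10	age_under_10
teens	age_10s	age_10s
teenager	age_10s	age_10s
twenties	age_20s	age_20s
20s	age_20s	age_20s
thirties	age_30s	age_30s
30s	age_30s	age_30s
forties	age_40s	age_40s
40s	age_40s	age_40s
fifties	age_50s	age_50s
50s	age_50s	age_50s
sixties	age_60s	age_60s
60s	age_60s	age_60s
seventies	age_70s	age_70s
70s	age_70s	age_70s
over eighty	age_over_80	age_over_80
80s	age_over_80	age_over_80
breast cancer	breast_cancer	breast_cancer
유방암	breast_cancer	breast_cancer
colon cancer	colon_cancer	colon_cancer
대장암	colon_cancer	colon_cancer
gastric cancer	gastric_cancer	gastric_cancer
stomach cancer	gastric_cancer	gastric_cancer
위암	gastric_cancer	gastric_cancer
leukemia	leukemia	leukemia
백혈병	leukemia	leukemia
lung cancer	lung_cancer	lung_cancer
폐암	lung_cancer	lung_cancer
cervical cancer	cervical_cancer	cervical_cancer
자궁경부암	cervical_cancer	cervical_cancer
liver cancer	liver_cancer	liver_cancer
간암	liver_cancer	liver_cancer
brain cancer	brain_cancer	brain_cancer
뇌종양	brain_cancer	brain_cancer
pancreatic cancer	pancreatic_cancer	pancreatic_cancer
췌장암	pancreatic_cancer	pancreatic_cancer
ovarian cancer	ovarian_cancer	ovarian_cancer
난소암	ovarian_cancer	ovarian_cancer
prostatic cancer	prostatic_cancer	prostatic_cancer
prostate cancer	prostatic_cancer	prostatic_cancer
전립선암	prostatic_cancer	prostatic_cancer
gallbladder cancer	gallbladder_cancer	gallbladder_cancer
담낭암	gallbladder_cancer	gallbladder_cancer
kidney cancer	kidney_cancer	kidney_cancer
신장암	kidney_cancer	kidney_cancer
thyroid cancer	thyroid_cancer	thyroid_cancer
갑상선암	thyroid_cancer	thyroid_cancer
early stage	early_stage	early_stage
초기	early_stage	early_stage
middle stage	middle_stage	middle_stage
중기	middle_stage	middle_stage
terminal stage	terminal_stage	terminal_stage
말기	terminal_stage	terminal_stage
surgery	surgery	surgery
operation	surgery	surgery
수술	surgery	surgery
chemotherapy	chemotherapy	chemotherapy
chemo	chemotherapy	chemotherapy
항암치료	chemotherapy	chemotherapy
radiation therapy	radiation_therapy	radiation_therapy
radiotherapy	radiation_therapy	radiation_therapy
방사선치료	radiation_therapy	radiation_therapy
immunotherapy	immunotherapy	immunotherapy
면역치료	immunotherapy	immunotherapy
alternative medicine	cam	cam
herbal remedy	cam	cam
대체요법	cam	cam
transplantation	transplantation	transplantation
transplant	transplantation	transplantation
이식	transplantation	transplantation
acute survival	acute_survival	acute_survival
newly diagnosed	acute_survival	acute_survival
진단	acute_survival	acute_survival
extended survival	extended_survival	extended_survival
follow up care	extended_survival	extended_survival
permanent survival	permanent_survival	permanent_survival
cancer free	permanent_survival	permanent_survival
완치	permanent_survival	permanent_survival
fatigue	fatigue_pain_fever	fatigue_pain_fever
pain	fatigue_pain_fever	fatigue_pain_fever
fever	fatigue_pain_fever	fatigue_pain_fever
통증	fatigue_pain_fever	fatigue_pain_fever
nausea	gastrointestinal_problems	gastrointestinal_problems
vomiting	gastrointestinal_problems	gastrointestinal_problems
구토	gastrointestinal_problems	gastrointestinal_problems
hair loss	hair_loss_skin_problems	hair_loss_skin_problems
skin rash	hair_loss_skin_problems	hair_loss_skin_problems
탈모	hair_loss_skin_problems	hair_loss_skin_problems
poor circulation	poor_circulation	poor_circulation
numb hands	poor_circulation	poor_circulation
수족냉증	poor_circulation	poor_circulation
thrombocytopenia	thrombocytopenia	thrombocytopenia
low platelets	thrombocytopenia	thrombocytopenia
혈소판감소	thrombocytopenia	thrombocytopenia
infection	infection	infection
감염	infection	infection
sepsis	infection	infection
malicious virus	stop	stop_keyword
computer virus	stop	stop_keyword
zodiac	stop	stop_keyword
horoscope	stop	stop_keyword
detoxification	ad	ad_keyword
miracle cure	ad	ad_keyword
discount event	ad	ad_keyword
buy now	ad	ad_keyword
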