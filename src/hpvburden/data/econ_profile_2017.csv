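# Age-bin x sex economic inputs for the human-capital productivity model:
# 2017 US labor-force participation (%), 2017 median weekly wage (USD), and
# annual value of non-market (household/caregiving) work in 2017 USD.
# Age 15 carries zero productivity (no participation data for that age).
# The 75+ bin extends to the top of the mortality age domain (100) and is
# also applied to attained ages beyond 100 during discounting.
age_lo,age_hi,sex,labor_force_participation_pct,median_weekly_wage_usd,nonmarket_annual_usd
15,15,male,0.0,0,0
15,15,female,0.0,0,0
16,17,male,23.0,459,8169
16,17,female,26.3,402,14489
18,19,male,48.2,459,8169
18,19,female,47.2,402,14489
20,24,male,74.1,570,8169
20,24,female,68.5,514,14489
25,29,male,87.5,821,19097
25,29,female,76.4,724,33087
30,34,male,90.2,821,19097
30,34,female,74.5,724,33087
35,39,male,90.9,1062,25117
35,39,female,74.3,860,35822
40,44,male,90.5,1062,25117
40,44,female,75.7,860,35822
45,49,male,88.3,1103,19318
45,49,female,75.8,855,25261
50,54,male,84.6,1103,19318
50,54,female,73.2,855,25261
55,59,male,78.0,1098,16760
55,59,female,66.2,856,23079
60,64,male,62.4,1098,16760
60,64,female,51.0,856,23079
65,69,male,37.3,1016,17676
65,69,female,27.9,782,22914
70,74,male,23.7,1016,17676
70,74,female,16.2,782,22914
75,100,male,11.5,1016,11896
75,100,female,6.0,782,13515
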