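age_band,gender,d_earnings,d_missed_value,total,emp_prob_baseline,emp_prob_followup,missed_days_baseline,missed_days_followup,daily_earnings
40-49,M,14486,1344,15830,0.55,0.82,50,14,230
50-59,M,15408,991,16399,0.50,0.78,50,14,240
60-64,M,14021,397,14418,0.40,0.62,50,14,215
65-69,M,9336,79,9415,0.25,0.38,50,14,140
70-74,M,4283,-9,4274,0.12,0.18,50,14,65
75+,M,0,0,0,0.0,0.0,0,0,0
40-49,F,11781,761,12542,0.48,0.72,50,14,185
50-59,F,12352,559,12911,0.44,0.66,50,14,195
60-64,F,9930,167,10097,0.33,0.50,50,14,150
65-69,F,5477,-6,5471,0.20,0.30,50,14,85
70-74,F,1927,-10,1917,0.08,0.12,50,14,30
75+,F,0,0,0,0.0,0.0,0,0,0
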