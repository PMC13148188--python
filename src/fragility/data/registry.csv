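name,a,b,c,d,expected_status,note
counterexample-1,3,0,4,11,not_attainable,constructed counterexample; arm with fewer events has zero nonevents so no legal toggle exists
counterexample-2,9,1,10,90,not_attainable,constructed counterexample; a single legal toggle exists but leaves the result highly significant
counterexample-3,9,35,8,8,not_attainable,constructed counterexample; toggling the smaller-event arm drives p away from 0.05 until the arm is exhausted
empirical-1,910,1262,1028,1646,not_attainable,FINEARTS-HF adverse events by ejection-fraction stratum (910/2172 vs 1028/2674)
empirical-2,1594,638,282,58,not_attainable,ISCHEMIA freedom from angina at 48 months (1594/2232 conservative vs 282/340 bypass)
fresco,188,90,109,29,not_attainable,FRESCO deaths (188/278 treatment vs 109/138 placebo)
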