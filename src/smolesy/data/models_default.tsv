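target	reference	slope	intercept	residual_sd
cho-nme3	ala-ch3	0.3939145674	2.62279428	0.0003713830155
cho-nme3	lac-ch3	0.4729760425	2.575960435	0.0003729569078
crn-ch2	ala-ch3	0.4235730483	3.431927359	0.0003799467131
crn-ch2	crn-ch3	0.7808417664	1.677981934	0.0004328425766
crn-ch2	lac-ch3	0.5082799711	3.381975927	0.0003830811842
crn-ch3	ala-ch3	0.5004578026	2.308301508	0.0003734426259
crn-ch3	crn-ch2	1.041789152	-1.179565187	0.0004999635826
crn-ch3	lac-ch3	0.6011116397	2.248523237	0.0003748584126
crt-ch3	ala-ch3	0.3998980335	2.444946267	0.0003660884689
crt-ch3	lac-ch3	0.476225993	2.402633903	0.0003843437748
dmso2-ch3	ala-ch3	0.2380891593	2.788041009	0.0003652482156
dmso2-ch3	lac-ch3	0.286408135	2.759025176	0.0003644475614
gly-ch2	ala-ch3	0.3339018726	3.067458793	0.0003757620894
gly-ch2	lac-ch3	0.4075881162	3.018889181	0.000352330256
his-h2	ala-ch3	1.028389141	6.250073639	0.0004328399919
his-h2	lac-ch3	1.220671952	6.146587802	0.000557185684
met-sch3	ala-ch3	0.3398587719	1.625713075	0.0003612953121
met-sch3	lac-ch3	0.4056260273	1.588557781	0.0003714978627
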