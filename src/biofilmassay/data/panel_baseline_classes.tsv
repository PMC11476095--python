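isolate_id	class_24h	class_48h
A2.48.2016	NP	WP
N9.25.2016	NP	NP
A1.6.2017	SP	WP
N10.27.2017	NP	NP
A4.16.2019	WP	MP
N9.1.2019	MP	MP
A4.26.2021	MP	WP
N10.1.2021	NP	WP
A1.14.2022	SP	SP
N10.55.2022	WP	MP
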