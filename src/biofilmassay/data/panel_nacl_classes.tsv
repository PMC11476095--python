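isolate_id	level	class_24h	class_48h
A2.48.2016	1	NP	NP
A2.48.2016	2	NP	NP
A2.48.2016	4	NP	NP
A2.48.2016	8	NP	NP
N9.25.2016	1	NP	NP
N9.25.2016	2	NP	NP
N9.25.2016	4	NP	NP
N9.25.2016	8	WP	WP
A1.6.2017	1	WP	MP
A1.6.2017	2	WP	WP
A1.6.2017	4	WP	WP
A1.6.2017	8	WP	SP
N10.27.2017	1	NP	NP
N10.27.2017	2	NP	NP
N10.27.2017	4	NP	NP
N10.27.2017	8	NP	NP
A4.16.2019	1	WP	WP
A4.16.2019	2	WP	NP
A4.16.2019	4	NP	NP
A4.16.2019	8	NP	NP
N9.1.2019	1	WP	WP
N9.1.2019	2	WP	WP
N9.1.2019	4	WP	WP
N9.1.2019	8	NP	WP
A4.26.2021	1	WP	WP
A4.26.2021	2	NP	NP
A4.26.2021	4	NP	NP
A4.26.2021	8	WP	SP
N10.1.2021	1	NP	WP
N10.1.2021	2	WP	WP
N10.1.2021	4	NP	NP
N10.1.2021	8	NP	WP
A1.14.2022	1	MP	SP
A1.14.2022	2	MP	MP
A1.14.2022	4	MP	SP
A1.14.2022	8	MP	MP
N10.55.2022	1	NP	MP
N10.55.2022	2	WP	WP
N10.55.2022	4	NP	WP
N10.55.2022	8	NP	MP
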