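isolate_id	level	class_24h	class_48h
A2.48.2016	5	NP	NP
A2.48.2016	6	NP	NP
A2.48.2016	7	NP	NP
A2.48.2016	8	NP	WP
A2.48.2016	9	NP	NP
N9.25.2016	5	NP	NP
N9.25.2016	6	NP	NP
N9.25.2016	7	NP	NP
N9.25.2016	8	NP	MP
N9.25.2016	9	NP	WP
A1.6.2017	5	WP	WP
A1.6.2017	6	WP	WP
A1.6.2017	7	WP	WP
A1.6.2017	8	WP	WP
A1.6.2017	9	WP	WP
N10.27.2017	5	NP	NP
N10.27.2017	6	NP	NP
N10.27.2017	7	NP	NP
N10.27.2017	8	NP	NP
N10.27.2017	9	NP	NP
A4.16.2019	5	NP	WP
A4.16.2019	6	WP	WP
A4.16.2019	7	WP	WP
A4.16.2019	8	WP	MP
A4.16.2019	9	WP	MP
N9.1.2019	5	MP	MP
N9.1.2019	6	WP	WP
N9.1.2019	7	SP	MP
N9.1.2019	8	WP	WP
N9.1.2019	9	WP	WP
A4.26.2021	5	NP	WP
A4.26.2021	6	NP	NP
A4.26.2021	7	WP	NP
A4.26.2021	8	NP	WP
A4.26.2021	9	WP	NP
N10.1.2021	5	WP	MP
N10.1.2021	6	WP	WP
N10.1.2021	7	WP	WP
N10.1.2021	8	WP	WP
N10.1.2021	9	WP	WP
A1.14.2022	5	WP	MP
A1.14.2022	6	MP	MP
A1.14.2022	7	MP	SP
A1.14.2022	8	MP	SP
A1.14.2022	9	SP	SP
N10.55.2022	5	NP	WP
N10.55.2022	6	NP	WP
N10.55.2022	7	WP	WP
N10.55.2022	8	NP	MP
N10.55.2022	9	MP	SP
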