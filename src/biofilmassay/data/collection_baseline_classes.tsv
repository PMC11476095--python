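isolate_id	class_24h	class_48h
A1.40.2016	NP	WP
A2.48.2016	NP	WP
A3.34.2016	NP	WP
A4.19.2016	NP	NP
A5.17.2016	NP	NP
N9.25.2016	NP	WP
N10.46.2016	WP	NP
A1.6.2017	SP	WP
A2.17.2017	NP	NP
A3.9.2017	WP	WP
A4.6.2017	NP	NP
A5.18.2017	MP	WP
N9.1.2017	NP	NP
N10.27.2017	NP	NP
A1.9.2019	WP	MP
A2.20.2019	NP	WP
A3.2.2019	NP	WP
A4.16.2019	WP	MP
N9.1.2019	MP	MP
N10.14.2019	NP	MP
A1.2.2021	MP	WP
A1.24.2021	MP	WP
A1.45.2021	NP	WP
A1.59.2021	NP	WP
A2.3.2021	NP	NP
A2.17.2021	WP	MP
A2.32.2021	NP	NP
A2.58.2021	NP	NP
A3.4.2021	NP	WP
A3.9.2021	WP	NP
A3.16.2021	NP	WP
A3.19.2021	NP	MP
A3.26.2021	NP	WP
A3.39.2021	NP	MP
A3.45.2021	NP	WP
A4.7.2021	NP	NP
A4.11.2021	WP	NP
A4.21.2021	NP	NP
A4.26.2021	MP	WP
A4.41.2021	WP	WP
N9.21.2021	NP	WP
N9.46.2021	NP	NP
N9.58.2021	NP	NP
N10.1.2021	NP	WP
N10.21.2021	MP	NP
N10.45.2021	NP	MP
N10.47.2021	WP	MP
N10.49.2021	WP	WP
A1.14.2022	SP	SP
A1.54.2022	WP	MP
A2.1.2022	NP	NP
A2.23.2022	NP	NP
A2.34.2022	NP	WP
A2.38.2022	WP	WP
A3.14.2022	WP	NP
A3.38.2022	MP	WP
A3.47.2022	NP	NP
A3.49.2022	NP	WP
A3.57.2022	NP	WP
A4.5.2022	NP	MP
A4.11.2022	NP	WP
A4.12.2022	WP	MP
A4.20.2022	WP	MP
A4.30.2022	WP	MP
A4.43.2022	NP	WP
A4.54.2022	NP	WP
A4.59.2022	WP	WP
N9.1.2022	WP	WP
N9.23.2022	WP	MP
N9.58.2022	NP	WP
N10.18.2022	WP	MP
N10.55.2022	WP	MP
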