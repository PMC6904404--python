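1	Leeds	Leeds		53.79648	-1.54785	GB	474632
2	Berlin	Berlin		52.52437	13.41053	DE	3426354
3	Springfield	Springfield		39.80172	-89.64371	US	167000
4	Springfield	Springfield		-33.95000	147.00000	AU	5000
5	Münster	Muenster	Munster,Muenster in Westfalen	51.96236	7.62571	DE	270184
6	Madrid	Madrid		40.41650	-3.70256	ES	3255944
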