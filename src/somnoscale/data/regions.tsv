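region_id	region_name	lobe	n_channels_W	n_channels_N2	n_channels_N3	n_channels_R
1	Superior and middle occipital gyri	Occipital	21	16	16	14
2	Inferior occipital gyrus and occipital pole	Occipital	23	22	22	17
3	Cuneus	Occipital	19	18	18	18
4	Calcarine cortex	Occipital	12	10	10	8
5	Lingual gyrus and occipital fusiform gyrus	Occipital	29	21	21	12
6	Postcentral gyrus (including medial segment)	Parietal	64	43	43	31
7	Superior parietal lobule	Parietal	53	40	40	36
8	Parietal operculum	Parietal	41	31	31	10
9	Supramarginal gyrus	Parietal	70	65	65	39
10	Angular gyrus	Parietal	53	52	52	42
11	Precuneus	Parietal	43	37	37	32
12	Posterior cingulate	Parietal	29	25	25	14
13	Anterior insula	Insular	71	54	54	35
14	Posterior insula	Insular	35	25	25	14
15	Gyrus rectus and orbital gyri	Medial frontal	45	41	41	28
16	Anterior cingulate	Medial frontal	31	31	31	19
17	Middle cingulate	Medial frontal	40	31	31	21
18	Supplementary motor cortex	Medial frontal	47	37	37	28
19	Medial frontal cortex	Medial frontal	19	15	15	10
20	Central operculum	Medial frontal	63	46	46	29
21	Frontal operculum	Lateral frontal	29	24	24	18
22	Opercular part of inferior frontal gyrus	Lateral frontal	38	30	30	20
23	Triangular part of inferior frontal gyrus	Lateral frontal	47	41	41	29
24	Orbital part of inferior frontal gyrus	Lateral frontal	19	17	17	13
25	Middle frontal gyrus	Lateral frontal	173	149	149	106
26	Superior frontal gyrus and frontal pole	Lateral frontal	89	78	78	64
27	Medial segment of superior frontal gyrus	Medial frontal	16	16	16	13
28	Medial segment of precentral gyrus	Medial frontal	18	13	13	11
29	Precentral gyrus	Lateral frontal	123	82	82	60
30	Superior temporal gyrus	Temporal	79	69	69	46
31	Middle temporal gyrus	Temporal	126	115	115	73
32	Inferior temporal gyrus	Temporal	41	40	40	29
33	Temporal pole and planum polare	Temporal	22	16	16	7
34	Transverse temporal gyrus	Temporal	14	12	12	4
35	Planum temporale	Temporal	43	29	29	15
36	Fusiform and parahippocampal gyri	Temporal	45	41	41	29
37	Hippocampus	Temporal	36	30	30	13
38	Amygdala	Temporal	6	6	6	5
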