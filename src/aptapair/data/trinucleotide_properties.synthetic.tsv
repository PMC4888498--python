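# SYNTHETIC stand-in for a published 12-property trinucleotide compendium:
# six base-step helical parameters averaged over the two steps, three
# composition fractions, and three step-to-step parameter differences.
# Deterministically derived from dinucleotide_properties.tsv.
tuple	twist_mean	tilt_mean	roll_mean	shift_mean	slide_mean	rise_mean	gc_frac	purine_frac	amino_frac	twist_diff	roll_diff	slide_diff
AAA	35.1000	-1.4000	0.7000	-0.0300	-0.0800	3.2700	0.0000	1.0000	1.0000	0.0000	0.0000	0.0000
AAC	33.3000	-0.7500	0.7000	0.0500	-0.3300	3.3150	0.3333	0.6667	1.0000	-3.6000	0.0000	-0.5000
AAG	33.5000	-1.5500	2.6000	0.0300	-0.1650	3.3050	0.3333	1.0000	0.6667	-3.2000	3.8000	-0.1700
AAT	32.2000	-0.7000	0.9000	-0.0150	-0.3350	3.2900	0.0000	0.6667	0.6667	-5.8000	0.4000	-0.5100
ACA	34.4000	0.2000	2.7000	0.1100	-0.0250	3.3450	0.3333	0.6667	1.0000	5.8000	4.0000	1.1100
ACC	32.2000	-0.1000	2.1500	0.0900	-0.4000	3.3900	0.6667	0.3333	1.0000	1.4000	2.9000	0.3600
ACG	33.8000	-0.0500	3.0500	0.0650	-0.0850	3.3750	0.6667	0.6667	0.6667	4.6000	4.7000	0.9900
ACT	31.7000	0.8000	2.6000	0.0200	-0.4150	3.3500	0.3333	0.3333	0.6667	0.4000	3.8000	0.3300
AGA	34.1000	-1.6000	3.2000	-0.0950	-0.0800	3.3550	0.3333	1.0000	0.6667	4.4000	-2.6000	0.3400
AGC	32.7500	-0.8500	2.4000	0.0450	-0.3150	3.3700	0.6667	0.6667	0.6667	1.7000	-4.2000	-0.1300
AGG	32.4000	-0.8000	4.0500	0.0200	-0.2350	3.3800	0.6667	1.0000	0.3333	1.0000	-0.9000	0.0300
AGT	31.7000	-0.8000	2.6000	-0.0200	-0.4150	3.3500	0.3333	0.6667	0.3333	-0.4000	-3.8000	-0.3300
ATA	33.5500	0.0000	2.2000	0.0000	-0.2700	3.3650	0.0000	0.6667	0.6667	8.5000	2.2000	0.6400
ATC	32.8000	0.7500	1.5000	0.1400	-0.2500	3.3400	0.3333	0.3333	0.6667	7.0000	0.8000	0.6800
ATG	33.3000	-0.2500	2.9000	-0.0450	-0.0300	3.3200	0.3333	0.6667	0.3333	8.0000	3.6000	1.1200
ATT	32.2000	0.7000	0.9000	0.0150	-0.3350	3.2900	0.0000	0.3333	0.3333	5.8000	-0.4000	0.5100
CAA	36.2000	-0.4500	2.7000	0.0300	0.2250	3.3000	0.3333	0.6667	1.0000	-2.2000	-4.0000	-0.6100
CAC	34.4000	0.2000	2.7000	0.1100	-0.0250	3.3450	0.6667	0.3333	1.0000	-5.8000	-4.0000	-1.1100
CAG	34.6000	-0.6000	4.6000	0.0900	0.1400	3.3350	0.6667	0.6667	0.6667	-5.4000	-0.2000	-0.7800
CAT	33.3000	0.2500	2.9000	0.0450	-0.0300	3.3200	0.3333	0.3333	0.6667	-8.0000	-3.6000	-1.1200
CCA	35.1000	0.2000	4.1500	0.0700	0.1550	3.3750	0.6667	0.3333	1.0000	4.4000	1.1000	0.7500
CCC	32.9000	-0.1000	3.6000	0.0500	-0.2200	3.4200	1.0000	0.0000	1.0000	0.0000	0.0000	0.0000
CCG	34.5000	-0.0500	4.5000	0.0250	0.0950	3.4050	1.0000	0.3333	0.6667	3.2000	1.8000	0.6300
CCT	32.4000	0.8000	4.0500	-0.0200	-0.2350	3.3800	0.6667	0.0000	0.6667	-1.0000	0.9000	-0.0300
CGA	36.2000	-0.7500	3.6500	-0.1400	0.2500	3.3800	0.6667	0.6667	0.6667	0.2000	-3.5000	-0.3200
CGC	34.8500	0.0000	2.8500	0.0000	0.0150	3.3950	1.0000	0.3333	0.6667	-2.5000	-5.1000	-0.7900
CGG	34.5000	0.0500	4.5000	-0.0250	0.0950	3.4050	1.0000	0.6667	0.3333	-3.2000	-1.8000	-0.6300
CGT	33.8000	0.0500	3.0500	-0.0650	-0.0850	3.3750	0.6667	0.3333	0.3333	-4.6000	-4.7000	-0.9900
CTA	34.8500	0.8500	3.9000	-0.0450	-0.1000	3.3800	0.3333	0.3333	0.6667	5.9000	-1.2000	0.3000
CTC	34.1000	1.6000	3.2000	0.0950	-0.0800	3.3550	0.6667	0.0000	0.6667	4.4000	-2.6000	0.3400
CTG	34.6000	0.6000	4.6000	-0.0900	0.1400	3.3350	0.6667	0.3333	0.3333	5.4000	0.2000	0.7800
CTT	33.5000	1.5500	2.6000	-0.0300	-0.1650	3.3050	0.3333	0.0000	0.3333	3.2000	-3.8000	0.1700
GAA	35.7000	-1.4500	1.3000	-0.1550	0.0050	3.3200	0.3333	1.0000	0.6667	-1.2000	-1.2000	-0.1700
GAC	33.9000	-0.8000	1.3000	-0.0750	-0.2450	3.3650	0.6667	0.6667	0.6667	-4.8000	-1.2000	-0.6700
GAG	34.1000	-1.6000	3.2000	-0.0950	-0.0800	3.3550	0.6667	1.0000	0.3333	-4.4000	2.6000	-0.3400
GAT	32.8000	-0.7500	1.5000	-0.1400	-0.2500	3.3400	0.3333	0.6667	0.3333	-7.0000	-0.8000	-0.6800
GCA	35.4500	0.2500	2.5000	0.0450	0.0750	3.3650	0.6667	0.6667	0.6667	3.7000	4.4000	0.9100
GCC	33.2500	-0.0500	1.9500	0.0250	-0.3000	3.4100	1.0000	0.3333	0.6667	-0.7000	3.3000	0.1600
GCG	34.8500	0.0000	2.8500	0.0000	0.0150	3.3950	1.0000	0.6667	0.3333	2.5000	5.1000	0.7900
GCT	32.7500	0.8500	2.4000	-0.0450	-0.3150	3.3700	0.6667	0.3333	0.3333	-1.7000	4.2000	0.1300
GGA	34.6000	-0.7000	2.7500	-0.1650	-0.0650	3.3950	0.6667	1.0000	0.3333	3.4000	-1.7000	0.3100
GGC	33.2500	0.0500	1.9500	-0.0250	-0.3000	3.4100	1.0000	0.6667	0.3333	0.7000	-3.3000	-0.1600
GGG	32.9000	0.1000	3.6000	-0.0500	-0.2200	3.4200	1.0000	1.0000	0.0000	0.0000	0.0000	0.0000
GGT	32.2000	0.1000	2.1500	-0.0900	-0.4000	3.3900	0.6667	0.6667	0.0000	-1.4000	-2.9000	-0.3600
GTA	34.6500	0.0500	2.0000	-0.0650	-0.2650	3.3900	0.3333	0.6667	0.3333	6.3000	2.6000	0.6300
GTC	33.9000	0.8000	1.3000	0.0750	-0.2450	3.3650	0.6667	0.3333	0.3333	4.8000	1.2000	0.6700
GTG	34.4000	-0.2000	2.7000	-0.1100	-0.0250	3.3450	0.6667	0.6667	0.0000	5.8000	4.0000	1.1100
GTT	33.3000	0.7500	0.7000	-0.0500	-0.3300	3.3150	0.3333	0.3333	0.0000	3.6000	0.0000	0.5000
TAA	36.4500	-0.7000	2.0000	-0.0150	-0.0150	3.3450	0.0000	0.6667	0.6667	-2.7000	-2.6000	-0.1300
TAC	34.6500	-0.0500	2.0000	0.0650	-0.2650	3.3900	0.3333	0.3333	0.6667	-6.3000	-2.6000	-0.6300
TAG	34.8500	-0.8500	3.9000	0.0450	-0.1000	3.3800	0.3333	0.6667	0.3333	-5.9000	1.2000	-0.3000
TAT	33.5500	0.0000	2.2000	0.0000	-0.2700	3.3650	0.0000	0.3333	0.3333	-8.5000	-2.2000	-0.6400
TCA	36.8000	1.0000	3.3000	0.1850	0.3100	3.3500	0.3333	0.3333	0.6667	1.0000	2.8000	0.4400
TCC	34.6000	0.7000	2.7500	0.1650	-0.0650	3.3950	0.6667	0.0000	0.6667	-3.4000	1.7000	-0.3100
TCG	36.2000	0.7500	3.6500	0.1400	0.2500	3.3800	0.6667	0.3333	0.3333	-0.2000	3.5000	0.3200
TCT	34.1000	1.6000	3.2000	0.0950	-0.0800	3.3550	0.3333	0.0000	0.3333	-4.4000	2.6000	-0.3400
TGA	36.8000	-1.0000	3.3000	-0.1850	0.3100	3.3500	0.3333	0.6667	0.3333	-1.0000	-2.8000	-0.4400
TGC	35.4500	-0.2500	2.5000	-0.0450	0.0750	3.3650	0.6667	0.3333	0.3333	-3.7000	-4.4000	-0.9100
TGG	35.1000	-0.2000	4.1500	-0.0700	0.1550	3.3750	0.6667	0.6667	0.0000	-4.4000	-1.1000	-0.7500
TGT	34.4000	-0.2000	2.7000	-0.1100	-0.0250	3.3450	0.3333	0.3333	0.0000	-5.8000	-4.0000	-1.1100
TTA	36.4500	0.7000	2.0000	0.0150	-0.0150	3.3450	0.0000	0.3333	0.3333	2.7000	2.6000	0.1300
TTC	35.7000	1.4500	1.3000	0.1550	0.0050	3.3200	0.3333	0.0000	0.3333	1.2000	1.2000	0.1700
TTG	36.2000	0.4500	2.7000	-0.0300	0.2250	3.3000	0.3333	0.3333	0.0000	2.2000	4.0000	0.6100
TTT	35.1000	1.4000	0.7000	0.0300	-0.0800	3.2700	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
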