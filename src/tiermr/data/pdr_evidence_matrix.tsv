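gene	smr_disc_psmr_fdr	smr_disc_pheidi	smr_blood_psmr_fdr	smr_blood_pheidi	smr_rep_psmr_fdr	smr_rep_pheidi	mr_disc_p	mr_rep_p	coloc_pp4	category
CTSH	1.88E-02 √	6.11E-01 √	1.82E-02 √	5.94E-02 √	9.66E-14 √	4.46E-01 √	9.04E-06 √	5.29E-03 √	Weak (0.67) √	Tier 1
CYP21A2	8.72E-16 √	2.55E-04 ×	1.74E-09 √	6.06E-02 √	1.73E-02 √	4.80E-01 √	6.40E-04 √	2.11E-02 √	No ×	Tier 2
MICB	4.68E-04 √	8.66E-02 √	4.67E-03 √	9.39E-02 √	3.13E-05 √	1.39E-01 √	No ×	No ×	No ×	Tier 2
CCNE2	3.34E-02 √	7.31E-01 √	No ×	No ×	9.91E-01 ×	5.48E-01 ×	3.48E-02 √	9.97E-01 ×	Strong (0.86) √	Tier 2
TP53INP1	1.22E-02 √	1.04E-03 ×	4.92E-02 √	7.88E-01 √	9.96E-01 ×	3.89E-01 ×	No ×	No ×	Strong (0.90) √	Tier 2
PPIP5K2	4.49E-02 √	4.00E-01 √	6.74E-02 ×	6.09E-01 ×	9.72E-01 ×	3.16E-01 ×	No ×	No ×	Weak (0.75) √	Tier 3
XRCC1	1.05E-02 √	9.65E-02 √	8.72E-01 ×	4.77E-02 ×	9.95E-01 ×	6.33E-01 ×	No ×	8.34E-01 ×	Strong (0.96) √	Tier 3
C4B	4.27E-18 √	5.08E-13 ×	1.75E-12 √	2.29E-02 ×	9.96E-01 ×	9.99E-01 ×	2.61E-06 √	No ×	No ×	Tier 3
C4A	7.70E-17 √	1.48E-07 ×	1.75E-12 √	2.73E-05 ×	9.87E-01 ×	3.66E-01 ×	7.57E-08 √	No ×	No ×	Tier 3
HLA-C	1.12E-06 √	1.19E-08 ×	1.97E-09 √	7.79E-03 ×	9.73E-01 ×	2.25E-01 ×	6.33E-03 √	4.37E-01 ×	No ×	Tier 3
ZBTB22	7.43E-03 √	3.01E-05 ×	4.44E-02 √	3.69E-01 √	No ×	No ×	No ×	No ×	No ×	Tier 3
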