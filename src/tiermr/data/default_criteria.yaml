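# Default evidence criteria for tiered causal-gene classification.
# Nine criteria: three SMR/HEIDI pairs (discovery cis-eQTL, whole-blood
# eQTL, replication cohort), two two-sample-MR p-values (discovery and
# replication outcome cohorts), and moderate-or-better colocalization
# (PP4 > 0.5).
criteria:
  - name: discovery cis pSMR-FDR
    source: smr_p_fdr
    column: smr_disc_psmr_fdr
    threshold: 0.05
    direction: below
  - name: discovery cis pHEIDI
    source: heidi_p
    column: smr_disc_pheidi
    threshold: 0.05
    direction: above
    requires: discovery cis pSMR-FDR
  - name: whole-blood pSMR-FDR
    source: smr_p_fdr
    column: smr_blood_psmr_fdr
    threshold: 0.05
    direction: below
  - name: whole-blood pHEIDI
    source: heidi_p
    column: smr_blood_pheidi
    threshold: 0.05
    direction: above
    requires: whole-blood pSMR-FDR
  - name: replication cis pSMR-FDR
    source: smr_p_fdr
    column: smr_rep_psmr_fdr
    threshold: 0.05
    direction: below
  - name: replication pHEIDI
    source: heidi_p
    column: smr_rep_pheidi
    threshold: 0.05
    direction: above
    requires: replication cis pSMR-FDR
  - name: MR discovery p
    source: mr_p
    column: mr_disc_p
    threshold: 0.05
    direction: below
  - name: MR replication p
    source: mr_p
    column: mr_rep_p
    threshold: 0.05
    direction: below
  - name: coloc PP4
    source: coloc_pp4
    column: coloc_pp4
    threshold: 0.5
    direction: above

tier_rule:
  tier2_min: 4      # Tier 2 when n_satisfied >= tier2_min (set tier2_strict for > tier2_min)
  tier3_exact: 3    # Tier 3 when n_satisfied == tier3_exact
  tier2_strict: false
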