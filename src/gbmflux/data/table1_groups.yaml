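# Key-flux and flux-ratio definitions for GBM metabolic phenotyping on the
# full two-cell-type brain reconstruction (reaction ids r_*/e_* follow that
# reconstruction; astrocytic and neuronal counterparts are summed).
# reference_* fields carry literature values for context; they are metadata,
# never pipeline inputs.
groups:
  - name: lactate_production
    kind: sum
    member_ids: [r_11, r_56]
    reference_value: 1.336
    reference_source: "DeBerardinis et al. 2007"
  - name: pyruvate_carboxylase_ratio
    kind: ratio
    numerator: pyruvate_carboxylase
    denominator: glucose_uptake
    reference_range: [0.0, 0.227]
    reference_source: "Portais et al. 1993"
  - name: pyruvate_carboxylase
    kind: sum
    member_ids: [r_12]
  - name: glucose_uptake
    kind: sum
    member_ids: [r_596, r_597]
    uptake: true
  - name: oxidative_ppp_ratio
    kind: ratio
    numerator: oxidative_ppp
    denominator: glucose_uptake
    reference_value: 0.060
    reference_source: "DeBerardinis et al. 2007"
  - name: oxidative_ppp
    kind: sum
    member_ids: [r_17, r_61]
  - name: nonoxidative_ppp
    kind: sum
    member_ids: [r_21, r_65]
    reference_source: "increase vs healthy brain (Wolf et al. 2010)"
  - name: tca_citrate_synthase
    kind: sum
    member_ids: [r_25, r_69]
    reference_source: "decrease vs healthy brain (Wolf et al. 2010; Ru et al. 2013)"
  - name: acetyl_coa_lipid_precursor
    kind: sum
    member_ids: [r_28, r_72]
    reference_source: "increase vs healthy brain (Wolf et al. 2010; Boroughs & DeBerardinis 2015)"
  - name: anaplerosis
    kind: sum
    member_ids: [r_89, r_90, r_92, r_93]
    reference_range: [0.039, 0.078]
    reference_source: "Portais et al. 1993"
  - name: anaplerosis_to_cs_ratio
    kind: ratio
    numerator: anaplerosis
    denominator: tca_citrate_synthase
    reference_range: [0.940, 1.800]
    reference_source: "Maher et al. 2012"
  - name: acetyl_coa_carboxylase
    kind: sum
    member_ids: [r_289]
    reference_source: "increase vs healthy brain (Wolf et al. 2010)"
  - name: nh3_release
    kind: sum
    member_ids: [r_607]
    reference_value: 0.023
    reference_source: "DeBerardinis et al. 2007"
  - name: growth_rate
    kind: sum
    member_ids: [e_46]
    reference_range: [0.0006, 0.0095]
    reference_source: "Perego et al.; Pennington et al.; Wang et al.; Stensjoen et al."
  # additional named fluxes discussed alongside the main table
  - name: atp_glycolysis
    kind: sum
    member_ids: [r_7, r_10, r_52, r_55]
  - name: atp_oxphos
    kind: sum
    member_ids: [r_45, r_88]
  - name: pyruvate_dehydrogenase
    kind: sum
    member_ids: [r_13, r_57]
  - name: malic_enzyme
    kind: sum
    member_ids: [r_39, r_82]
  - name: malate_dehydrogenase
    kind: sum
    member_ids: [r_37, r_38, r_80]
  - name: glutaminase
    kind: sum
    member_ids: [r_96, r_97]
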