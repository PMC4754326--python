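# Default feature manifest: 34 regional cortical thickness means (Desikan-Killiany
# parcellation, left/right averaged, mm) and 21 subcortical / global volumes
# (aseg segmentation, bilateral structures left/right averaged, mm^3).
features:
  - {name: bankssts_thickness, kind: thickness}
  - {name: caudalanteriorcingulate_thickness, kind: thickness}
  - {name: caudalmiddlefrontal_thickness, kind: thickness}
  - {name: cuneus_thickness, kind: thickness}
  - {name: entorhinal_thickness, kind: thickness}
  - {name: fusiform_thickness, kind: thickness}
  - {name: inferiorparietal_thickness, kind: thickness}
  - {name: inferiortemporal_thickness, kind: thickness}
  - {name: isthmuscingulate_thickness, kind: thickness}
  - {name: lateraloccipital_thickness, kind: thickness}
  - {name: lateralorbitofrontal_thickness, kind: thickness}
  - {name: lingual_thickness, kind: thickness}
  - {name: medialorbitofrontal_thickness, kind: thickness}
  - {name: middletemporal_thickness, kind: thickness}
  - {name: parahippocampal_thickness, kind: thickness}
  - {name: paracentral_thickness, kind: thickness}
  - {name: parsopercularis_thickness, kind: thickness}
  - {name: parsorbitalis_thickness, kind: thickness}
  - {name: parstriangularis_thickness, kind: thickness}
  - {name: pericalcarine_thickness, kind: thickness}
  - {name: postcentral_thickness, kind: thickness}
  - {name: posteriorcingulate_thickness, kind: thickness}
  - {name: precentral_thickness, kind: thickness}
  - {name: precuneus_thickness, kind: thickness}
  - {name: rostralanteriorcingulate_thickness, kind: thickness}
  - {name: rostralmiddlefrontal_thickness, kind: thickness}
  - {name: superiorfrontal_thickness, kind: thickness}
  - {name: superiorparietal_thickness, kind: thickness}
  - {name: superiortemporal_thickness, kind: thickness}
  - {name: supramarginal_thickness, kind: thickness}
  - {name: frontalpole_thickness, kind: thickness}
  - {name: temporalpole_thickness, kind: thickness}
  - {name: transversetemporal_thickness, kind: thickness}
  - {name: insula_thickness, kind: thickness}
  - {name: Lateral-Ventricle_volume, kind: volume}
  - {name: Inf-Lat-Vent_volume, kind: volume}
  - {name: Cerebellum-White-Matter_volume, kind: volume}
  - {name: Cerebellum-Cortex_volume, kind: volume}
  - {name: Thalamus-Proper_volume, kind: volume}
  - {name: Caudate_volume, kind: volume}
  - {name: Putamen_volume, kind: volume}
  - {name: Pallidum_volume, kind: volume}
  - {name: Hippocampus_volume, kind: volume}
  - {name: Amygdala_volume, kind: volume}
  - {name: Accumbens-area_volume, kind: volume}
  - {name: VentralDC_volume, kind: volume}
  - {name: vessel_volume, kind: volume}
  - {name: choroid-plexus_volume, kind: volume}
  - {name: 3rd-Ventricle_volume, kind: volume}
  - {name: 4th-Ventricle_volume, kind: volume}
  - {name: Brain-Stem_volume, kind: volume}
  - {name: CSF_volume, kind: volume}
  - {name: WM-hypointensities_volume, kind: volume}
  - {name: Optic-Chiasm_volume, kind: volume}
  - {name: Corpus-Callosum_volume, kind: volume}
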