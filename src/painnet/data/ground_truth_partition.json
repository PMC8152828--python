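{
  "description": "Four-module reference partition of the pain network: sensorimotor (SM), medial fronto-parietal (med-FP), lateral fronto-parietal (lat-FP) and amygdalo-hippocampal (limbic). A1 nodes appear only in the audio-augmented 36-node network and form their own auditory module for synthetic-data generation.",
  "partition": {
    "S2_left": "SM",
    "pI_left": "SM",
    "aI_left": "SM",
    "Foper_left": "SM",
    "S1_left": "SM",
    "SMA_left": "SM",
    "MCC_left": "SM",
    "pACC_left": "med-FP",
    "ACC_left": "med-FP",
    "dPCC_left": "med-FP",
    "vPCC_left": "med-FP",
    "Prec_left": "med-FP",
    "OFC_left": "med-FP",
    "PPC_left": "lat-FP",
    "DLPFC_left": "lat-FP",
    "Amyg_left": "limbic",
    "Hipp_left": "limbic",
    "A1_left": "auditory",
    "S2_right": "SM",
    "pI_right": "SM",
    "aI_right": "SM",
    "Foper_right": "SM",
    "S1_right": "SM",
    "SMA_right": "SM",
    "MCC_right": "SM",
    "pACC_right": "med-FP",
    "ACC_right": "med-FP",
    "dPCC_right": "med-FP",
    "vPCC_right": "med-FP",
    "Prec_right": "med-FP",
    "OFC_right": "med-FP",
    "PPC_right": "lat-FP",
    "DLPFC_right": "lat-FP",
    "Amyg_right": "limbic",
    "Hipp_right": "limbic",
    "A1_right": "auditory"
  }
}
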