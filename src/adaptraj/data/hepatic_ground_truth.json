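{
 "description": "Synthetic ground-truth fixture for the bundled hepatic model: a wild-type (phenotype A) parameter set designed to give a physiological steady state (all fluxes well below 100 mM/h), and the default fold perturbation producing the treated phenotype B.",
 "phenotype_A": {
  "parameters": {
   "k1": 1.25, "k2": 0.5, "k3": 0.35, "k4": 1.1, "k5": 2.4, "k6": 2.0,
   "k7": 0.4, "k8": 0.4, "k9": 0.4, "k10": 0.3, "k11": 0.32, "k12": 0.5,
   "k13": 0.2, "k14": 0.5, "k15": 0.05, "k16": 2.0, "k17": 0.5, "k18": 0.8,
   "k19": 0.4, "k20": 0.3, "k21": 0.2, "k22": 0.1
  },
  "inputs": {"FFA_plasma": 0.8}
 },
 "phenotype_B": {
  "fold_perturbation": {
   "k1": 1.5, "k2": 3.0, "k4": 2.0, "k6": 1.5, "k7": 1.5, "k8": 1.5,
   "k10": 0.7, "k11": 2.0, "k13": 1.5, "k14": 2.0, "k15": 0.8, "k16": 2.6,
   "k17": 2.5, "k18": 2.5, "k20": 1.5, "k21": 1.5
  },
  "inputs": {"FFA_plasma": 0.8}
 },
 "notes": "Perturbation directions follow pharmacological LXR activation: induced lipogenesis (k2), TG mobilization and VLDL secretion (k4, k6, k14), lipolysis and hepatic remnant re-uptake (k16, k17, k18), cholesterol synthesis/excretion and HDL fluxes (k7, k8, k20, k21), and a slight decrease in apoB particle production (k15)."
}
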