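"""A miniature power experiment: fixed- vs random-effect test.

Runs two small simulation cells (additive causality and epistatic
pleiotropy) at reduced scale and prints the power of each method at the
study-wide threshold.  Full-scale cells use 1,000 peaks; 150 keeps this
example under a minute.
"""

from recwas import ExperimentConfig, bonferroni_threshold, power_cell

thr = bonferroni_threshold(0.05, 5580)

cells = [
    ("additive causality",
     ExperimentConfig(architecture="additive", disease_model="causality",
                      n_causal=5, h2_cistrome=0.25, h2_pheno=0.15,
                      n_peaks=150, threshold=thr)),
    ("epistatic pleiotropy",
     ExperimentConfig(architecture="epistatic", disease_model="pleiotropy",
                      n_causal=2, h2_cistrome=0.08, h2_pheno=0.08,
                      n_peaks=150, threshold=thr)),
]

print(f"rejection threshold: {thr:.3e} (0.05 / 5580 peaks)")
for label, cfg in cells:
    res = power_cell(cfg, master_seed=42)
    print(f"{label:22s} fixed-effect power {res['power_cwas']:.2f}  "
          f"random-effect power {res['power_recwas']:.2f}  "
          f"(MC se ~{res['mc_se_cwas']:.02f}, n={res['n_peaks']} peaks)")
print()
print("Additive signals favor the fixed-effect test (the sparse trained")
print("direction is near-optimal); interaction signals with weak training")
print("favor the random-effect kernel test.")
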