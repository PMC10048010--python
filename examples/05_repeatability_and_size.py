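"""Digitization repeatability and centroid-size dimorphism.

A second digitization round (fresh per-landmark noise, re-projected onto
each specimen's geometry) emulates an operator re-measuring scans; the
Procrustes ANOVA splits total shape variance into among-specimen signal and
within-specimen measurement error.  The Welch t test on log centroid size
asks whether the sexes differ in tooth size.
"""

import numpy as np

import crownmorph as cm

spec = cm.DimorphismSpec(teeth=(cm.Tooth.FP,), n_f=15, n_m=15, seed=13)
cohort = cm.generate_cohort(spec)

round1 = cm.generalized_procrustes(cohort.configs_for(cm.Tooth.FP))
round2_cfgs = cm.generate_repeat_round(cohort, spec.digitization_sd, seed=99)
round2 = cm.generalized_procrustes(
    [round2_cfgs[s][cm.Tooth.FP] for s in cohort.specimen_ids]
)
rep = cm.repeatability(round1, round2)
print(f"measurement-error share of shape variance: "
      f"{100 * rep.error_variance_fraction:.2f}%")
print(f"intraclass-style agreement between rounds: {rep.agreement:.3f}")

labels = [cohort.labels()[s] for s in round1.specimen_ids]
t, p = cm.centroid_size_dimorphism_test(round1.centroid_sizes, labels)
sizes = np.asarray(round1.centroid_sizes)
f_mean = np.mean([s for s, l in zip(sizes, labels) if l == "F"])
m_mean = np.mean([s for s, l in zip(sizes, labels) if l == "M"])
print(f"centroid size: F mean {f_mean:.2f} mm, M mean {m_mean:.2f} mm, "
      f"Welch t = {t:.2f}, p = {p:.4g}")
# An error share of ~1% says digitization noise is negligible next to real
# among-specimen shape differences; p < 0.05 confirms size dimorphism.
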