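"""Aggregating association evidence across tumor cohorts.

Per-cohort p-values become 1-df chi-square z-scores, sum into a
groups-df statistic, and convert back to one signed z. The factor-of-20
confound filter and the two-of-three HRD activity flag are shown alongside.
"""

import pancansig as ps

evidence = [
    ps.CohortEvidence("Breast-DuctalCA", p=1e-6, direction=+1, significant=True),
    ps.CohortEvidence("Ovary-AdenoCA", p=0.003, direction=+1),
    ps.CohortEvidence("Uterus-AdenoCA", p=0.04, direction=+1, n_tests=3),
]
res = ps.combine_groups(evidence)
print(f"3 cohorts -> chi2 statistic {res.statistic:.2f} on {res.df} df")
print(f"aggregate p = {res.p:.2e}, signed single-df z = {res.z:+.2f}")

family = {"BRCA2": res.p, "BRCA1": res.p * 8, "TP53": res.p * 500}
kept = ps.confound_filter(family)
print(f"\nconfound filter keeps {sorted(kept)} of {sorted(family)} "
      "(within 20x of the family minimum)")

for acts in [(120, 40, 3), (120, 0, 0)]:
    print(f"SBS3={acts[0]}, ID6={acts[1]}, CN17={acts[2]} -> "
          f"HRD indicator {ps.hrd_flag(*acts)}")
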