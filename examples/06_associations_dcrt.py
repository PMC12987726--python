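"""Signature-activity association with dCRT significance.

A cohort is simulated in which treatment exposure adds one log-unit of
signature activity. The count-GLM arm estimates the effect; significance
comes from the distilled conditional randomization test (target resampled
from its covariate model 100 times) next to the logistic Wilks arm on the
binarized activity.
"""

import numpy as np

import pancansig as ps

rng = np.random.default_rng(14)
n = 400
covariates = ps.gen_covariates(n, seed=15)
Q = covariates.to_numpy()
treated = rng.binomial(1, 0.3, n).astype(float)
mu = np.exp(2.5 + 0.3 * Q[:, 0] + 1.0 * treated)   # true effect beta = 1
activity = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))

task = ps.AssociationTask(activity=activity, covariates=covariates,
                          target=treated, target_kind="binary_logistic",
                          n_resamples=100)
dcrt, logistic = ps.run_association(task, seed=16)
print(f"count-GLM ({dcrt.family_used}) effect beta = {dcrt.beta:.2f} "
      "(log activity per unit exposure; truth 1.0)")
print(f"dCRT p = {dcrt.p_dcrt:.2e}   (z_alt {dcrt.z_alt:.3f} vs "
      f"null z mean {dcrt.z_null.mean():.3f} +- {dcrt.z_null.std(ddof=1):.3f})")
print(f"logistic Wilks p = {logistic.p_wilks:.2e}, beta = {logistic.beta_logit:.2f}")

print("\nnull calibration (mock 2, heavy-tailed activities, 100 replicates):")
mc = ps.mock_calibration(2, n_reps=100, seed=17, n_samples=150)
print(f"  dCRT false-positive rate at 0.05: {mc.fpr_dcrt:.3f} "
      f"(KS-uniformity p = {mc.ks_p_dcrt:.2f})")
print(f"  naive NB Wilks false-positive rate: {mc.fpr_wilks:.3f} "
      f"(KS p = {mc.ks_p_wilks:.1e}) — the inflation the dCRT removes")
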