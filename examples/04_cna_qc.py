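"""Copy-number QC from VAF peaks, with purity re-estimation.

A diploid tumor is simulated at true purity 0.6 but handed to the QC with a
badly wrong initial purity estimate of 0.3. Attempt 1 fails the concordance
criterion (eta >= 5%); the VAF peaks invert to a corrected purity, and the
reprofiled attempt passes.
"""

import pancansig as ps

dataset = ps.gen_vaf_dataset(
    purity=0.6,
    segments=[dict(major=1, minor=1, n_snvs=3000)],
    depth=80, seed=5,
    purity_estimate=0.3,      # deliberately wrong initial estimate
    ploidy_estimate=2.0,
)
result = ps.run_qc_loop(dataset)
print(f"true purity 0.60, initial estimate 0.30")
print(f"passed: {result.passed} after {result.attempts} attempt(s)")
print(f"re-estimated purity rho_new = {result.rho_new:.3f}, eta = {result.eta:.4f}")
print("criteria:", {k: bool(v) for k, v in result.criteria.items()})
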