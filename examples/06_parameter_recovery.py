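"""Small parameter-recovery study: does the sampler find known truths?

Simulates panels from the NB-L hierarchy, refits the same family, and scores
bias / RMSE / 95%-interval coverage per parameter.  The identified block is
the slope and the mean-scale level; the raw intercept and theta are reported
but only their combination is pinned down by data.
"""

from nblcrash import McmcConfig
from nblcrash.recovery import recovery_study

study = recovery_study(
    "NB-L", n_reps=6, I=150, T=4,
    mcmc=McmcConfig(chains=2, iterations=4000, burn_in=1500, thin=5), seed=5)
print(study["scorecard"].round(3).to_string())
print("\n'level' = intercept + log E[mixing]: the identified location parameter.")
print("Expect slope and level covered in ~95% of replicates; raw intercept")
print("and theta trade off along the mixing-scale ridge and are not separately")
print("identified, so their raw-coordinate coverage is uninformative.")
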