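"""Test-retest reliability statistics on simulated scan/rescan pairs.

Subjects draw a latent parameter level (between-subject spread) and two
noisy measurements (within-subject spread).  ICC(1,1) measures how much
of the total variance is between subjects; wsCV measures repeatability
as a percentage of the mean.  Protocols are commonly accepted when
ICC > 0.85 and wsCV < 4%.
"""

from csdsi.metrics import trt_report
from csdsi.phantom import trt_replicates

for label, sw in (("low noise", 0.005), ("moderate", 0.02), ("high", 0.06)):
    ds = trt_replicates(mu=0.5, sigma_between=0.05, sigma_within=sw,
                        n_subjects=100, seed=3)
    rep = trt_report(ds.scan, ds.rescan)
    band = "PASS" if (rep.icc > 0.85 and rep.wscv < 4.0) else "fail"
    print(f"{label:9s}: ICC {rep.icc:5.3f} (truth {ds.true_icc:5.3f})  "
          f"wsCV {rep.wscv:5.2f}% (truth {ds.true_wscv:5.2f}%)  "
          f"band: {band}")
# Increasing within-subject noise degrades both statistics; only the
# low-noise regime clears the joint acceptance band.
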