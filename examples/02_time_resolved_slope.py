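"""Estimate the instantaneous aperiodic slope of known 1/f^x signals.

Single-cycle cosine/sine wavelet pairs give an instantaneous power estimate
at 2.5, 5, 7.5, 15 and 25 Hz; regressing log power on log frequency at every
sample (excluding the alpha-adjacent 7.5-15 Hz points) yields a slope time
course whose value estimates -x.
"""

import numpy as np

from aperislope import fit_slope_timecourse, synthesize_power_law_epochs, wavelet_power

FS = 512.0
rng = np.random.default_rng(0)

print("constant exponents (100 epochs each, mid-epoch average):")
for x in (1.0, 1.5, 2.0):
    sig = synthesize_power_law_epochs(x, FS, 1024, rng, size=100)
    power = wavelet_power(sig[:, None, :], fs=FS)
    series = fit_slope_timecourse(power, fs=FS)
    est = series.slope[:, :, 300:700].mean()
    print(f"  true x = {x:3.1f}  ->  fitted slope = {est:+.3f}  (target {-x:+.1f})")

# a step change in the exponent is tracked within the epoch
n = 1024
prof = np.where(np.arange(n) < n // 2, 1.0, 2.5)
sig = synthesize_power_law_epochs(prof, FS, n, rng, size=200)
power = wavelet_power(sig[:, None, :], fs=FS)
series = fit_slope_timecourse(power, fs=FS)
first = series.slope[:, :, 250:400].mean()
second = series.slope[:, :, 650:800].mean()
print("\ntime-varying exponent (step 1.0 -> 2.5 at mid-epoch, 200 epochs):")
print(f"  first-half slope  = {first:+.2f}   second-half slope = {second:+.2f}")
print("the estimator clearly tracks the within-epoch steepening (that is what")
print("makes time-resolved congruency analyses possible), though the step's")
print("full depth is attenuated: the 400-ms reach of the 2.5 Hz one-cycle")
print("kernel and the censored-power clamp both assume locally stationary")
print("power, and a hard mid-epoch step violates that harder than the")
print("smooth exponent dynamics the pipeline targets.")
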