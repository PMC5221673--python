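"""Evaluate a truncated log-parabola CSF and its summary statistics.

Builds a typical adult CSF (peak sensitivity 100, peak at 3 c/deg,
4-octave bandwidth, 0.5-logCS low-frequency plateau) and prints the curve
at chart frequencies plus the two standard summaries.
"""

from csfkit import CSFParams, aulcsf, evaluate_csf, high_sf_cutoff

params = CSFParams(peak_logcs=2.0, peak_sf=3.0, bandwidth_oct=4.0, truncation=0.5)

sfs = [1.5, 3.0, 6.0, 12.0, 18.0]
curve = evaluate_csf(params, sfs)
print("spatial frequency (c/deg) -> logCS")
for sf, v in zip(sfs, curve):
    print(f"  {sf:5.1f}  {v:6.3f}")

area = aulcsf(params, 1.5, 18.0)
cutoff = high_sf_cutoff(params)
print(f"AULCSF over 1.5-18 c/deg : {area:.4f}  (total log-visibility)")
print(f"high-SF cutoff           : {cutoff:.1f} c/deg  (threshold reaches 100% contrast)")
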