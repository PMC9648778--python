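"""Measure central-zone attenuation (AoHU) on a phantom scan.

The vessel mask is eroded to 50% of its equivalent radius; the mean and
SD of the remaining blood-pool pixels, per vertebral level, are the
AoHU statistics that drive dynamic thresholding.
"""

from aohu import PhantomParams, sample_scan, scan_zone_stats
from aohu.phantom import ScanMeta

params = PhantomParams(plaque_prevalence=0.0)
meta = ScanMeta("EX-00001", "EX", "arterial", "F", age=62, weight=71, rng_stream_id=4)
scan = sample_scan(params, meta)

print(f"generative scan mean: {scan.scan_mean_HU:.1f} HU (F, arterial)")
print("level  code  mean AoHU   SD AoHU   n px")
for st in scan_zone_stats(scan, fraction=0.5):
    print(f"{st.level:>5}  {st.level_code:>4}  {st.mean_AoHU:9.1f}  {st.sd_AoHU:8.1f}  {st.n_pixels:5d}")
# Reading: measured means track the generative slice means (the mild
# level-to-level drift is the configured vertebral trend), and SDs sit
# near the configured 30 HU within-scan noise.
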