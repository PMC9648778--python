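"""Segment plaque under uniform vs dynamic thresholds and score it.

A uniform 130 HU cutoff floods an arterial-phase vessel (blood pool
~326 HU) with false positives; the dynamic mean + 3.SD cutoff adapts to
each scan's own enhancement.
"""

from dataclasses import replace

from aohu import (
    PhantomParams,
    ThresholdScheme,
    agatston_score,
    sample_scan,
    scan_zone_stats,
    segment_plaque,
)
from aohu.phantom import ScanMeta

params = replace(PhantomParams(), plaque_prevalence=1.0, lesions_per_scan=(3, 3))
meta = ScanMeta("EX-00002", "EX", "arterial", "M", age=58, weight=85, rng_stream_id=9)
scan = sample_scan(params, meta)
stats = {st.level: st for st in scan_zone_stats(scan, fraction=0.5)}

truth_px = int(scan.plaque_truth_mask.sum())
print(f"ground-truth plaque pixels: {truth_px}")
for scheme in (ThresholdScheme("uniform", T=130),
               ThresholdScheme("uniform", T=550),
               ThresholdScheme("dynamic", N=3)):
    seg = segment_plaque(scan, scheme, stats, pixel_spacing_mm=params.pixel_spacing_mm)
    score = agatston_score(seg, params.pixel_spacing_mm, scan.meta.slice_thickness)
    desc = f"uniform {scheme.T:.0f} HU" if scheme.kind == "uniform" else f"dynamic {scheme.N:.0f} SD"
    tp = int((seg.plaque_mask & scan.plaque_truth_mask).sum())
    fp = int((seg.plaque_mask & ~scan.plaque_truth_mask).sum())
    print(f"{desc:>16}: {len(seg.lesions):3d} lesions, {tp:5d} true / {fp:5d} false pixels, "
          f"Agatston {score.total_score:8.1f}")
# Reading: at 130 HU nearly the whole enhanced blood pool is "plaque"
# (huge false-pixel count); the dynamic cutoff keeps false pixels near
# the 0.13% floor while retaining the bright lesion cores.
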