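# axonquant

Quantitative evaluation of peripheral-nerve axonal degeneration and
regeneration from 3-D fluorescence volumes of cleared tissue.

After a nerve is transected and surgically repaired, the distal axon
segments fragment into chains of ovoid debris (Wallerian degeneration) and
are gradually replaced by thin regenerating axons. Tissue clearing makes
whole rat sciatic nerves optically transparent, so confocal stacks capture
every axon in the volume — and the state of the nerve becomes measurable
from the *shapes* of its fluorescent segments. `axonquant` implements that
measurement for researchers studying nerve repair in rodent models, plus
the surrounding toolkit: a synthetic cleared-nerve generator with planted
ground truth, virtual cross-sectioning, depth/lateral intensity profiles,
and the sciatic functional index (SFI) from walking-track prints.

## The score

Each volume is sampled with 32 random regions of interest of
200 × 200 × 24 µm³. An ROI is collapsed to 2-D by summing 13 z-slices at
2 µm intervals, binarized (Otsu), and segmented into connected components.
A segment is classified **long** (intact or regenerating axon) iff,
strictly,

    eccentricity > 0.99   and   major axis > 200 px   and   filled area > 2000 px

where eccentricity and major axis come from the ellipse with matching
second central moments. Everything else is **short** (debris). The
**normalized length score** of the ROI is

    score = (pixels in long segments) / (pixels in all segments)

— 1.0 for a healthy nerve, falling toward its minimum around day 9
post-repair and recovering to ≈ 0.4–0.5 by day 12. The SFI module
implements the Bain–Mackinnon–Hunter formula

    SFI = -38.3·(EPL-NPL)/NPL + 109.5·(ETS-NTS)/NTS + 13.3·(EIT-NIT)/NIT - 8.8

over ≥ 3 consecutive prints (print length, toe spread, intermediary toe
spread; experimental vs normal side), with −100 ≈ complete transection.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
import axonquant as aq

config = aq.RunConfig(seed=0)                    # the published protocol defaults
for stage in ("baseline", "d12"):
    spec = aq.scene_for_stage(stage, seed=0)     # synthetic study conditions
    volume, truth = aq.generate_nerve_volume(spec)
    scores = aq.score_volume(volume, config, seed=0)
    values = [s.score for s in scores if s.valid]
    print(f"{stage:9s} planted fraction = {truth.planted_long_fraction:.3f}  "
          f"mean score = {np.mean(values):.3f}  (sd {np.std(values):.3f}, n {len(values)})")
```

prints

```
baseline  planted fraction = 1.000  mean score = 1.000  (sd 0.000, n 32)
d12       planted fraction = 0.455  mean score = 0.444  (sd 0.003, n 32)
```

The baseline volume contains only continuous field-spanning axons, so all
32 ROIs score exactly 1. The day-12 volume plants 45.5% of its labelled
voxels in thin regenerating axons and the rest in sub-threshold ovoid
debris; the pipeline recovers that composition from the images alone.
Further narrative scripts live in `examples/` (the five-stage time course,
virtual reslicing and attenuation-constant recovery, and an SFI recovery
trajectory rising to ≈ 60% of baseline function by week 12).

A thin CLI mirrors the library:

```sh
axonquant simulate --stage d12 --seed 0 --out out/
axonquant score out/nerve_d12.tif --seed 0 --out out/   # scores_per_roi.csv, scores_summary.csv
axonquant sfi prints.csv --out sfi.csv
```

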