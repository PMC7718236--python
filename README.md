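# spheroquant

Quantitative image analysis for multicellular tumor spheroid (MCTS)
experiments: spheroid size from bright-field images, radial
distribution of a fluorescent cell label across cryosections, and
Picro Sirius Red collagen scoring — together with the statistical
protocol that goes with them and a seeded synthetic-image generator
that provides ground truth for every stage.

## Who this is for

Labs using 3-D spheroid co-culture models (tumor cells plus
fibroblasts) read three things off their microscopy:

1. **Growth kinetics** — equivalent circular diameter
   `d = 2·s·√(A/π)` (s = pixel size, A = segmented area) of
   bright-field spheroids, summarized as mean ± SD per condition and
   day.
2. **Where the labeled cells sit** — a cryosection is decomposed into
   50 concentric rims of linearly decreasing diameter (rim 1 = center,
   rim 50 = boundary); the mean fluorescence intensity m_i of each rim
   is normalized to p_i = m_i / Σm_j, replicate sections aggregate to
   mean ± SD, and two conditions are compared rim by rim with Welch's
   t-test (raw p < 0.05 flags, Holm-adjusted p reported alongside).
   This answers questions like "did sequential seeding put the
   fibroblasts on the periphery?".
3. **How much collagen was deposited** — stained sections are
   inverted, the green channel extracted (fibers stain red → bright
   after inversion; cytoplasm yellow → dark), a rolling-ball
   background is subtracted, and the mean corrected intensity over the
   cryosection area is the collagen score.

No public image data accompany this kind of assay, so the package
ships a generator of synthetic sections with exact ground truth
(radial label density, collagen pixel fraction, true mask), and every
analysis guarantee is stated — and tested — as a recovery problem on
those images.

## Worked example

Compare the radial fibroblast distribution of two seeding protocols
(six simulated cryosections per group; `examples/03_radial_profiles.py`):

```python
from spheroquant import (SectionSpec, SpheroidMask, aggregate_profiles,
                         compare_profiles, compute_rims,
                         generate_fluorescence_section, radial_profile)

def build_group(label_mode, seeds):
    profiles = []
    for seed in seeds:
        spec = SectionSpec(seed=seed, label_mode=label_mode, n_clusters=500)
        image, truth = generate_fluorescence_section(spec)
        rims = compute_rims(SpheroidMask(truth.mask), n_rims=50)
        profiles.append(radial_profile(image, rims))
    return aggregate_profiles(profiles, label=label_mode)

sequential = build_group("peripheral", range(6))
simultaneous = build_group("central", range(10, 16))
table = compare_profiles(sequential, simultaneous, alpha=0.05).table
print(table.loc[table.rim >= 46, ["rim", "mean_A", "mean_B", "p_raw", "p_holm"]])
```

Output:

```
 rim  mean_A  mean_B  p_raw  p_holm
  46  0.0729  0.0046 0.0000  0.0000
  47  0.0717  0.0046 0.0000  0.0000
  48  0.0706  0.0046 0.0000  0.0000
  49  0.0691  0.0046 0.0000  0.0000
  50  0.0556  0.0046 0.0000  0.0000
```

Each row is one outer rim: the "sequential" group carries ~7 % of its
normalized fluorescence per outer rim versus ~0.5 % for the
"simultaneous" group — the labeled fibroblasts sit on the periphery,
and the difference is significant at every outer rim even after Holm
adjustment.

Collagen scoring works the same way (`examples/04_collagen_scoring.py`):
control sections at 10 % collagen fraction score 24.7 ± 0.2 and
treated sections at 25 % score 50.0 ± 0.2 (8-bit intensity units),
Welch p ≈ 1e-25.

The other examples cover the generator (`01`), growth kinetics from
bright-field images (`02`), and the end-to-end pipeline with its
bit-reproducible CSV outputs (`05`).

A thin CLI wraps the same functions for shell use:

```bash
spheroquant simulate --what stained --out out/sim
spheroquant segment out/sim/image.tif --out out/seg
spheroquant run experiment.yaml
```

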