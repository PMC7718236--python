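"""Compare the radial distribution of labeled fibroblasts in two groups.

Builds two groups of six fluorescent cryosections each — one with
peripherally enriched label, one with centrally concentrated label —
computes 50-rim normalized profiles, and tests each rim with Welch's t.
This is the analysis behind "is the dye significantly more peripheral
in condition A than in condition B?".
"""

import numpy as np

from spheroquant import (SectionSpec, SpheroidMask, aggregate_profiles,
                         compare_profiles, compute_rims,
                         generate_fluorescence_section, radial_profile)


def build_group(label_mode, seeds):
    profiles = []
    for seed in seeds:
        spec = SectionSpec(seed=seed, label_mode=label_mode, n_clusters=500)
        image, truth = generate_fluorescence_section(spec)
        mask = SpheroidMask(truth.mask)
        rim_map = compute_rims(mask, n_rims=50, mode="star_convex")
        profiles.append(radial_profile(image, rim_map))
    return aggregate_profiles(profiles, label=label_mode)


sequential = build_group("peripheral", range(6))     # fibroblasts added late
simultaneous = build_group("central", range(10, 16))  # fibroblasts in the core

comparison = compare_profiles(sequential, simultaneous, alpha=0.05)
table = comparison.table
outer = table[(table.rim >= 41) & table.significant]
print(f"rims significant at p < 0.05 (raw): {len(comparison.significant_rims)}")
print(f"  of which in the outer fifth (rims 41-50): {len(outer)}")
print("outer-rim group means (peripheral vs central):")
print(table.loc[table.rim >= 46, ["rim", "mean_A", "mean_B", "p_raw", "p_holm"]]
      .to_string(index=False, float_format="%.4f"))
# mean_A >> mean_B in the outer rims: the peripheral group carries
# significantly more normalized fluorescence near the boundary.
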