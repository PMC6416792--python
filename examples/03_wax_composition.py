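"""Cuticular wax composition statistics.

Simulates GC-derived wax profiles for the two species templates and
computes class coverages, the mole-based chain-length distribution, the
weighted median carbon chain length (MCL) and the <C40 / >=C40 partition
that separates ordinary aliphatics from very-long-chain alkyl esters.
"""

import cuticle as c

for template in ("colocynthis-like", "dactylifera-like"):
    profile = c.simulate_wax_profile(template, seed=1)
    coverage = c.class_coverage(profile)
    dist = c.mole_fractions(profile, vlc_only=True)
    overall = c.mcl(dist)
    split = c.split_chain_fractions(dist, cutoff=40)

    print(f"\n{template}:")
    print(f"  total coverage     : {coverage['total']:.1f} ug/cm^2")
    print(f"  MCL (interpolated) : {overall.interpolated_percentile:.1f} "
          f"(discrete {overall.eq_median})")
    print(f"  mol% >= C40        : {split['at_or_above']:.1f}")
    if split["mcl_at_or_above"] is not None:
        print(f"  MCL of ester part  : "
            f"{split['mcl_at_or_above'].interpolated_percentile:.1f}")

# An ester molecule of ~51 carbons can intercalate into two adjacent
# crystalline lamellae formed by ~31-carbon chains, bridging them; a wax
# with ~30 mol% of such esters melts later and resists thermal damage.
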