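"""Measure image-patch net water uptake on a synthetic head phantom.

Builds a noisy head CT with a known lesion water uptake of 18.2%, places
four mirrored 30x30 patch pairs inside the lesion, and recovers the uptake
from the density ratio 1 - D_ischemic / D_normal.
"""

from nwuct import PhantomSpec, generate_phantom, lesion_patch_specs, measure_ip_nwu

spec = PhantomSpec(
    image_shape=(6, 192, 192),
    water_uptake_w=0.182,   # true fractional uptake
    noise_sigma=2.0,        # HU noise
    lesion_slice_range=(0, 6),
    seed=7,
)
volume, truth = generate_phantom(spec)
specs = lesion_patch_specs(truth.lesion_mask, n_pairs=4)
result, maps = measure_ip_nwu(volume, specs)

print(f"true uptake w:        {truth.true_w:.3f}")
print(f"pooled IP-NWU:        {result.ip_nwu:.3f}")
print(f"per-pair NWU:         {[round(v, 3) for v in result.per_pair_nwu]}")
print(f"D_ischemic / D_normal: {result.d_ischemic:.2f} / {result.d_normal:.2f} HU")
print(f"map voxels clamped:   {maps.clamp_count} of 3600")
# The pooled estimate should sit within ~0.005 of the true uptake: the
# densitometric ratio inverts the (1 - w) attenuation model exactly, and
# averaging 3600 voxels suppresses the 2-HU scanner noise.
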