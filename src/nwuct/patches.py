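"""Mirrored-patch densitometry: the image-patch net water uptake (IP-NWU).

Net water uptake of ischemic tissue is inferred from CT hypoattenuation as

    NWU = 1 - D_ischemic / D_normal

where ``D_ischemic`` is the mean density (HU) of tissue in the infarcted MCA
territory and ``D_normal`` the mean density of the mirrored contralateral
tissue.  The patch variant measures both from four mirrored pairs of 30x30
voxel patches placed on reference slices, with no lesion segmentation.

Voxel-wise ratio maps pair each ischemic voxel with its mirror-image voxel
(the normal patch is column-flipped), yielding four 30x30 maps of per-voxel
NWU clamped to [0, 1] — the input to the histogram features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .volumes import CTVolume

__all__ = [
    "PatchSpec",
    "PatchPair",
    "NWUResult",
    "RatioMapSet",
    "PatchPlacementError",
    "DensitometryError",
    "AmbiguousPairError",
    "mirror_center",
    "extract_patch",
    "validate_patch",
    "classify_pair",
    "compute_ip_nwu",
    "compute_ratio_maps",
    "lesion_patch_specs",
    "extract_mirrored_pairs",
    "measure_ip_nwu",
]


class PatchPlacementError(ValueError):
    """A patch does not fit inside the volume."""


class DensitometryError(ValueError):
    """Non-physical densities (e.g. D_normal <= 0) make NWU undefined."""


class AmbiguousPairError(ValueError):
    """Equal-density pair with no declared ischemic side."""


@dataclass(frozen=True)
class PatchSpec:
    """Placement of one square patch: slice plus centre voxel coordinates.

    The patch covers the half-open window ``[centre - size/2, centre + size/2)``
    on each in-plane axis; the default edge length is 30 voxels.
    """

    slice_index: int
    center_row: int
    center_col: int
    size: int = 30

    def __post_init__(self) -> None:
        if self.size < 2 or self.size % 2 != 0:
            raise ValueError("patch size must be even and >= 2")

    @property
    def half(self) -> int:
        return self.size // 2

    def bounds(self) -> tuple[int, int, int, int]:
        h = self.half
        return (
            self.center_row - h,
            self.center_row + h,
            self.center_col - h,
            self.center_col + h,
        )

    def fits(self, volume_shape: tuple[int, int, int]) -> bool:
        ns, nr, nc = volume_shape
        r0, r1, c0, c1 = self.bounds()
        return 0 <= self.slice_index < ns and r0 >= 0 and c0 >= 0 and r1 <= nr and c1 <= nc


@dataclass(frozen=True)
class PatchPair:
    """A mirrored patch pair with its ischemic/normal designation.

    Both patches are stored in native (unflipped) orientation; voxel-wise
    mirror correspondence is ``ischemic[i, j] <-> normal[i, size-1-j]``.
    """

    left_patch: np.ndarray
    right_patch: np.ndarray
    ischemic_side: Literal["left", "right"]

    def __post_init__(self) -> None:
        lp = np.asarray(self.left_patch, dtype=np.float64)
        rp = np.asarray(self.right_patch, dtype=np.float64)
        if lp.shape != rp.shape:
            raise ValueError("patch pair shapes differ")
        object.__setattr__(self, "left_patch", lp)
        object.__setattr__(self, "right_patch", rp)

    @property
    def ischemic_patch(self) -> np.ndarray:
        return self.left_patch if self.ischemic_side == "left" else self.right_patch

    @property
    def normal_patch(self) -> np.ndarray:
        return self.right_patch if self.ischemic_side == "left" else self.left_patch

    @property
    def d_ischemic(self) -> float:
        return float(self.ischemic_patch.mean())

    @property
    def d_normal(self) -> float:
        return float(self.normal_patch.mean())

    @property
    def nwu(self) -> float:
        dn = self.d_normal
        if dn <= 0:
            raise DensitometryError("D_normal <= 0: non-physical parenchymal density")
        return 1.0 - self.d_ischemic / dn


@dataclass(frozen=True)
class NWUResult:
    ip_nwu: float
    per_pair_nwu: tuple[float, ...]
    pooling_mode: Literal["pooled", "per-pair-mean"]
    d_ischemic: float
    d_normal: float

    @property
    def per_pair_mean(self) -> float:
        return float(np.mean(self.per_pair_nwu))


@dataclass(frozen=True)
class RatioMapSet:
    """Per-voxel NWU maps for the patch pairs, clamped into [0, 1]."""

    maps: tuple[np.ndarray, ...]
    clamp_count: int
    excluded_count: int

    def values(self) -> np.ndarray:
        """All retained map elements as one flat vector (NaN = excluded)."""
        flat = np.concatenate([m.ravel() for m in self.maps])
        return flat[~np.isnan(flat)]

    @property
    def total_retained(self) -> int:
        return int(self.values().size)


# ---------------------------------------------------------------------------

def mirror_center(spec: PatchSpec, volume_shape: tuple[int, int, int]) -> PatchSpec:
    """Reflect a patch centre across the midsagittal (column-midline) plane.

    Same slice, same row; column ``c`` maps to ``n_cols - 1 - c``.  An
    involution: applying it twice returns the original spec.
    """
    ns, nr, nc = volume_shape
    if not spec.fits(volume_shape):
        raise PatchPlacementError(f"patch {spec} does not fit volume shape {volume_shape}")
    mirrored = replace(spec, center_col=(nc - 1) - spec.center_col)
    if not mirrored.fits(volume_shape):
        raise PatchPlacementError("mirrored patch extends outside the volume")
    return mirrored


def extract_patch(volume: CTVolume, spec: PatchSpec) -> np.ndarray:
    """Extract the HU patch covered by ``spec`` (copy, float64)."""
    if not spec.fits(volume.shape):
        raise PatchPlacementError(f"patch {spec} out of bounds for shape {volume.shape}")
    r0, r1, c0, c1 = spec.bounds()
    return volume.voxels[spec.slice_index, r0:r1, c0:c1].astype(np.float64).copy()


def validate_patch(
    patch: np.ndarray,
    csf_hu_threshold: float = 20.0,
    max_csf_fraction: float = 0.1,
    bone_hu_threshold: float = 100.0,
) -> dict:
    """Report-only check that a patch avoids CSF and bone.

    CSF in a patch lowers the apparent density and inflates NWU, so patches
    where more than ``max_csf_fraction`` of voxels fall below the CSF
    threshold are flagged; voxels above the bone threshold are counted too.
    """
    p = np.asarray(patch, dtype=np.float64)
    n = p.size
    csf_fraction = float((p < csf_hu_threshold).sum()) / n
    bone_fraction = float((p > bone_hu_threshold).sum()) / n
    return {
        "n_voxels": n,
        "csf_fraction": csf_fraction,
        "bone_fraction": bone_fraction,
        "csf_ok": csf_fraction <= max_csf_fraction,
        "bone_ok": bone_fraction == 0.0,
        "valid": csf_fraction <= max_csf_fraction and bone_fraction == 0.0,
    }


def classify_pair(
    left_patch: np.ndarray,
    right_patch: np.ndarray,
    declared_side: Optional[Literal["left", "right"]] = None,
    tol: float = 1e-9,
) -> PatchPair:
    """Designate the hypoattenuated (lower mean HU) side as ischemic.

    Equal means within ``tol`` fall back to ``declared_side``; with no
    declaration the pair is ambiguous and an error is raised.
    """
    lp = np.asarray(left_patch, dtype=np.float64)
    rp = np.asarray(right_patch, dtype=np.float64)
    if lp.shape != rp.shape:
        raise ValueError("patch shapes differ")
    lm, rm = float(lp.mean()), float(rp.mean())
    if abs(lm - rm) <= tol:
        if declared_side is None:
            raise AmbiguousPairError(
                "patch means are equal; declare the ischemic side explicitly"
            )
        side = declared_side
    else:
        side = "left" if lm < rm else "right"
    return PatchPair(left_patch=lp, right_patch=rp, ischemic_side=side)


def compute_ip_nwu(
    pairs: Sequence[PatchPair],
    pooling_mode: Literal["pooled", "per-pair-mean"] = "pooled",
) -> NWUResult:
    """Apply the NWU formula to a set of classified patch pairs.

    Pooled mode treats all ischemic voxels as one sample and all normal
    voxels as another (voxel-weighted means), then takes
    ``1 - D_ischemic / D_normal`` once; per-pair mode averages the four
    per-pair NWU values.  Both are returned; ``pooling_mode`` selects which
    one ``ip_nwu`` reports.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one patch pair")
    per_pair = tuple(p.nwu for p in pairs)  # raises DensitometryError if bad
    isch = np.concatenate([p.ischemic_patch.ravel() for p in pairs])
    norm = np.concatenate([p.normal_patch.ravel() for p in pairs])
    d_i, d_n = float(isch.mean()), float(norm.mean())
    if d_n <= 0:
        raise DensitometryError("pooled D_normal <= 0")
    pooled = 1.0 - d_i / d_n
    value = pooled if pooling_mode == "pooled" else float(np.mean(per_pair))
    return NWUResult(
        ip_nwu=value,
        per_pair_nwu=per_pair,
        pooling_mode=pooling_mode,
        d_ischemic=d_i,
        d_normal=d_n,
    )


def compute_ratio_maps(
    pairs: Sequence[PatchPair],
    denominator_floor: float = 1.0,
    map_value: Literal["nwu", "ratio"] = "nwu",
) -> RatioMapSet:
    """Voxel-wise NWU maps: each ischemic voxel against its mirror voxel.

    Element ``(i, j)`` of map ``m`` is ``1 - ischemic[i, j] / normal[i, j']``
    with ``j'`` the column-mirrored index.  Values are clamped into [0, 1]
    (and counted) rather than dropped, so the downstream histogram conserves
    its 3600 voxels; voxels whose denominator is at or below
    ``denominator_floor`` HU are excluded (set to NaN) and counted.
    ``map_value="ratio"`` stores the raw density ratio instead of the NWU.
    """
    maps = []
    clamped = 0
    excluded = 0
    for pair in pairs:
        isch = pair.ischemic_patch
        norm_mirrored = pair.normal_patch[:, ::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = isch / norm_mirrored
        bad = norm_mirrored <= denominator_floor
        values = ratio if map_value == "ratio" else 1.0 - ratio
        out_of_range = (~bad) & ((values < 0.0) | (values > 1.0))
        values = np.clip(values, 0.0, 1.0)
        values = np.where(bad, np.nan, values)
        clamped += int(out_of_range.sum())
        excluded += int(bad.sum())
        maps.append(values)
    result = RatioMapSet(maps=tuple(maps), clamp_count=clamped, excluded_count=excluded)
    if result.total_retained == 0:
        raise DensitometryError("all map voxels excluded (invalid denominators)")
    return result


# ---------------------------------------------------------------------------
# Convenience placement / measurement on phantoms and volumes
# ---------------------------------------------------------------------------

def lesion_patch_specs(
    lesion_mask: np.ndarray, n_pairs: int = 4, size: int = 30
) -> list[PatchSpec]:
    """Place ``n_pairs`` patches fully inside a lesion mask, one per slice.

    Slices are chosen closest to the lesion's slice-wise centre; within each
    slice the patch is centred on the lesion centroid.  This is the synthetic
    stand-in for expert placement from standard reference images.
    """
    mask = np.asarray(lesion_mask, dtype=bool)
    slice_counts = mask.reshape(mask.shape[0], -1).sum(axis=1)
    candidates = np.nonzero(slice_counts > 0)[0]
    if candidates.size < n_pairs:
        raise PatchPlacementError(
            f"lesion spans {candidates.size} slices; need {n_pairs}"
        )
    centre = float(np.average(candidates, weights=slice_counts[candidates]))
    order = candidates[np.argsort(np.abs(candidates - centre), kind="stable")]
    specs: list[PatchSpec] = []
    h = size // 2
    for s in order:
        rr, cc = np.nonzero(mask[s])
        r0, c0 = int(round(rr.mean())), int(round(cc.mean()))
        window = mask[s, r0 - h : r0 + h, c0 - h : c0 + h]
        if window.shape == (size, size) and window.all():
            specs.append(PatchSpec(slice_index=int(s), center_row=r0, center_col=c0, size=size))
        if len(specs) == n_pairs:
            break
    if len(specs) < n_pairs:
        raise PatchPlacementError("could not fit the requested patches inside the lesion")
    return sorted(specs, key=lambda sp: sp.slice_index)


def extract_mirrored_pairs(
    volume: CTVolume,
    specs: Sequence[PatchSpec],
    declared_side: Optional[Literal["left", "right"]] = None,
) -> list[PatchPair]:
    """Extract each spec'd patch plus its mirror and classify the pair.

    ``declared_side`` names the ischemic side of the *pair* (used only to
    break exact density ties); each spec may sit on either hemisphere.
    """
    pairs = []
    for spec in specs:
        mspec = mirror_center(spec, volume.shape)
        a = extract_patch(volume, spec)
        b = extract_patch(volume, mspec)
        nc = volume.shape[2]
        # order the two patches as (left, right) by column position
        if spec.center_col <= (nc - 1) - spec.center_col:
            left, right = a, b
        else:
            left, right = b, a
        pairs.append(classify_pair(left, right, declared_side=declared_side))
    return pairs


def measure_ip_nwu(
    volume: CTVolume,
    specs: Sequence[PatchSpec],
    pooling_mode: Literal["pooled", "per-pair-mean"] = "pooled",
    declared_side: Optional[Literal["left", "right"]] = None,
) -> tuple[NWUResult, RatioMapSet]:
    """Full patch pipeline: extract, mirror, classify, NWU and ratio maps."""
    pairs = extract_mirrored_pairs(volume, specs, declared_side=declared_side)
    return compute_ip_nwu(pairs, pooling_mode=pooling_mode), compute_ratio_maps(pairs)
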