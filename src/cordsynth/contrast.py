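"""Lesion-appearance statistics and the truncated-normal contrast model.

The defining feature of a hyperintense cord lesion is its contrast with
the surrounding normal-appearing tissue,

    C_p = (mean_{M_p} I − mean_{M_p*} I) / mean_{M_p*} I ,

where M_p is the lesion mask and M_p* its neighbourhood: the lesion mask
dilated by a 5-voxel disc within each sagittal slice, minus the lesion,
restricted to the cord mask eroded by a 1-voxel disc (to keep bright CSF
out of the neighbourhood). Observed contrasts across a training set are
summarised by a truncated normal psi(mu_bar, sigma_bar, a, b): mean,
standard deviation, lower truncation at the 20th percentile (to avoid
sampling very low or negative contrasts), upper truncation fixed at 1.0.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .grid import LabelMask, VolumeGrid, check_same_grid
from .morphology import dilate_sagittal, erode_sagittal

__all__ = [
    "ContrastParams",
    "RadialProfile",
    "neighbourhood_mask",
    "lesion_contrast",
    "fit_contrast_distribution",
    "sample_contrast",
    "radial_intensity_profile",
    "within_mask_sd",
]


@dataclass
class ContrastParams:
    """Truncated-normal contrast model psi(mu_bar, sigma_bar, a, b)."""

    mu_bar: float
    sigma_bar: float
    a: float
    b: float = 1.0
    n_lesions: int = 1
    contrasts: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError(f"require a < b, got a={self.a}, b={self.b}")
        if self.sigma_bar < 0:
            raise ValueError("sigma_bar must be non-negative")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")

    def save(self, path: str | os.PathLike) -> None:
        payload = {"mu_bar": self.mu_bar, "sigma_bar": self.sigma_bar,
                   "a": self.a, "b": self.b, "n_lesions": self.n_lesions,
                   "contrasts": list(self.contrasts)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ContrastParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class RadialProfile:
    """Mean lesion intensity vs distance (mm) from the lesion centroid.

    Distances are rounded to the nearest 0.5 mm; the standard error is
    taken across all pooled voxels in each bin.
    """

    bin_centres: np.ndarray
    mean_intensity: np.ndarray
    standard_error: np.ndarray
    voxel_counts: np.ndarray


def neighbourhood_mask(lesion: LabelMask, cord: LabelMask,
                       dilation_radius_vox: int = 5,
                       cord_erosion_radius_vox: int = 1) -> LabelMask:
    """Neighbourhood M_p* of a lesion: in-sagittal-slice dilated shell
    clipped to the eroded cord.

    Dilation and erosion act within sagittal planes only because the
    in-plane spacing of the source acquisitions is much smaller than the
    slice spacing. An empty result is returned with a ``warning`` flag set
    (downstream contrast is undefined on it).
    """
    check_same_grid(lesion, cord)
    if lesion.is_empty():
        raise ValueError("lesion mask is empty")
    shell = dilate_sagittal(lesion.data, dilation_radius_vox) & ~lesion.data
    eroded = erode_sagittal(cord.data, cord_erosion_radius_vox)
    out = LabelMask(shell & eroded, lesion.spacing)
    if out.is_empty():
        out.warning = "empty neighbourhood: lesion exhausts the eroded cord"
        warnings.warn(out.warning, stacklevel=2)
    return out


def lesion_contrast(volume: VolumeGrid, lesion: LabelMask,
                    neighbourhood: LabelMask) -> float:
    """Contrast ratio C_p; positive for hyperintense lesions."""
    check_same_grid(volume, lesion)
    check_same_grid(volume, neighbourhood)
    if lesion.is_empty() or neighbourhood.is_empty():
        raise ValueError("lesion and neighbourhood must be non-empty")
    if np.any(lesion.data & neighbourhood.data):
        raise ValueError("lesion and neighbourhood masks overlap")
    mean_lesion = float(volume.data[lesion.data].mean())
    mean_neigh = float(volume.data[neighbourhood.data].mean())
    if mean_neigh == 0:
        raise ValueError("mean neighbourhood intensity is zero")
    return (mean_lesion - mean_neigh) / mean_neigh


def fit_contrast_distribution(contrasts) -> ContrastParams:
    """Fit psi from observed contrasts: sample mean, sample SD, 20th
    percentile (linear interpolation) as the lower bound, b = 1.0."""
    values = np.asarray(list(contrasts), dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 contrast values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    a = float(np.percentile(values, 20))
    return ContrastParams(mu_bar=mu, sigma_bar=sigma, a=a, b=1.0,
                          n_lesions=int(values.size),
                          contrasts=values.tolist())


def sample_contrast(params: ContrastParams, rng: np.random.Generator,
                    size: int | None = None) -> float | np.ndarray:
    """Draw c ~ Normal(mu_bar, sigma_bar) truncated to [a, b].

    Sampling is by inverse CDF on a uniform stream from ``rng``, so draws
    are exact (no rejection loop) and reproducible. A degenerate model
    (sigma_bar = 0) returns mu_bar clamped to [a, b].
    """
    if params.sigma_bar == 0:
        c = float(np.clip(params.mu_bar, params.a, params.b))
        if size is None:
            # still consume one uniform so call sequences stay aligned
            rng.uniform()
            return c
        rng.uniform(size=size)
        return np.full(size, c)
    alpha = (params.a - params.mu_bar) / params.sigma_bar
    beta = (params.b - params.mu_bar) / params.sigma_bar
    fa, fb = ndtr(alpha), ndtr(beta)
    u = rng.uniform(size=size)
    c = params.mu_bar + params.sigma_bar * ndtri(fa + u * (fb - fa))
    c = np.clip(c, params.a, params.b)  # guard fp round-off at the bounds
    return float(c) if size is None else c


def radial_intensity_profile(volume: VolumeGrid, lesions,
                             standardise: bool = False) -> RadialProfile:
    """Pool lesion voxels and bin mean intensity by distance from each
    lesion's centroid (bins at multiples of 0.5 mm).

    ``standardise`` optionally z-scores the volume first, for pooling
    profiles across volumes with different intensity scales.
    """
    lesions = list(lesions)
    if not lesions or all(m.is_empty() for m in lesions):
        raise ValueError("need at least one non-empty lesion")
    data = volume.data
    if standardise:
        data = (data - data.mean()) / data.std(ddof=0)
    spacing = np.asarray(volume.spacing)
    dists, vals = [], []
    for mask in lesions:
        if mask.is_empty():
            continue
        check_same_grid(volume, mask)
        coords = np.argwhere(mask.data).astype(np.float64)
        centroid = coords.mean(axis=0)
        d_mm = np.sqrt((((coords - centroid) * spacing) ** 2).sum(axis=1))
        dists.append(d_mm)
        vals.append(data[mask.data])
    d = np.concatenate(dists)
    v = np.concatenate(vals)
    bin_idx = np.rint(d / 0.5).astype(int)
    uniq = np.unique(bin_idx)
    means = np.array([v[bin_idx == u].mean() for u in uniq])
    ses = np.array([
        v[bin_idx == u].std(ddof=1) / np.sqrt((bin_idx == u).sum())
        if (bin_idx == u).sum() > 1 else 0.0
        for u in uniq
    ])
    counts = np.array([(bin_idx == u).sum() for u in uniq])
    return RadialProfile(uniq * 0.5, means, ses, counts)


def within_mask_sd(volume: VolumeGrid, mask: LabelMask) -> float:
    """Sample standard deviation of intensities over a mask (|mask| >= 2)."""
    check_same_grid(volume, mask)
    if mask.count() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    return float(volume.data[mask.data].std(ddof=1))
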