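"""PET voxel signal -> regional amyloid deposition probabilities.

Instead of thresholding SUVR-like values directly, each voxel is scored by an
extreme-value bootstrap of the reference region: the reference voxels are
trimmed to their 5-95% band, resampled with replacement 40 000 times, and the
per-sample extreme statistic (the maximum for a cerebellar-cortex reference,
the 75th percentile for the hotter brainstem reference) forms an extreme value
distribution (EVD).  A voxel's deposition probability is the fraction of EVD
entries it strictly exceeds — the empirical extreme CDF — and a region's
probability is the mean over its voxels.  The metric is invariant to common
increasing affine rescaling of image and reference, and a voxel drawn from
the reference distribution itself rarely beats the extremes, which is what
makes it a specificity filter.

For cohorts with a reliable amyloid-negative control group, regional
probabilities can additionally be re-expressed relative to the controls:
per-region z-scores against the pooled control distribution, absolute value,
then min-max scaled back to [0, 1] across all carrier observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ExtremeStatistic",
    "VoxelImage",
    "EVDistribution",
    "RegionalAmyloidMatrix",
    "build_evd",
    "voxel_probability",
    "roi_probabilities",
    "control_reference_rescale",
    "load_voxel_image",
]


class ExtremeStatistic(str, Enum):
    """Bootstrap extreme statistic: per-sample maximum, or 75th percentile
    (used with high-signal reference regions such as the brainstem)."""

    MAX = "max"
    PERCENTILE75 = "percentile75"


@dataclass
class VoxelImage:
    """A registered PET volume with matching atlas labels.

    ``values`` and ``voxel_labels`` share one shape; label 0 is background
    and every other label code must appear in ``label_map``.
    """

    values: np.ndarray
    voxel_labels: np.ndarray
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_labels = np.asarray(self.voxel_labels, dtype=int)
        if self.values.shape != self.voxel_labels.shape:
            raise ValueError("values and voxel_labels must share a shape")
        present = set(np.unique(self.voxel_labels).tolist()) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_map")

    def region_values(self, label: int) -> np.ndarray:
        return self.values[self.voxel_labels == label]


@dataclass
class EVDistribution:
    """Sorted bootstrap extreme statistics of a reference region."""

    extremes: np.ndarray
    statistic: ExtremeStatistic
    trim_bounds: tuple[float, float] = (5.0, 95.0)
    n_boot: int = 40_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.extremes = np.sort(np.asarray(self.extremes, dtype=float))
        if self.extremes.size != self.n_boot:
            raise ValueError("extremes length must equal n_boot")


@dataclass
class RegionalAmyloidMatrix:
    """Subjects x regions deposition probabilities in [0, 1]."""

    values: np.ndarray
    subject_ids: list[str]
    region_labels: list[str]
    timepoints: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        ns, nr = self.values.shape
        if len(self.subject_ids) != ns or len(self.region_labels) != nr:
            raise ValueError("ids/labels must match the value matrix shape")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("deposition probabilities must lie in [0, 1]")
        if self.timepoints is not None and len(self.timepoints) != ns:
            raise ValueError("timepoints must align with subjects")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.region_labels
        )
        df.insert(0, "subject_id", self.subject_ids)
        if self.timepoints is not None:
            df.insert(1, "timepoint", self.timepoints)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionalAmyloidMatrix":
        meta = [c for c in ("subject_id", "timepoint") if c in df.columns]
        regions = [c for c in df.columns if c not in meta]
        return cls(
            values=df[regions].to_numpy(dtype=float),
            subject_ids=[str(s) for s in df["subject_id"]]
            if "subject_id" in df
            else [f"sub-{i:04d}" for i in range(len(df))],
            region_labels=regions,
            timepoints=list(df["timepoint"]) if "timepoint" in df else None,
        )

    def write_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str) -> "RegionalAmyloidMatrix":
        return cls.from_dataframe(pd.read_csv(path))


def build_evd(
    reference_values: np.ndarray,
    statistic: ExtremeStatistic | str = ExtremeStatistic.MAX,
    n_boot: int = 40_000,
    trim_bounds: tuple[float, float] = (5.0, 95.0),
    subsample_size: int | None = None,
    seed: int = 0,
) -> EVDistribution:
    """Bootstrap the reference region's extreme statistic.

    Values outside the [lo, hi] percentile band are excluded; each of the
    ``n_boot`` subsamples draws ``subsample_size`` retained values with
    replacement (default: as many as were retained) and contributes one
    extreme statistic.  Deterministic given ``seed``.
    """
    statistic = ExtremeStatistic(statistic)
    ref = np.asarray(reference_values, dtype=float).ravel()
    if ref.size == 0:
        raise ValueError("reference region is empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    lo, hi = np.percentile(ref, trim_bounds)
    kept = ref[(ref >= lo) & (ref <= hi)]
    if kept.size == 0:
        raise ValueError("no reference values survive percentile trimming")
    m = int(subsample_size) if subsample_size else kept.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, kept.size, size=(n_boot, m))
    samples = kept[idx]
    if statistic is ExtremeStatistic.MAX:
        extremes = samples.max(axis=1)
    else:
        extremes = np.percentile(samples, 75.0, axis=1)
    return EVDistribution(
        extremes=extremes,
        statistic=statistic,
        trim_bounds=tuple(trim_bounds),
        n_boot=n_boot,
        seed=seed,
    )


def voxel_probability(value, evd: EVDistribution):
    """Probability of exceeding the reference extremes: the fraction of EVD
    entries strictly below ``value`` (ties count as not exceeded).

    Vectorized over ``value``; monotone non-decreasing; in [0, 1].
    """
    counts = np.searchsorted(evd.extremes, np.asarray(value, dtype=float), side="left")
    out = counts / evd.n_boot
    return float(out) if np.isscalar(value) else out


def roi_probabilities(
    image: VoxelImage,
    evd: EVDistribution,
    region_order: list[str] | None = None,
) -> pd.Series:
    """Mean voxel exceedance probability per region.

    Regions without voxels are reported as NaN, never as zero.  When
    ``region_order`` is given it must match the label map's region names and
    fixes the output ordering (to align with a connectome).
    """
    names = {code: name for code, name in image.label_map.items()}
    if region_order is not None:
        known = set(names.values())
        unknown = [r for r in region_order if r not in known]
        if unknown:
            raise KeyError(f"regions {unknown} not present in the atlas label map")
    probs = {}
    for code, name in names.items():
        vox = image.region_values(code)
        probs[name] = (
            float(np.mean(voxel_probability(vox, evd))) if vox.size else np.nan
        )
    order = region_order if region_order is not None else list(names.values())
    return pd.Series([probs[r] for r in order], index=order, name="probability")


def control_reference_rescale(
    carriers: RegionalAmyloidMatrix,
    controls: RegionalAmyloidMatrix,
) -> RegionalAmyloidMatrix:
    """Re-express carrier probabilities relative to an amyloid-negative
    control group.

    Per region: z = (x - mean_ctrl) / sd_ctrl for every carrier observation
    (controls pooled over timepoints), then |z| is min-max scaled to [0, 1]
    jointly across all carrier rows/timepoints of that region.  A region with
    zero control variance indicates a degenerate control set and raises.
    """
    if carriers.region_labels != controls.region_labels:
        raise ValueError("carrier and control region labels must match")
    if controls.values.shape[0] < 2:
        raise ValueError("need at least 2 control observations per region")
    mu = controls.values.mean(axis=0)
    sd = controls.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            "zero control variance in region(s): "
            + ", ".join(carriers.region_labels[i] for i in zero)
        )
    z = np.abs((carriers.values - mu) / sd)
    zmin = z.min(axis=0)
    zmax = z.max(axis=0)
    span = zmax - zmin
    scaled = np.where(span > 0, (z - zmin) / np.where(span > 0, span, 1.0), 0.0)
    return RegionalAmyloidMatrix(
        values=scaled,
        subject_ids=carriers.subject_ids,
        region_labels=carriers.region_labels,
        timepoints=carriers.timepoints,
    )


def load_voxel_image(
    pet_path: str,
    atlas_path: str,
    label_map: dict[int, str],
) -> VoxelImage:
    """Load a registered PET volume and its atlas label volume from NIfTI."""
    import nibabel as nib

    pet = np.asanyarray(nib.load(pet_path).dataobj, dtype=float)
    atlas = np.asanyarray(nib.load(atlas_path).dataobj).astype(int)
    return VoxelImage(values=pet, voxel_labels=atlas, label_map=label_map)
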