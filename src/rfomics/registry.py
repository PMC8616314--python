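"""Canonical radiomics feature registry.

The default registry enumerates the 109 features of the standard
radiomics feature dictionary, grouped into seven classes: first-order
intensity statistics (19), 3-D shape descriptors (15), and five texture
families — GLCM (24), GLSZM (16), GLRLM (16), NGTDM (5), GLDM (14).
Feature names follow the ``<class>.<FeatureName>`` dialect of the
reference extractor (e.g. ``firstorder.Maximum``, ``shape.Flatness``),
so CSV tables produced by common extraction toolkits map onto the
registry directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FEATURE_CLASSES = ("firstorder", "shape", "glcm", "glszm", "glrlm", "ngtdm", "gldm")

_FIRSTORDER = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "StandardDeviation", "TotalEnergy", "Uniformity", "Variance",
]

_SHAPE = [
    "Compactness2", "Elongation", "Flatness", "LeastAxisLength",
    "MajorAxisLength", "Maximum2DDiameterColumn", "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice", "Maximum3DDiameter", "MeshVolume",
    "MinorAxisLength", "Sphericity", "SurfaceArea", "SurfaceVolumeRatio",
    "VoxelVolume",
]

_GLCM = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]

_GLSZM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

_GLRLM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

_NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

_GLDM = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

_DEFAULT_ENTRIES = [
    *(("firstorder", n) for n in _FIRSTORDER),
    *(("shape", n) for n in _SHAPE),
    *(("glcm", n) for n in _GLCM),
    *(("glszm", n) for n in _GLSZM),
    *(("glrlm", n) for n in _GLRLM),
    *(("ngtdm", n) for n in _NGTDM),
    *(("gldm", n) for n in _GLDM),
]


@dataclass(frozen=True)
class FeatureRegistry:
    """An ordered list of (feature_class, feature_name) entries.

    The default registry has class cardinalities 19, 15, 24, 16, 16, 5
    and 14 (109 entries total).
    """

    entries: tuple = field(default_factory=lambda: tuple(_DEFAULT_ENTRIES))

    def __post_init__(self) -> None:
        seen = set()
        for cls, name in self.entries:
            if cls not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {cls!r}")
            if (cls, name) in seen:
                raise ValueError(f"duplicate registry entry ({cls!r}, {name!r})")
            seen.add((cls, name))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_names(self) -> list[str]:
        """Qualified names in registry order: ``<class>.<FeatureName>``."""
        return [f"{cls}.{name}" for cls, name in self.entries]

    def class_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in FEATURE_CLASSES}
        for cls, _ in self.entries:
            counts[cls] += 1
        return counts


def default_registry() -> FeatureRegistry:
    """The 109-feature default registry."""
    return FeatureRegistry()
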