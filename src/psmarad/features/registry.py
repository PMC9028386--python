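"""The documented feature battery.

Keys are namespaced by family. Every extraction returns exactly these keys;
features that are undefined on a given ROI (e.g. skewness of a constant
region) carry ``None`` rather than silently disappearing or propagating
NaN.
"""

from __future__ import annotations

FAMILIES: dict[str, tuple[str, ...]] = {
    "stat": (
        "mean",
        "variance",
        "skewness",
        "kurtosis",
        "median",
        "minimum",
        "p10",
        "p25",
        "p75",
        "p90",
        "maximum",
        "range",
        "interquartile_range",
        "energy",
        "root_mean_square",
        "mean_absolute_deviation",
        "entropy",
        "uniformity",
        "discretized_p90",
    ),
    "ivh": (
        "v10",
        "v90",
        "v10_minus_v90",
        "i10",
        "i90",
        "i10_minus_i90",
    ),
    "morph": (
        "volume",
        "surface_area",
        "surface_to_volume_ratio",
        "sphericity",
        "compactness",
        "flatness",
        "elongation",
        "inverse_elongation",
        "area_density_aabb",
        "volume_density_aabb",
    ),
    "glcm": (
        "joint_maximum",
        "joint_average",
        "joint_entropy",
        "angular_second_moment",
        "contrast",
        "dissimilarity",
        "inverse_difference",
        "normalized_inverse_difference",
        "inverse_difference_moment",
        "correlation",
        "information_correlation_1",
        "information_correlation_2",
        "cluster_shade",
        "cluster_prominence",
    ),
    "glrlm": (
        "short_run_emphasis",
        "long_run_emphasis",
        "low_grey_level_run_emphasis",
        "high_grey_level_run_emphasis",
        "grey_level_non_uniformity",
        "run_length_non_uniformity",
        "run_percentage",
        "run_entropy",
    ),
    "glszm": (
        "small_zone_emphasis",
        "large_zone_emphasis",
        "low_grey_level_zone_emphasis",
        "high_grey_level_zone_emphasis",
        "small_zone_low_grey_level_emphasis",
        "large_zone_low_grey_level_emphasis",
        "large_zone_high_grey_level_emphasis",
        "zone_size_non_uniformity",
        "grey_level_non_uniformity",
        "zone_percentage",
        "zone_entropy",
    ),
    "gldzm": (
        "small_distance_emphasis",
        "large_distance_emphasis",
        "low_grey_level_emphasis",
        "high_grey_level_emphasis",
        "zone_distance_non_uniformity",
        "zone_distance_percentage",
        "zone_distance_entropy",
    ),
}


def family_keys(family: str) -> tuple[str, ...]:
    return tuple(f"{family}.{name}" for name in FAMILIES[family])


#: the full, ordered battery
ALL_FEATURES: tuple[str, ...] = tuple(k for fam in FAMILIES for k in family_keys(fam))
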