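"""Synthetic benchmarks with known ground truth.

Two generators:

* :func:`generate_planted_images` — noise-background grayscale images with
  small planted black squares whose positions identify the class.  Because
  the informative pixels are known by construction, feature-selection recall
  and precision can be scored exactly.
* :func:`generate_planted_tabular` — an expression-like numeric table with a
  recorded set of informative columns carrying class-dependent mean shifts on
  a Gaussian background.

Image geometry (0-based, row-major, origin top-left):

* the "upper-left" square is anchored at (4, 4), the "lower-left" square at
  (H−8, 4) and the optional shared right-side square at (H//2, W−8);
* each planted square (except the shared one, which is fixed) is displaced
  from its anchor by exactly ``offset`` pixels in one of the four axis
  directions, chosen uniformly per image per square;
* "black" means intensity 0; the background is i.i.d. uniform integers on
  [intensity_low, intensity_high] inclusive.

Class semantics: with four classes, class 0 has no square, class 1 the
upper-left square, class 2 the lower-left square, class 3 both; with two
classes, class 1 has the upper-left square.  The ``truth_mask`` marks every
pixel that any planted square can ever cover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, LabelVector

__all__ = [
    "PlantedImageDataset",
    "PlantedTabularDataset",
    "generate_planted_images",
    "flatten_images",
    "generate_planted_tabular",
    "save_images_png",
]

_DIRECTIONS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)])


@dataclass
class PlantedImageDataset:
    images: np.ndarray  # n × H × W integer intensities
    labels: LabelVector
    truth_mask: np.ndarray  # H × W bool

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]


@dataclass
class PlantedTabularDataset:
    matrix: ExpressionMatrix
    labels: LabelVector
    informative_features: set


def _anchors(height: int, width: int) -> dict[str, tuple[int, int]]:
    return {
        "upper_left": (4, 4),
        "lower_left": (height - 8, 4),
        "common_right": (height // 2, width - 8),
    }


def _class_points(n_classes: int) -> dict[int, list[str]]:
    if n_classes == 2:
        return {0: [], 1: ["upper_left"]}
    if n_classes == 4:
        return {0: [], 1: ["upper_left"], 2: ["lower_left"], 3: ["upper_left", "lower_left"]}
    raise ValueError("ratios must describe 2 or 4 classes")


def _check_in_frame(anchor: tuple[int, int], point_size: int, offset: int, height: int, width: int) -> None:
    r, c = anchor
    if r - offset < 0 or c - offset < 0 or r + offset + point_size > height or c + offset + point_size > width:
        raise ValueError(
            f"point of size {point_size} at anchor {anchor} with offset {offset} "
            f"does not fit in a {height}×{width} frame"
        )


def generate_planted_images(
    n_total: int = 400,
    ratios: Sequence[int] = (26, 3, 7, 4),
    height: int = 112,
    width: int = 92,
    point_size: int = 4,
    offset: int = 3,
    intensity_low: int = 0,
    intensity_high: int = 244,
    common_point: bool = False,
    seed: int = 0,
) -> PlantedImageDataset:
    """Noise images with class-identifying planted black squares.

    ``ratios`` are exact per-class proportions; their sum must divide
    ``n_total`` so class counts honor the ratios with no rounding.  With
    ``common_point=True`` classes 1 and 2 additionally carry a fixed square in
    the middle of the right side, shared between them.
    """
    ratios = [int(r) for r in ratios]
    if any(r < 1 for r in ratios):
        raise ValueError("all ratios must be ≥ 1")
    total_ratio = sum(ratios)
    if n_total % total_ratio != 0:
        raise ValueError(f"sum of ratios {total_ratio} must divide n_total {n_total}")
    unit = n_total // total_ratio
    counts = [r * unit for r in ratios]
    points = _class_points(len(ratios))
    anchors = _anchors(height, width)

    used = sorted({p for plist in points.values() for p in plist})
    if common_point:
        used.append("common_right")
    for name in used:
        _check_in_frame(anchors[name], point_size, offset, height, width)

    rng = np.random.default_rng(seed)
    images = np.empty((n_total, height, width), dtype=np.int64)
    labels = []
    truth_mask = np.zeros((height, width), dtype=bool)

    # the mask is the exact union of achievable square positions
    for name in used:
        r0, c0 = anchors[name]
        displacements = [(0, 0)] if name == "common_right" or offset == 0 else [
            (dr * offset, dc * offset) for dr, dc in _DIRECTIONS
        ]
        for dr, dc in displacements:
            truth_mask[r0 + dr : r0 + dr + point_size, c0 + dc : c0 + dc + point_size] = True

    i = 0
    for cls, count in enumerate(counts):
        for _ in range(count):
            img = rng.integers(intensity_low, intensity_high + 1, size=(height, width))
            for name in points[cls]:
                r0, c0 = anchors[name]
                if offset > 0:
                    dr, dc = _DIRECTIONS[rng.integers(4)] * offset
                else:
                    dr, dc = 0, 0
                img[r0 + dr : r0 + dr + point_size, c0 + dc : c0 + dc + point_size] = 0
            if common_point and cls in (1, 2):
                r0, c0 = anchors["common_right"]
                img[r0 : r0 + point_size, c0 : c0 + point_size] = 0
            images[i] = img
            labels.append(cls)
            i += 1

    return PlantedImageDataset(
        images=images,
        labels=LabelVector.from_labels(labels, class_set=list(range(len(ratios)))),
        truth_mask=truth_mask,
    )


def flatten_images(ds: PlantedImageDataset):
    """Flatten to (ExpressionMatrix, LabelVector, truth feature names).

    Pixels become features named ``px_r{row}_c{col}`` in row-major order;
    the truth set is the names of ``truth_mask`` pixels.
    """
    n, (height, width) = ds.n, ds.shape
    feature_names = [f"px_r{r}_c{c}" for r in range(height) for c in range(width)]
    matrix = ExpressionMatrix(
        sample_ids=[f"img_{i}" for i in range(n)],
        feature_names=feature_names,
        values=ds.images.reshape(n, height * width).astype(float),
    )
    flat_mask = ds.truth_mask.reshape(-1)
    truth = {feature_names[j] for j in np.flatnonzero(flat_mask)}
    return matrix, ds.labels, truth


def generate_planted_tabular(
    n_per_class: dict,
    m: int = 1000,
    n_informative: int = 30,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PlantedTabularDataset:
    """Gaussian table with class-dependent mean shifts on known columns.

    Each informative feature is assigned one target class in rotation; samples
    of that class have their mean raised by ``effect_size`` on that feature.
    All other feature/class combinations are N(0, noise_sd), so null features
    are identically distributed across classes and ``effect_size=0`` is an
    exact global null.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_informative > m:
        raise ValueError("n_informative exceeds m")
    classes = list(n_per_class)
    counts = [int(n_per_class[c]) for c in classes]
    if any(c < 1 for c in counts):
        raise ValueError("all class counts must be ≥ 1")
    n = sum(counts)
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(n, m))

    labels = np.repeat(np.arange(len(classes)), counts)
    informative = [f"f{j}" for j in range(n_informative)]
    for j in range(n_informative):
        target = j % len(classes)
        values[labels == target, j] += effect_size

    matrix = ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(m)],
        values=values,
    )
    label_vec = LabelVector.from_labels([classes[k] for k in labels], class_set=classes)
    return PlantedTabularDataset(matrix=matrix, labels=label_vec, informative_features=set(informative))


def save_images_png(ds: PlantedImageDataset, directory) -> list[str]:
    """Dump each image as an 8-bit PNG (for visual inspection only)."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(ds.n):
        path = directory / f"img_{i}_class{ds.labels.labels[i]}.png"
        iio.imwrite(path, ds.images[i].astype(np.uint8))
        paths.append(str(path))
    return paths
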