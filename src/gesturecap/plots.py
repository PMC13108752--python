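"""Minimal plotting hooks (matplotlib)."""

from __future__ import annotations

from typing import Sequence, Set, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_error_boxes(cell_means: pd.DataFrame, ax=None):
    """Box plots of per-participant mean errors, one box per (group, method)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    groups = list(cell_means["group"].unique())
    methods = list(cell_means["method"].unique())
    width = 0.8 / len(methods)
    for mi, method in enumerate(methods):
        data, pos = [], []
        for gi, group in enumerate(groups):
            sub = cell_means[
                (cell_means["group"] == group) & (cell_means["method"] == method)
            ]
            data.append(sub["mean_e_mm"].to_numpy())
            pos.append(gi + (mi - len(methods) / 2 + 0.5) * width)
        ax.boxplot(data, positions=pos, widths=width * 0.9, whis=1.5)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=45, ha="right")
    ax.set_ylabel("mean Euclidean error (mm)")
    return ax


def plot_dice_curve(points: Sequence[Tuple[float, float]], ax=None):
    """Dice coefficient against voxel size."""
    if ax is None:
        _, ax = plt.subplots()
    xs, ys = zip(*points)
    ax.plot(xs, ys, "o-")
    ax.set_xlabel("voxel size (mm)")
    ax.set_ylabel("Dice coefficient")
    ax.set_ylim(0, 1)
    return ax


def plot_gesture_space(
    occ_ref: Set[tuple], occ_method: Set[tuple], voxel_mm: float = 50.0, ax=None
):
    """3D scatter of occupied voxels: both (green), reference-only (red),
    method-only (blue)."""
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    for occ, color in (
        (occ_ref & occ_method, "green"),
        (occ_ref - occ_method, "red"),
        (occ_method - occ_ref, "blue"),
    ):
        if occ:
            xs, ys, zs = zip(*occ)
            ax.scatter(
                [x * voxel_mm for x in xs],
                [y * voxel_mm for y in ys],
                [z * voxel_mm for z in zs],
                c=color, s=8, alpha=0.5,
            )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    return ax
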