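"""Figure helpers (headless matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["save_field_png", "save_profile_png", "save_polar_orientation_png",
           "save_volcano_png", "save_pca_png"]


def save_field_png(field, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(field.zeta, cmap="RdBu_r", origin="lower")
    ax.set_title("surface displacement")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_profile_png(profile, path, peaks=None) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.radii, profile.values, lw=1)
    if peaks is not None and peaks.n_peaks:
        ax.plot(peaks.peak_positions, peaks.peak_heights, "rv")
    ax.set_xlabel("radius (µm)")
    ax.set_ylabel("mean intensity")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_polar_orientation_png(hist, path) -> None:
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    theta = np.radians(hist.bin_centers)
    ax.plot(np.concatenate([theta, theta + np.pi]),
            np.concatenate([hist.weights, hist.weights]), lw=1)
    ax.set_title("orientation distribution")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_volcano_png(de_results, path) -> None:
    frame = de_results.frame
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = frame["direction"].map(
        {"up": "tab:red", "down": "tab:blue", "ns": "0.7"})
    ax.scatter(frame["log2fc"], -np.log10(frame["p"]), s=4, c=colors)
    ax.set_xlabel("log2 fold change (patterned / random)")
    ax.set_ylabel("-log10 p")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_pca_png(scores, groups, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    for g, color in (("patterned", "tab:red"), ("random", "tab:blue")):
        rows = [s for s in scores.scores.index if groups[s] == g]
        ax.scatter(scores.scores.loc[rows, "PC1"],
                   scores.scores.loc[rows, "PC2"], label=g, color=color)
    ax.set_xlabel(f"PC1 ({scores.explained[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({scores.explained[1] * 100:.1f}%)")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
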