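"""Figure helpers: TD-LR surface/contour views, landmark overlays, ROC panels.

All colormaps for log TD-LR are diverging and centered at 0 (no update);
undefined cells are left blank.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import TwoSlopeNorm


def _centered_norm(values: np.ndarray) -> TwoSlopeNorm:
    finite = values[np.isfinite(values)]
    vmax = float(np.abs(finite).max()) if finite.size else 1.0
    vmax = vmax if vmax > 0 else 1.0
    return TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)


def plot_surface3d(surface, path) -> None:
    """3-D view of the log TD-LR surface, with bands overlaid when present."""
    tt, xx = np.meshgrid(surface.t_grid, surface.x_grid, indexing="ij")
    norm = _centered_norm(surface.log_tdlr)
    fig = plt.figure(figsize=(7, 5.5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(tt, xx, surface.log_tdlr, cmap="RdYlGn_r", norm=norm,
                    edgecolor="none", alpha=0.95)
    for band in (surface.ci_lower, surface.ci_upper):
        if band is not None:
            ax.plot_wireframe(tt, xx, band, color="gray", linewidth=0.3, alpha=0.5)
    ax.set_xlabel("time")
    ax.set_ylabel("marker value")
    ax.set_zlabel("log TD-LR")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_contour(surface, path) -> None:
    norm = _centered_norm(surface.log_tdlr)
    fig, ax = plt.subplots(figsize=(6.5, 5))
    masked = np.ma.masked_invalid(surface.log_tdlr)
    cs = ax.contourf(surface.t_grid, surface.x_grid, masked.T, levels=21,
                     cmap="RdYlGn_r", norm=norm)
    fig.colorbar(cs, ax=ax, label="log TD-LR")
    ax.set_xlabel("time")
    ax.set_ylabel("marker value")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_landmark_overlay(profile, path) -> None:
    """One panel per landmark time; one line per marker_id over the u grid."""
    landmarks = sorted(profile["s"].unique())
    ncol = min(len(landmarks), 3) or 1
    nrow = int(np.ceil(len(landmarks) / ncol)) or 1
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 3.4 * nrow),
                             squeeze=False, sharey=True)
    for ax, s in zip(axes.ravel(), landmarks):
        sub = profile[profile["s"] == s]
        for mid, grp in sub.groupby("marker_id"):
            ax.plot(grp["u"], grp["log_tdlr_si"], marker=".", label=str(mid))
        ax.axhline(0.0, color="gray", lw=0.8, ls=":")
        ax.set_title(f"landmark s = {s:g}")
        ax.set_xlabel("placement value u")
        ax.set_ylabel("scale-invariant log TD-LR")
        ax.legend(fontsize=8)
    for ax in axes.ravel()[len(landmarks):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_auc_profile(profiles, path) -> None:
    """AUC(t) trajectories; ``profiles`` maps marker_id -> DataFrame(t, auc)."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for mid, prof in profiles.items():
        ax.plot(prof["t"], prof["auc"], marker="o", label=str(mid))
    ax.axhline(0.5, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("time")
    ax.set_ylabel("AUC(t)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_roc_derivative(curves, path) -> None:
    """Smoothed TD-ROC derivative vs FPR; ``curves`` maps marker_id -> TDROCCurve."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for mid, curve in curves.items():
        if curve.derivative is None:
            continue
        ax.plot(curve.fpr, curve.derivative, label=f"{mid} (t={curve.t:g})")
    ax.axhline(1.0, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("TD-ROC derivative")
    ax.legend()
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
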