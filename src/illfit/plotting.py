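"""Diagnostic figures: trait vs food concentration with the fitted curve.

One panel per clone: individual observations, the fitted saturation curve,
and shaded 95% CI bands for the break-point (vertical) and plateau
(horizontal).
"""

from __future__ import annotations

import numpy as np

from .plateau import (HOCKEY_STICK, PlateauFitResult, hockeystick_predict,
                      quadplateau_predict)


def plot_fit(ax, x, y, fit: PlateauFitResult, ill_ci=None, plateau_ci=None,
             title: str | None = None):
    """Draw one clone's observations and fitted curve onto ``ax``."""
    predict = hockeystick_predict if fit.model_tag == HOCKEY_STICK \
        else quadplateau_predict
    xg = np.linspace(0, float(np.max(x)), 300)
    ax.scatter(x, y, s=12, color="0.35", zorder=2, label="individuals")
    ax.plot(xg, predict(fit.params, xg), color="C3", zorder=3, label="fit")
    if ill_ci is not None:
        ax.axvspan(ill_ci.lower, ill_ci.upper, color="C0", alpha=0.2, lw=0)
    if plateau_ci is not None:
        ax.axhspan(plateau_ci.lower, plateau_ci.upper, color="C2", alpha=0.2, lw=0)
    ax.axvline(fit.ill, color="C0", ls="--", lw=0.8)
    ax.axhline(fit.plateau_elevation, color="C2", ls="--", lw=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("food concentration (mg C$_{org}$ L$^{-1}$)")


def plot_clone_fits(observations, fits, trait_label="trait", path=None):
    """Grid of per-clone panels; saves to ``path`` if given.

    ``observations`` maps clone_id -> (x, y); ``fits`` maps clone_id ->
    (PlateauFitResult, ill_ci or None, plateau_ci or None).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    clones = sorted(observations)
    ncol = min(2, len(clones))
    nrow = -(-len(clones) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 3.2 * nrow),
                             squeeze=False, sharex=True)
    for ax, clone in zip(axes.ravel(), clones):
        x, y = observations[clone]
        fit, ill_ci, plateau_ci = fits[clone]
        plot_fit(ax, x, y, fit, ill_ci, plateau_ci, title=str(clone))
        ax.set_ylabel(trait_label)
    for ax in axes.ravel()[len(clones):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
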