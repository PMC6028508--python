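"""Overlay plots of observed vs. fitted intensity histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .fitting import FitResult
from .intensity import (InitialIntensityModel, IntensityHistogram,
                        MixtureParams, forward_model)

__all__ = ["plot_fit_overlay"]


def plot_fit_overlay(observed: IntensityHistogram, result: FitResult,
                     init: InitialIntensityModel, chase_time: float,
                     path=None):
    """Observed histogram with the fitted mixture and its bulk/slow
    components overlaid on a log-intensity axis."""
    edges = observed.bin_edges
    cfg = result.config
    kwargs = dict(method=cfg.forward_method, grid_step=cfg.grid_step) if cfg else {}
    total = forward_model(result.params, init, chase_time, edges, **kwargs)
    p = result.params
    bulk_only = forward_model(MixtureParams(p.bulk, p.bulk, 0.0), init,
                              chase_time, edges, **kwargs)
    slow_only = forward_model(MixtureParams(p.slow, p.slow, 0.0), init,
                              chase_time, edges, **kwargs)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.stairs(observed.density, edges, fill=True, alpha=0.35,
              color="0.4", label="observed")
    ax.plot(total.centers, total.density, "k-", lw=1.8, label="fitted mixture")
    ax.plot(bulk_only.centers, (1 - p.slow_fraction) * bulk_only.density,
            "C0--", lw=1.2, label="bulk component")
    ax.plot(slow_only.centers, p.slow_fraction * slow_only.density,
            "C3--", lw=1.2,
            label=f"slow component (alpha={p.slow_fraction:.3g})")
    ax.set_xscale("log")
    ax.set_xlabel("intensity (a.u.)")
    ax.set_ylabel("density per unit log-intensity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
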