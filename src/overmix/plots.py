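"""Basic diagnostic plots for a relabelled configuration.

Three panels: posterior parameter densities per aligned group (the
visual check that relabelling succeeded — each marginal should be
unimodal), an allocation-probability map, and the observed density over
a sweep of posterior predictive replicates.  Matplotlib is imported
lazily so the rest of the package works without a plotting backend.
"""

from __future__ import annotations

import numpy as np

from .postprocess import allocation_probabilities, posterior_predictive
from .relabel import RelabellingResult

__all__ = ["diagnostic_panels"]


def diagnostic_panels(
    result: RelabellingResult,
    y: np.ndarray,
    R: int = 200,
    rng: np.random.Generator | None = None,
    path: str | None = None,
):
    """Render the three standard panels for one configuration.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rng is None:
        rng = np.random.default_rng()
    k0 = result.k0
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))

    ax = axes[0]
    for name, arr in (("pi", result.pi), ("mu", result.mu),
                      ("sigma2", result.sigma2)):
        for k in range(k0):
            ax.hist(arr[:, k], bins=40, density=True, histtype="step",
                    label=f"{name} g{k + 1}" if name == "mu" else None)
    ax.set_title("posterior parameter draws per group")
    ax.legend(fontsize=7)

    ax = axes[1]
    probs = allocation_probabilities(result)
    order = np.argsort(np.asarray(y))
    im = ax.imshow(probs[order].T, aspect="auto", interpolation="nearest",
                   cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("observation (sorted by y)")
    ax.set_ylabel("group")
    ax.set_yticks(range(k0), [str(k + 1) for k in range(k0)])
    ax.set_title("allocation probabilities")
    fig.colorbar(im, ax=ax, fraction=0.046)

    ax = axes[2]
    reps = posterior_predictive(result, n=len(y), R=R, rng=rng)
    grid = np.linspace(min(np.min(reps), np.min(y)),
                       max(np.max(reps), np.max(y)), 200)
    bw = 1.06 * np.std(y) * len(y) ** (-0.2)
    for r in range(min(R, 60)):
        dens = np.exp(-0.5 * ((grid[:, None] - reps[r]) / bw) ** 2).sum(1)
        ax.plot(grid, dens / (len(y) * bw * np.sqrt(2 * np.pi)),
                color="0.8", lw=0.5)
    dens_y = np.exp(-0.5 * ((grid[:, None] - np.asarray(y)) / bw) ** 2).sum(1)
    ax.plot(grid, dens_y / (len(y) * bw * np.sqrt(2 * np.pi)),
            color="crimson", lw=1.5, label="observed")
    ax.set_title("posterior predictive densities")
    ax.legend(fontsize=8)

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
    return fig
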