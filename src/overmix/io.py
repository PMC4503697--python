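"""File formats: observation readers, draw/result writers, run metadata.

Observations are a single numeric column — CSV with an optional header,
or whitespace/newline-delimited plain text.  Draws go out as a long CSV
(iteration, chain, component, pi, mu, sigma2) plus an allocation matrix;
run metadata (ladder, swap acceptance, seed) as JSON.  All labels and
iteration numbers on disk are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .relabel import RelabellingResult
from .tempering import PosteriorDraws

__all__ = [
    "read_observations",
    "write_observations",
    "write_draws",
    "write_allocations",
    "write_metadata",
    "write_relabelled",
    "load_config",
]


def read_observations(path: str | Path) -> np.ndarray:
    """Read a one-column numeric file (CSV with optional header, or
    whitespace/newline-delimited text)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data file not found: {path}")
    tokens = path.read_text().replace(",", " ").split()
    if not tokens:
        raise ValueError(f"no data found in {path}")
    try:
        float(tokens[0])
    except ValueError:
        tokens = tokens[1:]  # single header token
        if not tokens:
            raise ValueError(f"no numeric data found in {path}") from None
    try:
        y = np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from None
    return y


def write_observations(
    path: str | Path, y: np.ndarray, labels: np.ndarray | None = None
) -> None:
    """Write data as a one-column CSV; labels (1-based) as a sibling CSV."""
    path = Path(path)
    pd.DataFrame({"y": np.asarray(y, float)}).to_csv(path, index=False)
    if labels is not None:
        lab_path = path.with_name(path.stem + "_labels.csv")
        pd.DataFrame({"label": np.asarray(labels, int) + 1}).to_csv(
            lab_path, index=False
        )


def draws_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Long-format target-chain draws (1-based iteration and component)."""
    T, K = draws.pi.shape
    it = np.repeat(np.arange(1, T + 1), K)
    comp = np.tile(np.arange(1, K + 1), T)
    return pd.DataFrame(
        {
            "iteration": it,
            "chain": draws.ladder.J,
            "component": comp,
            "pi": draws.pi.ravel(),
            "mu": draws.mu.ravel(),
            "sigma2": draws.sigma2.ravel(),
        }
    )


def write_draws(path: str | Path, draws: PosteriorDraws) -> None:
    draws_frame(draws).to_csv(path, index=False)


def write_allocations(path: str | Path, draws: PosteriorDraws) -> None:
    """Allocation matrix, one row per saved iteration, 1-based labels."""
    T, n = draws.z.shape
    df = pd.DataFrame(
        draws.z.astype(int) + 1, columns=[f"obs{i + 1}" for i in range(n)]
    )
    df.insert(0, "iteration", np.arange(1, T + 1))
    df.to_csv(path, index=False)


def write_metadata(path: str | Path, draws: PosteriorDraws) -> None:
    meta = {
        "ladder": [float(a) for a in draws.ladder.alphas],
        "J": draws.ladder.J,
        "K": draws.config.K,
        "n_iter": draws.config.n_iter,
        "burn_in": draws.config.burn_in,
        "u": draws.config.u,
        "seed": draws.config.seed,
        "n_observations": int(draws.y.size),
        "priors": {
            "alpha": draws.priors.alpha,
            "a": draws.priors.a,
            "b": draws.priors.b,
            "l": draws.priors.l,
            "tau": draws.priors.tau,
        },
        "swap_acceptance_rates": {
            str(j): (None if np.isnan(v) else v)
            for j, v in draws.swap_acceptance_rates().items()
        },
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def write_relabelled(path: str | Path, result: RelabellingResult) -> None:
    """Relabelled draws for one configuration, long format with the
    resolved label, phase and configuration size columns."""
    T, K = result.pi.shape
    it = np.repeat(result.iterations + 1, K)
    comp = np.tile(np.arange(1, K + 1), T)
    df = pd.DataFrame(
        {
            "iteration": it,
            "component": comp,
            "pi": result.pi.ravel(),
            "mu": result.mu.ravel(),
            "sigma2": result.sigma2.ravel(),
            "resolved_label": comp,
            "phase": np.repeat(result.phases, K),
            "k0": result.k0,
        }
    )
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return cfg
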