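"""Shapley-value interpretation of a trained bag classifier.

The explained scalar is the model's CWNS-side score ``1 - p(CWS)``, so a
*positive* Shapley value pushes the decision toward CWNS (rendered blue) and
a *negative* one toward CWS (rendered red).  The coalition unit is one cell
of the feature-by-timestep grid (19 x 24 raw cells or 19 x 8 change-score
cells); a missing cell is imputed from a background set of training bags.

Shapley values are estimated with the kernel-weighted linear-regression
estimator (KernelSHAP): coalitions are drawn with the Shapley kernel weight
``(M-1) / (C(M,s) s (M-s))``, the masked model outputs are regressed on the
coalition indicators, and the efficiency constraint (values sum to the
explained score minus the background expectation) is enforced exactly by
variable elimination.  When the budget covers full coalition enumeration the
estimate is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .features import MODALITIES, FeatureBag, feature_names
from .model import TrainedModel
from .preprocess import N_SEGMENTS


@dataclass
class ShapGrid:
    """Signed Shapley contributions per timestep x feature.

    ``scope`` is "personalized" (one window) or "global" (mean over a set).
    Positive values push toward CWNS, negative toward CWS.
    """

    values: np.ndarray  # (19, n_features)
    representation: str
    scope: str
    feature_names: List[str]
    base_value: float = 0.0  # background expectation of the explained score
    score: float = 0.0  # explained score of the bag (personalized scope)

    def __post_init__(self) -> None:
        width = 24 if self.representation == "raw" else 8
        if self.values.shape != (N_SEGMENTS, width):
            raise ValueError(
                f"grid shape {self.values.shape} does not match "
                f"representation {self.representation!r}"
            )


def _flat_to_xs(flat: np.ndarray, representation: str) -> Dict[str, np.ndarray]:
    """(n, 19*F) rows -> per-modality (n, 19, d) arrays."""
    width = 6 if representation == "raw" else 2
    grids = flat.reshape(len(flat), N_SEGMENTS, width * len(MODALITIES))
    return {
        m: grids[:, :, i * width : (i + 1) * width] for i, m in enumerate(MODALITIES)
    }


def cwns_score_fn(model: TrainedModel, representation: str) -> Callable[[np.ndarray], np.ndarray]:
    """Explained function: flattened grids -> 1 - p(CWS), batched."""

    def fn(flat: np.ndarray) -> np.ndarray:
        return 1.0 - model.predict_proba(_flat_to_xs(np.asarray(flat, float), representation))

    return fn


# ---------------------------------------------------------------------------
# KernelSHAP core
# ---------------------------------------------------------------------------


def _coalition_matrix(
    n_players: int, n_samples: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """(Z, kernel weights): enumerated sizes first, sampled remainder after."""
    M = n_players
    sizes = np.arange(1, M)
    size_w = (M - 1) / (sizes * (M - sizes))
    size_w = size_w / size_w.sum()
    rows: List[np.ndarray] = []
    weights: List[float] = []
    remaining = n_samples
    remaining_sizes: set = set()
    # enumerate complete sizes (paired s and M-s) while the budget allows
    order = np.argsort(-size_w)
    done: set = set()
    for si in order:
        s = int(sizes[si])
        if s in done or s in remaining_sizes:
            continue
        pair = {s, M - s}
        count = sum(comb(M, q) for q in pair)
        if count <= remaining:
            for q in sorted(pair):
                for idx in combinations(range(M), q):
                    z = np.zeros(M)
                    z[list(idx)] = 1.0
                    rows.append(z)
                    weights.append(size_w[q - 1] / comb(M, q))
            remaining -= count
            done |= pair
        else:
            remaining_sizes |= pair
    if remaining > 0 and remaining_sizes:
        # sampled rows share the kernel mass not covered by enumeration
        rs = np.array(sorted(remaining_sizes))
        pw = size_w[rs - 1]
        leftover_mass = float(pw.sum())
        pw = pw / pw.sum()
        draw = rng.choice(rs, size=remaining, p=pw)
        for s in draw:
            idx = rng.choice(M, size=int(s), replace=False)
            z = np.zeros(M)
            z[idx] = 1.0
            rows.append(z)
            weights.append(leftover_mass / remaining)
    return np.array(rows), np.array(weights)


def kernel_shap(
    fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = 4096,
    seed: int = 0,
    batch_size: int = 2048,
) -> Tuple[np.ndarray, float, float]:
    """Shapley values of ``fn`` at ``x`` against a background sample.

    Returns ``(phi, base_value, fx)`` with ``phi.sum() == fx - base_value``
    (efficiency, exact by construction).  ``fn`` maps (n, M) arrays to (n,)
    scores; missing features are imputed by averaging ``fn`` over background
    rows.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    M = x.size
    if M == 1:
        base_value = float(np.mean(fn(background)))
        fx = float(fn(x[None, :])[0])
        return np.array([fx - base_value]), base_value, fx
    if n_samples < 2 * M:
        warnings.warn(
            f"n_samples={n_samples} is small for {M} coalition players; "
            "Shapley estimates carry widened tolerance"
        )
    rng = np.random.default_rng(seed)
    Z, w = _coalition_matrix(M, n_samples, rng)

    base_value = float(np.mean(fn(background)))
    fx = float(fn(x[None, :])[0])

    # masked evaluations, averaged over the background, in memory-bounded chunks
    nbg = len(background)
    v = np.empty(len(Z))
    rows_per_chunk = max(1, batch_size // nbg)
    for lo in range(0, len(Z), rows_per_chunk):
        zc = Z[lo : lo + rows_per_chunk]  # (r, M)
        masked = zc[:, None, :] * x[None, None, :] + (1 - zc[:, None, :]) * background[None, :, :]
        out = fn(masked.reshape(-1, M))
        v[lo : lo + rows_per_chunk] = out.reshape(len(zc), nbg).mean(axis=1)

    # weighted regression with the efficiency constraint eliminated into phi_M
    y = v - base_value - Z[:, -1] * (fx - base_value)
    A = Z[:, :-1] - Z[:, [-1]]
    sw = np.sqrt(w)
    phi_rest, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    phi = np.empty(M)
    phi[:-1] = phi_rest
    phi[-1] = (fx - base_value) - phi_rest.sum()
    return phi, base_value, fx


# ---------------------------------------------------------------------------
# bag-level API
# ---------------------------------------------------------------------------


def background_sample(
    bags: Sequence[FeatureBag], k: int = 20, seed: int = 0
) -> List[FeatureBag]:
    """Medoid-style background: KMeans centers snapped to the nearest real bag."""
    if len(bags) <= k:
        return list(bags)
    X = np.stack([b.flatten().ravel() for b in bags])
    km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(X)
    chosen = []
    for c in km.cluster_centers_:
        chosen.append(int(np.argmin(np.sum((X - c) ** 2, axis=1))))
    return [bags[i] for i in sorted(set(chosen))]


def shap_values(
    model: TrainedModel,
    bag: FeatureBag,
    background: Sequence[FeatureBag],
    n_samples: int = 4096,
    seed: int = 0,
) -> ShapGrid:
    """Personalized Shapley grid of one window under the CWNS-score convention."""
    if not background:
        raise ValueError("background set must be non-empty")
    rep = bag.representation
    fn = cwns_score_fn(model, rep)
    x = bag.flatten().ravel()
    bg = np.stack([b.flatten().ravel() for b in background])
    phi, base, fx = kernel_shap(fn, x, bg, n_samples=n_samples, seed=seed)
    width = len(feature_names(rep))
    return ShapGrid(
        values=phi.reshape(N_SEGMENTS, width),
        representation=rep,
        scope="personalized",
        feature_names=feature_names(rep),
        base_value=base,
        score=fx,
    )


def global_importance(
    model: TrainedModel,
    bags: Sequence[FeatureBag],
    restrict: str,
    background: Sequence[FeatureBag],
    n_samples: int = 4096,
    seed: int = 0,
) -> ShapGrid:
    """Mean personalized grid over the correctly classified bags of one class.

    ``restrict`` is "true_CWS" or "true_CWNS": only bags whose true label is
    the requested class *and* whose model prediction matches it contribute.
    """
    want = {"true_CWS": 1, "true_CWNS": 0}[restrict]
    grids = []
    from .model import forward  # local import to avoid cycle at module load

    for i, bag in enumerate(bags):
        if bag.label != want:
            continue
        pred = int(forward(bag, model) >= 0.5)
        if pred != want:
            continue
        grids.append(
            shap_values(model, bag, background, n_samples=n_samples, seed=seed + i).values
        )
    if not grids:
        raise ValueError(f"no correctly classified {restrict} bags to average")
    rep = bags[0].representation
    return ShapGrid(
        values=np.mean(grids, axis=0),
        representation=rep,
        scope="global",
        feature_names=feature_names(rep),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _symmetric_limit(values: np.ndarray) -> float:
    """Symmetric color limit at the 99th percentile of |values| (min 1e-12)."""
    lim = float(np.percentile(np.abs(values), 99))
    return max(lim, 1e-12)


def render_group_heatmap(grid: ShapGrid, out: Optional[str] = None, ax=None):
    """Grid heatmap: features on X, 19 timesteps on Y, blue=CWNS / red=CWS."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(grid.feature_names)), 5))
    else:
        fig = ax.figure
    lim = _symmetric_limit(grid.values)
    im = ax.imshow(
        grid.values, aspect="auto", cmap="RdBu", vmin=-lim, vmax=lim, origin="upper"
    )
    ax.set_xticks(range(len(grid.feature_names)))
    ax.set_xticklabels(grid.feature_names, rotation=90, fontsize=7)
    ax.set_ylabel("2s segment (timestep)")
    ax.set_xlabel("feature")
    fig.colorbar(im, ax=ax, label="Shapley value (blue → CWNS, red → CWS)")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig, ax, im


def render_personalized_plot(
    feature_series: np.ndarray,
    shap_column: np.ndarray,
    out: Optional[str] = None,
    ax=None,
    vlim: Optional[float] = None,
    title: str = "",
):
    """One feature's 19-step trajectory with per-segment Shapley shading.

    Pass a shared ``vlim`` when rendering several participants side by side so
    their colors are comparable.
    """
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib import colors

    feature_series = np.asarray(feature_series, float)
    shap_column = np.asarray(shap_column, float)
    if feature_series.shape != (N_SEGMENTS,) or shap_column.shape != (N_SEGMENTS,):
        raise ValueError(f"expected {N_SEGMENTS}-step series")
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3))
    else:
        fig = ax.figure
    lim = vlim if vlim is not None else _symmetric_limit(shap_column)
    norm = colors.Normalize(vmin=-lim, vmax=lim)
    cmap = matplotlib.colormaps["RdBu"]
    for i, v in enumerate(shap_column):
        ax.axvspan(i - 0.5, i + 0.5, color=cmap(norm(v)), alpha=0.8, lw=0)
    ax.plot(range(N_SEGMENTS), feature_series, color="black", marker="o", ms=3)
    ax.set_xlim(-0.5, N_SEGMENTS - 0.5)
    ax.set_xlabel("2s segment (timestep)")
    ax.set_ylabel("feature value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig, ax


def save_grid(grid: ShapGrid, csv_path, meta_path=None) -> None:
    """Grid as CSV (timestep x feature) plus an optional metadata JSON."""
    import json

    import pandas as pd

    df = pd.DataFrame(grid.values, columns=grid.feature_names)
    df.index.name = "timestep"
    df.to_csv(csv_path)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump(
                {
                    "representation": grid.representation,
                    "scope": grid.scope,
                    "base_value": grid.base_value,
                    "score": grid.score,
                },
                fh,
                indent=1,
            )
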