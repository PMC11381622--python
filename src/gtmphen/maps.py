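"""Interpretation layers over the latent lattice.

Four kinds of layer share one container: membership maps (subject counts per
node), reference maps (one modelling variable's component across the
reference vectors; grey-red), investigative maps (per-node mean of a
variable withheld from modelling; grey-teal) and per-subject probability
maps (a responsibility distribution over nodes).  Layers are first-class
data (vector + metadata); rendering to an image is optional so the library
works headless.

Nodes with no assigned subjects carry NaN, never 0 - zero is a valid value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gtm
from .preprocessing import Standardizer

__all__ = ["MapLayer", "membership_map", "reference_map", "investigative_map",
           "probability_map", "render", "second_best_neighbour_fraction"]

_SCHEME_FOR_KIND = {
    "membership": "grey_red",
    "reference": "grey_red",
    "probability": "grey_red",
    "investigative": "grey_teal",
}


@dataclass
class MapLayer:
    side: int
    values: np.ndarray        # length side**2, node order row-major top-left
    kind: str
    scheme: str
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.side**2,):
            raise ValueError("values length must equal side**2")
        if self.kind not in _SCHEME_FOR_KIND:
            raise ValueError(f"unknown layer kind {self.kind!r}")

    def grid(self) -> np.ndarray:
        return self.values.reshape(self.side, self.side)

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.side**2)
        return pd.DataFrame({
            "node_index": idx,
            "row": idx // self.side,
            "col": idx % self.side,
            "value": self.values,
            "kind": self.kind,
        })

    def to_csv(self, path: str | Path) -> None:
        # repr-precision floats so exported layers re-load bit-identically
        self.to_frame().to_csv(path, index=False, na_rep="NA", float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, scheme: str | None = None,
                 name: str = "") -> "MapLayer":
        df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
        df = df.sort_values("node_index")
        side = int(np.sqrt(len(df)))
        kind = str(df["kind"].iloc[0])
        return cls(side=side, values=df["value"].to_numpy(dtype=float),
                   kind=kind, scheme=scheme or _SCHEME_FOR_KIND[kind], name=name)


def membership_map(model: gtm.GTMModel, data: np.ndarray) -> MapLayer:
    """Subject count per node (argmax responsibility); counts sum to N."""
    labels = gtm.assign_micro(model, data)
    counts = np.bincount(labels, minlength=model.K).astype(float)
    return MapLayer(side=model.grid.side, values=counts,
                    kind="membership", scheme="grey_red", name="membership")


def reference_map(model: gtm.GTMModel, variable_index: int,
                  scaler: Standardizer | None = None,
                  name: str = "") -> MapLayer:
    """One variable's component of every reference vector.

    By default on the standardized modelling scale; pass the pipeline's
    ``Standardizer`` to express values on the original variable scale (only
    meaningful when ``name`` is one of its variables).
    """
    Y = gtm.reference_vectors(model)
    if not 0 <= variable_index < Y.shape[1]:
        raise IndexError(f"variable_index {variable_index} out of range (D={Y.shape[1]})")
    vals = Y[:, variable_index]
    if scaler is not None:
        vals = scaler.inverse_column(name or scaler.names[variable_index], vals)
    return MapLayer(side=model.grid.side, values=vals,
                    kind="reference", scheme="grey_red", name=name)


def investigative_map(model: gtm.GTMModel, data: np.ndarray,
                      values: np.ndarray, name: str = "") -> MapLayer:
    """Per-node mean of a variable not used in modelling.

    Each occupied node gets the mean of the variable over its (non-missing)
    members; unoccupied nodes and nodes with only missing members are NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != np.asarray(data).shape[0]:
        raise ValueError("values must have one entry per subject")
    if np.isnan(values).all():
        raise ValueError("investigative variable has no observed values")
    labels = gtm.assign_micro(model, data)
    out = np.full(model.K, np.nan)
    for l in np.unique(labels):
        member_vals = values[labels == l]
        member_vals = member_vals[~np.isnan(member_vals)]
        if member_vals.size:
            out[l] = member_vals.mean()
    return MapLayer(side=model.grid.side, values=out,
                    kind="investigative", scheme="grey_teal", name=name)


def probability_map(model: gtm.GTMModel, subject_row: np.ndarray) -> MapLayer:
    """The responsibility distribution of one subject over all nodes."""
    row = np.asarray(subject_row, dtype=float).reshape(1, -1)
    if np.isnan(row).any():
        raise ValueError("subject row contains missing values")
    resp, _ = gtm.e_step(model, row)
    return MapLayer(side=model.grid.side, values=resp.R[0],
                    kind="probability", scheme="grey_red", name="probability")


def second_best_neighbour_fraction(model: gtm.GTMModel, data: np.ndarray) -> float:
    """Fraction of subjects whose second-highest-responsibility node is a
    lattice neighbour (Chebyshev distance 1) of their argmax node - the
    soft-assignment robustness diagnostic."""
    resp, _ = gtm.e_step(model, data)
    order = np.argsort(resp.R, axis=1)
    best, second = order[:, -1], order[:, -2]
    side = model.grid.side
    r1, c1 = best // side, best % side
    r2, c2 = second // side, second % side
    cheb = np.maximum(np.abs(r1 - r2), np.abs(c1 - c2))
    return float(np.mean(cheb == 1))


def render(layer: MapLayer, path: str | Path,
           sizes: np.ndarray | None = None) -> Path:
    """Write a lattice heatmap (PNG/SVG by extension).

    Grey->red for modelling-derived layers, grey->teal for investigative;
    missing nodes render neutral.  ``sizes`` (e.g. membership counts) scales
    the node markers.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmaps = {
        "grey_red": LinearSegmentedColormap.from_list("grey_red", ["#d9d9d9", "#b30000"]),
        "grey_teal": LinearSegmentedColormap.from_list("grey_teal", ["#d9d9d9", "#0b7285"]),
    }
    side = layer.side
    idx = np.arange(side**2)
    col, row = idx % side, idx // side
    vals = layer.values
    finite = np.isfinite(vals)
    if sizes is not None:
        sizes = np.asarray(sizes, dtype=float)
        smax = sizes.max() if sizes.max() > 0 else 1.0
        marker = 20 + 180 * sizes / smax
    else:
        marker = np.full(side**2, 120.0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(col[~finite], -row[~finite], s=marker[~finite], c="#f2f2f2",
               edgecolors="#cccccc", linewidths=0.4)
    sc = ax.scatter(col[finite], -row[finite], s=marker[finite], c=vals[finite],
                    cmap=cmaps[layer.scheme], edgecolors="none")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(layer.name or layer.kind)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    path = Path(path)
    fig.savefig(path, dpi=120, metadata={"Software": None} if path.suffix == ".png" else None)
    plt.close(fig)
    if not path.exists() or path.stat().st_size == 0:
        raise OSError(f"failed to write {path}")
    return path
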