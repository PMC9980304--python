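"""Per-ROI association maps: ROC-AUC for binary clinical features, Pearson
correlation for ordinal/interval ones, and their summaries.

The map for a feature lays the per-ROI statistic back onto the B × B bin
grid of each channel pair, so spatially coherent EV populations that shift
with the clinical condition show up as contiguous high- or low-AUC regions.
AUC orientation: values above 0.5 mean the ROI's particle concentration is
higher in the positive class.  ROIs with no variation across patients are
masked out rather than reported as 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np
from scipy.stats import rankdata

from evmap.binning import FeatureMatrix


def roi_auc(concentrations: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney (midrank) ROC AUC of one ROI's concentrations.

    Equals P(X_pos > X_neg) + ½·P(X_pos = X_neg) over all positive/negative
    patient pairs.  Requires both classes present.
    """
    x = np.asarray(concentrations, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roi_auc requires both classes present")
    ranks = rankdata(x)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class AUCMap:
    """B × B per-ROI AUC values for one channel pair and one feature."""

    channel_pair: tuple[str, str]
    values: np.ndarray  # B × B, NaN where masked out
    mask: np.ndarray  # True where the ROI is defined
    feature: str
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        v, m = np.asarray(self.values, float), np.asarray(self.mask, bool)
        if v.shape != m.shape:
            raise ValueError("values and mask shapes differ")
        inside = v[m]
        if inside.size and (inside.min() < 0 or inside.max() > 1):
            raise ValueError("masked-in AUC values must lie in [0, 1]")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one patient per class")
        self.values, self.mask = v, m

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class CorrelationMap:
    """B × B per-ROI Pearson r for one channel pair and one feature."""

    channel_pair: tuple[str, str]
    values: np.ndarray
    mask: np.ndarray
    feature: str

    def __post_init__(self) -> None:
        v, m = np.asarray(self.values, float), np.asarray(self.mask, bool)
        inside = v[m]
        if inside.size and (inside.min() < -1 - 1e-12 or inside.max() > 1 + 1e-12):
            raise ValueError("masked-in correlations must lie in [-1, 1]")
        self.values, self.mask = np.clip(v, -1, 1, where=m, out=v), m

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def _columnwise_auc(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank AUC per column plus a defined-mask (some variation exists)."""
    y = np.asarray(y).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_map requires at least one patient per class")
    ranks = rankdata(X, axis=0)
    r_pos = ranks[y == 1].sum(axis=0)
    auc = (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    varies = X.max(axis=0) > X.min(axis=0)
    auc = np.where(varies, auc, np.nan)
    return auc, varies


def auc_map(
    features: FeatureMatrix, labels: np.ndarray, feature_name: str = ""
) -> dict[tuple[str, str], AUCMap]:
    """One :class:`AUCMap` per channel pair; constant ROIs masked out.

    ``labels`` must align with ``features.patients``.  Patients with a
    missing label (NaN) are excluded from this map only.
    """
    y = np.asarray(labels, dtype=np.float64)
    keep = ~np.isnan(y)
    X = features.values[keep]
    y = y[keep].astype(int)
    auc, varies = _columnwise_auc(X, y)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())

    out: dict[tuple[str, str], AUCMap] = {}
    pairs = list(dict.fromkeys(p for p, _, _ in features.columns))
    for pair in pairs:
        idx = [k for k, (p, _, _) in enumerate(features.columns) if p == pair]
        B = int(round(len(idx) ** 0.5))
        out[pair] = AUCMap(
            channel_pair=pair,
            values=auc[idx].reshape(B, B),
            mask=varies[idx].reshape(B, B),
            feature=feature_name,
            n_pos=n_pos,
            n_neg=n_neg,
        )
    return out


def correlation_map(
    features: FeatureMatrix, y: np.ndarray, feature_name: str = ""
) -> dict[tuple[str, str], CorrelationMap]:
    """Pearson r of each ROI's concentration against a numeric feature."""
    yv = np.asarray(y, dtype=np.float64)
    keep = ~np.isnan(yv)
    if keep.sum() < 3:
        raise ValueError("correlation_map needs >= 3 patients with the feature")
    X = features.values[keep]
    yv = yv[keep]
    if yv.max() == yv.min():
        raise ValueError("clinical feature is constant; correlation undefined")

    Xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    varies = sx > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(varies, r, np.nan)

    out: dict[tuple[str, str], CorrelationMap] = {}
    pairs = list(dict.fromkeys(p for p, _, _ in features.columns))
    for pair in pairs:
        idx = [k for k, (p, _, _) in enumerate(features.columns) if p == pair]
        B = int(round(len(idx) ** 0.5))
        out[pair] = CorrelationMap(
            channel_pair=pair,
            values=r[idx].reshape(B, B),
            mask=varies[idx].reshape(B, B),
            feature=feature_name,
        )
    return out


def top_decile_mean(map_: AUCMap, absolute: bool = False) -> float:
    """Mean of the highest 10% of a map's defined AUC values.

    k = round(0.10 × number of defined ROIs), at least 1, with half-up
    rounding.  Ties at the cut are broken by flat bin index (higher index
    included last), which makes the selection deterministic.  With
    ``absolute=True`` the ranking uses |AUC − 0.5| instead (both strongly
    high and strongly low AUCs are informative); the default follows the
    plain highest-values rule.
    """
    vals = map_.values.ravel()
    mask = map_.mask.ravel()
    n_valid = int(mask.sum())
    if n_valid < 10:
        raise ValueError(f"only {n_valid} defined ROIs; need >= 10")
    k = max(1, int(np.floor(0.10 * n_valid + 0.5)))
    idx = np.nonzero(mask)[0]
    key = np.abs(vals[idx] - 0.5) if absolute else vals[idx]
    # stable sort on (key, bin index): equal keys keep lower index first,
    # so the top-k slice includes higher bin indices last
    order = np.lexsort((idx, key))
    top = idx[order][-k:]
    return float(vals[top].mean())


def top_decile_sd(map_: AUCMap) -> float:
    """SD across the ROIs included in the top-decile mean."""
    vals = map_.values.ravel()
    mask = map_.mask.ravel()
    n_valid = int(mask.sum())
    k = max(1, int(np.floor(0.10 * n_valid + 0.5)))
    idx = np.nonzero(mask)[0]
    order = np.lexsort((idx, vals[idx]))
    return float(vals[idx[order][-k:]].std(ddof=0))


def overlay_gain(
    map_: AUCMap,
    gain: np.ndarray,
    out_prefix: str | Path,
) -> Path:
    """Export AUC and boosted-tree gain side by side on the same grid.

    ``gain`` is the per-ROI total split gain reshaped to the map's grid.
    Writes ``<prefix>.csv`` (long format: row, col, auc, gain) and
    ``<prefix>.png`` (two heatmaps), returning the CSV path.
    """
    gain = np.asarray(gain, dtype=np.float64)
    if gain.shape != map_.values.shape:
        raise ValueError(
            f"gain shape {gain.shape} does not match map grid {map_.values.shape}"
        )
    out_prefix = Path(out_prefix)
    B = map_.values.shape[0]
    rows = []
    for i in range(B):
        for j in range(B):
            rows.append((i, j, map_.values[i, j], gain[i, j]))
    import pandas as pd

    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(rows, columns=["row", "col", "auc", "gain"]).to_csv(
        csv_path, index=False
    )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    im0 = axes[0].imshow(map_.values.T, origin="lower", cmap="coolwarm",
                         vmin=0, vmax=1)
    axes[0].set_title(f"AUC: {map_.feature or '-'}")
    fig.colorbar(im0, ax=axes[0])
    im1 = axes[1].imshow(gain.T, origin="lower", cmap="viridis")
    axes[1].set_title("XGBoost gain")
    fig.colorbar(im1, ax=axes[1])
    for ax in axes:
        ax.set_xlabel(map_.channel_pair[0])
        ax.set_ylabel(map_.channel_pair[1])
    fig.tight_layout()
    fig.savefig(out_prefix.with_suffix(".png"), dpi=100)
    plt.close(fig)
    return csv_path


def export_map_csv(values: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    """Long-format CSV export (row, col, value, defined) of any grid map."""
    import pandas as pd

    B = values.shape[0]
    rows = [
        (i, j, values[i, j], bool(mask[i, j])) for i in range(B) for j in range(B)
    ]
    pd.DataFrame(rows, columns=["row", "col", "value", "defined"]).to_csv(
        path, index=False
    )
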