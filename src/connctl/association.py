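"""Permutation-null spatial association and regional differential expression.

Node-level abnormality maps (signed group-difference statistics) are related
to molecular annotation maps by Pearson correlation, with significance from
spatial permutation nulls: either plain label shuffling or autocorrelation-
preserving surrogates (shuffled values re-smoothed with a Gaussian kernel
whose scale is fitted to the annotation map's empirical correlogram).  The
regional transcriptomic analysis contrasts mean expression inside a detected
region against the background via random node sets of matched size.

All permutation p-values use the two-sided add-one convention
``p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm)`` and so are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import fdr_bh
from .synthetic import AnnotationMap, ExpressionMatrix

MIN_PERMUTATIONS = 100


@dataclass(frozen=True)
class AbnormalityMap:
    """Per-node signed abnormality statistic with a detected-node mask."""

    values: np.ndarray
    mask: np.ndarray  # boolean, True where the omnibus test survived FDR

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        m = np.asarray(self.mask, bool)
        if v.ndim != 1 or m.shape != v.shape:
            raise ValueError("values and mask must be 1-D and equally long")
        if not np.all(np.isfinite(v[m])):
            raise ValueError("masked nodes must carry finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)


def _map_values(m) -> np.ndarray:
    if isinstance(m, AnnotationMap):
        return np.asarray(m.values, float)
    if isinstance(m, AbnormalityMap):
        return np.asarray(m.values, float)
    return np.asarray(m, float)


def spatial_correlation(map1, map2, mask: np.ndarray | None = None) -> float:
    """Pearson correlation between two node maps over the evaluated nodes."""
    a = _map_values(map1)
    b = _map_values(map2)
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    if mask is not None:
        mask = np.asarray(mask, bool)
        a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 nodes to correlate maps")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map; spatial correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _correlogram(coords: np.ndarray, values: np.ndarray, bins: int = 6):
    """Lag-binned spatial correlation profile (Moran-type correlogram)."""
    z = (values - values.mean()) / values.std()
    iu = np.triu_indices(len(values), k=1)
    d = np.sqrt(np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1))[iu]
    prod = (z[:, None] * z[None, :])[iu]
    edges = np.quantile(d, np.linspace(0, 1, bins + 1))
    edges[-1] += 1e-9
    which = np.digitize(d, edges) - 1
    prof = np.array([prod[which == b].mean() if np.any(which == b) else 0.0
                     for b in range(bins)])
    return prof


def _fit_smoothing_scale(coords: np.ndarray, values: np.ndarray,
                         rng: np.random.Generator, bins: int = 6) -> float:
    """Pick the kernel scale whose re-smoothed shuffles best match the map's correlogram."""
    from .synthetic import _smooth_field

    target = _correlogram(coords, values, bins)
    span = np.ptp(np.linalg.norm(coords - coords.mean(0), axis=1))
    scales = np.concatenate([[0.0], np.geomspace(max(span, 1.0) / 50, max(span, 1.0), 8)])
    best, best_err = 0.0, np.inf
    for s in scales:
        profs = []
        for _ in range(4):
            surr = _smooth_field(coords, rng.permutation(values), s)
            if surr.std() == 0:
                continue
            profs.append(_correlogram(coords, surr, bins))
        if not profs:
            continue
        err = float(np.sum((np.mean(profs, axis=0) - target) ** 2))
        if err < best_err:
            best, best_err = s, err
    return best


def permutation_null_pvalue(
    map1,
    map2,
    n_perm: int = 5000,
    null_kind: str = "label_shuffle",
    seed: int | np.random.Generator | None = None,
    coords: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Two-sided permutation p-value for the spatial correlation of two maps.

    ``label_shuffle`` permutes the node assignment of ``map2`` (preserving
    its value multiset exactly); ``autocorr_preserving`` re-smooths shuffled
    values with a Gaussian kernel whose scale is fitted to ``map2``'s
    empirical correlogram, yielding surrogates with matched distance-decay
    of spatial correlation (requires ``coords``).
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS} for a stable p-value")
    if null_kind not in ("label_shuffle", "autocorr_preserving"):
        raise ValueError("null_kind must be 'label_shuffle' or 'autocorr_preserving'")
    rng = np.random.default_rng(seed)
    a = _map_values(map1)
    b = _map_values(map2)
    r_obs = spatial_correlation(a, b, mask=mask)

    scale = None
    if null_kind == "autocorr_preserving":
        if coords is None:
            raise ValueError("autocorr_preserving null requires node coordinates")
        scale = _fit_smoothing_scale(np.asarray(coords, float), b, rng)

    from .synthetic import _smooth_field

    null = np.empty(n_perm)
    for i in range(n_perm):
        surr = rng.permutation(b)
        if null_kind == "autocorr_preserving" and scale and scale > 0:
            surr = _smooth_field(np.asarray(coords, float), surr, scale)
        if (surr if mask is None else surr[np.asarray(mask, bool)]).std() == 0:
            null[i] = 0.0
            continue
        null[i] = spatial_correlation(a, surr, mask=mask)
    p = (1.0 + np.sum(np.abs(null) >= abs(r_obs))) / (1.0 + n_perm)
    return float(p), null


def associate_all(
    map1,
    annotation_maps,
    n_perm: int = 5000,
    null_kind: str = "label_shuffle",
    seed: int | np.random.Generator | None = None,
    coords: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlate an abnormality map with every annotation map; FDR across maps."""
    rng = np.random.default_rng(seed)
    rows = []
    for ann in annotation_maps:
        r = spatial_correlation(map1, ann, mask=mask)
        p, _ = permutation_null_pvalue(
            map1, ann, n_perm=n_perm, null_kind=null_kind, seed=rng,
            coords=coords, mask=mask,
        )
        name = ann.name if isinstance(ann, AnnotationMap) else str(len(rows))
        rows.append({"map": name, "r": r, "p_perm": p})
    out = pd.DataFrame(rows, columns=["map", "r", "p_perm"])
    out["q"] = fdr_bh(out["p_perm"].to_numpy()) if len(out) else np.nan
    return out


def differential_expression_by_region(
    expr: ExpressionMatrix,
    region,
    n_perm: int = 5000,
    min_samples: int = 5,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Region-versus-background differential expression by permutation.

    For each gene, ``delta`` is the mean expression inside the region minus
    the mean over the background (all other nodes).  The null redraws random
    node sets of the same size; the two-sided add-one p-value is adjusted
    across genes by BH-FDR.  Returns the per-gene table and the surviving
    gene list (q < ``alpha``).
    """
    region = np.asarray(region, int)
    values = expr.values
    n_nodes, n_genes = values.shape
    if len(region) < min_samples:
        raise ValueError(
            f"region has {len(region)} nodes; at least min_samples={min_samples} required"
        )
    if len(region) >= n_nodes:
        raise ValueError("region covers the whole parcellation; no background remains")
    if len(np.unique(region)) != len(region):
        raise ValueError("region nodes must be unique")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}")
    rng = np.random.default_rng(seed)

    in_region = np.zeros(n_nodes, bool)
    in_region[region] = True
    col_sum = values.sum(axis=0)
    k = len(region)

    def deltas(mask: np.ndarray) -> np.ndarray:
        s = values[mask].sum(axis=0)
        return s / k - (col_sum - s) / (n_nodes - k)

    d_obs = deltas(in_region)
    exceed = np.ones(n_genes)  # add-one numerator
    for _ in range(n_perm):
        perm_mask = np.zeros(n_nodes, bool)
        perm_mask[rng.choice(n_nodes, size=k, replace=False)] = True
        exceed += np.abs(deltas(perm_mask)) >= np.abs(d_obs)
    p = exceed / (1.0 + n_perm)
    q = fdr_bh(p)
    table = pd.DataFrame(
        {"gene": list(expr.gene_ids), "delta": d_obs, "p": p, "q": q}
    )
    surviving = table.loc[table["q"] < alpha, "gene"].tolist()
    return table, surviving


__all__ = [
    "AbnormalityMap",
    "associate_all",
    "differential_expression_by_region",
    "permutation_null_pvalue",
    "spatial_correlation",
]
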