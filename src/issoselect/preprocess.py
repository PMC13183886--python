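"""Preprocessing chain for clinical tables.

Order follows the study pipeline: KNN/mode imputation, min-max
normalization, one-hot encoding, z-score outlier reporting, class balancing
by SMOTE (training folds only — applied downstream, not here), and pruning
of highly correlated columns.  Every transform is fit on training data only
and stores its learned parameters so it can be re-applied to held-out rows;
all transforms serialize to a JSON-compatible dict for exact re-application.

Outliers are reported, never auto-removed: extreme but clinically plausible
values (a very high cholesterol, say) carry signal.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.neighbors import NearestNeighbors

from .config import PreprocessConfig
from .dataio import Dataset, FeatureKind, numeric
from .errors import DegenerateColumnError, ImputeError, SmoteError

__all__ = [
    "impute",
    "minmax_fit_apply",
    "one_hot",
    "flag_outliers",
    "prune_correlated",
    "smote",
    "Preprocessor",
]


def _fingerprint(x: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(x).tobytes()).hexdigest()[:12]


class FittedTransform:
    """Base: a transform with learned parameters and a deterministic apply."""

    kind: str = ""

    def apply(self, data: Dataset) -> Dataset:  # pragma: no cover - abstract
        raise NotImplementedError

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            if isinstance(v, FeatureKind):
                return {"kind": v.kind, "levels": v.levels}
            return v

        return {"kind": self.kind, **{k: conv(v) for k, v in vars(self).items()}}


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class ImputeTransform(FittedTransform):
    kind = "impute"

    def __init__(self, k, numeric_cols, col_min, col_max, donor_scaled,
                 donor_values, modes, fingerprint):
        self.k = k
        self.numeric_cols = numeric_cols
        self.col_min = col_min
        self.col_max = col_max
        self.donor_scaled = donor_scaled  # scaled complete numeric fit block
        self.donor_values = donor_values  # imputed numeric fit values
        self.modes = modes  # categorical col index -> mode level
        self.fingerprint = fingerprint

    def _scale(self, block: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        span = np.where(span == 0, 1.0, span)
        return (block - self.col_min) / span

    def apply(self, data: Dataset) -> Dataset:
        out = data.copy()
        for j, mode in self.modes.items():
            col = out.features[:, j]
            col[np.isnan(col)] = mode
        num = self.numeric_cols
        if num:
            block = out.features[:, num]
            miss_rows = np.where(np.isnan(block).any(axis=1))[0]
            if len(miss_rows):
                scaled = self._scale(block)
                dist = nan_euclidean_distances(scaled[miss_rows], self.donor_scaled)
                for r, i in enumerate(miss_rows):
                    order = np.argsort(dist[r], kind="stable")
                    order = order[np.isfinite(dist[r][order])]
                    k_eff = min(self.k, len(order))
                    if k_eff == 0:
                        raise ImputeError("no usable donor rows for imputation")
                    nn = order[:k_eff]
                    for c in np.where(np.isnan(block[i]))[0]:
                        block[i, c] = self.donor_values[nn, c].mean()
                out.features[:, num] = block
        return out


def impute(data: Dataset, k: int = 5) -> tuple[Dataset, ImputeTransform]:
    """Fill missing cells: numeric by K-nearest-neighbour mean, categorical by mode.

    Neighbour distances are Euclidean over mutually observed numeric columns
    after min-max scaling, so columns with large ranges do not dominate.
    Donors for a cell are the fit rows where that cell is observed; ``k`` is
    clamped (with a warning) when fewer donors exist.
    """
    if k < 1:
        raise ImputeError("k must be >= 1")
    out = data.copy()
    X = out.features

    modes: dict[int, float] = {}
    for j in out.categorical_columns():
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            raise ImputeError(f"column {out.feature_names[j]!r} is entirely missing")
        levels, counts = np.unique(obs, return_counts=True)
        modes[j] = float(levels[np.argmax(counts)])  # ties -> smallest level
        col[np.isnan(col)] = modes[j]

    num = out.numeric_columns()
    col_min = np.zeros(len(num))
    col_max = np.ones(len(num))
    if num:
        block = X[:, num]
        for i, j in enumerate(num):
            obs = block[:, i][~np.isnan(block[:, i])]
            if len(obs) == 0:
                raise ImputeError(f"column {out.feature_names[j]!r} is entirely missing")
            col_min[i], col_max[i] = obs.min(), obs.max()
        span = np.where(col_max - col_min == 0, 1.0, col_max - col_min)
        scaled = (block - col_min) / span
        dist = None
        for i in range(block.shape[1]):
            miss = np.where(np.isnan(block[:, i]))[0]
            if len(miss) == 0:
                continue
            if dist is None:
                dist = nan_euclidean_distances(scaled, scaled)
                np.fill_diagonal(dist, np.inf)
            donors = np.where(~np.isnan(block[:, i]))[0]
            for r in miss:
                d = dist[r, donors]
                usable = donors[np.isfinite(d)]
                d = d[np.isfinite(d)]
                k_eff = min(k, len(usable))
                if k_eff == 0:
                    raise ImputeError("no usable donor rows for imputation")
                if k_eff < k:
                    warnings.warn(
                        f"k clamped to {k_eff} available donors", stacklevel=2
                    )
                nn = usable[np.argsort(d, kind="stable")[:k_eff]]
                block[r, i] = block[nn, i].mean()
        X[:, num] = block

    donor_scaled = (
        (X[:, num] - col_min) / np.where(col_max - col_min == 0, 1.0, col_max - col_min)
        if num
        else np.empty((len(X), 0))
    )
    tr = ImputeTransform(
        k, num, col_min, col_max, donor_scaled, X[:, num].copy(), modes,
        _fingerprint(data.features),
    )
    return out, tr


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

class MinMaxTransform(FittedTransform):
    kind = "minmax"

    def __init__(self, columns, col_min, col_max, fingerprint):
        self.columns = columns
        self.col_min = col_min
        self.col_max = col_max
        self.fingerprint = fingerprint

    def apply(self, data: Dataset) -> Dataset:
        out = data.copy()
        for i, j in enumerate(self.columns):
            out.features[:, j] = (out.features[:, j] - self.col_min[i]) / (
                self.col_max[i] - self.col_min[i]
            )
        return out


def minmax_fit_apply(
    data: Dataset, columns: list[int] | None = None
) -> tuple[Dataset, MinMaxTransform]:
    """Map each numeric column by (x - min)/(max - min); fit values land in [0, 1].

    Stored min/max are reused on new data (values may leave [0, 1]; no
    clipping).  A constant column raises :class:`DegenerateColumnError`.
    """
    if columns is None:
        columns = data.numeric_columns()
    lo = np.empty(len(columns))
    hi = np.empty(len(columns))
    for i, j in enumerate(columns):
        col = data.features[:, j]
        lo[i], hi[i] = np.nanmin(col), np.nanmax(col)
        if hi[i] == lo[i]:
            raise DegenerateColumnError(
                f"column {data.feature_names[j]!r} is constant; cannot min-max scale"
            )
    tr = MinMaxTransform(list(columns), lo, hi, _fingerprint(data.features))
    return tr.apply(data), tr


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------

class OneHotTransform(FittedTransform):
    kind = "onehot"

    def __init__(self, levels_by_col, feature_names, feature_kinds, fingerprint):
        self.levels_by_col = levels_by_col  # original col idx -> level tuple
        self.feature_names = feature_names  # original names
        self.feature_kinds = feature_kinds
        self.fingerprint = fingerprint

    def apply(self, data: Dataset) -> Dataset:
        blocks: list[np.ndarray] = []
        names: list[str] = []
        kinds: list[FeatureKind] = []
        group_map: dict[int, tuple[int, ...]] = {}
        col = 0
        for g in sorted(data.group_map):
            (j,) = data.group_map[g]  # encoding precedes any other regrouping
            if j in self.levels_by_col:
                levels = self.levels_by_col[j]
                vals = data.features[:, j]
                block = np.zeros((data.n_samples, len(levels)))
                matched = np.zeros(data.n_samples, dtype=bool)
                for li, lvl in enumerate(levels):
                    hit = vals == lvl
                    block[hit, li] = 1.0
                    matched |= hit
                if not matched.all():
                    warnings.warn(
                        f"unseen level(s) in column {data.feature_names[j]!r}; "
                        "encoded as all-zero block",
                        stacklevel=2,
                    )
                blocks.append(block)
                names.extend(
                    f"{data.feature_names[j]}={lvl:g}" for lvl in levels
                )
                kinds.extend([numeric()] * len(levels))
                group_map[g] = tuple(range(col, col + len(levels)))
                col += len(levels)
            else:
                blocks.append(data.features[:, [j]])
                names.append(data.feature_names[j])
                kinds.append(data.feature_kinds[j])
                group_map[g] = (col,)
                col += 1
        return Dataset(
            np.hstack(blocks), names, kinds, data.target.copy(),
            group_map, list(data.group_names),
        )


def one_hot(data: Dataset) -> tuple[Dataset, OneHotTransform]:
    """Replace each categorical column by one indicator column per level.

    Levels come from the declared kind when present, otherwise from the fit
    data.  The group map is updated so all indicators of one clinical
    feature share its group; unseen levels at apply time become an all-zero
    block with a warning.
    """
    levels_by_col: dict[int, tuple[float, ...]] = {}
    for j in data.categorical_columns():
        kind = data.feature_kinds[j]
        if kind.levels:
            levels = kind.levels
        else:  # pragma: no cover - kinds always carry levels
            levels = tuple(np.unique(data.features[:, j]))
        levels_by_col[j] = tuple(float(v) for v in levels)
    tr = OneHotTransform(
        levels_by_col, list(data.feature_names), list(data.feature_kinds),
        _fingerprint(data.features),
    )
    return tr.apply(data), tr


# ---------------------------------------------------------------------------
# outlier reporting
# ---------------------------------------------------------------------------

def flag_outliers(
    data: Dataset, column: int | str, threshold: float = 3.0
) -> np.ndarray:
    """Per-row flags |x - mean| / sd > threshold (strict) for one numeric column.

    Flagged rows are reported for review, not removed.
    """
    j = data.feature_names.index(column) if isinstance(column, str) else column
    col = data.features[:, j]
    sd = np.nanstd(col)
    if sd == 0:
        raise DegenerateColumnError(
            f"column {data.feature_names[j]!r} has zero variance"
        )
    z = np.abs(col - np.nanmean(col)) / sd
    return np.nan_to_num(z, nan=0.0) > threshold


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------

class CorrPruneTransform(FittedTransform):
    kind = "corrprune"

    def __init__(self, threshold, retained, removed, removed_names, fingerprint):
        self.threshold = threshold
        self.retained = retained
        self.removed = removed
        self.removed_names = removed_names
        self.fingerprint = fingerprint

    def apply(self, data: Dataset) -> Dataset:
        keep = list(self.retained)
        remap = {old: new for new, old in enumerate(keep)}
        group_map = {}
        for g, cols in data.group_map.items():
            left = tuple(remap[c] for c in cols if c in remap)
            if left:
                group_map[g] = left
        return Dataset(
            data.features[:, keep],
            [data.feature_names[c] for c in keep],
            [data.feature_kinds[c] for c in keep],
            data.target.copy(),
            group_map,
            list(data.group_names),
        )


def prune_correlated(
    data: Dataset, threshold: float = 0.85
) -> tuple[Dataset, CorrPruneTransform]:
    """Greedily drop one member of each column pair with |Pearson r| > threshold.

    The dropped member is the one with larger mean absolute correlation to
    the remaining columns (the more redundant one); the comparison is
    strict, so a pair at exactly the threshold is kept.
    """
    p = data.n_columns
    if p < 2:
        raise DegenerateColumnError("need at least 2 columns to prune")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data.features, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = list(range(p))
    removed: list[int] = []
    while True:
        sub = np.abs(corr[np.ix_(alive, alive)])
        flat = np.argmax(sub)
        i, j = divmod(flat, len(alive))
        if sub[i, j] <= threshold:
            break
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        # drop the more redundant member; tie -> the later column
        drop_local = j if (mean_j > mean_i or (mean_j == mean_i)) else i
        drop = alive[drop_local]
        removed.append(drop)
        alive.remove(drop)
        if len(alive) < 2:
            break
    tr = CorrPruneTransform(
        threshold,
        sorted(alive),
        sorted(removed),
        [data.feature_names[c] for c in sorted(removed)],
        _fingerprint(data.features),
    )
    return tr.apply(data), tr


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(
    features: np.ndarray,
    target: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample the minority class to the majority count by interpolation.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``,
    ``x`` a minority row and ``x_nn`` one of its ``k`` minority nearest
    neighbours — so every synthetic row is a convex combination of two
    original minority rows.  Already-balanced input is returned unchanged.
    """
    features = np.asarray(features, dtype=float)
    target = np.asarray(target)
    classes, counts = np.unique(target, return_counts=True)
    if len(classes) != 2:
        raise SmoteError("SMOTE needs exactly two classes")
    if counts[0] == counts[1]:
        return features.copy(), target.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise SmoteError("minority class has a single sample; no neighbour exists")
    k_eff = min(k, n_min - 1)
    if k_eff < k:
        warnings.warn(f"smote k clamped to {k_eff} (minority size {n_min})",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    Xm = features[target == minority]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
    n_syn = n_maj - n_min
    base = rng.integers(0, n_min, size=n_syn)
    pick = rng.integers(1, k_eff + 1, size=n_syn)
    u = rng.random(n_syn)
    neighbors = Xm[idx[base, pick]]
    synthetic = Xm[base] + u[:, None] * (neighbors - Xm[base])
    X_out = np.vstack([features, synthetic])
    y_out = np.concatenate([target, np.full(n_syn, minority, dtype=target.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# the fitted chain
# ---------------------------------------------------------------------------

class Preprocessor:
    """The full fitted chain, training-data only, re-applicable to new rows.

    ``fit_transform`` runs impute -> min-max -> one-hot -> outlier report ->
    correlation prune on the training table; SMOTE is deliberately *not*
    part of the chain because it must run inside training folds only (the
    fitness evaluator and the final-model fit apply it themselves).
    """

    def __init__(self, cfg: PreprocessConfig | None = None):
        self.cfg = cfg or PreprocessConfig()
        self.transforms: list[FittedTransform] = []
        self.outlier_report: dict[str, np.ndarray] = {}

    def fit_transform(self, data: Dataset) -> Dataset:
        self.transforms = []
        out, tr = impute(data, self.cfg.knn_k)
        self.transforms.append(tr)
        # outlier z-scores on imputed, pre-normalization values
        self.outlier_report = {
            out.feature_names[j]: flag_outliers(out, j, self.cfg.zscore_threshold)
            for j in out.numeric_columns()
            if np.nanstd(out.features[:, j]) > 0
        }
        out, tr = minmax_fit_apply(out)
        self.transforms.append(tr)
        out, tr = one_hot(out)
        self.transforms.append(tr)
        if self.cfg.prune_correlated:
            out, tr = prune_correlated(out, self.cfg.corr_threshold)
            self.transforms.append(tr)
        return out

    def transform(self, data: Dataset) -> Dataset:
        if not self.transforms:
            raise RuntimeError("Preprocessor not fitted")
        out = data
        for tr in self.transforms:
            out = tr.apply(out)
        return out

    def to_dict(self) -> dict:
        return {
            "config": vars(self.cfg),
            "transforms": [tr.to_dict() for tr in self.transforms],
            "n_outliers_flagged": {
                name: int(flags.sum()) for name, flags in self.outlier_report.items()
            },
        }
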