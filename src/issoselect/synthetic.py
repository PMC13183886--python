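"""Synthetic generator for heart-disease-like tables with known ground truth.

Emulates the UCI Cleveland schema: mixed numeric/categorical predictors, a
binary diagnosis target driven by a small planted informative subset through
a logistic model, optional missing-completely-at-random cells marked like
the "?" cells of the real file, controllable prevalence and inter-feature
correlation.  Because the planted subset is known, every pipeline stage —
imputation, balancing, wrapper selection, attribution — can be tested
against ground truth without downloading the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .dataio import Dataset, FeatureKind, categorical, numeric
from .errors import SpecError

__all__ = ["SyntheticSpec", "generate", "inject_missing", "PLANTED_SPEC", "uci_like_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic table.

    ``effects`` are log-odds per standardized unit for numeric informative
    columns, and log-odds per standardized level code for categorical ones.
    ``correlated_pairs`` entries ``(i, j, r)`` request Pearson correlation r
    between two *numeric* columns (induced via Cholesky factorisation of the
    implied correlation matrix).
    """

    n: int = 600
    m: int = 20
    informative: tuple[int, ...] = (0, 1, 2, 3, 4)
    effects: tuple[float, ...] = (1.2, -1.0, 1.0, 0.9, -0.8)
    categorical_levels: dict[int, int] = field(default_factory=dict)
    prevalence: float = 0.5
    missing_rate: float = 0.0
    correlated_pairs: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2 or self.m < 1:
            raise SpecError("need n >= 2 and m >= 1")
        if len(self.informative) != len(self.effects):
            raise SpecError("informative and effects must have equal length")
        if not set(self.informative) <= set(range(self.m)):
            raise SpecError("informative indices out of range")
        if not 0.0 < self.prevalence < 1.0:
            raise SpecError("prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must be in [0, 1)")
        for i, j, r in self.correlated_pairs:
            if i in self.categorical_levels or j in self.categorical_levels:
                raise SpecError("correlated pairs must join numeric columns")
            if not -1.0 < r < 1.0:
                raise SpecError("pair correlation must be in (-1, 1)")


#: Frozen default fixture: 20 predictors, 5 informative with absolute
#: log-odds effects >= 0.8, a few categorical noise columns mimicking the
#: clinical schema, balanced classes.  Used throughout the test suite so
#: results are stable run to run.
PLANTED_SPEC = SyntheticSpec(
    n=600,
    m=20,
    informative=(0, 1, 2, 3, 4),
    effects=(1.2, -1.0, 1.0, 0.9, -0.8),
    categorical_levels={10: 4, 11: 3, 12: 2},
    prevalence=0.5,
    seed=0,
)


def uci_like_spec(n: int = 303, seed: int = 0, missing_rate: float = 0.0) -> SyntheticSpec:
    """A 13-predictor spec mirroring the clinical schema's kind layout.

    Categorical level counts follow the real table (4-level chest-pain,
    3-level resting ECG / slope / thalassemia, binary sex / fbs / exang);
    four planted informative predictors stand in for the clinically dominant
    ones (chest pain, ST depression, vessel count, thalassemia).  Prevalence
    0.46 reflects the slight class imbalance of the Cleveland file.
    """
    return SyntheticSpec(
        n=n,
        m=13,
        informative=(2, 9, 11, 12),
        effects=(1.1, 1.0, 1.2, -0.9),
        categorical_levels={1: 2, 2: 4, 5: 2, 6: 3, 8: 2, 10: 3, 12: 3},
        prevalence=0.46,
        missing_rate=missing_rate,
        correlated_pairs=(),
        seed=seed,
    )


def _numeric_block(spec: SyntheticSpec, cols: list[int], rng: np.random.Generator) -> np.ndarray:
    """Correlated standard-normal block over the numeric columns."""
    k = len(cols)
    pos = {c: i for i, c in enumerate(cols)}
    corr = np.eye(k)
    for i, j, r in spec.correlated_pairs:
        corr[pos[i], pos[j]] = corr[pos[j], pos[i]] = r
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise SpecError("requested correlation matrix is not positive definite") from exc
    z = rng.standard_normal((spec.n, k))
    return z @ chol.T


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw one table from ``spec`` (deterministic given ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    numeric_cols = [c for c in range(spec.m) if c not in spec.categorical_levels]
    X = np.empty((spec.n, spec.m))
    X[:, numeric_cols] = _numeric_block(spec, numeric_cols, rng)

    kinds: list[FeatureKind] = [None] * spec.m  # type: ignore[list-item]
    for c in numeric_cols:
        kinds[c] = numeric()
    for c, n_levels in sorted(spec.categorical_levels.items()):
        levels = np.arange(n_levels, dtype=float)
        probs = rng.dirichlet(np.full(n_levels, 4.0))
        X[:, c] = rng.choice(levels, size=spec.n, p=probs)
        kinds[c] = categorical(*levels)

    # linear predictor on standardized column scores
    eta = np.zeros(spec.n)
    for c, eff in zip(spec.informative, spec.effects):
        col = X[:, c]
        sd = col.std()
        if sd == 0:
            raise SpecError(f"informative column {c} is constant under this seed")
        eta += eff * (col - col.mean()) / sd

    def gap(intercept: float) -> float:
        return float(expit(intercept + eta).mean()) - spec.prevalence

    intercept = brentq(gap, -40.0, 40.0)
    y = rng.binomial(1, expit(intercept + eta))

    names = [f"x{c}" for c in range(spec.m)]
    data = Dataset(X, names, kinds, y)
    if spec.missing_rate > 0:
        data = inject_missing(data, spec.missing_rate, int(rng.integers(2**31)))
    return data


def inject_missing(data: Dataset, rate: float, seed: int) -> Dataset:
    """Blank predictor cells independently with probability ``rate`` (MCAR).

    The target column is never masked.  ``rate = 0`` returns an identical
    copy.
    """
    if not 0.0 <= rate < 1.0:
        raise SpecError("rate must be in [0, 1)")
    out = data.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.features.shape) < rate
    out.features[mask] = np.nan
    return out
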