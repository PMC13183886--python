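"""Binary wrapper feature selection by improved squirrel search (ISSO/ESSO).

Candidate feature subsets are squirrels: continuous positions in the unit
hypercube, thresholded into binary masks (a bit selects one *group* — all
one-hot columns of one original clinical feature — by default).  Fitness is
the composite wrapper objective

    fitness = alpha * accuracy - beta * (n_selected / m_total)

with accuracy the stratified cross-validated accuracy of a random forest
restricted to the masked columns.  The "improved" mechanics over the base
squirrel search are: a gliding distance that decays linearly over
iterations, a per-squirrel predator probability forcing random relocation,
a seasonal stagnation check that redraws the worst half of the population,
and small-probability bit-flip mutation.  The global best (hickory) squirrel
is exempt from predator and seasonal relocation, so the best-ever fitness
trace is non-decreasing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import ISSOConfig, PipelineConfig
from .dataio import Dataset
from .errors import StateError, ValidationError
from .preprocess import smote as smote_balance

__all__ = [
    "fitness",
    "FitnessRecord",
    "Squirrel",
    "CVMaskEvaluator",
    "initialize_population",
    "assign_roles",
    "glide_step",
    "predator_event",
    "seasonal_check",
    "mutate",
    "run_isso",
    "random_search",
    "exhaustive_search",
    "select_features",
]

HICKORY, OAK, NORMAL = "hickory", "oak", "normal"


def fitness(
    accuracy: float, n_selected: int, m_total: int, alpha: float, beta: float
) -> float:
    """Composite wrapper objective: reward accuracy, penalise subset size.

    Pure arithmetic, exact: ``alpha * accuracy - beta * (n_selected / m_total)``.
    An empty subset is invalid.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValidationError(f"accuracy must be in [0, 1], got {accuracy}")
    if n_selected < 1:
        raise ValidationError("empty feature subset has no defined fitness")
    if n_selected > m_total:
        raise ValidationError("n_selected exceeds m_total")
    return alpha * accuracy - beta * (n_selected / m_total)


@dataclass(frozen=True)
class FitnessRecord:
    accuracy: float
    n_selected: int
    m_total: int
    fitness: float
    fold_scores: tuple[float, ...] = ()


@dataclass
class Squirrel:
    position: np.ndarray
    mask: np.ndarray
    record: FitnessRecord | None = None
    role: str | None = None

    @property
    def fitness(self) -> float | None:
        return None if self.record is None else self.record.fitness

    def clone(self) -> "Squirrel":
        return Squirrel(self.position.copy(), self.mask.copy(), self.record, self.role)


def derive_mask(position: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a position into a mask; repair all-zero masks in place.

    Repair sets the bit of the largest coordinate and lifts that coordinate
    to the threshold so mask and position stay consistent.
    """
    mask = (position >= threshold).astype(np.int8)
    if mask.sum() == 0:
        j = int(np.argmax(position))
        mask[j] = 1
        position[j] = threshold
    return mask


# ---------------------------------------------------------------------------
# fitness evaluation
# ---------------------------------------------------------------------------

class CVMaskEvaluator:
    """Memoized cross-validated random-forest fitness of a feature mask.

    Folds, fold-level SMOTE resamples and the forest seed are fixed at
    construction so every mask is scored under identical conditions and a
    repeated mask costs nothing (results memoized by mask bits).  SMOTE runs
    once per training fold in the full encoded space; candidate masks then
    select columns of the balanced arrays — matching a pipeline that
    balances classes before feature selection.
    """

    def __init__(
        self,
        data: Dataset,
        cfg: PipelineConfig,
        row_indices: np.ndarray | None = None,
    ):
        self.cfg = cfg
        self.data = data
        self.granularity = cfg.optimizer.granularity
        self.n_features = (
            data.n_groups if self.granularity == "group" else data.n_columns
        )
        self.row_indices = (
            np.arange(data.n_samples) if row_indices is None else np.asarray(row_indices)
        )
        self._memo: dict[bytes, FitnessRecord] = {}
        self.n_calls = 0
        self._group_keys = sorted(data.group_map)

        ss = np.random.SeedSequence([cfg.seed, 0x5EA50])
        cv_seed, rf_seed, smote_seed = (
            int(s) % (2**31) for s in ss.generate_state(3)
        )
        self._rf_seed = rf_seed
        y = data.target
        skf = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cv_seed)
        self._folds = []
        for f, (tr, va) in enumerate(skf.split(data.features, y)):
            Xtr, ytr = data.features[tr], y[tr]
            if cfg.preprocessing.use_smote and len(np.unique(ytr)) == 2:
                counts = np.bincount(ytr)
                if counts.min() >= 2 and counts[0] != counts[1]:
                    Xtr, ytr = smote_balance(
                        Xtr, ytr, cfg.preprocessing.smote_k,
                        seed=(smote_seed + f) % (2**31),
                    )
            self._folds.append((Xtr, ytr, data.features[va], y[va]))

    @property
    def n_unique_evaluations(self) -> int:
        return len(self._memo)

    def columns_for_mask(self, mask: np.ndarray) -> list[int]:
        if self.granularity == "group":
            groups = [self._group_keys[i] for i in np.flatnonzero(mask)]
            return self.data.columns_for_groups(groups)
        return list(np.flatnonzero(mask))

    def evaluate(self, mask: np.ndarray) -> FitnessRecord:
        mask = np.asarray(mask, dtype=np.int8)
        if mask.sum() == 0:
            raise ValidationError("cannot evaluate an empty mask")
        self.n_calls += 1
        key = mask.tobytes()
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        cols = self.columns_for_mask(mask)
        scores = []
        for Xtr, ytr, Xva, yva in self._folds:
            clf = RandomForestClassifier(
                n_estimators=self.cfg.classifier.n_trees,
                criterion=self.cfg.classifier.criterion,
                bootstrap=self.cfg.classifier.bootstrap,
                max_depth=self.cfg.classifier.max_depth,
                min_samples_split=2,
                random_state=self._rf_seed,
                n_jobs=1,
            )
            clf.fit(Xtr[:, cols], ytr)
            scores.append(float((clf.predict(Xva[:, cols]) == yva).mean()))
        acc = float(np.mean(scores))
        rec = FitnessRecord(
            accuracy=acc,
            n_selected=int(mask.sum()),
            m_total=self.n_features,
            fitness=fitness(
                acc, int(mask.sum()), self.n_features,
                self.cfg.optimizer.alpha, self.cfg.optimizer.beta,
            ),
            fold_scores=tuple(scores),
        )
        self._memo[key] = rec
        return rec


# ---------------------------------------------------------------------------
# squirrel mechanics
# ---------------------------------------------------------------------------

def initialize_population(
    m: int, cfg: ISSOConfig, rng: np.random.Generator | None = None
) -> list[Squirrel]:
    """N positions uniform on [0,1]^m; masks derived and repaired."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pop = []
    for _ in range(cfg.n_squirrels):
        pos = rng.random(m)
        pop.append(Squirrel(pos, derive_mask(pos, cfg.binarize_threshold)))
    return pop


def _rank_key(s: Squirrel, idx: int):
    return (-s.record.fitness, s.record.n_selected, idx)


def assign_roles(population: list[Squirrel]) -> list[Squirrel]:
    """Sort by fitness (ties: fewer features, then index) and assign roles.

    Rank 1 is hickory (global best), ranks 2..ceil(N/2) oak, the rest
    normal.  Returns the population in rank order.
    """
    for s in population:
        if s.record is None:
            raise StateError("assign_roles requires evaluated fitness")
    order = sorted(range(len(population)), key=lambda i: _rank_key(population[i], i))
    ranked = [population[i] for i in order]
    n_upper = math.ceil(len(ranked) / 2)
    for rank, s in enumerate(ranked, start=1):
        s.role = HICKORY if rank == 1 else OAK if rank <= n_upper else NORMAL
    return ranked


def glide_step(s: Squirrel, target: Squirrel, t: int, cfg: ISSOConfig) -> Squirrel:
    """Move toward a better squirrel with an iteration-decaying step.

    ``dg(t)`` decays linearly from ``dg_max`` to ``dg_min`` over the run so
    early iterations explore and late ones refine; the result is clipped to
    the unit cube and the mask re-derived.
    """
    T = cfg.n_iterations
    frac = 0.0 if T <= 1 else t / (T - 1)
    dg = cfg.dg_max - (cfg.dg_max - cfg.dg_min) * frac
    pos = np.clip(
        s.position + dg * cfg.glide_constant * (target.position - s.position),
        0.0, 1.0,
    )
    out = Squirrel(pos, derive_mask(pos, cfg.binarize_threshold))
    out.role = s.role
    return out


def predator_event(
    s: Squirrel, cfg: ISSOConfig, rng: np.random.Generator
) -> Squirrel:
    """With probability p_predator, relocate to a fresh uniform position.

    The hickory squirrel is exempt (elitism).
    """
    if s.role != HICKORY and rng.random() < cfg.p_predator:
        pos = rng.random(len(s.position))
        out = Squirrel(pos, derive_mask(pos, cfg.binarize_threshold))
        out.role = s.role
        return out
    return s


def mutate(
    mask: np.ndarray, p_m: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit independently with probability p_m; repair all-zero."""
    mask = np.asarray(mask, dtype=np.int8)
    flips = rng.random(len(mask)) < p_m
    out = mask ^ flips.astype(np.int8)
    if out.sum() == 0:
        out[int(rng.integers(len(out)))] = 1
    return out


def _mutate_squirrel(s: Squirrel, cfg: ISSOConfig, rng: np.random.Generator) -> None:
    """Bit-flip mutation keeping position and mask consistent."""
    flips = np.flatnonzero(rng.random(len(s.mask)) < cfg.p_mutation)
    if len(flips) == 0:
        return
    thr = cfg.binarize_threshold
    for j in flips:
        if s.mask[j]:
            s.mask[j] = 0
            s.position[j] = rng.uniform(0.0, thr) if thr > 0 else 0.0
        else:
            s.mask[j] = 1
            s.position[j] = rng.uniform(thr, 1.0)
    if s.mask.sum() == 0:
        j = int(np.argmax(s.position))
        s.mask[j] = 1
        s.position[j] = max(s.position[j], thr)
    s.record = None


def seasonal_check(
    population: list[Squirrel],
    best_history: list[float],
    cfg: ISSOConfig,
    rng: np.random.Generator,
) -> tuple[list[Squirrel], bool]:
    """Stagnation check: if the best fitness did not improve over the last
    season window, redraw the worst floor(N/2) squirrels uniformly.

    The hickory squirrel is always retained.  Returns (population,
    relocated?).
    """
    w = cfg.season_interval
    if len(best_history) < w + 1:
        return population, False
    if best_history[-1] > best_history[-1 - w]:
        return population, False
    ranked = sorted(
        range(len(population)), key=lambda i: _rank_key(population[i], i)
    )
    n_reloc = len(population) // 2
    for i in ranked[len(population) - n_reloc:]:
        s = population[i]
        if s.role == HICKORY:  # pragma: no cover - hickory ranks first
            continue
        s.position = rng.random(len(s.position))
        s.mask = derive_mask(s.position, cfg.binarize_threshold)
        s.record = None
    return population, True


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _evaluate_all(population: list[Squirrel], evaluator) -> None:
    for s in population:
        if s.record is None:
            s.record = evaluator.evaluate(s.mask)


def _better(rec: FitnessRecord, best: FitnessRecord | None) -> bool:
    if best is None:
        return True
    if rec.fitness != best.fitness:
        return rec.fitness > best.fitness
    return rec.n_selected < best.n_selected


def run_isso(
    evaluator, cfg: ISSOConfig
) -> tuple[np.ndarray, FitnessRecord, list[float]]:
    """Run the improved squirrel search against a mask evaluator.

    Returns the best-ever mask, its fitness record, and the per-iteration
    best-ever fitness history (entry 0 is the initial population; the trace
    is non-decreasing by elitism).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = evaluator.n_features
    pop = initialize_population(m, cfg, rng)
    _evaluate_all(pop, evaluator)

    best_mask: np.ndarray | None = None
    best_rec: FitnessRecord | None = None
    for s in pop:
        if _better(s.record, best_rec):
            best_rec, best_mask = s.record, s.mask.copy()
    history = [best_rec.fitness]

    for t in range(cfg.n_iterations):
        pop = assign_roles(pop)
        hickory = pop[0]
        oaks = [s for s in pop if s.role == OAK]
        moved = [hickory.clone()]
        for s in pop[1:]:
            if s.role == OAK:
                target = hickory
            else:  # normal: random oak w.p. 0.5, else hickory
                if oaks and rng.random() < 0.5:
                    target = oaks[int(rng.integers(len(oaks)))]
                else:
                    target = hickory
            moved.append(glide_step(s, target, t, cfg))
        pop = [predator_event(s, cfg, rng) for s in moved]
        for s in pop:
            before = s.mask.copy()
            _mutate_squirrel(s, cfg, rng)
            if s.record is not None and not np.array_equal(before, s.mask):
                s.record = None
        _evaluate_all(pop, evaluator)
        for s in pop:
            if _better(s.record, best_rec):
                best_rec, best_mask = s.record, s.mask.copy()
        history.append(best_rec.fitness)
        if (t + 1) % cfg.season_interval == 0:
            pop, relocated = seasonal_check(pop, history, cfg, rng)
            if relocated:
                _evaluate_all(pop, evaluator)
                for s in pop:
                    if _better(s.record, best_rec):
                        best_rec, best_mask = s.record, s.mask.copy()
                history[-1] = best_rec.fitness
    return best_mask, best_rec, history


def random_search(
    evaluator, budget: int, seed: int, threshold: float = 0.5
) -> tuple[np.ndarray, FitnessRecord, list[float]]:
    """Uniform random masks at the same evaluation budget (baseline)."""
    rng = np.random.default_rng(seed)
    m = evaluator.n_features
    best_mask = best_rec = None
    history = []
    for _ in range(budget):
        pos = rng.random(m)
        mask = derive_mask(pos, threshold)
        rec = evaluator.evaluate(mask)
        if _better(rec, best_rec):
            best_rec, best_mask = rec, mask.copy()
        history.append(best_rec.fitness)
    return best_mask, best_rec, history


def exhaustive_search(
    evaluator, m_limit: int = 15
) -> tuple[np.ndarray, FitnessRecord]:
    """Evaluate every non-empty mask; the testing oracle for small m.

    Ties break toward fewer selected features, then lexicographically
    smaller masks.
    """
    m = evaluator.n_features
    if m > m_limit:
        raise ValidationError(
            f"exhaustive search over 2^{m} masks refused (limit m <= {m_limit})"
        )
    best_mask = best_rec = None
    for bits in itertools.product((0, 1), repeat=m):
        if not any(bits):
            continue
        mask = np.array(bits, dtype=np.int8)
        rec = evaluator.evaluate(mask)
        if best_rec is None or rec.fitness > best_rec.fitness or (
            rec.fitness == best_rec.fitness
            and (
                rec.n_selected < best_rec.n_selected
                or (
                    rec.n_selected == best_rec.n_selected
                    and tuple(mask) < tuple(best_mask)
                )
            )
        ):
            best_rec, best_mask = rec, mask
    return best_mask, best_rec


def select_features(
    data: Dataset, cfg: PipelineConfig, row_indices: np.ndarray | None = None
) -> tuple[np.ndarray, FitnessRecord, list[float], CVMaskEvaluator]:
    """Convenience driver: build the CV evaluator on preprocessed data and
    run the squirrel search.  Returns mask, record, history and the
    evaluator (for audits and reuse)."""
    evaluator = CVMaskEvaluator(data, cfg, row_indices)
    mask, rec, history = run_isso(evaluator, cfg.optimizer)
    return mask, rec, history, evaluator
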