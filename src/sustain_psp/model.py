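"""Piecewise-linear z-score subtype-and-stage mixture model.

The model describes disease progression as an ordered sequence of *events*,
each event being one biomarker (a regional brain volume expressed as a
sign-flipped z-score against controls) reaching a new z-score threshold.
A subject at stage ``k`` of a subtype has passed the first ``k`` events of
that subtype's sequence; the expected z-score of each biomarker follows a
piecewise-linear trajectory through its threshold anchors. Observations are
Gaussian around the trajectory, stages carry a uniform prior, and subjects
are a mixture over ``C`` subtype sequences.

Fitting follows the standard recipe for this model class: greedy
coordinate-ascent over event orderings from many random restarts for a single
sequence, hierarchical cluster splitting with EM refinement for the mixture,
and Metropolis-Hastings sampling over orderings (fractions held fixed) for
positional uncertainty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


class EventGrid:
    """Per-biomarker z-score thresholds plus a maximum z.

    Parameters
    ----------
    biomarkers : sequence of str
        Biomarker names.
    thresholds : sequence of sequences of float
        Strictly increasing z-score thresholds for each biomarker. Each
        threshold is one event; the total number of events ``E`` (= number of
        stages beyond stage 0) is the sum of threshold counts.
    z_max : sequence of float
        The asymptotic z-score each biomarker tends to beyond its last
        threshold (reached at the virtual anchor stage ``E + 1``).
    sigma : sequence of float, optional
        Observation noise SD per biomarker; defaults to 1 (inputs are
        control-referenced z-scores).
    """

    def __init__(self, biomarkers, thresholds, z_max, sigma=None):
        self.biomarkers = [str(b) for b in biomarkers]
        self.thresholds = [np.asarray(t, dtype=float) for t in thresholds]
        self.z_max = np.asarray(z_max, dtype=float)
        n = len(self.biomarkers)
        if not (len(self.thresholds) == len(self.z_max) == n):
            raise ValueError("biomarkers, thresholds and z_max must align")
        if sigma is None:
            sigma = np.ones(n)
        self.sigma = np.asarray(sigma, dtype=float)
        if self.sigma.shape != (n,) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive, one value per biomarker")
        for name, t, zm in zip(self.biomarkers, self.thresholds, self.z_max):
            if t.size == 0:
                raise ValueError(f"{name}: at least one threshold required")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name}: thresholds must be strictly increasing")
            if zm < t[-1]:
                raise ValueError(f"{name}: z_max {zm} below last threshold {t[-1]}")
        # Flat event bookkeeping: event e -> (biomarker index, rank, z value)
        self.event_biomarker = np.concatenate(
            [np.full(t.size, i, dtype=int) for i, t in enumerate(self.thresholds)]
        )
        self.event_rank = np.concatenate(
            [np.arange(t.size) for t in self.thresholds]
        )
        self.event_z = np.concatenate(self.thresholds)
        self.n_events = int(self.event_z.size)
        if self.n_events < 1:
            raise ValueError("grid defines no events")
        # events_of[i]: event indices of biomarker i, in rank order
        self.events_of = [
            np.flatnonzero(self.event_biomarker == i) for i in range(n)
        ]

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_stages(self) -> int:
        """Number of stages including stage 0, i.e. ``E + 1``."""
        return self.n_events + 1

    def event_labels(self) -> list[str]:
        return [
            f"{self.biomarkers[b]}:z{z:g}"
            for b, z in zip(self.event_biomarker, self.event_z)
        ]

    def to_dict(self) -> dict:
        return {
            "biomarkers": self.biomarkers,
            "thresholds": [t.tolist() for t in self.thresholds],
            "z_max": self.z_max.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventGrid":
        return cls(d["biomarkers"], d["thresholds"], d["z_max"], d.get("sigma"))


@dataclass(frozen=True)
class SubtypeSequence:
    """An ordering of all events of a grid (one subtype's trajectory).

    ``order[t]`` is the event occurring at stage ``t + 1``. Within one
    biomarker, lower thresholds must precede higher ones.
    """

    order: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "order", np.asarray(self.order, dtype=int))

    def validate(self, grid: EventGrid) -> None:
        E = grid.n_events
        if sorted(self.order.tolist()) != list(range(E)):
            raise ValueError("order is not a permutation of all events")
        pos = self.positions()
        for evs in grid.events_of:
            if np.any(np.diff(pos[evs]) <= 0):
                raise ValueError(
                    "within-biomarker threshold order violated in sequence"
                )

    def positions(self) -> np.ndarray:
        """positions[e] = stage at which event e occurs (1-based)."""
        pos = np.empty(self.order.size, dtype=int)
        pos[self.order] = np.arange(1, self.order.size + 1)
        return pos

    def labels(self, grid: EventGrid) -> list[str]:
        lab = grid.event_labels()
        return [lab[e] for e in self.order]


# ---------------------------------------------------------------------------
# Trajectories and likelihood
# ---------------------------------------------------------------------------

def trajectory_matrix(grid: EventGrid, order: np.ndarray) -> np.ndarray:
    """Expected z-score ``g_i(k)`` for every biomarker and stage.

    Returns an array of shape ``(n_biomarkers, E + 1)`` with the piecewise
    linear interpolation through the anchors ``(0, 0)``,
    ``(position(e_ir), z_ir)`` and ``(E + 1, z_max_i)``, evaluated at the
    integer stages ``k = 0..E``.
    """
    E = grid.n_events
    pos = np.empty(E, dtype=float)
    pos[order] = np.arange(1, E + 1)
    stages = np.arange(E + 1, dtype=float)
    G = np.empty((grid.n_biomarkers, E + 1))
    for i, evs in enumerate(grid.events_of):
        xp = np.concatenate(([0.0], pos[evs], [E + 1.0]))
        fp = np.concatenate(([0.0], grid.thresholds[i], [grid.z_max[i]]))
        G[i] = np.interp(stages, xp, fp)
    return G


def trajectory_value(sequence: SubtypeSequence, grid: EventGrid,
                     biomarker: int | str, stage: int) -> float:
    """Expected z-score of one biomarker at one stage under a sequence."""
    if isinstance(biomarker, str):
        biomarker = grid.biomarkers.index(biomarker)
    if not 0 <= stage <= grid.n_events:
        raise ValueError(f"stage {stage} outside [0, {grid.n_events}]")
    return float(trajectory_matrix(grid, sequence.order)[biomarker, stage])


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _check_finite(X: np.ndarray, grid: EventGrid) -> None:
    if X.shape[1] != grid.n_biomarkers:
        raise ValueError(
            f"data has {X.shape[1]} biomarkers, grid has {grid.n_biomarkers}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite (or missing) biomarker values")


def _stage_loglik_matrix(X: np.ndarray, G: np.ndarray,
                         sigma: np.ndarray) -> np.ndarray:
    """log P(x_j | S, k) for all subjects j and stages k; shape (n, E+1)."""
    inv2 = 1.0 / sigma**2
    const = -0.5 * X.shape[1] * _LOG_2PI - float(np.sum(np.log(sigma)))
    # Expand the square so the cross term is a single matmul.
    t1 = -0.5 * (X**2 * inv2).sum(axis=1)            # (n,)
    t2 = (X * inv2) @ G                               # (n, E+1)
    t3 = -0.5 * (G**2 * inv2[:, None]).sum(axis=0)    # (E+1,)
    return t1[:, None] + t2 + t3[None, :] + const


def log_stage_likelihood(x, sequence: SubtypeSequence, grid: EventGrid,
                         stage: int) -> float:
    """log P(x | S, k): Gaussian observation model around the trajectory."""
    if not 0 <= stage <= grid.n_events:
        raise ValueError(f"stage {stage} outside [0, {grid.n_events}]")
    X = _as_matrix(x)
    _check_finite(X, grid)
    G = trajectory_matrix(grid, sequence.order)
    return float(_stage_loglik_matrix(X, G, grid.sigma)[0, stage])


def stage_likelihood(x, sequence: SubtypeSequence, grid: EventGrid,
                     stage: int) -> float:
    """P(x | S, k), the density of one subject's panel at one stage."""
    return float(np.exp(log_stage_likelihood(x, sequence, grid, stage)))


def _log_subject_marginal(X: np.ndarray, grid: EventGrid,
                          order: np.ndarray) -> np.ndarray:
    G = trajectory_matrix(grid, order)
    L = _stage_loglik_matrix(X, G, grid.sigma)
    return logsumexp(L, axis=1) - np.log(grid.n_stages)


def subject_marginal(x, sequence: SubtypeSequence, grid: EventGrid) -> float:
    """P(x | S) = (1/(E+1)) sum_k P(x | S, k) — uniform stage prior."""
    X = _as_matrix(x)
    _check_finite(X, grid)
    return float(np.exp(_log_subject_marginal(X, grid, sequence.order)[0]))


@dataclass
class PositionalVariance:
    """Per-subtype matrix M[e, p]: fraction of MCMC samples with event e at
    position p (1-based positions stored at column p - 1)."""

    matrix: np.ndarray
    event_labels: list[str]

    def __post_init__(self):
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("positional variance rows must sum to 1")


@dataclass
class MCMCResult:
    samples: list[np.ndarray]          # per subtype: (n_kept, E) orderings
    positional_variance: list[PositionalVariance]
    acceptance_rate: float
    log_likelihoods: np.ndarray


@dataclass
class SuStaInFit:
    """A fitted mixture of subtype sequences."""

    grid: EventGrid
    sequences: list[SubtypeSequence]
    fractions: np.ndarray
    log_likelihood: float
    seed: int | None = None
    mcmc: MCMCResult | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.size != len(self.sequences):
            raise ValueError("one fraction per sequence required")
        if np.any(self.fractions <= 0) or abs(self.fractions.sum() - 1) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def to_json(self) -> str:
        doc = {
            "grid": self.grid.to_dict(),
            "sequences": [s.order.tolist() for s in self.sequences],
            "sequence_labels": [s.labels(self.grid) for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SuStaInFit":
        doc = json.loads(text)
        grid = EventGrid.from_dict(doc["grid"])
        seqs = [SubtypeSequence(np.asarray(o)) for o in doc["sequences"]]
        return cls(grid, seqs, np.asarray(doc["fractions"]),
                   doc["log_likelihood"], doc.get("seed"))


def _log_mixture_matrix(X: np.ndarray, fit: SuStaInFit) -> np.ndarray:
    """log f_c + log P(x_j | S_c); shape (n, C)."""
    cols = [
        np.log(f) + _log_subject_marginal(X, fit.grid, s.order)
        for f, s in zip(fit.fractions, fit.sequences)
    ]
    return np.column_stack(cols)


def dataset_loglik(X, fit: SuStaInFit) -> float:
    """Total mixture log-likelihood: sum_j log sum_c f_c P(x_j | S_c)."""
    X = _as_matrix(X)
    _check_finite(X, fit.grid)
    return float(logsumexp(_log_mixture_matrix(X, fit), axis=1).sum())


def event_grid_from_data(X, biomarkers, thresholds=(1.0, 2.0, 3.0),
                         quantile: float = 0.95, sigma=None) -> EventGrid:
    """Data-driven default grid from a patient baseline z-score matrix.

    Each biomarker keeps the candidate thresholds lying below the given
    quantile of its observed patient z-scores (at least the first), and its
    z_max is that quantile floored at the last kept threshold. This yields
    the mixed two-or-three-events-per-region pattern seen when severity
    ceilings differ across regions.
    """
    X = _as_matrix(X)
    q = np.quantile(X, quantile, axis=0)
    ths, zmax = [], []
    for qi in q:
        kept = [t for t in thresholds if t < qi]
        if not kept:
            kept = [float(thresholds[0])]
        ths.append(kept)
        zmax.append(max(float(qi), kept[-1]))
    return EventGrid(biomarkers, ths, zmax, sigma)


# ---------------------------------------------------------------------------
# Greedy sequence optimization
# ---------------------------------------------------------------------------

def _random_valid_order(grid: EventGrid, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation, then within-biomarker ranks sorted."""
    key = rng.random(grid.n_events)
    for evs in grid.events_of:
        key[evs] = np.sort(key[evs])
    return np.argsort(key, kind="stable")


def _weighted_objective(X, grid, order, weights):
    lm = _log_subject_marginal(X, grid, order)
    return float(weights @ lm) if weights is not None else float(lm.sum())


def _valid_insertions(grid: EventGrid, rem: np.ndarray, e: int) -> np.ndarray:
    """Insertion indices into ``rem`` keeping biomarker-rank order for e."""
    b = grid.event_biomarker[e]
    r = grid.event_rank[e]
    evs = grid.events_of[b]
    lo, hi = 0, rem.size
    if r > 0:
        lo = int(np.flatnonzero(rem == evs[r - 1])[0]) + 1
    if r + 1 < evs.size:
        hi = int(np.flatnonzero(rem == evs[r + 1])[0])
    return np.arange(lo, hi + 1)


def _move_objectives(X, grid, rem, e, slots, weights):
    """Objective of inserting event e at each slot of ``rem``, batched.

    Builds the trajectory matrix for every candidate at once and evaluates
    the stage-marginalized log-likelihood with a single tensor contraction.
    """
    E = grid.n_events
    n_cand = slots.size
    stages = np.arange(E + 1, dtype=float)
    # positions of the remaining events for each candidate slot
    base = np.arange(1, E, dtype=float)
    pos_rem = base[None, :] + (base[None, :] > slots[:, None])
    pos_e = slots.astype(float) + 1.0
    pos = np.empty((n_cand, E))
    pos[:, rem] = pos_rem
    pos[:, e] = pos_e
    G = np.empty((n_cand, grid.n_biomarkers, E + 1))
    for i, evs in enumerate(grid.events_of):
        fp = np.concatenate(([0.0], grid.thresholds[i], [grid.z_max[i]]))
        for c in range(n_cand):
            xp = np.concatenate(([0.0], pos[c, evs], [E + 1.0]))
            G[c, i] = np.interp(stages, xp, fp)
    inv2 = 1.0 / grid.sigma**2
    const = (-0.5 * X.shape[1] * _LOG_2PI - float(np.sum(np.log(grid.sigma)))
             - np.log(grid.n_stages))
    t1 = -0.5 * (X**2 * inv2).sum(axis=1)                    # (n,)
    N, K = grid.n_biomarkers, E + 1
    Gf = G.transpose(1, 0, 2).reshape(N, n_cand * K)
    t2 = ((X * inv2) @ Gf).reshape(X.shape[0], n_cand, K)    # (n, c, E+1)
    t3 = -0.5 * (inv2 @ (Gf * Gf)).reshape(n_cand, K)        # (c, E+1)
    L = t2.transpose(1, 0, 2) + t3[:, None, :]
    m = L.max(axis=2)
    lm = m + np.log(np.exp(L - m[:, :, None]).sum(axis=2))   # (c, n)
    lm += t1[None, :] + const
    if weights is None:
        return lm.sum(axis=1)
    return lm @ weights


def _greedy_pass(X, grid, order, weights, rng, tol=1e-9):
    """One sweep over events in random order; returns (order, obj, moved).

    All candidate positions of a move (including the current one) are scored
    by the same batched evaluator, so the keep-or-move comparison is exact.
    """
    moved = False
    for e in rng.permutation(grid.n_events):
        cur_idx = int(np.flatnonzero(order == e)[0])
        rem = np.delete(order, cur_idx)
        slots = _valid_insertions(grid, rem, e)
        objs = _move_objectives(X, grid, rem, e, slots, weights)
        cur_slot = int(np.flatnonzero(slots == cur_idx)[0])
        best = int(np.argmax(objs))  # first occurrence: lowest position wins ties
        if best != cur_slot and objs[best] > objs[cur_slot] + tol:
            order = np.insert(rem, slots[best], e)
            moved = True
    return order, _weighted_objective(X, grid, order, weights), moved


def _greedy_to_convergence(X, grid, order, weights, rng, max_passes=50):
    obj = _weighted_objective(X, grid, order, weights)
    for _ in range(max_passes):
        order, obj, moved = _greedy_pass(X, grid, order, weights, rng)
        if not moved:
            break
    return order, obj


def optimize_sequence_greedy(X, grid: EventGrid, n_starts: int = 24,
                             seed: int | None = None, weights=None):
    """Maximum-likelihood single sequence by greedy ascent from random starts.

    Each start draws a random valid permutation and repeatedly sweeps over
    events, trying every insertion position that preserves within-biomarker
    threshold order and keeping the best, until a full sweep improves nothing.

    Returns ``(SubtypeSequence, log_likelihood)`` of the best start.
    """
    X = _as_matrix(X)
    _check_finite(X, grid)
    if X.shape[0] == 0:
        raise ValueError("no subjects provided")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    best_order, best_obj = None, -np.inf
    for _ in range(n_starts):
        order = _random_valid_order(grid, rng)
        order, obj = _greedy_to_convergence(X, grid, order, weights, rng)
        if obj > best_obj:
            best_order, best_obj = order, obj
    return SubtypeSequence(best_order), best_obj


# ---------------------------------------------------------------------------
# Mixture fitting: hierarchical splitting + EM refinement
# ---------------------------------------------------------------------------

def _responsibilities(X, grid, orders, fractions):
    logj = np.column_stack([
        np.log(f) + _log_subject_marginal(X, grid, o)
        for f, o in zip(fractions, orders)
    ])
    ll = float(logsumexp(logj, axis=1).sum())
    resp = np.exp(logj - logsumexp(logj, axis=1, keepdims=True))
    return resp, ll


def _em_refine(X, grid, orders, fractions, rng, tol=1e-6, max_iter=100):
    """Alternate responsibilities / (fractions, weighted greedy re-ordering)."""
    orders = [o.copy() for o in orders]
    fractions = np.asarray(fractions, dtype=float)
    fractions = fractions / fractions.sum()
    prev_ll = -np.inf
    for _ in range(max_iter):
        resp, ll = _responsibilities(X, grid, orders, fractions)
        # Guard against clusters dying: reseed from the worst-fit subjects.
        counts = resp.sum(axis=0)
        for c in np.flatnonzero(counts < 1.0):
            logger.warning("EM cluster %d empty; reseeding from worst-fit", c)
            lm = logsumexp(
                np.column_stack([_log_subject_marginal(X, grid, o)
                                 for o in orders]), axis=1)
            worst = np.argsort(lm)[: max(2, X.shape[0] // 10)]
            resp[worst] = 0.0
            resp[worst, c] = 1.0
            counts = resp.sum(axis=0)
        fractions = np.clip(counts / counts.sum(), 1e-6, None)
        fractions = fractions / fractions.sum()
        for c in range(len(orders)):
            orders[c], _ = _greedy_to_convergence(
                X, grid, orders[c], resp[:, c], rng)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    _, ll = _responsibilities(X, grid, orders, fractions)
    return orders, fractions, ll


def _split_candidates(X, grid, members, order_c, rng, n_splits, worst_frac):
    """Bipartitions of a cluster's members used to seed a split: the
    worst-fitting fraction under the cluster's own sequence versus the rest
    (subjects of an unmodelled subtype fit poorly), plus random halvings."""
    out = []
    if members.size >= 8:
        lm = _log_subject_marginal(X[members], grid, order_c)
        k = max(2, int(round(worst_frac * members.size)))
        idx = np.argsort(lm)
        out.append((members[idx[k:]], members[idx[:k]]))
    for _ in range(n_splits):
        half = rng.permutation(members)
        out.append((half[: members.size // 2], half[members.size // 2:]))
    return out


def fit_mixture_path(X, grid: EventGrid, max_subtypes: int,
                     seed: int | None = None, n_starts: int = 24,
                     split_starts: int = 4, n_splits: int = 1,
                     worst_frac: float = 0.25, em_tol: float = 1e-6,
                     em_max_iter: int = 100) -> list[SuStaInFit]:
    """Hierarchical fits for C = 1..max_subtypes; returns one fit per C.

    C = 1 is the greedy multi-start optimum. Each subsequent C takes the
    previous model, hard-assigns subjects, and tries splitting every cluster:
    each candidate bipartition of the cluster's members (see
    :func:`_split_candidates`) seeds two fresh sequences, the whole mixture
    is refined with EM, and the best refined likelihood wins.
    """
    X = _as_matrix(X)
    _check_finite(X, grid)
    if max_subtypes < 1:
        raise ValueError("max_subtypes must be >= 1")
    if X.shape[0] < 10 * max_subtypes:
        raise ValueError(
            f"need >= {10 * max_subtypes} subjects for {max_subtypes} subtypes"
        )
    rng = np.random.default_rng(seed)
    seq, ll = optimize_sequence_greedy(
        X, grid, n_starts=n_starts,
        seed=int(rng.integers(2**31 - 1)))
    fits = [SuStaInFit(grid, [seq], np.array([1.0]), ll, seed=seed)]
    for C in range(2, max_subtypes + 1):
        prev = fits[-1]
        orders_prev = [s.order for s in prev.sequences]
        resp, _ = _responsibilities(X, grid, orders_prev, prev.fractions)
        hard = resp.argmax(axis=1)
        best = None
        for c_split in range(prev.n_subtypes):
            members = np.flatnonzero(hard == c_split)
            if members.size < 4:
                continue
            for a, b in _split_candidates(X, grid, members,
                                          orders_prev[c_split], rng,
                                          n_splits, worst_frac):
                seq_a, _ = optimize_sequence_greedy(
                    X[a], grid, n_starts=split_starts,
                    seed=int(rng.integers(2**31 - 1)))
                seq_b, _ = optimize_sequence_greedy(
                    X[b], grid, n_starts=split_starts,
                    seed=int(rng.integers(2**31 - 1)))
                orders = [o.copy() for i, o in enumerate(orders_prev)
                          if i != c_split] + [seq_a.order, seq_b.order]
                f_split = prev.fractions[c_split]
                fracs = np.concatenate((
                    np.delete(prev.fractions, c_split),
                    [f_split * a.size / members.size,
                     f_split * b.size / members.size],
                ))
                orders, fracs, ll_c = _em_refine(
                    X, grid, orders, fracs, rng, tol=em_tol,
                    max_iter=em_max_iter)
                if best is None or ll_c > best[2]:
                    best = (orders, fracs, ll_c)
        if best is None:
            raise ValueError(f"no cluster large enough to split into {C}")
        orders, fracs, ll_c = best
        fits.append(SuStaInFit(
            grid, [SubtypeSequence(o) for o in orders], fracs, ll_c, seed=seed))
        if ll_c < fits[-2].log_likelihood - 1e-6:
            logger.warning(
                "log-likelihood decreased from C=%d (%.4f) to C=%d (%.4f)",
                C - 1, fits[-2].log_likelihood, C, ll_c)
    return fits


def fit_mixture(X, grid: EventGrid, n_subtypes: int,
                seed: int | None = None, **kwargs) -> SuStaInFit:
    """Fit a C-subtype model (see :func:`fit_mixture_path`)."""
    return fit_mixture_path(X, grid, n_subtypes, seed=seed, **kwargs)[-1]


# ---------------------------------------------------------------------------
# MCMC uncertainty
# ---------------------------------------------------------------------------

def mcmc_uncertainty(X, fit: SuStaInFit, iterations: int = 100_000,
                     seed: int | None = None,
                     keep_every: int | None = None) -> MCMCResult:
    """Metropolis-Hastings over event orderings with fractions held fixed.

    Each iteration picks one subtype and one event uniformly, proposes a
    uniformly random valid new position for that event, and accepts with
    probability ``min(1, L'/L)`` on the full-data mixture likelihood. Every
    retained state contributes to the positional variance; a thinned sample
    list is returned (``keep_every`` defaults to ``max(1, iterations // 1000)``).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = _as_matrix(X)
    grid = fit.grid
    _check_finite(X, grid)
    rng = np.random.default_rng(seed)
    if keep_every is None:
        keep_every = max(1, iterations // 1000)
    C, E = fit.n_subtypes, grid.n_events
    orders = [s.order.copy() for s in fit.sequences]
    logM = np.column_stack(
        [_log_subject_marginal(X, grid, o) for o in orders])
    logf = np.log(fit.fractions)
    ll = float(logsumexp(logM + logf, axis=1).sum())
    counts = np.zeros((C, E, E))
    kept: list[list[np.ndarray]] = [[] for _ in range(C)]
    lls = np.empty(iterations)
    accepted = 0
    for it in range(iterations):
        c = int(rng.integers(C))
        e = int(rng.integers(E))
        order = orders[c]
        cur_idx = int(np.flatnonzero(order == e)[0])
        rem = np.delete(order, cur_idx)
        slots = _valid_insertions(grid, rem, e)
        t = int(slots[rng.integers(slots.size)])
        cand = np.insert(rem, t, e)
        if t == cur_idx:
            accepted += 1  # proposal equal to current state: accept
        else:
            col = _log_subject_marginal(X, grid, cand)
            logM_new = logM.copy()
            logM_new[:, c] = col
            ll_new = float(logsumexp(logM_new + logf, axis=1).sum())
            if np.log(rng.random()) < ll_new - ll:
                orders[c] = cand
                logM = logM_new
                ll = ll_new
                accepted += 1
        lls[it] = ll
        for cc in range(C):
            pos = np.empty(E, dtype=int)
            pos[orders[cc]] = np.arange(E)
            counts[cc, np.arange(E), pos] += 1
        if (it + 1) % keep_every == 0:
            for cc in range(C):
                kept[cc].append(orders[cc].copy())
    rate = accepted / iterations
    logger.info("MCMC acceptance rate %.3f over %d iterations", rate, iterations)
    labels = grid.event_labels()
    pv = [PositionalVariance(counts[c] / iterations, labels) for c in range(C)]
    samples = [np.array(k) for k in kept]
    result = MCMCResult(samples, pv, rate, lls)
    fit.mcmc = result
    return result
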