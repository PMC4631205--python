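"""Flux-space random sampling and transcriptional-regulation calls.

The sampler is an artificial-centering hit-and-run (ACHR) walk over the
flux polytope {v : S v = 0, lb <= v <= ub}. Warmup points are the FVA
vertex witnesses (the LP solutions attaining each reaction's min and max);
subsequent directions run from the running center of all stored points
through a randomly chosen stored point, which adapts step directions to the
polytope's elongation. Every accepted point is re-projected onto the null
space of S, so the steady-state residual never accumulates. Given a seed
the sample matrix is bitwise reproducible.

``call_regulated`` compares per-reaction flux means between two sampled
conditions: a flux change is called when the means differ by more than
``separation`` times the summed standard deviations (i.e. the mean ± sd
intervals do not overlap at separation 1), and a reaction is
*transcriptionally regulated* when that flux direction agrees with the
expression direction of its genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .model_core import MetabolicModel
from .rmetd import ReactionDirectionMap

__all__ = ["SampleSet", "FluxChangeCall", "sample_fluxes", "call_regulated"]

_PROJ_TOL = 1e-10
_MIN_STEP = 1e-9


@dataclass
class SampleSet:
    matrix: np.ndarray          # n_samples x n_reactions
    reaction_ids: list[str]
    seed: int
    warmup: int
    thinning: int

    def column(self, rid: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rid)]

    def means(self) -> dict[str, float]:
        mu = self.matrix.mean(axis=0)
        return dict(zip(self.reaction_ids, mu.tolist()))

    def sds(self) -> dict[str, float]:
        sd = self.matrix.std(axis=0)
        return dict(zip(self.reaction_ids, sd.tolist()))


class SamplingError(RuntimeError):
    pass


def _stoich_matrix(model: MetabolicModel, rids: list[str]) -> np.ndarray:
    mids = list(model.metabolites)
    midx = {mid: i for i, mid in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    for j, rid in enumerate(rids):
        for mid, c in model.reactions[rid].stoichiometry.items():
            S[midx[mid], j] = c
    return S


def _fva_witnesses(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """LP witness vectors attaining each reaction's min and max flux."""
    n = S.shape[1]
    pts = []
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    for j in range(n):
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = scipy.optimize.linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds,
                                         method="highs")
            if not res.success:
                raise SamplingError(
                    f"model infeasible or unbounded while probing reaction {j}: "
                    f"{res.message}")
            pts.append(res.x)
    return np.asarray(pts)


def sample_fluxes(model: MetabolicModel, n: int, seed: int,
                  warmup: int = 200, thinning: int = 10) -> SampleSet:
    """Draw ``n`` flux vectors by seeded ACHR over the feasible region."""
    rids = list(model.reactions)
    nr = len(rids)
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    S = _stoich_matrix(model, rids)
    rng = np.random.default_rng(seed)

    base = _fva_witnesses(S, lb, ub)

    # fold bound-pinned fluxes (ub == lb) into the equality system so the
    # null-space projection preserves them exactly
    fixed = ub - lb < 1e-9
    A = S
    b = np.zeros(S.shape[0])
    if fixed.any():
        rows = np.eye(nr)[fixed]
        A = np.vstack([S, rows])
        b = np.concatenate([b, (lb[fixed] + ub[fixed]) / 2.0])
    N = scipy.linalg.null_space(A)
    x0, *_ = np.linalg.lstsq(A, b, rcond=None)

    if N.shape[1] == 0:
        # fully determined flux space: every sample is the single point
        x = base.mean(axis=0)
        return SampleSet(matrix=np.tile(x, (n, 1)), reaction_ids=rids,
                         seed=seed, warmup=warmup, thinning=thinning)

    def project(x: np.ndarray) -> np.ndarray:
        return x0 + N @ (N.T @ (x - x0))

    # warmup set: FVA witnesses, padded with random convex combinations
    pts = [project(p) for p in base]
    while len(pts) < warmup:
        w = rng.dirichlet(np.ones(len(base)))
        pts.append(project(w @ base))
    pts = pts[:max(warmup, 2)]
    center = np.mean(pts, axis=0)

    samples = np.empty((n, nr))
    x = center.copy()
    collected = 0
    step = 0
    stored = list(pts)
    while collected < n:
        # direction: center -> random stored point (artificial centering)
        for _ in range(50):
            p = stored[rng.integers(len(stored))]
            d = p - center
            norm = np.linalg.norm(d)
            if norm > _PROJ_TOL:
                d = d / norm
                break
        else:
            raise SamplingError("degenerate direction set; region may be a point")
        # feasible step interval along d
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_t = (lb - x) / d
            hi_t = (ub - x) / d
        active = np.abs(d) > _PROJ_TOL
        t_lo = np.minimum(lo_t, hi_t)[active]
        t_hi = np.maximum(lo_t, hi_t)[active]
        tmin, tmax = np.max(t_lo), np.min(t_hi)
        if tmax - tmin < _MIN_STEP:
            continue
        t = rng.uniform(tmin, tmax)
        x = project(x + t * d)
        np.clip(x, lb, ub, out=x)
        stored.append(x.copy())
        center = center + (x - center) / len(stored)
        step += 1
        if step % thinning == 0:
            samples[collected] = x
            collected += 1
    return SampleSet(matrix=samples, reaction_ids=rids, seed=seed,
                     warmup=warmup, thinning=thinning)


@dataclass
class FluxChangeCall:
    reaction_id: str
    mean_ref: float
    sd_ref: float
    mean_cond: float
    sd_cond: float
    flux_direction: str        # 'up' | 'down' | 'none'
    expression_direction: str  # 'up' | 'down' | 'unchanged'
    regulated: bool = field(init=False)

    def __post_init__(self):
        self.regulated = (self.flux_direction != "none"
                          and self.flux_direction == self.expression_direction)


def call_regulated(samples_ref: SampleSet, samples_cond: SampleSet,
                   directions: ReactionDirectionMap,
                   separation: float = 1.0) -> list[FluxChangeCall]:
    """Concordance of sampled flux shifts with expression direction calls.

    flux_direction is up/down when |mean_cond - mean_ref| exceeds
    ``separation`` x (sd_ref + sd_cond), 'none' otherwise; ``regulated``
    marks agreement between the flux and expression directions.
    """
    if samples_ref.reaction_ids != samples_cond.reaction_ids:
        only_ref = set(samples_ref.reaction_ids) - set(samples_cond.reaction_ids)
        only_cond = set(samples_cond.reaction_ids) - set(samples_ref.reaction_ids)
        raise ValueError(
            "sample sets disagree on reactions: "
            f"only in reference {sorted(only_ref)}, only in condition "
            f"{sorted(only_cond)}; order must match too")
    mu_r = samples_ref.matrix.mean(axis=0)
    sd_r = samples_ref.matrix.std(axis=0)
    mu_c = samples_cond.matrix.mean(axis=0)
    sd_c = samples_cond.matrix.std(axis=0)
    calls = []
    for i, rid in enumerate(samples_ref.reaction_ids):
        delta = mu_c[i] - mu_r[i]
        if abs(delta) > separation * (sd_r[i] + sd_c[i]):
            flux_dir = "up" if delta > 0 else "down"
        else:
            flux_dir = "none"
        calls.append(FluxChangeCall(
            reaction_id=rid, mean_ref=float(mu_r[i]), sd_ref=float(sd_r[i]),
            mean_cond=float(mu_c[i]), sd_cond=float(sd_c[i]),
            flux_direction=flux_dir,
            expression_direction=directions.direction(rid)))
    return calls
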