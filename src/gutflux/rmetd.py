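"""RMetD: integration of relative differential expression into flux bounds.

Given a reference-condition model (e.g. the germ-free small intestine), a
table of differentially expressed genes between a perturbed condition and
the reference, and a diet-derived set of uptake limits, the method

1. applies the diet uptake limits to both a reference and a condition copy;
2. forces each objective product's secretion to a floor — a fraction
   (default 20%) of that product's maximum attainable secretion;
3. projects gene-level up/down calls onto reactions through the GPR rules
   (reactions whose significant genes disagree in direction are treated as
   unchanged);
4. runs FVA for the mapped reactions in the reference copy (floors active);
5. installs the FVA ranges as hard bounds in the reference copy and, in the
   condition copy, the same ranges scaled multiplicatively by (1 ± alpha)
   according to the reaction's direction call — up-regulated reactions may
   carry more flux, down-regulated less;
6. solves both copies by parsimonious FBA maximizing the primary product
   and compares per-product secretion.

The scaling acts on flux *ranges* rather than point estimates: the
reference flux distribution of a genome-scale model is rarely unique, but
its variability ranges are robust, and pushing the ranges by a relative
factor encodes "this enzyme is up/down-regulated" without pretending the
expression change maps to an absolute flux.

Infeasibility after bound tightening is never silently repaired: an elastic
re-solve (slack on the tightened bounds, minimal total violation) names the
conflicting reactions in the result diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from . import lp_engine
from .model_core import MetabolicModel

__all__ = [
    "DEGene",
    "DETable",
    "RMetDConfig",
    "ReactionDirectionMap",
    "RMetDResult",
    "map_de_to_reactions",
    "run_rmetd",
    "sensitivity_scan",
    "scale_range",
]


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    direction: str  # 'up' | 'down'
    q_value: float
    log2fc: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0,1]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.log2fc is not None and self.log2fc != 0:
            implied = "up" if self.log2fc > 0 else "down"
            if implied != self.direction:
                raise ValueError(
                    f"{self.gene_id}: direction {self.direction} inconsistent "
                    f"with log2fc {self.log2fc}")


@dataclass
class DETable:
    entries: list[DEGene] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.gene_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in DE table: {dup}")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def significant(self, q_threshold: float) -> dict[str, str]:
        """gene id -> direction for genes below the significance threshold."""
        return {e.gene_id: e.direction for e in self.entries
                if e.q_value < q_threshold}

    @classmethod
    def from_tsv(cls, path: str) -> "DETable":
        """Read columns ``gene_id  log2fc  q_value``."""
        df = pd.read_csv(path, sep="\t")
        entries = [
            DEGene(gene_id=str(r.gene_id),
                   direction="up" if r.log2fc > 0 else "down",
                   q_value=float(r.q_value), log2fc=float(r.log2fc))
            for r in df.itertuples()
        ]
        return cls(entries=entries)

    def to_tsv(self, path: str) -> None:
        rows = [{"gene_id": e.gene_id,
                 "log2fc": e.log2fc if e.log2fc is not None
                 else (1.0 if e.direction == "up" else -1.0),
                 "q_value": e.q_value} for e in self.entries]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class RMetDConfig:
    alpha: float = 0.20            # relative bound push per direction call
    q_threshold: float = 0.05
    objective_products: list[str] = field(default_factory=list)  # primary first
    product_floor_fraction: float = 0.20
    cap_at_model_bounds: bool = True

    def __post_init__(self):
        for name in ("alpha", "product_floor_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be strictly inside (0,1), got {v}")


@dataclass(frozen=True)
class ReactionCall:
    direction: str       # 'up' | 'down' | 'unchanged'
    genes: frozenset[str]
    reason: str          # 'all-concordant' | 'mixed-directions'


@dataclass
class ReactionDirectionMap:
    """Per-reaction up/down/unchanged calls with contributing genes.

    Reactions with no significant gene are absent from ``calls``.
    ``coverage`` records how many DE genes mapped into the model versus
    were ignored.
    """

    calls: dict[str, ReactionCall] = field(default_factory=dict)
    coverage: dict[str, int] = field(default_factory=dict)

    def direction(self, rid: str) -> str:
        call = self.calls.get(rid)
        return call.direction if call is not None else "unchanged"

    def __len__(self):
        return len(self.calls)

    def __contains__(self, rid):
        return rid in self.calls


def map_de_to_reactions(model: MetabolicModel, de: DETable,
                        q_threshold: float = 0.05) -> ReactionDirectionMap:
    """Project gene-level calls onto reactions via the GPR rules.

    A reaction is called up (down) when *all* its significant genes are up
    (down); significant genes disagreeing in direction make the reaction
    'unchanged' (reason 'mixed-directions'). DE genes absent from the model
    are ignored but counted in the coverage report.
    """
    sig = de.significant(q_threshold)
    model_genes = model.genes
    mapped_genes = set(sig) & model_genes
    out = ReactionDirectionMap(coverage={
        "de_genes_total": len(de),
        "de_genes_significant": len(sig),
        "de_genes_in_model": len(mapped_genes),
        "de_genes_ignored": len(set(sig) - model_genes),
    })
    for rid, rxn in model.reactions.items():
        hits = {g: sig[g] for g in rxn.genes if g in sig}
        if not hits:
            continue
        dirs = set(hits.values())
        if dirs == {"up"}:
            call = ReactionCall("up", frozenset(hits), "all-concordant")
        elif dirs == {"down"}:
            call = ReactionCall("down", frozenset(hits), "all-concordant")
        else:
            call = ReactionCall("unchanged", frozenset(hits), "mixed-directions")
        out.calls[rid] = call
    return out


def scale_range(lo: float, hi: float, direction: str, alpha: float,
                ) -> tuple[float, float]:
    """Scale an FVA interval by the direction call.

    Both bounds are multiplied by (1 + alpha) for 'up' and (1 - alpha) for
    'down', so up-regulation expands the interval away from zero on both
    sides (e.g. [-5, 10] -> [-6, 12]) and down-regulation shrinks it toward
    zero; 'unchanged' returns the interval untouched. Multiplicative on each
    bound, hence preserving lo <= hi and reversibility.
    """
    if direction == "up":
        f = 1.0 + alpha
    elif direction == "down":
        f = 1.0 - alpha
    else:
        return lo, hi
    return lo * f, hi * f


@dataclass
class ProductComparison:
    product: str
    reference_flux: float
    condition_flux: float

    @property
    def ratio(self) -> float:
        if self.reference_flux == 0.0:
            return 1.0 if abs(self.condition_flux) < lp_engine.FEAS_TOL else float("inf")
        return self.condition_flux / self.reference_flux


@dataclass
class RMetDResult:
    reference_bounds: lp_engine.FluxRange
    condition_bounds: lp_engine.FluxRange
    reference_solution: lp_engine.FBAResult
    condition_solution: lp_engine.FBAResult
    product_comparison: list[ProductComparison]
    direction_map: ReactionDirectionMap
    alpha: float
    product_maxima: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    #: fully constrained copies (diet + floors + FVA/scaled bounds), ready
    #: for downstream sampling
    reference_model: MetabolicModel | None = None
    condition_model: MetabolicModel | None = None

    @property
    def feasible(self) -> bool:
        return self.reference_solution.ok and self.condition_solution.ok

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"product": c.product, "reference_flux": c.reference_flux,
             "condition_flux": c.condition_flux, "ratio": c.ratio}
            for c in self.product_comparison])


def _apply_diet(model: MetabolicModel, diet_bounds: dict[str, float]) -> None:
    """Set each listed exchange's uptake limit (uptake = negative flux)."""
    for ex_id, max_uptake in diet_bounds.items():
        if ex_id not in model.reactions:
            raise KeyError(f"diet exchange {ex_id!r} not in model {model.id!r}")
        if max_uptake < 0:
            raise ValueError(f"max uptake for {ex_id} must be >= 0")
        model.reactions[ex_id].lower_bound = -float(max_uptake)


def _elastic_diagnosis(model: MetabolicModel,
                       tightened: dict[str, tuple[float, float]]) -> dict:
    """Minimal-slack relaxation of the tightened bounds (LP, scipy/HiGHS).

    Returns the subset of tightened bounds that must be violated, with the
    violation magnitudes, so infeasibility is explained rather than hidden.
    """
    rids = list(model.reactions)
    idx = {rid: j for j, rid in enumerate(rids)}
    mids = list(model.metabolites)
    midx = {mid: i for i, mid in enumerate(mids)}
    n, m, k = len(rids), len(mids), len(tightened)
    S = np.zeros((m, n + 2 * k))
    for rid, rxn in model.reactions.items():
        for mid, c in rxn.stoichiometry.items():
            S[midx[mid], idx[rid]] = c
    # v_i + s_lo_i >= lo_i  and  v_i - s_hi_i <= hi_i ; slacks >= 0
    t_rids = list(tightened)
    A_ub = np.zeros((2 * k, n + 2 * k))
    b_ub = np.zeros(2 * k)
    for j, rid in enumerate(t_rids):
        lo, hi = tightened[rid]
        A_ub[2 * j, idx[rid]] = -1.0
        A_ub[2 * j, n + 2 * j] = -1.0
        b_ub[2 * j] = -lo
        A_ub[2 * j + 1, idx[rid]] = 1.0
        A_ub[2 * j + 1, n + 2 * j + 1] = -1.0
        b_ub[2 * j + 1] = hi
    bounds = [(-lp_engine.CLIP_BOUND, lp_engine.CLIP_BOUND) if rid in tightened
              else (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
              for rid in rids] + [(0, None)] * (2 * k)
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    res = scipy.optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                                 b_eq=np.zeros(m), bounds=bounds, method="highs")
    if not res.success:
        return {"elastic_status": res.message}
    slacks = res.x[n:]
    violated = {}
    for j, rid in enumerate(t_rids):
        s_lo, s_hi = slacks[2 * j], slacks[2 * j + 1]
        if s_lo > lp_engine.FEAS_TOL or s_hi > lp_engine.FEAS_TOL:
            violated[rid] = {"lower_slack": float(s_lo), "upper_slack": float(s_hi)}
    return {"elastic_status": "optimal", "total_violation": float(res.fun),
            "violated_bounds": violated}


def run_rmetd(reference_model: MetabolicModel, de: DETable,
              diet_bounds: dict[str, float], config: RMetDConfig) -> RMetDResult:
    """Execute the full bound-scaling comparison between two conditions."""
    if not config.objective_products:
        raise ValueError("config.objective_products must list at least one product")
    primary = config.objective_products[0]

    ref = reference_model.copy()
    _apply_diet(ref, diet_bounds)

    # (2) product secretion floors: fraction of each product's own maximum;
    # maxima computed independently before any floor is installed
    product_maxima: dict[str, float] = {}
    for product in config.objective_products:
        probe = ref.copy()
        probe.objective = (product, "max")
        sol = lp_engine.fba(probe)
        if not sol.ok:
            raise lp_engine.LPConfigError(
                f"reference model infeasible while maximizing {product}")
        product_maxima[product] = sol.objective_value
    for product in config.objective_products:
        floor = config.product_floor_fraction * product_maxima[product]
        ref.reactions[product].lower_bound = max(
            ref.reactions[product].lower_bound, floor)

    cond = ref.copy()

    # (3) expression -> reaction direction calls
    dmap = map_de_to_reactions(reference_model, de, config.q_threshold)

    # (4) FVA over mapped reactions in the reference copy (floors active,
    # objective NOT fixed at its optimum)
    mapped = list(dmap.calls)
    ref.objective = (primary, "max")
    cond.objective = (primary, "max")
    fva_ranges = lp_engine.fva(ref, mapped) if mapped else lp_engine.FluxRange({})

    # (5)+(6) hard bounds: raw ranges in the reference copy, scaled in the
    # condition copy, optionally capped at the original model bounds
    cond_ranges: dict[str, tuple[float, float]] = {}
    for rid in mapped:
        lo, hi = fva_ranges[rid]
        ref.reactions[rid].lower_bound = lo
        ref.reactions[rid].upper_bound = hi
        slo, shi = scale_range(lo, hi, dmap.direction(rid), config.alpha)
        if config.cap_at_model_bounds:
            olo = reference_model.reactions[rid].lower_bound
            ohi = reference_model.reactions[rid].upper_bound
            slo = min(max(slo, olo), ohi)
            shi = max(min(shi, ohi), slo)
        cond_ranges[rid] = (slo, shi)
        cond.reactions[rid].lower_bound = slo
        cond.reactions[rid].upper_bound = shi

    # (7) parsimonious FBA on the primary product in both copies
    diagnostics: dict = {}
    ref_sol = lp_engine.pfba(ref)
    cond_sol = lp_engine.pfba(cond)
    if not ref_sol.ok:
        diagnostics["reference"] = _elastic_diagnosis(
            reference_model, {rid: fva_ranges[rid] for rid in mapped})
    if not cond_sol.ok:
        diagnostics["condition"] = _elastic_diagnosis(reference_model, cond_ranges)

    # (8) per-product secretion read-out from the primary-product solutions
    comparison = []
    for product in config.objective_products:
        rf = ref_sol.fluxes.get(product, float("nan"))
        cf = cond_sol.fluxes.get(product, float("nan"))
        comparison.append(ProductComparison(product, rf, cf))

    return RMetDResult(
        reference_bounds=lp_engine.FluxRange(
            {rid: fva_ranges[rid] for rid in mapped}),
        condition_bounds=lp_engine.FluxRange(cond_ranges),
        reference_solution=ref_sol,
        condition_solution=cond_sol,
        product_comparison=comparison,
        direction_map=dmap,
        alpha=config.alpha,
        product_maxima=product_maxima,
        diagnostics=diagnostics,
        reference_model=ref,
        condition_model=cond,
    )


def sensitivity_scan(reference_model: MetabolicModel, de: DETable,
                     diet_bounds: dict[str, float], config: RMetDConfig,
                     alphas: list[float]) -> pd.DataFrame:
    """run_rmetd per alpha; returns the per-alpha product-comparison table.

    The frame carries a ``stable`` attr: True when the sign of
    (condition - reference) agrees across all alphas for every product.
    """
    rows = []
    for alpha in alphas:
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha {alpha} outside (0,1)")
        cfg = RMetDConfig(alpha=alpha, q_threshold=config.q_threshold,
                          objective_products=list(config.objective_products),
                          product_floor_fraction=config.product_floor_fraction,
                          cap_at_model_bounds=config.cap_at_model_bounds)
        try:
            result = run_rmetd(reference_model, de, diet_bounds, cfg)
        except lp_engine.LPConfigError as exc:
            for product in config.objective_products:
                rows.append({"alpha": alpha, "product": product,
                             "reference_flux": float("nan"),
                             "condition_flux": float("nan"),
                             "ratio": float("nan"), "feasible": False,
                             "error": str(exc)})
            continue
        for comp in result.product_comparison:
            rows.append({"alpha": alpha, "product": comp.product,
                         "reference_flux": comp.reference_flux,
                         "condition_flux": comp.condition_flux,
                         "ratio": comp.ratio, "feasible": result.feasible,
                         "error": ""})
    table = pd.DataFrame(rows)
    ok = table[table.feasible] if len(table) else table
    stable = len(table) > 0 and bool(table.feasible.all())
    if stable:
        for _, grp in ok.groupby("product"):
            signs = np.sign(np.round(grp.condition_flux - grp.reference_flux, 6))
            if len(set(signs)) > 1:
                stable = False
    table.attrs["stable"] = stable
    return table
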