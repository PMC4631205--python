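"""Gene-level statistics on the metabolic network and two-group tests.

Reporter metabolites: each metabolite is scored by aggregating the
standard-normal quantiles of the p-values of its *neighbor genes* — the
genes appearing in the GPR of any reaction that consumes or produces it.
For a metabolite with k scored neighbors,

    z_raw       = (sum of neighbor z) / sqrt(k),
    z_corrected = (z_raw - mu_k) / sigma_k,

where mu_k and sigma_k come from repeatedly drawing k random genes from the
scored gene pool (seeded). Under null scores z_corrected is approximately
standard normal, so hot spots of coordinated transcriptional change around
a metabolite stand out regardless of its connectivity.

Also here: a greedy reporter-subnetwork expansion over the
reaction-metabolite bipartite graph, Welch's two-sample t-test with the
Welch-Satterthwaite df, Benjamini-Hochberg FDR adjustment and the
lowest-Q merge of per-segment differential-expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .model_core import MetabolicModel
from .rmetd import DEGene, DETable

__all__ = [
    "GeneScore",
    "ReporterScore",
    "GroupComparison",
    "reporter_metabolites",
    "greedy_reporter_subnetwork",
    "welch_test",
    "bh_fdr",
    "merge_segment_de",
]

_P_CLAMP = 1e-15


def _p_to_z(p) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _P_CLAMP, 1.0 - _P_CLAMP)
    return scipy.stats.norm.isf(p)   # inverse survival: z = Phi^-1(1 - p)


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    p_value: float

    @property
    def z(self) -> float:
        return float(_p_to_z(self.p_value))


@dataclass
class ReporterScore:
    metabolite_id: str
    k: int
    z_raw: float
    z_corrected: float
    p_reporter: float
    neighbor_genes: frozenset[str] = field(default_factory=frozenset)


def _neighbor_genes(model: MetabolicModel) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {mid: set() for mid in model.metabolites}
    for rxn in model.reactions.values():
        genes = rxn.genes
        if not genes:
            continue
        for mid in rxn.stoichiometry:
            out[mid] |= genes
    return {m: frozenset(g) for m, g in out.items()}


def reporter_metabolites(model: MetabolicModel, gene_pvalues: dict[str, float],
                         n_background: int = 10_000, seed: int = 0,
                         ) -> list[ReporterScore]:
    """Score every metabolite with >= 1 scored neighbor gene.

    The background pool for the size-k correction is the set of scored
    genes that map into the model.
    """
    scored = {g: p for g, p in gene_pvalues.items() if g in model.genes}
    if not scored:
        raise ValueError("no overlap between scored genes and model genes")
    genes = sorted(scored)
    z_all = _p_to_z([scored[g] for g in genes])
    z_of = dict(zip(genes, z_all))
    rng = np.random.default_rng(seed)

    neighbors = _neighbor_genes(model)
    ks = sorted({len([g for g in nbr if g in scored])
                 for nbr in neighbors.values()} - {0})
    background: dict[int, tuple[float, float]] = {}
    for k in ks:
        draws = rng.choice(z_all, size=(n_background, k), replace=True)
        stat = draws.sum(axis=1) / np.sqrt(k)
        background[k] = (float(stat.mean()), float(stat.std()))

    out = []
    for mid in sorted(model.metabolites):
        nbr = [g for g in neighbors[mid] if g in scored]
        k = len(nbr)
        if k == 0:
            continue
        z_raw = sum(z_of[g] for g in nbr) / np.sqrt(k)
        mu, sigma = background[k]
        z_corr = (z_raw - mu) / sigma if sigma > 0 else 0.0
        out.append(ReporterScore(
            metabolite_id=mid, k=k, z_raw=float(z_raw),
            z_corrected=float(z_corr),
            p_reporter=float(scipy.stats.norm.sf(z_corr)),
            neighbor_genes=frozenset(nbr)))
    out.sort(key=lambda r: (r.p_reporter, r.metabolite_id))
    return out


@dataclass
class ReporterSubnetwork:
    metabolite_ids: list[str]
    reaction_ids: frozenset[str]
    score: float            # mean z_corrected over the selected metabolites


def greedy_reporter_subnetwork(model: MetabolicModel,
                               reporter_scores: list[ReporterScore],
                               size_limit: int = 10) -> ReporterSubnetwork:
    """Greedy expansion from the best-scoring metabolite.

    At each step the adjacent *scored* metabolite (sharing a reaction with
    the current set) that maximizes the mean z_corrected of the expanded
    set is added; expansion stops at ``size_limit`` or when the best
    candidate no longer carries positive corrected evidence (z_corrected
    <= 0), since a mean-improvement rule would never grow past the seed.
    Ties break lexicographically on metabolite id.
    """
    if not reporter_scores:
        raise ValueError("no reporter scores given")
    z = {r.metabolite_id: r.z_corrected for r in reporter_scores}
    # metabolite adjacency through shared reactions
    rxns_of: dict[str, set[str]] = {m: set() for m in model.metabolites}
    for rid, rxn in model.reactions.items():
        for mid in rxn.stoichiometry:
            rxns_of[mid].add(rid)
    start = min(z, key=lambda m: (-z[m], m))
    selected = [start]
    while len(selected) < size_limit:
        sel_rxns = set().union(*(rxns_of[m] for m in selected))
        candidates = sorted(
            m for m in z
            if m not in selected and rxns_of[m] & sel_rxns)
        if not candidates:
            break
        best, best_mean = None, -np.inf
        for cand in candidates:
            mean = float(np.mean([z[m] for m in selected + [cand]]))
            if mean > best_mean + 1e-12:
                best, best_mean = cand, mean
        if best is None or z[best] <= 0.0:
            break
        selected.append(best)
    reactions = frozenset().union(*(rxns_of[m] for m in selected))
    return ReporterSubnetwork(
        metabolite_ids=selected, reaction_ids=reactions,
        score=float(np.mean([z[m] for m in selected])))


@dataclass
class GroupComparison:
    analyte: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    q: float | None = None


def welch_test(group_a, group_b, analyte: str = "") -> GroupComparison:
    """Welch's two-sample t-test with the Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(analyte, float(a.mean()), float(b.mean()),
                                   t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / len(a)) ** 2 / (len(a) - 1)
                     + (vb / len(b)) ** 2 / (len(b) - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return GroupComparison(analyte, float(a.mean()), float(b.mean()),
                           t=float(t), df=float(df), p=float(p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(table: pd.DataFrame, group_col: str = "group",
                   value_col: str = "value", analyte_col: str = "analyte",
                   ) -> pd.DataFrame:
    """Welch + BH over a long-format two-group measurement table."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    rows = []
    for analyte, sub in table.groupby(analyte_col):
        a = sub.loc[sub[group_col] == groups[0], value_col].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], value_col].to_numpy()
        c = welch_test(a, b, analyte=str(analyte))
        rows.append({"analyte": c.analyte, "mean_a": c.mean_a, "mean_b": c.mean_b,
                     "t": c.t, "df": c.df, "p": c.p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def merge_segment_de(tables: list[DETable], q_threshold: float = 0.05) -> DETable:
    """Merge per-segment DE tables: keep each gene's lowest-Q entry.

    Genes significant (q < threshold) in *opposite* directions across the
    segments are dropped entirely — conflicting evidence is worse than no
    evidence.
    """
    if not tables:
        raise ValueError("need at least one DE table")
    best: dict[str, DEGene] = {}
    sig_dirs: dict[str, set[str]] = {}
    for table in tables:
        for entry in table:
            cur = best.get(entry.gene_id)
            if cur is None or entry.q_value < cur.q_value:
                best[entry.gene_id] = entry
            if entry.q_value < q_threshold:
                sig_dirs.setdefault(entry.gene_id, set()).add(entry.direction)
    conflicted = {g for g, dirs in sig_dirs.items() if len(dirs) > 1}
    return DETable(entries=[e for g, e in sorted(best.items())
                            if g not in conflicted])
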