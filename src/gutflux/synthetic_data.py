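"""Seeded generators for every input class the pipeline consumes.

The generators are drop-in replacements for the external inputs of a real
study — deposited tissue models, microarray differential-expression tables,
a chow-diet composition, bacterial community members and portal-vein
metabolomics — scaled to sizes where every linear program can be checked by
hand or brute force. Each emitted model records its analytically known
optimum in ``metadata`` so tests can compare solver output against a value
derived without an LP. All generators are pure functions of (spec, seed).

Templates
---------
chain           linear uptake -> conversion -> sink; optimum = uptake bound
diamond         two routes of unequal length between uptake and sink
futile_cycle    chain plus a 2-reaction loop that parsimony must silence
epithelium      small-intestine enterocyte sketch: diet uptakes, a
                glutathione-synthesis chain and competing chylomicron / HDL
                lipoprotein assembly from a shared lipid precursor
crossfeed_pair  saccharolytic acetate producer + acetate-consuming butyrate
                producer (the classic Bacteroides/Eubacterium motif)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_sim import (
    AminoAcidFraction,
    CommunityMember,
    DietComponent,
    DietComposition,
)
from .model_core import MetabolicModel, Metabolite, Reaction, assert_valid
from .rmetd import DEGene, DETable

__all__ = [
    "ToyNetworkSpec",
    "SyntheticExpressionSpec",
    "SyntheticMetabolomicsSpec",
    "make_toy_gem",
    "make_de_table",
    "make_metabolomics",
    "make_crossfeed_pair",
]

TEMPLATES = ("chain", "diamond", "futile_cycle", "epithelium", "crossfeed_pair")


@dataclass
class ToyNetworkSpec:
    template: str = "chain"
    uptake: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"template must be one of {TEMPLATES}")


def _rxn(model: MetabolicModel, rid: str, stoich: dict[str, float],
         lb: float, ub: float, gpr: str = "") -> None:
    model.reactions[rid] = Reaction(id=rid, stoichiometry=dict(stoich),
                                    lower_bound=lb, upper_bound=ub, gpr=gpr)
    for mid in stoich:
        model.metabolites.setdefault(mid, Metabolite(id=mid, compartment="c"))


def _chain(uptake: float) -> MetabolicModel:
    m = MetabolicModel(id="chain")
    _rxn(m, "EX_A", {"A[e]": -1}, -uptake, 0.0)
    _rxn(m, "CONV", {"A[e]": -1, "B[e]": 1}, 0.0, 1000.0, gpr="g_conv")
    _rxn(m, "EX_B", {"B[e]": -1}, 0.0, 1000.0)
    m.objective = ("EX_B", "max")
    m.metadata["recorded_optimum"] = uptake
    return m


def _diamond(uptake: float) -> MetabolicModel:
    # short route R1 (1 reaction) vs long route R2a+R2b (2 reactions):
    # FBA optimum = uptake with the split free; parsimony picks R1 alone
    m = MetabolicModel(id="diamond")
    _rxn(m, "EX_A", {"A[e]": -1}, -uptake, 0.0)
    _rxn(m, "R1", {"A[e]": -1, "B[e]": 1}, 0.0, 1000.0, gpr="g_r1")
    _rxn(m, "R2a", {"A[e]": -1, "C[c]": 1}, 0.0, 1000.0, gpr="g_r2")
    _rxn(m, "R2b", {"C[c]": -1, "B[e]": 1}, 0.0, 1000.0, gpr="g_r2")
    _rxn(m, "EX_B", {"B[e]": -1}, 0.0, 1000.0)
    m.objective = ("EX_B", "max")
    m.metadata["recorded_optimum"] = uptake
    m.metadata["short_route"] = ["R1"]
    m.metadata["long_route"] = ["R2a", "R2b"]
    return m


def _futile_cycle(uptake: float) -> MetabolicModel:
    m = _chain(uptake)
    m.id = "futile_cycle"
    _rxn(m, "CYC1", {"A[e]": -1, "F[c]": 1}, 0.0, 1000.0)
    _rxn(m, "CYC2", {"F[c]": -1, "A[e]": 1}, 0.0, 1000.0)
    m.metadata["cycle_reactions"] = ["CYC1", "CYC2"]
    return m


#: diet uptake limits of the epithelium template (mmol/day): glucose, a
#: long-chain fatty-acid pool and the three glutathione precursors
EPITHELIUM_DIET = {"EX_glc": 10.0, "EX_fa": 5.0, "EX_glu": 3.0,
                   "EX_cys": 3.0, "EX_gly": 3.0}


def _epithelium() -> MetabolicModel:
    m = MetabolicModel(id="epithelium")
    for ex, cap in EPITHELIUM_DIET.items():
        mid = ex.removeprefix("EX_") + "[e]"
        _rxn(m, ex, {mid: -1}, -cap, 0.0)
    # lipoprotein branch: triacylglycerol assembled from glucose + fatty
    # acids, then packaged as chylomicrons or HDL (competing for the pool)
    _rxn(m, "TAG_SYN", {"glc[e]": -1, "fa[e]": -3, "tag[c]": 1}, 0.0, 1000.0,
         gpr="g_dgat")
    _rxn(m, "CHYLO_ASM", {"tag[c]": -1, "chylo[c]": 1}, 0.0, 1000.0,
         gpr="g_mttp")
    _rxn(m, "HDL_ASM", {"tag[c]": -1, "hdl[c]": 1}, 0.0, 1000.0,
         gpr="g_abca1")
    # glutathione branch: glutamate + cysteine -> gamma-glutamylcysteine,
    # then + glycine -> GSH (the ligase is a two-subunit complex)
    _rxn(m, "GCL", {"glu[e]": -1, "cys[e]": -1, "gcs[c]": 1}, 0.0, 1000.0,
         gpr="g_gclc and g_gclm")
    _rxn(m, "GSS", {"gcs[c]": -1, "gly[e]": -1, "gsh[c]": 1}, 0.0, 1000.0,
         gpr="g_gss")
    for product in ("chylo", "hdl", "gsh"):
        _rxn(m, f"EX_{product}", {f"{product}[c]": -1}, 0.0, 1000.0)
    m.objective = ("EX_chylo", "max")
    # fatty acids limit TAG to 5/3; with no HDL floor all of it can go to
    # chylomicrons
    m.metadata["recorded_optimum"] = 5.0 / 3.0
    m.metadata["diet_bounds"] = dict(EPITHELIUM_DIET)
    m.metadata["objective_products"] = ["EX_chylo", "EX_hdl"]
    m.metadata["lipid_genes"] = ["g_dgat", "g_mttp"]
    m.metadata["gsh_genes"] = ["g_gclc", "g_gclm", "g_gss"]
    return m


def _producer() -> MetabolicModel:
    m = MetabolicModel(id="acetate_producer")
    _rxn(m, "EX_glc", {"glc[e]": -1}, 0.0, 0.0)
    _rxn(m, "EX_gly", {"gly[e]": -1}, 0.0, 0.0)
    _rxn(m, "EX_ser", {"ser[e]": -1}, 0.0, 0.0)
    _rxn(m, "BIO", {"glc[e]": -1, "gly[e]": -0.1, "ser[e]": -0.1,
                    "bm[c]": 1, "ac[e]": 2}, 0.0, 1000.0, gpr="g_fermA")
    _rxn(m, "EX_ac", {"ac[e]": -1}, 0.0, 1000.0)
    _rxn(m, "EX_bm", {"bm[c]": -1}, 0.0, 1000.0)
    m.objective = ("BIO", "max")
    return m


def _consumer() -> MetabolicModel:
    m = MetabolicModel(id="butyrate_producer")
    _rxn(m, "EX_ac", {"ac[e]": -1}, 0.0, 0.0)
    _rxn(m, "EX_val", {"val[e]": -1}, 0.0, 0.0)
    _rxn(m, "BIO", {"ac[e]": -2, "val[e]": -0.1, "bm[c]": 1, "but[e]": 1},
         0.0, 1000.0, gpr="g_butB")
    _rxn(m, "EX_but", {"but[e]": -1}, 0.0, 1000.0)
    _rxn(m, "EX_bm", {"bm[c]": -1}, 0.0, 1000.0)
    m.objective = ("BIO", "max")
    return m


def make_toy_gem(spec: ToyNetworkSpec) -> MetabolicModel:
    """Build the named template; deterministic given the spec."""
    if spec.template == "chain":
        model = _chain(spec.uptake)
    elif spec.template == "diamond":
        model = _diamond(spec.uptake)
    elif spec.template == "futile_cycle":
        model = _futile_cycle(spec.uptake)
    elif spec.template == "epithelium":
        model = _epithelium()
    else:  # crossfeed_pair: the producer half (see make_crossfeed_pair)
        model = _producer()
    assert_valid(model)
    return model


@dataclass
class SyntheticExpressionSpec:
    n_genes: int = 200          # padded with off-model genes beyond the GPRs
    fraction_up: float = 0.2
    fraction_down: float = 0.2
    sig_q_range: tuple[float, float] = (0.001, 0.04)
    null_q_range: tuple[float, float] = (0.06, 1.0)
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.fraction_up + self.fraction_down > 1.0 + 1e-9:
            raise ValueError("fraction_up + fraction_down exceeds 1")


def make_de_table(spec: SyntheticExpressionSpec, model: MetabolicModel,
                  ) -> tuple[DETable, dict[str, str]]:
    """DE table over the model's genes plus the implied reaction truth.

    Model genes are shuffled (seeded) and the first ``fraction_up`` /
    ``fraction_down`` shares become significantly up / down; remaining
    model genes and the off-model padding get null q-values. The returned
    truth map gives, per reaction with >= 1 significant gene, the direction
    the GPR projection must produce (mixed significant directions ->
    'unchanged').
    """
    genes = sorted(model.genes)
    if not genes:
        raise ValueError(f"model {model.id!r} has no genes")
    rng = np.random.default_rng(spec.seed)
    order = list(rng.permutation(genes))
    n_up = round(spec.fraction_up * len(order))
    n_down = round(spec.fraction_down * len(order))
    direction: dict[str, str] = {}
    entries = []
    for i, g in enumerate(order):
        if i < n_up:
            d, q = "up", rng.uniform(*spec.sig_q_range)
            direction[g] = "up"
        elif i < n_up + n_down:
            d, q = "down", rng.uniform(*spec.sig_q_range)
            direction[g] = "down"
        else:
            d = "up" if rng.random() < 0.5 else "down"
            q = rng.uniform(*spec.null_q_range)
        entries.append(DEGene(gene_id=g, direction=d, q_value=float(q),
                              log2fc=1.0 if d == "up" else -1.0))
    for j in range(max(0, spec.n_genes - len(order))):
        d = "up" if rng.random() < 0.5 else "down"
        entries.append(DEGene(gene_id=f"g_offmodel_{j}", direction=d,
                              q_value=float(rng.uniform(*spec.null_q_range)),
                              log2fc=1.0 if d == "up" else -1.0))
    truth: dict[str, str] = {}
    for rid, rxn in model.reactions.items():
        dirs = {direction[g] for g in rxn.genes if g in direction}
        if not dirs:
            continue
        truth[rid] = dirs.pop() if len(dirs) == 1 else "unchanged"
    return DETable(entries=entries), truth


@dataclass
class SyntheticMetabolomicsSpec:
    n_analytes: int = 20
    n_a: int = 6
    n_b: int = 6
    base_log_mean: float = 2.0
    noise_sd: float = 0.25           # in log units
    effects: dict[int, float] = field(default_factory=dict)  # analyte idx -> log-fold
    seed: int = 0

    def __post_init__(self):
        if self.n_a < 3 or self.n_b < 3:
            raise ValueError("group sizes must be >= 3")


def make_metabolomics(spec: SyntheticMetabolomicsSpec,
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Log-normal two-group measurement table plus the true effects.

    Analytes without an entry in ``spec.effects`` are true nulls. Returns a
    long-format frame (analyte, group, value) mirroring a portal-vein
    metabolite panel, and a dict analyte -> true log-fold effect.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth: dict[str, float] = {}
    for i in range(spec.n_analytes):
        name = f"analyte_{i:04d}"
        effect = spec.effects.get(i, 0.0)
        truth[name] = effect
        for _ in range(spec.n_a):
            rows.append({"analyte": name, "group": "a",
                         "value": float(np.exp(
                             spec.base_log_mean + rng.normal(0, spec.noise_sd)))})
        for _ in range(spec.n_b):
            rows.append({"analyte": name, "group": "b",
                         "value": float(np.exp(
                             spec.base_log_mean + effect
                             + rng.normal(0, spec.noise_sd)))})
    return pd.DataFrame(rows), truth


def make_crossfeed_pair(seed: int = 0,
                        ) -> tuple[list[CommunityMember], DietComposition]:
    """Producer/consumer member pair plus a four-class chow-style diet.

    The producer ferments glucose to acetate (2 mmol per mmol glucose)
    while drawing glycine and serine into biomass; the consumer can grow
    only on acetate (2 mmol per unit biomass) with a valine requirement,
    releasing butyrate. ``seed`` is accepted for interface uniformity; the
    fixture itself is deterministic.
    """
    producer = CommunityMember(
        id="acetate_producer", model=_producer(), biomass_id="BIO",
        uptake_exchanges={"glc": "EX_glc", "gly": "EX_gly", "ser": "EX_ser"},
        secretion_exchanges={"ac": "EX_ac"})
    consumer = CommunityMember(
        id="butyrate_producer", model=_consumer(), biomass_id="BIO",
        uptake_exchanges={"ac": "EX_ac", "val": "EX_val"},
        secretion_exchanges={"but": "EX_but"})
    diet = DietComposition(components=[
        DietComponent(
            name="casein", nutrient_class="protein", grams_per_day=10.0,
            aa_profile=[
                AminoAcidFraction("gly", 0.30, 0.075),
                AminoAcidFraction("ser", 0.30, 0.105),
                AminoAcidFraction("val", 0.40, 0.117),
            ]),
        DietComponent(name="starch_glucose", nutrient_class="digestible_carb",
                      grams_per_day=18.0, molar_mass=0.180, metabolite_id="glc"),
        DietComponent(name="fiber", nutrient_class="non_digestible_carb",
                      grams_per_day=5.0, molar_mass=0.162, metabolite_id="fiber"),
        DietComponent(name="lard", nutrient_class="fat", grams_per_day=5.0,
                      molar_mass=0.860, metabolite_id="fa"),
    ])
    return [producer, consumer], diet
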