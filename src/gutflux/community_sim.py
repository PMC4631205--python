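"""Diet partitioning and multi-species gut community simulation.

The diet — grams per day of protein, digestible carbohydrate,
non-digestible carbohydrate and fat — is first split among three consumers
(the small-intestine microbiota, the small-intestine epithelium and the
colon) by class-specific fractions, then converted to mmol/day nutrient
pools via explicit molar masses; protein is expanded into amino acids
through a weight-fraction profile.

The bacterial pool then drives a round-robin community optimization: in
each round every member receives a share of each pool nutrient
(proportional to its LP-probed maximum uptake demand when the nutrient is
contested), maximizes its biomass by FBA, fixes its fluxes by parsimonious
FBA, and returns its secretions to the shared pool, where they are
available to the members that follow — this is how acetate secreted by a
saccharolytic producer ends up fueling butyrate production in a
cross-feeding consumer. Rounds repeat until all growth values stabilize.

Daily amounts act directly as flux caps for one simulated day at unit
biomass; there is no dynamic biomass integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import lp_engine
from .model_core import MetabolicModel

__all__ = [
    "DietComponent",
    "DietComposition",
    "PartitionConfig",
    "CommunityMember",
    "CommunityResult",
    "partition_diet",
    "simulate_community",
    "consumption_report",
]

NUTRIENT_CLASSES = ("protein", "digestible_carb", "non_digestible_carb", "fat")
CONSUMERS = ("bacteria", "small_intestine", "colon")
_TOL = 1e-6


@dataclass
class AminoAcidFraction:
    metabolite_id: str
    weight_fraction: float     # of total protein mass
    molar_mass: float          # g/mmol


@dataclass
class DietComponent:
    name: str
    nutrient_class: str
    grams_per_day: float
    molar_mass: float | None = None          # g/mmol; None for protein
    metabolite_id: str | None = None         # pool id; defaults to name
    aa_profile: list[AminoAcidFraction] = field(default_factory=list)

    def __post_init__(self):
        if self.nutrient_class not in NUTRIENT_CLASSES:
            raise ValueError(
                f"{self.name}: class {self.nutrient_class!r} not in {NUTRIENT_CLASSES}")
        if self.grams_per_day < 0:
            raise ValueError(f"{self.name}: negative amount")
        if self.nutrient_class == "protein":
            total = sum(a.weight_fraction for a in self.aa_profile)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.name}: amino-acid weight fractions sum to {total}, not 1")
        elif self.molar_mass is None:
            raise ValueError(f"{self.name}: molar mass required (g/mmol)")

    @property
    def pool_id(self) -> str:
        return self.metabolite_id or self.name


@dataclass
class DietComposition:
    components: list[DietComponent] = field(default_factory=list)

    def scaled(self, factor: float) -> "DietComposition":
        out = []
        for c in self.components:
            out.append(DietComponent(
                name=c.name, nutrient_class=c.nutrient_class,
                grams_per_day=c.grams_per_day * factor,
                molar_mass=c.molar_mass, metabolite_id=c.metabolite_id,
                aa_profile=list(c.aa_profile)))
        return DietComposition(components=out)

    @classmethod
    def from_tsv(cls, path: str) -> "DietComposition":
        """Columns: component  class  grams_per_day  molar_mass  aa_profile_json.

        ``aa_profile_json`` (protein rows) maps amino-acid metabolite id to
        ``[weight_fraction, molar_mass]``. An optional ``metabolite_id``
        column names the pool metabolite when it differs from the component.
        """
        import json

        df = pd.read_csv(path, sep="\t")
        comps = []
        for _, r in df.iterrows():
            profile = []
            raw = r.get("aa_profile_json", "")
            if isinstance(raw, str) and raw.strip():
                for mid, (wf, mm) in json.loads(raw).items():
                    profile.append(AminoAcidFraction(mid, float(wf), float(mm)))
            mm = r.get("molar_mass")
            mid = r.get("metabolite_id")
            comps.append(DietComponent(
                name=str(r["component"]),
                nutrient_class=str(r["class"]),
                grams_per_day=float(r["grams_per_day"]),
                molar_mass=None if pd.isna(mm) else float(mm),
                metabolite_id=None if (mid is None or pd.isna(mid)) else str(mid),
                aa_profile=profile))
        return cls(components=comps)


# Defaults: at most 40% of protein and digestible carbohydrate go to the
# small-intestine bacteria and 5% of each is passed on to the colon, the
# epithelium taking the remainder; only 5% of non-digestible carbohydrate is
# available to the small-intestine bacteria (the rest reaches the colon);
# fat is absorbed by the epithelium.
DEFAULT_FRACTIONS: dict[str, dict[str, float]] = {
    "protein": {"bacteria": 0.40, "colon": 0.05, "small_intestine": 0.55},
    "digestible_carb": {"bacteria": 0.40, "colon": 0.05, "small_intestine": 0.55},
    "non_digestible_carb": {"bacteria": 0.05, "colon": 0.95, "small_intestine": 0.0},
    "fat": {"bacteria": 0.0, "colon": 0.0, "small_intestine": 1.0},
}


@dataclass
class PartitionConfig:
    fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FRACTIONS.items()})

    def __post_init__(self):
        for cls_, alloc in self.fractions.items():
            if cls_ not in NUTRIENT_CLASSES:
                raise ValueError(f"unknown nutrient class {cls_!r}")
            total = sum(alloc.values())
            if total > 1.0 + 1e-9 or any(f < 0 for f in alloc.values()):
                raise ValueError(
                    f"{cls_}: fractions {alloc} invalid (each >= 0, sum <= 1)")


def partition_diet(diet: DietComposition, config: PartitionConfig | None = None,
                   ) -> dict[str, dict[str, float]]:
    """Split the diet into per-consumer nutrient pools (mmol/day).

    Grams are divided by the class fractions, protein mass is expanded to
    amino acids by the weight profile, and everything is converted to mmol
    via the molar masses.
    """
    config = config or PartitionConfig()
    pools: dict[str, dict[str, float]] = {c: {} for c in CONSUMERS}
    for comp in diet.components:
        alloc = config.fractions.get(comp.nutrient_class, {})
        for consumer in CONSUMERS:
            grams = comp.grams_per_day * alloc.get(consumer, 0.0)
            if grams == 0.0:
                continue
            pool = pools[consumer]
            if comp.nutrient_class == "protein":
                for aa in comp.aa_profile:
                    mmol = grams * aa.weight_fraction / aa.molar_mass
                    pool[aa.metabolite_id] = pool.get(aa.metabolite_id, 0.0) + mmol
            else:
                mmol = grams / comp.molar_mass
                pool[comp.pool_id] = pool.get(comp.pool_id, 0.0) + mmol
    return pools


@dataclass
class CommunityMember:
    id: str
    model: MetabolicModel
    biomass_id: str
    uptake_exchanges: dict[str, str] = field(default_factory=dict)   # pool id -> exchange rxn
    secretion_exchanges: dict[str, str] = field(default_factory=dict)  # pool id -> exchange rxn

    def __post_init__(self):
        named = [self.biomass_id, *self.uptake_exchanges.values(),
                 *self.secretion_exchanges.values()]
        missing = [r for r in named if r not in self.model.reactions]
        if missing:
            raise ValueError(f"member {self.id}: reactions not in model: {missing}")


@dataclass
class PoolLedger:
    allocated: float = 0.0
    consumed: float = 0.0
    cross_fed: float = 0.0

    @property
    def residual(self) -> float:
        return self.allocated + self.cross_fed - self.consumed


@dataclass
class CommunityResult:
    growth: dict[str, float]
    uptake: dict[str, dict[str, float]]       # member -> pool id -> mmol consumed
    secretion: dict[str, dict[str, float]]    # member -> pool id -> mmol secreted
    ledger: dict[str, PoolLedger]
    rounds: int
    converged: bool
    growth_trace: list[dict[str, float]] = field(default_factory=list)


def _probe_demand(member: CommunityMember, avail: dict[str, float]) -> dict[str, float]:
    """Max uptake (mmol) of each available nutrient, pool-bounded FVA query."""
    model = member.model.copy()
    for pid, rid in member.uptake_exchanges.items():
        model.reactions[rid].lower_bound = -max(avail.get(pid, 0.0), 0.0)
    targets = [rid for pid, rid in member.uptake_exchanges.items()
               if avail.get(pid, 0.0) > _TOL]
    if not targets:
        return {}
    ranges = lp_engine.fva(model, targets)
    rid_to_pid = {rid: pid for pid, rid in member.uptake_exchanges.items()}
    return {rid_to_pid[rid]: max(0.0, -ranges[rid][0]) for rid in targets}


def _solve_member(member: CommunityMember, share: dict[str, float],
                  ) -> tuple[float, dict[str, float], dict[str, float]]:
    """FBA-maximize biomass under the allocated share, pFBA-fix the fluxes."""
    model = member.model.copy()
    for pid, rid in member.uptake_exchanges.items():
        model.reactions[rid].lower_bound = -max(share.get(pid, 0.0), 0.0)
    model.objective = (member.biomass_id, "max")
    sol = lp_engine.pfba(model)
    if not sol.ok:
        return 0.0, {}, {}
    uptake, secretion = {}, {}
    for pid, rid in member.uptake_exchanges.items():
        v = sol.fluxes[rid]
        if v < -_TOL:
            uptake[pid] = -v
    for pid, rid in member.secretion_exchanges.items():
        v = sol.fluxes[rid]
        if v > _TOL:
            secretion[pid] = v
    return sol.objective_value, uptake, secretion


def simulate_community(members: list[CommunityMember],
                       pools: dict[str, float],
                       tolerance: float = 1e-6,
                       max_rounds: int = 20) -> CommunityResult:
    """Round-robin community optimization over a shared nutrient pool.

    Member order is the input order and is significant: a member's
    secretions become available to the members after it in the same round
    and to every member from the next round on. Contested nutrients are
    split proportionally to the probed demands of the members that have not
    yet consumed this round.
    """
    if not members:
        raise ValueError("need at least one community member")
    ids = [m.id for m in members]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate member ids: {ids}")

    growth = {m.id: 0.0 for m in members}
    uptakes: dict[str, dict[str, float]] = {m.id: {} for m in members}
    secretions: dict[str, dict[str, float]] = {m.id: {} for m in members}
    trace: list[dict[str, float]] = []
    converged = False
    rounds_done = 0

    for rnd in range(1, max_rounds + 1):
        rounds_done = rnd
        # pool at round start: fresh allocation plus last round's secretions
        avail = dict(pools)
        for m in members:
            for pid, amt in secretions[m.id].items():
                avail[pid] = avail.get(pid, 0.0) + amt
        new_growth: dict[str, float] = {}
        for i, member in enumerate(members):
            # swap this member's stale secretion out before it re-secretes
            for pid, amt in secretions[member.id].items():
                avail[pid] = max(0.0, avail.get(pid, 0.0) - amt)
            # proportional allocation among members still waiting this round
            demands = {m.id: _probe_demand(m, avail) for m in members[i:]}
            share: dict[str, float] = {}
            for pid, have in avail.items():
                want = {mid: d.get(pid, 0.0) for mid, d in demands.items()}
                total = sum(want.values())
                mine = want[member.id]
                if total <= have + _TOL:
                    share[pid] = mine
                else:
                    share[pid] = have * mine / total if total > 0 else 0.0
            g, upt, sec = _solve_member(member, share)
            new_growth[member.id] = g
            uptakes[member.id] = upt
            secretions[member.id] = sec
            for pid, amt in upt.items():
                avail[pid] = max(0.0, avail.get(pid, 0.0) - amt)
            for pid, amt in sec.items():
                avail[pid] = avail.get(pid, 0.0) + amt
        trace.append(dict(new_growth))
        delta = max(abs(new_growth[k] - growth[k]) for k in new_growth)
        growth = new_growth
        if delta < tolerance:
            converged = True
            break

    ledger: dict[str, PoolLedger] = {}
    all_pids = set(pools) | {p for s in secretions.values() for p in s} \
        | {p for u in uptakes.values() for p in u}
    for pid in sorted(all_pids):
        ledger[pid] = PoolLedger(
            allocated=pools.get(pid, 0.0),
            consumed=sum(u.get(pid, 0.0) for u in uptakes.values()),
            cross_fed=sum(s.get(pid, 0.0) for s in secretions.values()),
        )
    return CommunityResult(growth=growth, uptake=uptakes, secretion=secretions,
                           ledger=ledger, rounds=rounds_done,
                           converged=converged, growth_trace=trace)


def consumption_report(result: CommunityResult, amino_acid_ids: list[str],
                       ) -> pd.DataFrame:
    """Member x amino-acid consumed amounts plus per-acid exhausted flags."""
    unknown = [a for a in amino_acid_ids if a not in result.ledger]
    if unknown:
        raise KeyError(f"amino acids not in the community ledger: {unknown}")
    rows = []
    for member, upt in result.uptake.items():
        for aa in amino_acid_ids:
            rows.append({
                "member": member,
                "amino_acid": aa,
                "consumed_mmol": upt.get(aa, 0.0),
                "exhausted": result.ledger[aa].residual < _TOL,
            })
    return pd.DataFrame(rows)
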