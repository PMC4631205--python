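"""Data model for genome-scale metabolic models (GEMs) and I/O.

A :class:`MetabolicModel` is the substrate of every linear-programming
operation in this package: a stoichiometric matrix implied by its reactions,
flux bounds in mmol·gDW⁻¹·h⁻¹, boolean gene–protein–reaction (GPR) rules
(AND = enzyme complex, OR = isoenzymes) and a single-reaction objective.

Two on-disk dialects are supported: SBML Level 3 with the flux-balance
constraints (fbc) extension — the convention of the deposited tissue model
family — and a minimal tab-separated ``toy_tsv`` format meant for
hand-written test fixtures (one reaction per row, equations such as
``2 A[c] + B[c] => C[e]``).

Sign convention for exchange (single-metabolite boundary) reactions:
negative flux = uptake, positive flux = secretion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import cobra
from cobra.core.gene import GPR

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ElementSets",
    "ModelValidationError",
    "validate_model",
    "element_sets",
    "load_model",
    "save_model",
    "gpr_genes",
    "parse_equation",
]

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates structural invariants.

    Carries the full list of violations in :attr:`report`.
    """

    def __init__(self, report: list[str]):
        self.report = list(report)
        super().__init__("model validation failed:\n" + "\n".join(self.report))


def gpr_genes(gpr: str) -> frozenset[str]:
    """Gene ids referenced by a boolean GPR string ('' -> empty set)."""
    if not gpr or not gpr.strip():
        return frozenset()
    return frozenset(GPR.from_string(gpr).genes)


def gpr_equivalent(a: str, b: str) -> bool:
    """Logical equivalence of two GPR strings over their joint gene set."""
    ga, gb = gpr_genes(a), gpr_genes(b)
    genes = sorted(ga | gb)
    if not genes:
        return (not a.strip()) == (not b.strip())
    pa, pb = GPR.from_string(a), GPR.from_string(b)
    for mask in range(2 ** len(genes)):
        on = {g for i, g in enumerate(genes) if mask >> i & 1}
        if pa.eval(ga - on) != pb.eval(gb - on):  # eval takes knockouts
            return False
    return True


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None


@dataclass
class Reaction:
    """A (possibly boundary) reaction with bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str | None = None

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: tuple[str, str] | None = None  # (reaction id, 'max'|'min')
    metadata: dict = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return frozenset(out)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions={rid: replace(r, stoichiometry=dict(r.stoichiometry))
                       for rid, r in self.reactions.items()},
            objective=self.objective,
            metadata=dict(self.metadata),
        )

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]


@dataclass(frozen=True)
class ElementSets:
    """The reaction / metabolite / gene id sets of one model.

    The unit of comparison for ensemble Hamming statistics.
    """

    reaction_ids: frozenset[str]
    metabolite_ids: frozenset[str]
    gene_ids: frozenset[str]


def element_sets(model: MetabolicModel) -> ElementSets:
    return ElementSets(
        reaction_ids=frozenset(model.reactions),
        metabolite_ids=frozenset(model.metabolites),
        gene_ids=model.genes,
    )


def validate_model(model: MetabolicModel) -> list[str]:
    """Return a report of violated invariants (empty = valid)."""
    report: list[str] = []
    for rid, rxn in model.reactions.items():
        if rxn.lower_bound > rxn.upper_bound:
            report.append(f"reaction {rid}: lower_bound > upper_bound")
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                report.append(f"reaction {rid}: undeclared metabolite {mid}")
        if not rxn.stoichiometry:
            report.append(f"reaction {rid}: empty stoichiometry")
    if model.objective is not None:
        obj_rid, sense = model.objective
        if obj_rid not in model.reactions:
            report.append(f"objective reaction {obj_rid} not in model")
        if sense not in ("max", "min"):
            report.append(f"objective sense {sense!r} not max/min")
    return report


def assert_valid(model: MetabolicModel) -> None:
    report = validate_model(model)
    if report:
        raise ModelValidationError(report)


# ---------------------------------------------------------------------------
# toy_tsv equation syntax: "2 A[c] + B[c] => C[e]"  ("<=>" reversible)

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S.*?)\s*$")


def _parse_side(side: str, sign: float, stoich: dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split(" + "):
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"cannot parse equation term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        stoich[m.group(2)] = stoich.get(m.group(2), 0.0) + sign * coeff


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string; returns (stoichiometry, reversible)."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        rev = True
    elif "=>" in eq:
        lhs, rhs = eq.split("=>")
        rev = False
    else:
        raise ValueError(f"equation {eq!r} lacks '=>' or '<=>'")
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich)
    _parse_side(rhs, +1.0, stoich)
    return {k: v for k, v in stoich.items() if v != 0.0}, rev


def format_equation(rxn: Reaction) -> str:
    def side(items):
        parts = []
        for mid, c in items:
            c = abs(c)
            parts.append(mid if c == 1 else f"{c:g} {mid}")
        return " + ".join(parts)

    lhs = side(sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0))
    rhs = side(sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0))
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{lhs} {arrow} {rhs}".strip()


def _compartment_of(mid: str) -> str:
    m = re.search(r"\[(\w+)\]$", mid)
    return m.group(1) if m else "c"


def _model_from_rows(model_id: str, rows: list[dict]) -> MetabolicModel:
    model = MetabolicModel(id=model_id)
    for row in rows:
        stoich, rev = parse_equation(row["equation"])
        lb = float(row["lb"]) if row["lb"] != "" else (-DEFAULT_BOUND if rev else 0.0)
        ub = float(row["ub"]) if row["ub"] != "" else DEFAULT_BOUND
        rxn = Reaction(id=row["id"], stoichiometry=stoich, lower_bound=lb,
                       upper_bound=ub, gpr=row.get("gpr", ""))
        model.reactions[rxn.id] = rxn
        for mid in stoich:
            model.metabolites.setdefault(
                mid, Metabolite(id=mid, compartment=_compartment_of(mid)))
        obj = row.get("objective", "")
        if obj:
            model.objective = (rxn.id, "min" if obj == "min" else "max")
    return model


def _load_toy_tsv(path: str) -> MetabolicModel:
    import pathlib

    lines = pathlib.Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    required = {"id", "equation", "lb", "ub"}
    if not required.issubset(header):
        raise ValueError(f"toy_tsv header must contain {sorted(required)}, got {header}")
    rows = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        vals = ln.split("\t")
        rows.append({h: (vals[i] if i < len(vals) else "") for i, h in enumerate(header)})
    name = pathlib.Path(path).stem
    return _model_from_rows(name, rows)


def _save_toy_tsv(model: MetabolicModel, path: str) -> None:
    cols = ["id", "equation", "lb", "ub", "gpr", "objective"]
    lines = ["\t".join(cols)]
    for rid, rxn in model.reactions.items():
        obj = ""
        if model.objective and model.objective[0] == rid:
            obj = model.objective[1]
        lines.append("\t".join([
            rid, format_equation(rxn), f"{rxn.lower_bound:g}", f"{rxn.upper_bound:g}",
            rxn.gpr, obj,
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML via COBRApy (L3V1 + fbc v2)

_SBML_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sbml_id(raw: str) -> str:
    """SBML SIds forbid brackets; encode 'A[c]' as 'A__91__c__93__'-free form."""
    return _SBML_SAFE.sub(lambda m: f"__{ord(m.group(0))}__", raw)


def _un_sbml_id(sid: str) -> str:
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), sid)


def _rename_gpr(gpr: str, rename) -> str:
    parsed = GPR.from_string(gpr)
    return parsed.to_string(names={g: rename(g) for g in parsed.genes})


def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Convert to a cobra.Model (ids passed through an SBML-safe encoding)."""
    cm = cobra.Model(_sbml_id(model.id) or "model")
    cmets = {}
    for mid, met in model.metabolites.items():
        c = cobra.Metabolite(_sbml_id(mid), name=met.name or mid,
                             compartment=_sbml_id(met.compartment),
                             formula=met.formula)
        cmets[mid] = c
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for rid, rxn in model.reactions.items():
        cr = cobra.Reaction(_sbml_id(rid), lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        if rxn.subsystem:
            cr.subsystem = rxn.subsystem
        crxns.append(cr)
        cr.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
    cm.add_reactions(crxns)
    # GPRs after add_reactions so genes register with the model
    for rid, rxn in model.reactions.items():
        if rxn.gpr:
            cm.reactions.get_by_id(_sbml_id(rid)).gene_reaction_rule = \
                _rename_gpr(rxn.gpr, _sbml_id)
    if model.objective is not None:
        obj_rid, sense = model.objective
        cm.objective = cm.reactions.get_by_id(_sbml_id(obj_rid))
        cm.objective_direction = sense
    return cm


def from_cobra(cm: cobra.Model, model_id: str | None = None) -> MetabolicModel:
    model = MetabolicModel(id=_un_sbml_id(model_id or cm.id or "model"))
    for met in cm.metabolites:
        mid = _un_sbml_id(met.id)
        model.metabolites[mid] = Metabolite(
            id=mid, name=met.name or "",
            compartment=_un_sbml_id(met.compartment or "c"),
            formula=met.formula or None)
    for rxn in cm.reactions:
        rid = _un_sbml_id(rxn.id)
        gpr = rxn.gene_reaction_rule
        if gpr:
            gpr = _rename_gpr(gpr, _un_sbml_id)
        model.reactions[rid] = Reaction(
            id=rid,
            stoichiometry={_un_sbml_id(m.id): c for m, c in rxn.metabolites.items()},
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gpr=gpr, subsystem=rxn.subsystem or None)
    # recover a single-reaction objective from the linear coefficients
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
    except Exception:  # pragma: no cover - solver-less models
        coeffs = {}
    if coeffs:
        obj_rxn = max(coeffs, key=lambda r: abs(coeffs[r]))
        model.objective = (_un_sbml_id(obj_rxn.id), cm.objective_direction)
    return model


def load_model(path: str, format: str = "sbml") -> MetabolicModel:
    """Load and validate a model from ``sbml`` or ``toy_tsv``.

    Raises :class:`ModelValidationError` with the full violation report when
    the parsed document breaks a structural invariant.
    """
    if format == "toy_tsv":
        model = _load_toy_tsv(path)
    elif format == "sbml":
        try:
            cm = cobra.io.read_sbml_model(path)
        except Exception as exc:
            raise ValueError(f"SBML parse failure for {path}: {exc}") from exc
        model = from_cobra(cm)
    else:
        raise ValueError(f"unknown model format {format!r}")
    assert_valid(model)
    return model


def save_model(model: MetabolicModel, path: str, format: str = "sbml") -> None:
    assert_valid(model)
    if format == "toy_tsv":
        _save_toy_tsv(model, path)
    elif format == "sbml":
        cobra.io.write_sbml_model(to_cobra(model), path)
    else:
        raise ValueError(f"unknown model format {format!r}")
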