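"""Stoichiometric network data model and readers/writers.

The in-memory representation is deliberately small: metabolites, reactions
with explicit stoichiometry maps and flux bounds, genes, and boolean
gene-protein-reaction (GPR) rules.  Three on-disk dialects are supported:

* SBML Level 3 with the FBC package (via python-libsbml),
* COBRA-style JSON (compatible with cobrapy's schema),
* a minimal TSV dialect, one reaction per row, used for diffable fixtures.

Flux bounds are in mmol gDW^-1 h^-1 (biomass in h^-1).  Absent bounds
default to [-1000, 1000] for reversible and [0, 1000] for irreversible
reactions, the usual COBRA convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

DEFAULT_BOUND = 1000.0

__all__ = [
    "GPRExpression",
    "GeneLeaf",
    "BoolNode",
    "parse_gpr",
    "gpr_to_string",
    "GPRParseError",
    "MetaboliteRecord",
    "ReactionRecord",
    "GeneRecord",
    "MetabolicNetwork",
    "ModelLoadError",
    "read_model",
    "write_model",
]


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

class GPRParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


@dataclass(frozen=True)
class GeneLeaf:
    """A single gene reference inside a GPR rule."""

    gene: str

    def genes(self) -> set[str]:
        return {self.gene}

    def evaluate(self, states: Mapping[str, bool]) -> bool:
        return bool(states.get(self.gene, True))

    def aggregate(self, scores: Mapping[str, float], default: float) -> float:
        return float(scores.get(self.gene, default))


@dataclass(frozen=True)
class BoolNode:
    """An AND/OR node over two or more child expressions.

    AND encodes enzyme complexes (all subunits needed, score = min of the
    children); OR encodes isozymes (any suffices, score = max).
    """

    op: str  # "and" | "or"
    children: tuple["GPRExpression", ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("GPR boolean node needs >= 2 children")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, states: Mapping[str, bool]) -> bool:
        vals = (c.evaluate(states) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def aggregate(self, scores: Mapping[str, float], default: float) -> float:
        vals = [c.aggregate(scores, default) for c in self.children]
        return min(vals) if self.op == "and" else max(vals)


GPRExpression = GeneLeaf | BoolNode


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            tokens.append((rule[i:j], i))
            i = j
    return tokens


def parse_gpr(rule: str) -> GPRExpression | None:
    """Parse a GPR rule string into an expression tree.

    ``and`` binds tighter than ``or`` (COBRA convention); both operators are
    case-insensitive; parentheses override precedence.  An empty or
    whitespace-only string yields ``None`` (no gene association).
    """
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def error(msg: str, at: int) -> GPRParseError:
        return GPRParseError(f"{msg} at position {at} in rule {rule!r}")

    def parse_or() -> GPRExpression:
        nonlocal pos
        terms = [parse_and()]
        while (tk := peek()) is not None and tk[0].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else BoolNode("or", tuple(terms))

    def parse_and() -> GPRExpression:
        nonlocal pos
        factors = [parse_factor()]
        while (tk := peek()) is not None and tk[0].lower() == "and":
            pos += 1
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else BoolNode("and", tuple(factors))

    def parse_factor() -> GPRExpression:
        nonlocal pos
        tk = peek()
        if tk is None:
            raise error("dangling operator or empty group", len(rule))
        tok, at = tk
        if tok == "(":
            pos += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise error("unbalanced parenthesis", at)
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise error(f"unexpected token {tok!r}", at)
        pos += 1
        return GeneLeaf(tok)

    tree = parse_or()
    if pos != len(tokens):
        raise error(f"unexpected token {tokens[pos][0]!r}", tokens[pos][1])
    return tree


def gpr_to_string(expr: GPRExpression | None) -> str:
    """Serialize an expression tree back to a rule string.

    The output re-parses to an identical tree; child OR groups under an AND
    node are parenthesized, redundant parentheses are not emitted.
    """
    if expr is None:
        return ""
    if isinstance(expr, GeneLeaf):
        return expr.gene

    def fmt(child: GPRExpression, parent_op: str) -> str:
        s = gpr_to_string(child)
        if isinstance(child, BoolNode) and parent_op == "and" and child.op == "or":
            return f"({s})"
        return s

    return f" {expr.op} ".join(fmt(c, expr.op) for c in expr.children)


# ---------------------------------------------------------------------------
# Network records
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteRecord:
    id: str
    compartment: str = "c"
    name: str | None = None


@dataclass
class GeneRecord:
    id: str
    name: str | None = None


@dataclass
class ReactionRecord:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression | None = None
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


class ModelLoadError(ValueError):
    """Raised when an on-disk model violates the network invariants."""


@dataclass
class MetabolicNetwork:
    metabolites: list[MetaboliteRecord]
    reactions: list[ReactionRecord]
    genes: list[GeneRecord] = field(default_factory=list)
    objective_reaction: str | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelLoadError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelLoadError("duplicate reaction ids")
        missing: list[str] = []
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    missing.append(f"{r.id} -> {m}")
        if missing:
            raise ModelLoadError(
                "reactions reference unknown metabolites: " + ", ".join(missing)
            )
        known_genes = {g.id for g in self.genes}
        gpr_genes = set()
        for r in self.reactions:
            gpr_genes |= r.genes()
        orphans = gpr_genes - known_genes
        if orphans:
            # Auto-register genes only referenced by rules; keeps the
            # gene list invariant without forcing callers to maintain it.
            for g in sorted(orphans):
                self.genes.append(GeneRecord(g))
        if self.objective_reaction is not None and self.objective_reaction not in self._rxn_index:
            raise ModelLoadError(f"objective reaction {self.objective_reaction!r} not in model")

    # -- lookups ------------------------------------------------------------

    def reaction(self, rid: str) -> ReactionRecord:
        return self.reactions[self._rxn_index[rid]]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    # -- derived matrices ---------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); column j is reaction j."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[self._met_index[met], j] = coef
        return S

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            genes=[replace(g) for g in self.genes],
            objective_reaction=self.objective_reaction,
            id=self.id,
        )

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when clean)."""
        problems: list[str] = []
        S = self.stoichiometric_matrix()
        for j, r in enumerate(self.reactions):
            col = {self.metabolites[i].id: S[i, j] for i in np.nonzero(S[:, j])[0]}
            if col != {m: c for m, c in r.stoichiometry.items() if c != 0}:
                problems.append(f"S column of {r.id} disagrees with its stoichiometry map")
            if r.lower_bound > r.upper_bound:
                problems.append(f"{r.id}: crossed bounds")
        for m in self.metabolites:
            if not m.compartment:
                problems.append(f"metabolite {m.id}: empty compartment")
        if self.objective_reaction is None:
            problems.append("objective reaction unset")
        return problems


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DIALECTS = ("sbml", "cobra-json", "tsv-triple")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "cobra-json"
    if suffix in (".tsv", ".txt"):
        return "tsv-triple"
    raise ValueError(f"cannot infer model dialect from {path.name!r}")


def read_model(path: str | Path, dialect: str | None = None) -> MetabolicNetwork:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "cobra-json":
        net = _read_cobra_json(path)
    elif dialect == "tsv-triple":
        net = _read_tsv(path)
    else:
        net = _read_sbml(path)
    if net.objective_reaction is None:
        warnings.warn(f"model {path.name}: no objective reaction set", stacklevel=2)
    return net


def write_model(net: MetabolicNetwork, path: str | Path, dialect: str | None = None) -> Path:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "cobra-json":
        _write_cobra_json(net, path)
    elif dialect == "tsv-triple":
        _write_tsv(net, path)
    elif dialect == "sbml":
        _write_sbml(net, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    return path


# -- COBRA JSON -------------------------------------------------------------

def _read_cobra_json(path: Path) -> MetabolicNetwork:
    data = json.loads(path.read_text())
    mets = [
        MetaboliteRecord(m["id"], m.get("compartment") or _compartment_of(m["id"]), m.get("name"))
        for m in data.get("metabolites", [])
    ]
    genes = [GeneRecord(g["id"], g.get("name")) for g in data.get("genes", [])]
    rxns: list[ReactionRecord] = []
    objective = None
    for r in data.get("reactions", []):
        lb = r.get("lower_bound")
        ub = r.get("upper_bound")
        if lb is None and ub is None:
            lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        rxns.append(
            ReactionRecord(
                id=r["id"],
                stoichiometry={m: float(c) for m, c in r["metabolites"].items()},
                lower_bound=float(lb if lb is not None else 0.0),
                upper_bound=float(ub if ub is not None else DEFAULT_BOUND),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem") or None,
            )
        )
        if r.get("objective_coefficient"):
            objective = r["id"]
    return MetabolicNetwork(mets, rxns, genes, objective, id=data.get("id", path.stem))


def _write_cobra_json(net: MetabolicNetwork, path: Path) -> None:
    data = {
        "id": net.id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, **({"name": m.name} if m.name else {})}
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                **({"gene_reaction_rule": gpr_to_string(r.gpr)} if r.gpr else {}),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                **(
                    {"objective_coefficient": 1.0}
                    if r.id == net.objective_reaction
                    else {}
                ),
            }
            for r in net.reactions
        ],
        "genes": [
            {"id": g.id, **({"name": g.name} if g.name else {})} for g in net.genes
        ],
    }
    path.write_text(json.dumps(data, indent=1, sort_keys=False) + "\n")


# -- TSV fixture dialect ----------------------------------------------------
#
# Columns: reaction_id, stoichiometry ("met:coef" space-separated),
# lower_bound, upper_bound, gpr, objective (0/1).  Compartment of a
# metabolite is its trailing "_x" tag.

_TSV_HEADER = ["reaction_id", "stoichiometry", "lower_bound", "upper_bound", "gpr", "objective"]


def _compartment_of(met_id: str) -> str:
    return met_id.rsplit("_", 1)[1] if "_" in met_id else "c"


def _read_tsv(path: Path) -> MetabolicNetwork:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ModelLoadError(f"{path}: empty model file")
    header = lines[0].split("\t")
    if header[: len(_TSV_HEADER)] != _TSV_HEADER:
        raise ModelLoadError(f"{path}: expected header {_TSV_HEADER}, got {header}")
    rxns: list[ReactionRecord] = []
    met_ids: dict[str, None] = {}
    objective = None
    for ln in lines[1:]:
        fields = ln.split("\t")
        rid, stoich_s, lb_s, ub_s = fields[0], fields[1], fields[2], fields[3]
        gpr_s = fields[4] if len(fields) > 4 else ""
        obj_s = fields[5] if len(fields) > 5 else "0"
        stoich: dict[str, float] = {}
        for term in stoich_s.split():
            met, coef = term.rsplit(":", 1)
            stoich[met] = float(coef)
            met_ids.setdefault(met)
        rxns.append(
            ReactionRecord(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(lb_s) if lb_s else -DEFAULT_BOUND,
                upper_bound=float(ub_s) if ub_s else DEFAULT_BOUND,
                gpr=parse_gpr(gpr_s),
            )
        )
        if obj_s.strip() == "1":
            objective = rid
    mets = [MetaboliteRecord(m, _compartment_of(m)) for m in met_ids]
    return MetabolicNetwork(mets, rxns, [], objective, id=path.stem)


def _write_tsv(net: MetabolicNetwork, path: Path) -> None:
    rows = ["\t".join(_TSV_HEADER)]
    for r in net.reactions:
        stoich = " ".join(f"{m}:{c:g}" for m, c in r.stoichiometry.items())
        rows.append(
            "\t".join(
                [
                    r.id,
                    stoich,
                    f"{r.lower_bound:g}",
                    f"{r.upper_bound:g}",
                    gpr_to_string(r.gpr),
                    "1" if r.id == net.objective_reaction else "0",
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")


# -- SBML L3 + FBC ----------------------------------------------------------

def _read_sbml(path: Path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromString(path.read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelLoadError(f"{path}: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ModelLoadError(f"{path}: no model element")
    fbc = model.getPlugin("fbc")

    mets = [
        MetaboliteRecord(
            s.getId(), s.getCompartment() or "c", s.getName() or None
        )
        for s in model.getListOfSpecies()
    ]
    genes = []
    if fbc is not None:
        genes = [
            GeneRecord(gp.getLabel() or gp.getId(), gp.getName() or None)
            for gp in fbc.getListOfGeneProducts()
        ]
    gp_label = {g.id: g.id for g in genes}
    if fbc is not None:
        gp_label = {
            gp.getId(): (gp.getLabel() or gp.getId())
            for gp in fbc.getListOfGeneProducts()
        }

    def _param(pid: str, default: float) -> float:
        p = model.getParameter(pid)
        return p.getValue() if p is not None else default

    def _assoc_to_gpr(assoc) -> GPRExpression | None:
        import libsbml as _ls

        if assoc is None:
            return None
        if isinstance(assoc, _ls.GeneProductRef):
            return GeneLeaf(gp_label.get(assoc.getGeneProduct(), assoc.getGeneProduct()))
        if isinstance(assoc, (_ls.FbcAnd, _ls.FbcOr)):
            op = "and" if isinstance(assoc, _ls.FbcAnd) else "or"
            children = tuple(
                c
                for c in (_assoc_to_gpr(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations()))
                if c is not None
            )
            if len(children) == 1:
                return children[0]
            return BoolNode(op, children)
        return None

    rxns: list[ReactionRecord] = []
    for rx in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rx.getNumReactants()):
            sr = rx.getReactant(i)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for i in range(rx.getNumProducts()):
            sr = rx.getProduct(i)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.getLowerFluxBound():
            lb = _param(rfbc.getLowerFluxBound(), -DEFAULT_BOUND)
            ub = _param(rfbc.getUpperFluxBound(), DEFAULT_BOUND)
        else:
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
            ub = DEFAULT_BOUND
        gpr = None
        if rfbc is not None:
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _assoc_to_gpr(gpa.getAssociation())
        rxns.append(ReactionRecord(rx.getId(), stoich, lb, ub, gpr))

    objective = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getCoefficient():
                objective = fo.getReaction()
    return MetabolicNetwork(mets, rxns, genes, objective, id=model.getId() or path.stem)


def _write_sbml(net: MetabolicNetwork, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(net.id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({m.compartment for m in net.metabolites})
    for c in comps:
        comp = model.createCompartment()
        comp.setId(c)
        comp.setConstant(True)
    for m in net.metabolites:
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setCompartment(m.compartment)
        if m.name:
            sp.setName(m.name)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for g in net.genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + g.id.replace("-", "_"))
        gp.setLabel(g.id)
        if g.name:
            gp.setName(g.name)
    gid_of = {g.id: "G_" + g.id.replace("-", "_") for g in net.genes}

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def _set_assoc(parent, expr: GPRExpression) -> None:
        if isinstance(expr, GeneLeaf):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(gid_of[expr.gene])
        elif expr.op == "and":
            node = parent.createAnd()
            for c in expr.children:
                _set_assoc(node, c)
        else:
            node = parent.createOr()
            for c in expr.children:
                _set_assoc(node, c)

    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met, coef in r.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(met)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(r.upper_bound))
        if r.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            _set_assoc(gpa, r.gpr)

    if net.objective_reaction is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(net.objective_reaction)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    path.write_text(libsbml.writeSBMLToString(doc))


# ---------------------------------------------------------------------------
# Equality helpers (used by round-trip tests and compare tooling)
# ---------------------------------------------------------------------------

def gpr_truth_table_equal(a: GPRExpression | None, b: GPRExpression | None) -> bool:
    """Compare two GPRs by truth table over all assignments of their genes."""
    if a is None or b is None:
        return a is b or (a is None and b is None)
    genes = sorted(a.genes() | b.genes())
    if len(genes) > 16:
        raise ValueError("truth-table comparison limited to 16 genes")
    for mask in range(1 << len(genes)):
        states = {g: bool(mask >> i & 1) for i, g in enumerate(genes)}
        if a.evaluate(states) != b.evaluate(states):
            return False
    return True


def networks_equivalent(a: MetabolicNetwork, b: MetabolicNetwork, tol: float = 1e-9) -> bool:
    """Structural equivalence: same ids, stoichiometry, bounds, objective,
    and GPR truth tables (reaction/metabolite order ignored)."""
    if set(a.reaction_ids()) != set(b.reaction_ids()):
        return False
    if set(a.metabolite_ids()) != set(b.metabolite_ids()):
        return False
    if a.objective_reaction != b.objective_reaction:
        return False
    for rid in a.reaction_ids():
        ra, rb = a.reaction(rid), b.reaction(rid)
        if abs(ra.lower_bound - rb.lower_bound) > tol:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > tol:
            return False
        mets = set(ra.stoichiometry) | set(rb.stoichiometry)
        for m in mets:
            if abs(ra.stoichiometry.get(m, 0.0) - rb.stoichiometry.get(m, 0.0)) > tol:
                return False
        if not gpr_truth_table_equal(ra.gpr, rb.gpr):
            return False
    return True
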