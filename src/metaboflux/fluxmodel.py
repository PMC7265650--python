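"""Expression-constrained flux balance analysis (FBA) and pathway flux activities.

The model is a constraint-based metabolic network: stoichiometric matrix S,
flux bounds, a biomass objective and gene-protein-reaction (GPR) rules.
Plain FBA maximizes biomass flux subject to steady state (S v = 0) and the
bounds; parsimonious FBA (pFBA) additionally minimizes total absolute flux
among biomass-optimal solutions, giving a canonical flux vector.

Expression data enter through a modified E-flux scheme: per sample, the GPR
of each reaction is resolved numerically (OR = sum, AND = min), the
resulting reaction scores are max-min normalized to [0, 1] within the
sample, and each scored reaction's bounds are scaled by its score.  The
per-pathway "flux activity" is then the sum of absolute optimal fluxes of
the pathway's reactions — a pathway-level summary comparable across samples.

Flux units follow the COBRA convention, mmol . gDW^-1 . h^-1; unbounded
reactions default to |bound| = 1000 so that score x bound stays finite.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import lil_matrix, identity, hstack, vstack, csr_matrix

from .gpr import GprTree, parse_gpr, evaluate_gpr
from .omics import OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0  # COBRA convention for "unbounded"
MASS_BALANCE_TOL = 1e-6


class ModelError(ValueError):
    """Raised for inconsistent metabolic model definitions."""


class SolverError(RuntimeError):
    """Raised when an LP that must be optimal is not."""


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""


@dataclass
class Reaction:
    """A (possibly reversible) reaction with stoichiometry and bounds.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed).  ``gpr`` is the raw rule text; the parsed tree is cached.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    gpr: str | None = None
    _gpr_tree: GprTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelError(f"reaction {self.id}: lb {self.lower_bound} > ub {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction: all stoichiometric coefficients share one sign."""
        coefs = list(self.stoichiometry.values())
        return all(c <= 0 for c in coefs) or all(c >= 0 for c in coefs)

    def gpr_tree(self) -> GprTree | None:
        if self.gpr and self._gpr_tree is None:
            object.__setattr__(self, "_gpr_tree", parse_gpr(self.gpr))
        return self._gpr_tree


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds, GPRs, subsystem labels and a biomass objective."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective: str  # reaction id of the biomass reaction

    def __post_init__(self):
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise ModelError(f"reaction {r.id} references unknown metabolites {sorted(unknown)}")
        if self.objective not in set(rxn_ids):
            raise ModelError(f"objective reaction {self.objective!r} not in model")

    # ------------------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions:
            t = r.gpr_tree()
            if t is not None:
                out |= t.genes()
        return sorted(out)

    @property
    def subsystems(self) -> list[str]:
        return sorted({r.subsystem for r in self.reactions if r.subsystem})

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ModelError(f"unknown reaction {rid!r}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        midx = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[midx[m], j] = c
        return S

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[Metabolite(m.id, m.compartment, m.name) for m in self.metabolites],
            reactions=[
                Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                         r.subsystem, r.gpr)
                for r in self.reactions
            ],
            objective=self.objective,
        )

    def summary(self) -> dict:
        return {
            "n_genes": len(self.genes),
            "n_metabolites": len(self.metabolites),
            "n_reactions": len(self.reactions),
            "n_subsystems": len(self.subsystems),
            "subsystems": self.subsystems,
        }

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        """Serialize to the packaged JSON dialect (sorted keys, stable floats)."""
        doc = {
            "id": self.id,
            "objective": self.objective,
            "metabolites": [
                {"id": m.id, "compartment": m.compartment, "name": m.name}
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "subsystem": r.subsystem,
                    "gpr": r.gpr,
                }
                for r in self.reactions
            ],
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MetabolicModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            id=doc["id"],
            metabolites=[Metabolite(**m) for m in doc["metabolites"]],
            reactions=[
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    subsystem=r.get("subsystem", ""),
                    gpr=r.get("gpr"),
                )
                for r in doc["reactions"]
            ],
            objective=doc["objective"],
        )


# ----------------------------------------------------------------------
# SBML level 3 + FBC I/O
# ----------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path) -> None:
    """Write SBML Level 3 with the FBC package (bounds, objective, GPRs)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for cid in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{m.id}")
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for gid in _all_gene_ids(model):
        gp = mplug.createGeneProduct()
        gp.setId(f"G_{_sbml_safe(gid)}")
        gp.setLabel(gid)

    bound_ids: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(f"R_{r.id}")
        rx.setFast(False)
        rx.setReversible(r.reversible)
        for met, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(f"M_{met}")
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(r.lower_bound))
        rplug.setUpperFluxBound(_bound_param(r.upper_bound))
        if r.gpr:
            ga = rplug.createGeneProductAssociation()
            # match by gene-product label (the original gene id); never
            # auto-create products, they were declared above
            ga.setAssociation(r.gpr_tree().to_string(), False, False)
        if r.subsystem:
            rx.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>SUBSYSTEM: {r.subsystem}</p></body>'
            )
    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(f"R_{model.objective}")
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))


def _sbml_safe(gid: str) -> str:
    return gid.replace("-", "__").replace(".", "_")


def _all_gene_ids(model: MetabolicModel) -> list[str]:
    return model.genes


def read_sbml(path) -> MetabolicModel:
    """Read SBML L3/FBC into a :class:`MetabolicModel`; raises on parse errors."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    sm = doc.getModel()
    if sm is None:
        raise ModelError("SBML file contains no model")
    mplug = sm.getPlugin("fbc")

    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def strip(mid: str) -> str:
        return mid[2:] if mid.startswith("M_") else mid

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        metabolites.append(Metabolite(strip(sp.getId()), sp.getCompartment(), sp.getName()))
    known = {m.id for m in metabolites}

    params = {sm.getParameter(i).getId(): sm.getParameter(i).getValue()
              for i in range(sm.getNumParameters())}

    objective_rxn = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        ao = mplug.getActiveObjective()
        if ao.getNumFluxObjectives() > 0:
            objective_rxn = ao.getFluxObjective(0).getReaction()

    reactions = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid = rx.getId()
        rid_clean = rid[2:] if rid.startswith("R_") else rid
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            mid = strip(sr.getSpecies())
            if mid in known:
                stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            mid = strip(sr.getSpecies())
            if mid in known:
                stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND if rx.getReversible() else 0.0, DEFAULT_BOUND
        gpr_text = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
            ga = rplug.getGeneProductAssociation()
            if ga is not None and ga.getAssociation() is not None:
                gpr_text = _fbc_to_gpr(ga.getAssociation(), gene_labels)
        subsystem = ""
        if rx.isSetNotes():
            notes = rx.getNotesString()
            marker = "SUBSYSTEM:"
            if marker in notes:
                subsystem = notes.split(marker, 1)[1].split("<", 1)[0].strip()
        reactions.append(Reaction(rid_clean, stoich, lb, ub, subsystem, gpr_text))

    if objective_rxn is None:
        raise ModelError("SBML model defines no active flux objective")
    obj_clean = objective_rxn[2:] if objective_rxn.startswith("R_") else objective_rxn
    return MetabolicModel(sm.getId() or "sbml_model", metabolites, reactions, obj_clean)


def _fbc_to_gpr(assoc, gene_labels: dict[str, str]) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return gene_labels.get(gid, gid)
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_fbc_to_gpr(assoc.getAssociation(i), gene_labels)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_fbc_to_gpr(assoc.getAssociation(i), gene_labels)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelError(f"unsupported FBC association node {type(assoc)}")


def read_model(path, dialect: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML or the packaged JSON dialect.

    Dialect is inferred from the extension when not given.
    """
    path = str(path)
    if dialect is None:
        dialect = "json" if path.endswith(".json") else "sbml"
    if dialect == "json":
        model = MetabolicModel.from_json(path)
    elif dialect == "sbml":
        model = read_sbml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info("read model %s: %s", model.id,
                {k: v for k, v in model.summary().items() if k != "subsystems"})
    failures = []
    for r in model.reactions:
        if not r.gpr:
            continue
        try:
            r.gpr_tree()
        except Exception as err:  # noqa: BLE001 - report, do not abort the read
            failures.append((r.id, str(err)))
    if failures:
        logger.warning("GPR rules failed to parse for %d reactions: %s",
                       len(failures), failures[:5])
    return model


# ----------------------------------------------------------------------
# E-flux machinery
# ----------------------------------------------------------------------

def reaction_gpr_scores(
    model: MetabolicModel,
    gene_values: Mapping[str, float],
    missing_policy: str = "drop",
) -> dict[str, float]:
    """Resolve every reaction's GPR against one sample's expression values.

    Reactions without a GPR, or whose GPR is entirely unmeasured, are absent
    from the result (left unconstrained by E-flux).
    """
    scores: dict[str, float] = {}
    for r in model.reactions:
        try:
            tree = r.gpr_tree()
        except Exception:
            logger.warning("unparseable GPR on %s: reaction left unconstrained", r.id)
            continue
        if tree is None:
            continue
        val = evaluate_gpr(tree, gene_values, missing_policy)
        if val is not None:
            scores[r.id] = val
    return scores


def maxmin_normalize(scores: Mapping[str, float]) -> dict[str, float]:
    """Max-min normalize reaction scores to [0, 1] within one sample.

    Degenerate all-equal scores normalize to 1 (unconstrained), logged.
    """
    if not scores:
        return {}
    vals = np.asarray(list(scores.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        logger.warning("max-min normalization degenerate (all scores equal %.3g): using 1.0", hi)
        return {k: 1.0 for k in scores}
    return {k: (float(v) - lo) / (hi - lo) for k, v in scores.items()}


def apply_eflux_bounds(
    model: MetabolicModel,
    normalized: Mapping[str, float],
    symmetric: bool = True,
) -> MetabolicModel:
    """Scale reaction bounds by normalized expression scores (E-flux).

    Both bounds are scaled by default so reversible reactions shrink
    symmetrically; ``symmetric=False`` scales the upper bound only.
    Exchange reactions are never constrained by expression (GPRs do not
    gate the availability of the medium); unscored reactions are unchanged.
    """
    out = model.copy()
    for r in out.reactions:
        if r.id not in normalized or r.is_exchange:
            continue
        s = float(normalized[r.id])
        if not (0.0 <= s <= 1.0):
            raise ModelError(f"normalized score for {r.id} outside [0,1]: {s}")
        r.upper_bound = s * r.upper_bound
        if symmetric:
            r.lower_bound = s * r.lower_bound
        elif r.lower_bound > r.upper_bound:
            r.lower_bound = r.upper_bound
    return out


# ----------------------------------------------------------------------
# Linear programming
# ----------------------------------------------------------------------

@dataclass
class FluxSolution:
    """Optimal fluxes for one LP instance (one sample)."""

    fluxes: pd.Series  # per-reaction flux, indexed by reaction id
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded" | solver message
    sample_id: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def run_fba(model: MetabolicModel, variant: str = "pfba") -> FluxSolution:
    """Maximize biomass flux by linear programming.

    ``variant="fba"`` returns any optimizer of the biomass LP;
    ``variant="pfba"`` (default) additionally minimizes total absolute flux
    at the fixed biomass optimum (split-variable formulation), which makes
    the reported flux vector canonical.
    """
    if variant not in ("fba", "pfba"):
        raise ValueError(f"unknown FBA variant {variant!r}")
    S = csr_matrix(model.stoichiometric_matrix())
    n = len(model.reactions)
    bounds = model.bounds()
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective)] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution(pd.Series(dtype=float), math.nan, "infeasible")
    if res.status == 3:
        return FluxSolution(pd.Series(dtype=float), math.nan, "unbounded")
    if not res.success:
        return FluxSolution(pd.Series(dtype=float), math.nan, res.message)
    opt = -res.fun
    v = res.x
    if variant == "pfba":
        v = _pfba_vector(S, bounds, c, opt, n, model.reaction_ids)
    return FluxSolution(pd.Series(v, index=model.reaction_ids), opt, "optimal")


def _pfba_vector(S: csr_matrix, bounds, c_obj: np.ndarray, opt: float, n: int,
                 reaction_ids: list[str]) -> np.ndarray:
    """Minimize sum |v| subject to S v = 0, bounds, and objective = opt.

    Split v = p - q with p, q >= 0; minimize 1'p + 1'q, with a tiny
    deterministic per-reaction perturbation (ordered by reaction id) so that
    ties between equally parsimonious flux patterns — e.g. parallel routes
    of equal length — resolve identically regardless of variable ordering.
    """
    A_eq = hstack([S, -S], format="csr")
    A_eq = vstack([A_eq, csr_matrix(np.concatenate([-c_obj, c_obj]))], format="csr")
    b_eq = np.zeros(S.shape[0] + 1)
    b_eq[-1] = opt
    # p - q must respect the original bounds: lb <= p - q <= ub
    eye = identity(n, format="csr")
    A_ub = vstack([hstack([eye, -eye]), hstack([-eye, eye])], format="csr")
    ub_arr = np.array([b[1] for b in bounds], dtype=float)
    lb_arr = np.array([b[0] for b in bounds], dtype=float)
    b_ub = np.concatenate([ub_arr, -lb_arr])
    id_rank = np.argsort(np.argsort(reaction_ids)).astype(float)
    eps = 1e-6 * (id_rank + 1.0)
    cost = np.concatenate([1.0 + eps, 1.0 + 2.0 * eps])
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (2 * n), method="highs")
    if not res.success:
        raise SolverError(f"pFBA stage failed: {res.message}")
    return res.x[:n] - res.x[n:]


def check_mass_balance(model: MetabolicModel, solution: FluxSolution,
                       tol: float = MASS_BALANCE_TOL) -> float:
    """Return max |S v|; raises if above tolerance."""
    S = model.stoichiometric_matrix()
    resid = float(np.abs(S @ solution.fluxes.reindex(model.reaction_ids).to_numpy()).max())
    if resid > tol:
        raise SolverError(f"mass balance violated: max |S v| = {resid:.3g} > {tol}")
    return resid


def flux_activity(solution: FluxSolution, model: MetabolicModel) -> pd.Series:
    """Per-pathway sum of absolute fluxes over the pathway's reactions.

    The index is the model's full subsystem set; pathways whose reactions
    carry no flux report 0.
    """
    if not solution.optimal:
        raise SolverError("flux activities require an optimal solution")
    acts = {s: 0.0 for s in model.subsystems}
    for r in model.reactions:
        if r.subsystem:
            acts[r.subsystem] += abs(float(solution.fluxes[r.id]))
    return pd.Series(acts).sort_index()


def per_sample_fba(
    model: MetabolicModel,
    genes: OmicsMatrix,
    variant: str = "pfba",
    missing_policy: str = "drop",
    symmetric: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """E-flux FBA per sample: GPR resolution -> max-min -> bounds -> LP -> activities.

    Returns the per-sample growth rates and the pathway x sample flux
    activity matrix.  Raises if the expression matrix shares no gene ids
    with the model; the overlap fraction is logged.
    """
    model_genes = set(model.genes)
    overlap = model_genes & set(genes.feature_ids)
    if not overlap:
        raise ModelError("no overlap between expression features and model genes")
    frac = len(overlap) / len(model_genes) if model_genes else 0.0
    logger.info("expression covers %d/%d model genes (%.0f%%)",
                len(overlap), len(model_genes), 100 * frac)
    expr = genes.to_frame()
    growth = {}
    activities = {}
    for sample in genes.sample_ids:
        col = expr[sample].dropna()
        gene_values = {g: float(col[g]) for g in overlap if g in col.index}
        scores = reaction_gpr_scores(model, gene_values, missing_policy)
        normalized = maxmin_normalize(scores)
        constrained = apply_eflux_bounds(model, normalized, symmetric=symmetric)
        sol = run_fba(constrained, variant=variant)
        if not sol.optimal:
            raise SolverError(f"sample {sample}: LP status {sol.status}")
        sol.sample_id = sample
        growth[sample] = sol.objective_value
        activities[sample] = flux_activity(sol, model)
    growth_s = pd.Series(growth, name="growth")
    act_df = pd.DataFrame(activities)  # pathways x samples
    return growth_s, act_df
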