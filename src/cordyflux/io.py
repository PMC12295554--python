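"""Model readers and writers: SBML Level 3 + FBC v2, and a TSV dialect.

The TSV dialect is a directory holding two tab-separated tables, designed to
be human-diffable:

``reactions.tsv``
    columns ``id, name, equation, lb, ub, gpr, ec``; the equation string uses
    compartment-suffixed metabolite ids (``2 A[c] + B[c] => C[e]``), ``=>``
    for irreversible and ``<=>`` for reversible reactions, and an empty
    right-hand side for exchange sinks (``glc[e] <=>``).  Bounds are
    mandatory — a missing bound is an error, never silently defaulted.
``metabolites.tsv``
    columns ``id, name, compartment, formula``.

SBML ids cannot contain brackets, so ``glc[e]`` is written as ``M_glc_e``
(species, with the compartment also stored as the SBML compartment attribute)
and ``R_<id>`` for reactions; the mapping is inverted on read.  Flux bounds
are FBC parameters and GPRs are ``fbc:geneProductAssociation`` elements, with
a fallback to legacy ``GENE_ASSOCIATION:`` notes for models exported by older
toolchains.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

import pandas as pd

from .core import (
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    format_formula,
    parse_equation,
    parse_formula,
)
from .gpr import parse_gpr

log = logging.getLogger(__name__)


class ModelFormatError(ValueError):
    """Raised for malformed model files, with file/element context."""


# --------------------------------------------------------------------------
# TSV dialect
# --------------------------------------------------------------------------

_REACTION_COLUMNS = ["id", "name", "equation", "lb", "ub", "gpr", "ec"]
_METABOLITE_COLUMNS = ["id", "name", "compartment", "formula"]


def _infer_exchange(stoich: dict[str, float], model: MetabolicModel) -> bool:
    if len(stoich) != 1:
        return False
    (met_id,) = stoich
    met = model.metabolites.get(met_id)
    return met is not None and met.compartment == "e"


def read_model_tsv(path: str | Path) -> MetabolicModel:
    path = Path(path)
    rxn_file = path / "reactions.tsv"
    met_file = path / "metabolites.tsv"
    for f in (rxn_file, met_file):
        if not f.exists():
            raise ModelFormatError(f"missing model table {f}")
    mets = pd.read_csv(met_file, sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(rxn_file, sep="\t", dtype=str).fillna("")
    for df, cols, f in ((mets, _METABOLITE_COLUMNS, met_file), (rxns, _REACTION_COLUMNS, rxn_file)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ModelFormatError(f"{f}: missing columns {missing}")
    model = MetabolicModel(model_id=path.name or "model")
    for _, row in mets.iterrows():
        formula = parse_formula(row["formula"]) if row["formula"] else None
        model.add_metabolite(
            Metabolite(id=row["id"], name=row["name"], compartment=row["compartment"], formula=formula)
        )
    objective = None
    for _, row in rxns.iterrows():
        rid = row["id"]
        for col in ("lb", "ub"):
            if row[col] == "":
                raise ModelFormatError(f"{rxn_file}: reaction {rid!r} is missing bound {col!r}")
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ValueError as exc:
            raise ModelFormatError(f"{rxn_file}: reaction {rid!r}: {exc}") from exc
        try:
            rxn = Reaction(
                id=rid,
                name=row["name"],
                stoichiometry=stoich,
                lower_bound=float(row["lb"]),
                upper_bound=float(row["ub"]),
                gpr=row["gpr"],
                ec_numbers=[e for e in row["ec"].split(";") if e],
            )
        except ModelStructureError as exc:
            raise ModelFormatError(f"{rxn_file}: {exc}") from exc
        try:
            rxn.is_exchange = _infer_exchange(stoich, model)
            model.add_reaction(rxn)
        except ModelStructureError as exc:
            raise ModelFormatError(f"{rxn_file}: {exc}") from exc
        if row.get("objective", "") in ("1", "true", "True"):
            objective = rid
    if "objective" in rxns.columns and objective:
        model.objective_reaction_id = objective
    model.validate()
    return model


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": format_formula(m.formula) if m.formula else "",
            }
            for m in model.metabolites.values()
        ],
        columns=_METABOLITE_COLUMNS,
    )
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": r.equation(),
                "lb": repr(r.lower_bound),
                "ub": repr(r.upper_bound),
                "gpr": r.gpr,
                "ec": ";".join(r.ec_numbers),
                "objective": "1" if r.id == model.objective_reaction_id else "",
            }
            for r in model.reactions.values()
        ],
        columns=_REACTION_COLUMNS + ["objective"],
    )
    mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# SBML L3 + FBC v2
# --------------------------------------------------------------------------

_SUFFIX = re.compile(r"^(?P<base>.*)\[(?P<comp>[A-Za-z0-9]+)\]$")
_SBML_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _split_compartment(met_id: str) -> tuple[str, str]:
    m = _SUFFIX.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    return met_id, "c"


def _sbml_species_id(met_id: str) -> str:
    base, comp = _split_compartment(met_id)
    return f"M_{_SBML_SAFE.sub('_', base)}_{comp}"


def _sbml_reaction_id(rxn_id: str) -> str:
    return f"R_{_SBML_SAFE.sub('_', rxn_id)}"


def write_model_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_SBML_SAFE.sub("_", model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(model.compartments):
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        from .core import COMPARTMENT_NAMES

        c.setName(COMPARTMENT_NAMES.get(comp, comp))

    for met in model.metabolites.values():
        s = sbml_model.createSpecies()
        s.setId(_sbml_species_id(met.id))
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        if met.formula:
            s.getPlugin("fbc").setChemicalFormula(format_formula(met.formula))

    # one shared parameter per distinct bound value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    genes_seen: set[str] = set()
    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId(_sbml_reaction_id(rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(_sbml_species_id(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            expr = parse_gpr(rxn.gpr)
            for gene in sorted(expr.genes()):
                gid = f"G_{_SBML_SAFE.sub('_', gene)}"
                if gid not in genes_seen:
                    gp = mplug.createGeneProduct()
                    gp.setId(gid)
                    gp.setLabel(gene)
                    genes_seen.add(gid)
            gpa = rplug.createGeneProductAssociation()
            infix = re.sub(
                r"[^\s()]+",
                lambda m: m.group(0)
                if m.group(0).lower() in ("and", "or")
                else f"G_{_SBML_SAFE.sub('_', m.group(0))}",
                expr.to_string(),
            )
            gpa.setAssociation(infix)
        if rxn.ec_numbers:
            r.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'><p>EC Number: "
                + ";".join(rxn.ec_numbers)
                + "</p></body>"
            )

    if model.objective_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_reaction_id(model.objective_reaction_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


_NOTES_GA = re.compile(r"GENE_ASSOCIATION:\s*([^<]+)")
_NOTES_EC = re.compile(r"EC Number:\s*([^<]+)")


def read_model_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"no such file: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: file contains no SBML model element")

    model = MetabolicModel(model_id=sbml_model.getId() or path.stem)
    for i in range(sbml_model.getNumCompartments()):
        model.compartments.add(sbml_model.getCompartment(i).getId())

    sid_to_mid: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        comp = s.getCompartment()
        base = s.getId()
        if base.startswith("M_"):
            base = base[2:]
        if base.endswith(f"_{comp}"):
            base = base[: -(len(comp) + 1)]
        mid = f"{base}[{comp}]"
        formula = None
        splug = s.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = parse_formula(splug.getChemicalFormula())
        sid_to_mid[s.getId()] = mid
        model.add_metabolite(Metabolite(id=mid, name=s.getName(), compartment=comp, formula=formula))
        if s.isSetAnnotation():
            log.warning("ignoring annotation on species %s", s.getId())

    gene_labels: dict[str, str] = {}
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def param_value(pid: str, rid: str, which: str) -> float:
        p = sbml_model.getParameter(pid)
        if p is None or not p.isSetValue():
            raise ModelFormatError(f"{path}: reaction {rid}: {which} bound parameter {pid!r} undefined")
        return p.getValue()

    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = r.getId()
        if rid.startswith("R_"):
            rid = rid[2:]
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[sid_to_mid[ref.getSpecies()]] = stoich.get(sid_to_mid[ref.getSpecies()], 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[sid_to_mid[ref.getSpecies()]] = stoich.get(sid_to_mid[ref.getSpecies()], 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        if rplug is None or not (rplug.isSetLowerFluxBound() and rplug.isSetUpperFluxBound()):
            raise ModelFormatError(
                f"{path}: reaction {r.getId()} has no FBC flux bounds (bounds are mandatory)"
            )
        lb = param_value(rplug.getLowerFluxBound(), rid, "lower")
        ub = param_value(rplug.getUpperFluxBound(), rid, "upper")
        gpr = ""
        if rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                infix = assoc.toInfix()
                infix = re.sub(
                    r"[^\s()]+",
                    lambda m: m.group(0)
                    if m.group(0).lower() in ("and", "or")
                    else gene_labels.get(m.group(0), m.group(0)[2:] if m.group(0).startswith("G_") else m.group(0)),
                    infix,
                )
                gpr = parse_gpr(infix).to_string()
        notes = r.getNotesString() if r.isSetNotes() else ""
        if not gpr and notes:
            m = _NOTES_GA.search(notes)
            if m:
                gpr = parse_gpr(m.group(1).strip()).to_string()
        ec: list[str] = []
        if notes:
            m = _NOTES_EC.search(notes)
            if m:
                ec = [e.strip() for e in m.group(1).split(";") if e.strip()]
        if math.isnan(lb) or math.isnan(ub):
            raise ModelFormatError(f"{path}: reaction {rid} has NaN bounds")
        try:
            rxn = Reaction(
                id=rid, name=r.getName(), stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                gpr=gpr, ec_numbers=ec,
            )
        except ModelStructureError as exc:
            raise ModelFormatError(f"{path}: {exc}") from exc
        rxn.is_exchange = _infer_exchange(stoich, model)
        model.add_reaction(rxn)
        if r.isSetAnnotation():
            log.warning("ignoring annotation on reaction %s", r.getId())

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            target = obj.getFluxObjective(0).getReaction()
            if target.startswith("R_"):
                target = target[2:]
            if target in model.reactions:
                model.objective_reaction_id = target
    model.validate()
    return model


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML (``.xml``/``.sbml``) or the TSV dialect (a
    directory).  ``format`` may be ``"sbml"`` or ``"tsv"``; inferred from the
    path when omitted."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.is_dir() else "sbml"
    if format == "sbml":
        return read_model_sbml(path)
    if format == "tsv":
        return read_model_tsv(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if format == "sbml":
        write_model_sbml(model, path)
    elif format == "tsv":
        write_model_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
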